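# Methods

## Scope and model

`pvocta` implements the processing chain of a multi-MHz swept-source OCT
angiography (OCTA) system: planning of raster scan protocols, spectral
reconstruction of raw interferograms, phase-variance (PV) flow contrast
with bulk-motion correction, RPE-referenced flattening and depth-windowed
*en face* projection.  Because raw clinical volumes for such systems are
not publicly deposited, the package carries a physics-based interferogram
simulator that serves as ground truth for every downstream stage.  The
simulator is first-class, tested code, not a fixture.

## Forward model (simulator)

A recorded fringe at digitiser sample m is

    I(m) = S(k_m) [ DC + Σ_j 2 √r_j cos( 2 n k_m z_j + θ(k_m) + φ_bulk ) ]
           + F(m) + ε(m)

* `k_m` — wavenumber at sample m.  The sweep is centred on
  k0 = 2π/λ0 (λ0 = 1.065 µm) with a Gaussian spectral envelope of 80 nm
  FWHM; the sampled span is `span_factor` (default 2.0) times the FWHM
  k-bandwidth, and the index→k mapping may be polynomially chirped
  (monotonicity enforced).  With M = 512 samples this yields an axial
  pixel pitch of 0.665 µm in tissue (n = 1.33) after 4× zero-padding and
  a one-sided depth range of ~0.68 mm — a miniature of the full-scale
  geometry (1024 samples, 4096-point transforms, 3.5 mm range) that keeps
  the 4× padding ratio and all processing contracts intact.
* `z_j` — geometric scatterer depths.  Layers place `density` scatterers
  per A-scan uniformly within their thickness; every static scatterer
  additionally gets Gaussian sub-resolution interface roughness
  (σ = 0.25 µm ≈ 0.4 px).  Real interfaces are optically rough; without
  this, a deterministic specular plane stays phase-coherent across the
  field and survives the volume-mean fixed-pattern estimate as a static
  ghost field.
* flow — scatterers inside vessel voxels have their depths re-drawn on
  every B-scan repeat with axial jitter σ_flow.  The preset value
  σ_flow = λ0/(8n) ≈ 0.1 µm gives inter-repeat phase steps of
  ~1.6 rad: essentially full decorrelation, the regime PV OCTA detects.
  Flow is modelled as pure axial phase decorrelation without amplitude
  decorrelation, because phase variance is the contrast under test.
* `φ_bulk` — per-B-scan bulk axial-motion phase, a random walk with
  displacement step σ = λ0/16 per B-scan (phase step ≈ 1.05 rad), or an
  explicit displacement sequence.
* saccades — at a marked BM position the beam sweeps laterally between
  repeats: each repeat images tissue from a progressively shifted row and
  gets an independent bulk phase.  The speckle content itself
  decorrelates, which is what makes saccades *uncorrectable* by a
  per-column phase offset (a pure phase offset would be removed by the
  bulk correction and would leave nothing to reject).
* `F(m)` — a fixed non-interferometric fringe (amplitude 0.5, fixed
  depth) plus the DC envelope; `ε` — additive white detection noise
  (σ = 0.02 on unit-scale fringes, placing tissue speckle comfortably
  above the κ = 3 noise threshold, representative of a well-aligned
  system at the RPE).
* Fringes are quantised to 12 bits at 90% full scale (quantisation scale
  recorded, so reconstruction recovers the real-valued fringes exactly up
  to the quantisation step).

The model is scalar and single-scattering: no speckle correlation between
adjacent A-scans, no multiple scattering, no beam defocus, no fringe
washout at multi-MHz sweep rates.  Passing tests therefore demonstrate
the *processing chain* — not tissue-optics realism.

`retina_small` (64×64 positions, 5 repeats, 512 samples) has three curved
layers — two scattering slabs and a bright specular RPE band (the
brightest return, as in healthy B-scans) — plus two vessel tubes of 30
and 36 µm lumen diameter (typical small retinal arteriole/venule
calibers) running along the slow axis so each B-scan crosses them at the
same columns.  Layer curvature is a low-order polynomial bowl of ±32 µm.

## Reconstruction

1. **k-linearisation.**  The calibration fringe (single reflector at 25%
   of the Nyquist depth, ≥10 cycles) gives an instantaneous analytic
   phase; it is unwrapped, smoothed by a degree-7 polynomial fit (the
   physical sweep is smooth; the fit suppresses Hilbert edge ringing) and
   inverted onto a uniform grid.  Spectra are resampled there by cubic
   spline (natural ends, clamped positions) — sidelobe-safe versus linear
   interpolation.  Non-monotone unwrapped phase rejects the calibration.
2. **Fixed-pattern removal.**  The pattern is estimated as the mean of
   *all* acquired spectra of the volume and subtracted from every A-scan.
   The volume-wide estimate matters for angiography: it is identical for
   all repeats and therefore cancels in inter-repeat phase differences,
   whereas a per-B-scan estimate gives each repeat its own
   sample-contaminated mean whose subtraction injects decorrelated ghosts
   at the depths of moving structure (measured: ~100× higher static PV).
   The estimate has an irreducible sampling residual ∝ signal RMS/√N
   spectra; at full scale (≈5×10⁶ spectra) it is negligible, at miniature
   scale (5–20×10³) it is visible at near-threshold pixels, which is why
   the isolated bulk-motion benchmark below disables this stage.
3. **Dispersion compensation.**  Residual dispersion is a polynomial
   phase θ(ξ) = a₂ξ² + a₃ξ³ on the normalised band coordinate
   ξ = 2(k−k_center)/span ∈ [−1,1] (radians at the band edge).  The
   calibration fringe determines k only up to an affine map, so
   coefficients on an absolute k-axis would not be recoverable from data;
   the normalised form is what the simulator injects and the optimiser
   searches.  Compensation multiplies the analytic spectrum by
   exp(−iθ).  When coefficients are unknown, `optimize_dispersion`
   minimises the Shannon entropy of the reconstructed magnitude image
   (dispersion smears point scatterers, raising entropy) over a coarse
   (a₂, a₃) grid refined by Nelder–Mead; deterministic for a fixed grid.
4. **Apodisation.**  Default Hann window (first sidelobe −31.5 dB,
   magnitude-domain main-lobe broadening ×1.66 versus rectangular);
   the window family is configurable, and PSF-width benchmarks use the
   rectangular window so the Gaussian transform-limit analytics apply.
5. **FFT.**  Analytic signal, zero-padded to 4× the sample count
   (4096 at full scale), one-sided half kept.  Depth pixel 0 is zero path
   difference; the complex-conjugate ambiguity is left unresolved.

All stages are linear and deterministic, so a static noise-free phantom
yields bit-identical complex repeats — the property phase variance rests
on.

## Phase-variance angiography

For the N = 5 repeats of a BM-scan, the N−1 wrapped phase-difference
frames Δφ_i are computed; intensity thresholding (threshold
μ_noise + κσ_noise, κ = 3, noise statistics from the deepest 10% of the
axial range) excludes pixels whose phase is noise.

**Bulk-motion correction** estimates, per A-scan column, the common phase
offset of each difference frame by shifted-histogram mode estimation:
an intensity-weighted circular histogram on a fine grid of
n_bins × n_shifts bins (64 × 4 default) is smoothed with the triangular
kernel that averaging the n_shifts shifted coarse histograms induces, and
the circular argmax is the offset β(x).  Columns with fewer than 8 masked
pixels interpolate β from neighbours through the embedded unit vectors.
The estimator is per-column (axial bulk motion varies along a B-scan in
vivo), resolution ≈ 2π/256 ≈ 0.025 rad, and idempotent to that
resolution.

**Phase variance** is the mean of squared wrapped residuals,

    PV = (1/(N−1)) Σ_i wrap(Δφ_i − β_i)² ,

*without* per-pixel mean subtraction.  This form is zero for identical
repeats, bounded by π², and has expectation π²/3 for fully decorrelated
phases — the calibration the tests pin.  A per-pixel circular-mean-
subtracted variant is available (`center="circular"`) but is biased low
for decorrelated phases at small N (the circular mean follows the few
samples; Monte-Carlo: ×0.49 at N = 5), so it is not the default.
Flow-projection artifacts are deliberately not removed.

## Flattening and en-face projection

The RPE depth is segmented per A-scan as the argmax of the axially
median-smoothed (5 px) mean-intensity profile within the posterior half
of the depth range (the RPE is the dominant posterior reflector; the
band keeps bright inner structure from capturing the argmax).  Columns
whose peak is less than 4× the band median are marked missing (atrophy /
shadow emulation).  The raw surface is fitted with real Zernike
polynomials up to radial order 4 (15 terms) over the unit disk inscribed
in the scan field, corners extrapolated, with one round of outlier
rejection at 3× residual MAD.  Flattening shifts each A-scan by an
integer pixel count (phase and PV values preserved exactly; zero-fill at
the edges, never wrap-around); the reference for depth windows is the
argmax of the volume-mean axial intensity profile of the flattened
volume ("RPE peak").

Motion-corrupted BM positions are rejected when their masked-median PV
exceeds median + max(c·MAD, 0.05 rad²) over positions (c = 5); the
absolute floor keeps the threshold meaningful on quiet volumes where the
MAD is orders of magnitude below any genuine motion effect (decorrelation
raises a row's median PV by O(1) rad²).  Rejected rows are
nearest-neighbour filled (or dropped) in projections and recorded.

En-face projections sum the flattened PV volume over half-open depth
windows specified in µm relative to the RPE peak; presets: joint retina
(−90 µm, 138 µm), choroid 1 (+12 µm, 28–39 µm → midpoint), choroid 2
(+127 µm, 120–180 µm → midpoint).  Projections are cleaned by a 3×3
median then a σ = 1 px Gaussian (kernel sizes are explicit configuration;
the processing order matters — the median removes hot pixels before the
Gaussian can spread them).  Mosaicking registers tile pairs by phase
correlation around nominal offsets and feather-blends overlaps, falling
back to nominal offsets below a correlation floor.

## Benchmarks and their design

* PSF: corrected mirror PSF within 15% of the Gaussian transform limit
  (2 ln2/π)·λ0²/(nΔλ) ≈ 4.70 µm; without k-linearisation or dispersion
  compensation ≥2× broader.  Measured around the reflector depth (the DC
  lobe at zero path difference is skipped).
* Bulk motion: injected uniform (1.2 rad) and near-wrap (π−0.05) offsets
  recovered to ≤0.01 rad on a static phantom *without* DC/fixed-pattern
  terms and with fixed-pattern removal disabled — isolating the bulk
  estimator from the estimator-sampling ghost described above (residual
  static PV 0.1–0.2% of uncorrected).
* Separation: on `retina_small`, vessel/static PV contrast ≈9–11 with
  correction.  Without correction the ratio is ≈2.1–2.8 and has an
  analytic floor near 3 under the preset's bulk walk: static uncorrected
  PV is E[wrap(N(0, 1.05))²] ≈ 1.1 rad² while vessel PV saturates at
  π²/3 ≈ 3.3.  The static reference set excludes vessel columns (2-px
  lateral dilation of the footprint) because axial PSF tails of the lumen
  carry genuine flow signal — the same physics as the flow-projection
  artifact.
* En-face: retina-window projection shows vessel footprints at ≈6–11×
  the vessel-free background.
* Flattening: post-flatten RPE depth spread ≈0.55 px std; synthetic
  defocus surfaces recovered to ≪1%.
* Saccade rejection recovers exactly the injected BM positions.

Problem sizes: 64×64×5×512 for the retina phantom, 32×32×5×512 for the
flow slab, 10⁵ pixels for the PV Monte-Carlo — sizes chosen so the full
suite and the acceptance script each run in a couple of minutes on one
CPU while every contract is exercised at realistic SNR.

## Known limitations

* No speckle correlation between adjacent A-scans; lateral sampling
  effects (the 0.36/0.57 spot-sampling trade-off) are planned, not
  rendered.
* No velocity calibration: σ_flow controls phase decorrelation but no
  claim links it to absolute flow speed.
* Complex-conjugate ambiguity unresolved; sensitivity roll-off and
  fringe washout not modelled.
* The miniature fixed-pattern estimate carries a √N sampling ghost that
  full-scale volumes would not show (see above).
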