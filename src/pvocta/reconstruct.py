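"""Spectral-fringe to complex A-scan reconstruction.

The processing chain mirrors standard swept-source Fourier-domain OCT
practice: (1) resample the fringes from digitiser-sample space to a
uniform wavenumber grid using the instantaneous phase of a single-
reflector calibration fringe (k-clock), (2) subtract the mean spectrum of
each B-scan to remove fixed-pattern structure, (3) cancel residual
dispersion by multiplying the analytic spectrum with exp(-i theta(k)),
(4) apodise to suppress axial point-spread-function sidelobes, and
(5) zero-pad and Fourier transform, keeping the one-sided (positive
depth) half of the spectrum as the complex A-scan.

All operations are linear and deterministic, so static input repeats give
exactly identical complex outputs — the property that makes phase-variance
angiography meaningful downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize
from scipy.signal import hilbert

from .phantom import PAD_FACTOR, RawSpectraVolume, SourceModel


@dataclass
class CalibrationCurve:
    """Sample-index to wavenumber linearisation derived from a k-clock.

    ``psi`` is the unwrapped instantaneous phase of the calibration
    fringe, proportional to k(m) up to an affine map; ``sample_map`` gives,
    for each uniform-k output sample u, the fractional input sample index
    m'(u) at which psi is uniform.
    """

    psi: np.ndarray          # (M,) unwrapped phase, strictly monotone
    sample_map: np.ndarray   # (M,) fractional input indices

    @property
    def n_samples(self) -> int:
        return self.psi.size

    def is_identity(self, tol: float = 1e-3) -> bool:
        m = np.arange(self.n_samples)
        return bool(np.max(np.abs(self.sample_map - m)) < tol)


@dataclass(frozen=True)
class DispersionModel:
    """Residual dispersion as polynomial phase on the normalised band
    coordinate xi = 2(k - k_center)/k_span in [-1, 1]:
    theta(xi) = a2 xi^2 + a3 xi^3, coefficients in radians at band edge.
    Compensation multiplies the analytic spectrum by exp(-i theta)."""

    a2: float = 0.0
    a3: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a2) and math.isfinite(self.a3)):
            raise ValueError("dispersion coefficients must be finite")

    def phase(self, M: int) -> np.ndarray:
        xi = np.linspace(-1.0, 1.0, M)
        return self.a2 * xi ** 2 + self.a3 * xi ** 3


@dataclass
class ComplexVolume:
    """Reconstructed complex A-scans [BM-position][repeat][A-scan][depth].

    Depth pixel 0 is zero optical path difference; depths increase away
    from the reference mirror.  The complex-conjugate ambiguity of real
    spectra is left unresolved (one-sided spectrum, positive depths only).
    """

    data: np.ndarray          # complex64/128
    axial_pitch_um: float
    metadata: dict

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.data) ** 2

    @property
    def n_depth(self) -> int:
        return self.data.shape[-1]


def _analytic(spectra: np.ndarray) -> np.ndarray:
    """One-sided (analytic) representation along the spectral axis."""
    if np.iscomplexobj(spectra):
        return spectra
    return hilbert(spectra, axis=-1)


def calibrate_k(fringe: np.ndarray, smooth_deg: int = 7) -> CalibrationCurve:
    """Recover the k-linearisation map from a calibration fringe.

    The instantaneous phase is taken from the analytic signal, unwrapped,
    and smoothed with a low-order polynomial fit (the physical sweep
    nonlinearity is smooth; the fit suppresses Hilbert edge ringing).  The
    resampling map is the inverse interpolation of the phase onto a
    uniform grid.
    """
    fringe = np.asarray(fringe, dtype=float)
    M = fringe.size
    if M < 32:
        raise ValueError("calibration fringe too short")
    a = hilbert(fringe - fringe.mean())
    psi = np.unwrap(np.angle(a))
    if psi[-1] < psi[0]:
        psi = -psi  # orientation only; a mirror-side reflector flips sign
    total_cycles = (psi[-1] - psi[0]) / (2.0 * math.pi)
    if total_cycles < 10:
        raise ValueError(
            f"calibration fringe has only {total_cycles:.1f} cycles (< 10)")
    m = np.arange(M, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(m, psi, smooth_deg)
    psi_s = np.polynomial.polynomial.polyval(m, coeffs)
    if np.any(np.diff(psi_s) <= 0):
        raise ValueError("calibration phase is not strictly monotone; "
                         "fringe rejected")
    target = np.linspace(psi_s[0], psi_s[-1], M)
    sample_map = np.interp(target, psi_s, m)
    return CalibrationCurve(psi=psi_s, sample_map=sample_map)


def resample_to_k(spectra: np.ndarray, curve: CalibrationCurve) -> np.ndarray:
    """Cubic-spline resample fringes onto the uniform-k grid.

    Works on any array whose last axis is the spectral sample axis; edge
    positions are clamped to the valid sample range.
    """
    spectra = np.asarray(spectra, dtype=float)
    M = spectra.shape[-1]
    if M != curve.n_samples:
        raise ValueError("spectral length does not match calibration")
    pos = np.clip(curve.sample_map, 0.0, M - 1.0)
    flat = spectra.reshape(-1, M)
    cs = CubicSpline(np.arange(M), flat, axis=1, bc_type="natural")
    out = cs(pos)
    return out.reshape(spectra.shape)


def remove_fixed_pattern(spectra: np.ndarray,
                         mode: str = "volume") -> np.ndarray:
    """Subtract the mean interference spectrum (fixed-pattern estimate).

    ``mode='volume'`` (default) estimates the pattern by averaging all
    acquired spectra of the volume and subtracts that single estimate
    from every A-scan.  Averaging over the full volume dilutes any
    structure-specific contribution (sample fringes decorrelate across
    positions), and because the identical field is subtracted from every
    repeat it cancels exactly in inter-repeat phase differences — a
    per-B-scan estimate (``mode='bscan'``) instead leaves each repeat
    with its own residual ghost, which shows up as spurious flow signal
    at the depths of moving structure.

    Accepts a single B-scan ``(n_ascans, M)`` or a volume
    ``(..., n_ascans, M)``.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim < 2 or spectra.shape[-2] < 2:
        raise ValueError("need at least 2 A-scans per B-scan")
    if mode == "bscan":
        return spectra - spectra.mean(axis=-2, keepdims=True)
    if mode != "volume":
        raise ValueError("mode must be 'volume' or 'bscan'")
    axes = tuple(range(spectra.ndim - 1))
    return spectra - spectra.mean(axis=axes, keepdims=True)


def compensate_dispersion(spectra: np.ndarray,
                          model: DispersionModel) -> np.ndarray:
    """Cancel residual dispersion on the analytic spectrum.

    Input may be real (converted to its analytic signal) or already
    complex; output is complex.  Spectra must already be uniform in k.
    """
    a = _analytic(np.asarray(spectra))
    M = a.shape[-1]
    return a * np.exp(-1j * model.phase(M))


def shape_spectrum(spectra: np.ndarray,
                   window: Union[str, np.ndarray] = "hann") -> np.ndarray:
    """Apodise spectra to suppress axial PSF sidelobes.

    ``window`` is a named family ("hann", "hamming", "blackman",
    "rect") or an explicit unit-peak array of matching length.
    """
    spectra = np.asarray(spectra)
    M = spectra.shape[-1]
    if isinstance(window, str):
        if window == "rect":
            return spectra
        try:
            w = {"hann": np.hanning, "hamming": np.hamming,
                 "blackman": np.blackman}[window](M)
        except KeyError:
            raise ValueError(f"unknown window {window!r}") from None
    else:
        w = np.asarray(window, dtype=float)
        if w.shape != (M,):
            raise ValueError("window length must equal spectral length")
        if w.max() > 0:
            w = w / w.max()
    return spectra * w


def fft_reconstruct(spectra: np.ndarray,
                    pad_length: Optional[int] = None) -> np.ndarray:
    """Zero-padded Fourier transform to complex A-scans.

    Real input is first converted to its analytic signal so that the
    one-sided output half carries the full interferometric amplitude.
    ``pad_length`` defaults to ``PAD_FACTOR`` (4) times the spectral
    length, preserving the padding ratio of the full-scale system (1024
    samples -> 4096-point transforms) on miniature volumes.
    """
    a = _analytic(np.asarray(spectra))
    M = a.shape[-1]
    if pad_length is None:
        pad_length = PAD_FACTOR * M
    if pad_length < M:
        raise ValueError("pad_length must be >= spectral length")
    A = np.fft.fft(a, n=pad_length, axis=-1)
    return A[..., : pad_length // 2]


@dataclass(frozen=True)
class ReconstructionOptions:
    window: str = "hann"
    pad_length: Optional[int] = None       # default: 4 x samples
    dispersion: Optional[DispersionModel] = None
    optimize_dispersion: bool = False
    resample: bool = True
    remove_fixed_pattern: bool = True


def _image_entropy(mag: np.ndarray) -> float:
    """Shannon entropy of the normalised magnitude image; sharper images
    concentrate energy and have lower entropy."""
    p = mag.ravel().astype(float)
    s = p.sum()
    if s <= 0:
        return 0.0
    p = p / s
    nz = p[p > 1e-15]
    return float(-(nz * np.log(nz)).sum())


def optimize_dispersion(bscan_spectra: np.ndarray,
                        a2_range: float = 40.0,
                        a3_range: float = 10.0,
                        grid: int = 21,
                        window: str = "hann") -> DispersionModel:
    """Estimate dispersion coefficients from a structured B-scan.

    Searches (a2, a3) for minimum Shannon entropy of the reconstructed
    magnitude image — dispersion smears point scatterers axially, raising
    entropy — with a coarse grid followed by Nelder–Mead refinement.
    Deterministic for a fixed grid.
    """
    spectra = np.asarray(bscan_spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValueError("expected a single B-scan (n_ascans, M)")
    if float(np.abs(spectra - spectra.mean()).max()) < 1e-12:
        warnings.warn("flat B-scan: no structure to optimise dispersion on; "
                      "returning zeros")
        return DispersionModel(0.0, 0.0)
    a = _analytic(spectra)

    def cost(params) -> float:
        a2, a3 = params
        comp = a * np.exp(-1j * DispersionModel(a2, a3).phase(a.shape[-1]))
        mag = np.abs(fft_reconstruct(shape_spectrum(comp, window)))
        return _image_entropy(mag)

    a2_grid = np.linspace(-a2_range, a2_range, grid)
    a3_grid = np.linspace(-a3_range, a3_range, max(grid // 2, 5))
    best, best_c = (0.0, 0.0), math.inf
    for a2 in a2_grid:
        for a3 in a3_grid:
            c = cost((a2, a3))
            if c < best_c:
                best, best_c = (float(a2), float(a3)), c
    res = minimize(cost, best, method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": 400})
    a2, a3 = (res.x if res.fun <= best_c else best)
    return DispersionModel(float(a2), float(a3))


def reconstruct_volume(raw: RawSpectraVolume,
                       options: ReconstructionOptions = ReconstructionOptions()
                       ) -> ComplexVolume:
    """Full chain: raw fringes -> complex volume.

    Stages (each optional via ``options``): k-linearisation from the
    volume's calibration fringe, per-B-scan fixed-pattern removal,
    dispersion compensation (given coefficients, or entropy-optimised on
    the central B-scan), spectral shaping, zero-padded FFT.
    """
    spectra = raw.dequantized()
    meta = dict(raw.metadata)
    curve = None
    if options.resample:
        curve = calibrate_k(raw.calibration_fringe)
        spectra = resample_to_k(spectra, curve)
    if options.remove_fixed_pattern:
        spectra = remove_fixed_pattern(spectra)
    disp = options.dispersion
    if options.optimize_dispersion:
        ny = spectra.shape[0]
        sample = spectra[ny // 2, 0] if spectra.ndim == 4 else spectra
        disp = optimize_dispersion(np.asarray(sample))
    if disp is not None:
        spectra = compensate_dispersion(spectra, disp)
        meta["dispersion"] = {"a2": disp.a2, "a3": disp.a3}
    spectra = shape_spectrum(spectra, options.window)
    data = fft_reconstruct(spectra, options.pad_length).astype(np.complex128)

    source = SourceModel.from_dict(meta["source"])
    n = meta.get("n", 1.33)
    M = source.samples_per_ascan
    pad = options.pad_length if options.pad_length else PAD_FACTOR * M
    pitch = math.pi / (n * source.delta_k * pad)
    meta["window"] = options.window
    meta["pad_length"] = pad
    return ComplexVolume(data=data, axial_pitch_um=pitch, metadata=meta)
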