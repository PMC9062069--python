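"""Phase-variance OCT angiography.

Flow contrast is computed from the N repeated B-scans of each BM-scan:
the N-1 wrapped inter-repeat phase-difference frames are cleaned of the
bulk axial-motion phase common to each A-scan column (shifted-histogram
mode estimation) and their squared wrapped values averaged into a
phase-variance (PV) image.  Moving scatterers decorrelate the phase
between repeats and light up; static tissue stays near zero.  Pixels
below an intensity noise threshold are excluded (set to 0) because phase
is uniformly random where there is no signal.

All phase arithmetic is circular: differences are wrapped to [-pi, pi),
so 0 <= PV <= pi^2 and fully decorrelated phases give E[PV] = pi^2/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .reconstruct import ComplexVolume

PI = math.pi


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap to [-pi, pi)."""
    return (x + PI) % (2.0 * PI) - PI


@dataclass
class NoiseMask:
    """Per-pixel validity from intensity thresholding.

    ``threshold = mu_noise + kappa * sigma_noise`` on the magnitude scale;
    a pixel is valid when its repeat-averaged magnitude exceeds it.
    """

    mask: np.ndarray  # bool, same lateral/depth shape as one B-scan set
    mu_noise: float
    sigma_noise: float
    kappa: float

    @property
    def threshold(self) -> float:
        return self.mu_noise + self.kappa * self.sigma_noise


@dataclass
class AngioVolume:
    """Per-BM-position mean-intensity and phase-variance cross-sections.

    Arrays are ordered [BM-position][A-scan][depth].  ``bulk_offsets``
    holds the estimated per-column bulk phase for each of the N-1
    difference frames.
    """

    mean_intensity: np.ndarray   # float [ny, nx, nz]
    phase_variance: np.ndarray   # float [ny, nx, nz]
    bulk_offsets: np.ndarray     # float [ny, N-1, nx]
    mask: np.ndarray             # bool  [ny, nx, nz]
    axial_pitch_um: float
    metadata: dict = field(default_factory=dict)


def estimate_noise_stats(volume: ComplexVolume,
                         band: Optional[tuple[int, int]] = None
                         ) -> tuple[float, float]:
    """Magnitude statistics of a structure-free depth band.

    ``band`` is a (start, stop) depth-pixel range; the default is the
    deepest 10% of the axial range, which the phantom presets leave
    empty.  Returns (mean, std) of the magnitude there.
    """
    mag = volume.magnitude
    nz = mag.shape[-1]
    if band is None:
        band = (int(round(0.9 * nz)), nz)
    lo, hi = band
    if not (0 <= lo < hi <= nz):
        raise ValueError(f"invalid noise band {band} for depth {nz}")
    vals = mag[..., lo:hi]
    return float(vals.mean()), float(vals.std())


def make_noise_mask(volume: ComplexVolume, kappa: float = 3.0,
                    band: Optional[tuple[int, int]] = None) -> NoiseMask:
    """Threshold the repeat-averaged magnitude at mu + kappa*sigma."""
    mu, sigma = estimate_noise_stats(volume, band)
    mean_mag = volume.magnitude.mean(axis=1)  # average over repeats
    return NoiseMask(mask=mean_mag > (mu + kappa * sigma),
                     mu_noise=mu, sigma_noise=sigma, kappa=kappa)


def bulk_phase_offset(dphi: np.ndarray, weights: np.ndarray,
                      n_bins: int = 64, n_shifts: int = 4,
                      min_pixels: int = 8) -> np.ndarray:
    """Per-A-scan-column bulk phase via shifted-histogram mode estimation.

    For each column of the wrapped phase-difference frame ``dphi``
    (shape (n_ascans, n_depth)), an intensity-weighted circular histogram
    of the phase values is accumulated at ``n_shifts`` sub-bin offsets;
    averaging the shifted histograms is equivalent to smoothing a fine
    histogram (bin width 2*pi/(n_bins*n_shifts)) with a triangular kernel
    of the coarse bin width.  The circular position of the maximum is the
    bulk offset for that column.

    Columns with fewer than ``min_pixels`` weighted pixels get their
    offset by circular interpolation from neighbouring valid columns
    (zero when no column is valid).
    """
    dphi = np.asarray(dphi)
    weights = np.asarray(weights, dtype=float)
    if dphi.shape != weights.shape:
        raise ValueError("dphi and weights must share a shape")
    nx = dphi.shape[0]
    fine = n_bins * n_shifts
    edges = np.linspace(-PI, PI, fine + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # triangular kernel from averaging n_shifts box-smoothed histograms
    tri = (n_shifts - np.abs(np.arange(-n_shifts + 1, n_shifts))) / n_shifts

    beta = np.zeros(nx)
    valid = np.zeros(nx, dtype=bool)
    for ix in range(nx):
        w = weights[ix]
        nzc = np.count_nonzero(w)
        if nzc < min_pixels:
            continue
        hist, _ = np.histogram(dphi[ix], bins=edges, weights=w)
        # circular convolution with the triangular kernel
        pad = n_shifts - 1
        ext = np.concatenate([hist[-pad:], hist, hist[:pad]])
        sm = np.convolve(ext, tri, mode="valid")
        beta[ix] = centers[int(np.argmax(sm))]
        valid[ix] = True
    if not valid.any():
        return np.zeros(nx)
    if not valid.all():
        # circular interpolation via the embedded unit vectors
        idx = np.arange(nx)
        cosb = np.interp(idx, idx[valid], np.cos(beta[valid]))
        sinb = np.interp(idx, idx[valid], np.sin(beta[valid]))
        fill = np.arctan2(sinb, cosb)
        beta = np.where(valid, beta, fill)
    return beta


def phase_variance(dphi_frames: np.ndarray,
                   mask: Optional[np.ndarray] = None,
                   center: str = "none") -> np.ndarray:
    """Phase variance from bulk-corrected wrapped difference frames.

    ``dphi_frames`` has shape (N-1, n_ascans, n_depth).  The default
    (``center='none'``) averages the squared wrapped differences,

        PV = (1/(N-1)) sum_i wrap(dphi_i)^2,

    which is zero for identical repeats and has expectation pi^2/3 for
    fully decorrelated (uniform) phases.  ``center='circular'`` first
    subtracts the per-pixel circular mean of the frames; note that with
    few repeats that estimator is biased low for decorrelated phases
    because the circular mean follows the samples.

    Masked-out pixels are set to 0.
    """
    d = wrap_phase(np.asarray(dphi_frames))
    if d.ndim != 3 or d.shape[0] < 1:
        raise ValueError("expected (N-1, n_ascans, n_depth) difference frames")
    if center == "circular":
        if d.shape[0] < 2:
            raise ValueError("circular centering needs at least 2 frames "
                             "(N >= 3 repeats)")
        mean = np.angle(np.exp(1j * d).sum(axis=0))
        d = wrap_phase(d - mean)
    elif center != "none":
        raise ValueError("center must be 'none' or 'circular'")
    pv = np.mean(d ** 2, axis=0)
    if mask is not None:
        pv = np.where(mask, pv, 0.0)
    return pv


def mean_intensity(stack: np.ndarray) -> np.ndarray:
    """Pixel-wise mean of |A|^2 over the repeat axis (first axis)."""
    stack = np.asarray(stack)
    if np.iscomplexobj(stack):
        return (np.abs(stack) ** 2).mean(axis=0)
    return (stack ** 2).mean(axis=0)


def compute_angiography(volume: ComplexVolume, kappa: float = 3.0,
                        n_bins: int = 64, n_shifts: int = 4,
                        noise_band: Optional[tuple[int, int]] = None,
                        correct_bulk: bool = True,
                        center: str = "none") -> AngioVolume:
    """Full angiography pass over a reconstructed volume.

    For each BM position: wrapped inter-repeat phase differences, masked
    intensity weights, per-column bulk offsets (unless ``correct_bulk``
    is disabled, kept for ablation), phase variance and the
    repeat-averaged intensity B-scan.
    """
    data = volume.data
    if data.ndim != 4:
        raise ValueError("expected [BM-position][repeat][A-scan][depth]")
    ny, nrep, nx, nz = data.shape
    if nrep < 2:
        raise ValueError("phase variance needs at least 2 repeats")
    nm = make_noise_mask(volume, kappa=kappa, band=noise_band)

    mean_int = np.empty((ny, nx, nz))
    pv = np.empty((ny, nx, nz))
    offsets = np.zeros((ny, nrep - 1, nx))
    for iy in range(ny):
        stack = data[iy]
        mean_int[iy] = mean_intensity(stack)
        dphi = wrap_phase(np.diff(np.angle(stack), axis=0))
        w = np.where(nm.mask[iy], mean_int[iy], 0.0)
        if correct_bulk:
            for i in range(nrep - 1):
                beta = bulk_phase_offset(dphi[i], w, n_bins=n_bins,
                                         n_shifts=n_shifts)
                offsets[iy, i] = beta
                dphi[i] = wrap_phase(dphi[i] - beta[:, None])
        pv[iy] = phase_variance(dphi, mask=nm.mask[iy], center=center)

    return AngioVolume(
        mean_intensity=mean_int, phase_variance=pv,
        bulk_offsets=offsets, mask=nm.mask,
        axial_pitch_um=volume.axial_pitch_um,
        metadata={"kappa": kappa, "n_bins": n_bins, "n_shifts": n_shifts,
                  "mu_noise": nm.mu_noise, "sigma_noise": nm.sigma_noise,
                  "correct_bulk": correct_bulk, "center": center})
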