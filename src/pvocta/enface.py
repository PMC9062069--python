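"""RPE segmentation, Zernike flattening and depth-windowed en-face maps.

The retinal pigment epithelium (RPE) is the brightest posterior band of a
retinal B-scan and serves as the depth reference.  Its per-column depth is
estimated from the mean-intensity volume, smoothed by a low-order Zernike
polynomial surface fit over the scan field (robust to segmentation
dropouts), and every A-scan is shifted by an integer pixel count so the
fitted RPE lands on a common reference index.  Motion-corrupted BM
positions (saccades) are detected as outliers of the per-position
phase-variance statistics and removed.  En-face projections sum the
flattened volume over depth windows positioned in micrometres relative to
the RPE peak, then are cleaned by a median and a Gaussian filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .angio import AngioVolume


# ---------------------------------------------------------------------------
# Zernike basis (real-valued, on the unit disk)
# ---------------------------------------------------------------------------

def zernike_indices(order: int) -> list[tuple[int, int]]:
    """(n, m) index pairs for all radial orders n <= order."""
    return [(n, m) for n in range(order + 1)
            for m in range(-n, n + 1, 2)]


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * math.factorial(n - s)
             / (math.factorial(s) * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)))
        out = out + c * rho ** (n - 2 * s)
    return out

def zernike_basis(order: int, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Evaluate the (unnormalised) real Zernike polynomials at points
    (X, Y) of the unit disk; polynomials extend smoothly beyond rho = 1,
    so corner points of a square field are extrapolated naturally.

    Returns an array of shape (n_terms,) + X.shape; e.g. the defocus term
    Z(n=2, m=0) = 2 rho^2 - 1.
    """
    rho = np.sqrt(X ** 2 + Y ** 2)
    th = np.arctan2(Y, X)
    cols = []
    for n, m in zernike_indices(order):
        R = _radial_poly(n, m, rho)
        if m > 0:
            cols.append(R * np.cos(m * th))
        elif m < 0:
            cols.append(R * np.sin(-m * th))
        else:
            cols.append(R)
    return np.stack(cols)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RPESurface:
    """Raw and fitted RPE depth over the (y, x) scan grid, in pixels."""

    raw_depth_px: np.ndarray           # float, NaN where missing
    confidence: np.ndarray             # peak prominence per column
    fitted_depth_px: Optional[np.ndarray] = None
    coefficients: Optional[np.ndarray] = None
    order: Optional[int] = None
    outlier_mask: Optional[np.ndarray] = None  # True where rejected
    inlier_residual_px: Optional[float] = None

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.raw_depth_px).sum())


@dataclass(frozen=True)
class DepthWindow:
    """Axial summation window relative to the RPE peak.

    ``offset_um`` is signed: negative is anterior (toward the vitreous,
    smaller depth index), positive posterior.  The window spans
    [offset - width/2, offset + width/2) in micrometres.
    """

    offset_um: float
    width_um: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.width_um <= 0:
            raise ValueError("window width must be positive")


#: published axial windows relative to the RPE peak; ranged widths are
#: exposed at their midpoint.
DEPTH_WINDOWS: dict[str, DepthWindow] = {
    "retina": DepthWindow(-90.0, 138.0, "retina"),
    "chrd1": DepthWindow(+12.0, (28.0 + 39.0) / 2, "chrd1"),
    "chrd2": DepthWindow(+127.0, (120.0 + 180.0) / 2, "chrd2"),
}
DEPTH_WINDOW_RANGES_UM = {"chrd1": (28.0, 39.0), "chrd2": (120.0, 180.0)}


@dataclass
class EnFaceProjection:
    """A depth-window projection on the (y, x) scan grid with provenance."""

    image: np.ndarray
    window: DepthWindow
    rejected_rows: list[int] = field(default_factory=list)
    filters: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def segment_rpe(mean_intensity: np.ndarray,
                search_band: tuple[float, float] = (0.5, 1.0),
                median_size: int = 5,
                prominence_floor: float = 4.0) -> RPESurface:
    """Per-A-scan RPE depth as the argmax of the smoothed axial profile.

    ``mean_intensity`` is [y, x, z].  The search is restricted to a
    fractional depth band — by default the posterior half, where the RPE
    lives; this keeps bright inner-retinal structure and vessels from
    capturing the argmax.  Profiles are median-smoothed axially, and a
    column is marked
    missing (NaN) when the peak fails a prominence test: peak less than
    ``prominence_floor`` times the band median — which flags atrophic or
    shadowed columns rather than fitting garbage.
    """
    vol = np.asarray(mean_intensity, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected [y, x, z] mean-intensity volume")
    ny, nx, nz = vol.shape
    lo = int(search_band[0] * nz)
    hi = int(search_band[1] * nz)
    if hi - lo < 4:
        raise ValueError("search band too narrow")
    band = vol[:, :, lo:hi]
    sm = ndimage.median_filter(band, size=(1, 1, median_size))
    idx = np.argmax(sm, axis=-1)
    peak = np.take_along_axis(sm, idx[..., None], axis=-1)[..., 0]
    ref = np.median(sm, axis=-1)
    conf = np.where(ref > 0, peak / np.maximum(ref, 1e-30), np.inf)
    depth = (idx + lo).astype(float)
    missing = ~(conf > prominence_floor) | (peak <= 0)
    depth[missing] = np.nan
    if np.all(missing):
        raise ValueError("no column passed the RPE prominence test; "
                         "volume appears featureless")
    return RPESurface(raw_depth_px=depth,
                      confidence=np.where(np.isfinite(conf), conf, 0.0))


def fit_zernike(surface: RPESurface, order: int = 4,
                mad_factor: float = 3.0) -> RPESurface:
    """Least-squares Zernike fit of the raw RPE depths with one round of
    outlier rejection at ``mad_factor`` times the residual MAD.

    The fit uses points inside the unit disk inscribed in the scan field;
    the fitted smooth map is evaluated everywhere (corners extrapolated).
    Reduces the order with a warning if too few valid points remain.
    """
    raw = surface.raw_depth_px
    ny, nx = raw.shape
    X = (np.arange(nx) / max(nx - 1, 1)) * 2.0 - 1.0
    Y = (np.arange(ny) / max(ny - 1, 1)) * 2.0 - 1.0
    XX, YY = np.meshgrid(X, Y)
    inside = XX ** 2 + YY ** 2 <= 1.0
    valid = np.isfinite(raw) & inside

    n_terms = len(zernike_indices(order))
    while valid.sum() < n_terms and order > 0:
        order -= 1
        n_terms = len(zernike_indices(order))
        warnings.warn(f"too few valid RPE points; reduced Zernike order "
                      f"to {order}")
    if valid.sum() < n_terms:
        raise ValueError("not enough valid RPE points for any fit")

    basis_full = zernike_basis(order, XX, YY)       # (T, ny, nx)

    def lstsq(sel: np.ndarray) -> np.ndarray:
        A = basis_full[:, sel].T
        b = raw[sel]
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        return coef

    coef = lstsq(valid)
    fitted = np.tensordot(coef, basis_full, axes=1)
    resid = raw - fitted
    r = resid[valid]
    mad = np.median(np.abs(r - np.median(r)))
    outlier = np.zeros_like(valid)
    if mad > 0:
        outlier = valid & (np.abs(resid - np.median(r)) > mad_factor * mad)
        keep = valid & ~outlier
        if keep.sum() >= n_terms:
            coef = lstsq(keep)
            fitted = np.tensordot(coef, basis_full, axes=1)
            resid = raw - fitted
    inliers = valid & ~outlier
    rms = float(np.sqrt(np.mean(resid[inliers] ** 2))) if inliers.any() else np.nan
    return RPESurface(raw_depth_px=raw, confidence=surface.confidence,
                      fitted_depth_px=fitted, coefficients=coef,
                      order=order, outlier_mask=outlier,
                      inlier_residual_px=rms)


def flatten_volume(volume: np.ndarray, fitted_depth_px: np.ndarray,
                   reference_index: Optional[int] = None
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Shift each A-scan by an integer pixel count so the fitted RPE
    depth maps to a common reference index.

    ``volume`` is [y, x, z] (intensity or PV — apply to both with the
    same surface).  Integer shifts preserve the values exactly; samples
    shifted past either depth edge are zero-filled, never wrapped.
    Returns (flattened volume, shift map, reference index); the shift map
    equals ``round(fitted) - reference`` exactly, and shifting back
    reproduces the input away from the zero-filled edges.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3 or vol.shape[:2] != fitted_depth_px.shape:
        raise ValueError("volume [y, x, z] must match the surface grid")
    nz = vol.shape[2]
    fit_px = np.round(fitted_depth_px).astype(int)
    if reference_index is None:
        reference_index = int(np.round(np.nanmean(fitted_depth_px)))
    shifts = fit_px - reference_index          # positive: RPE deeper
    out = np.zeros_like(vol)
    for s in np.unique(shifts):
        sel = shifts == s
        if s == 0:
            out[sel] = vol[sel]
        elif s > 0:                             # pull content up
            out[sel, : nz - s] = vol[sel, s:]
        else:
            out[sel, -s:] = vol[sel, : nz + s]
    return out, shifts, reference_index


def unflatten_volume(volume: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_volume` (zero-filled at the edges)."""
    return flatten_volume(volume,
                          -shifts + 0.0,
                          reference_index=0)[0]


def rpe_reference_index(flat_intensity: np.ndarray) -> int:
    """RPE peak: global argmax of the volume-mean axial intensity profile
    of a flattened volume — the reference depth windows are tied to."""
    profile = np.asarray(flat_intensity).mean(axis=(0, 1))
    return int(np.argmax(profile))


def reject_motion_bscans(angio: AngioVolume, c: float = 5.0,
                         min_excess: float = 0.05
                         ) -> tuple[list[int], list[int]]:
    """Detect motion-corrupted BM positions from their PV statistics.

    A BM position whose median phase variance over masked pixels exceeds
    ``median + max(c * MAD, min_excess)`` of all positions is rejected (a
    saccade raises PV across the whole cross-section, unlike vessels
    which are sparse).  ``min_excess`` (rad^2) keeps the threshold
    meaningful on very quiet volumes, where the MAD of the row scores can
    be orders of magnitude below any genuine motion effect — decorrelated
    phase raises a row's median PV by O(1) rad^2.
    Returns (kept, rejected) BM-position index lists and warns when more
    than 30% of the volume is rejected.
    """
    ny = angio.phase_variance.shape[0]
    scores = np.zeros(ny)
    for iy in range(ny):
        m = angio.mask[iy]
        scores[iy] = (np.median(angio.phase_variance[iy][m])
                      if m.any() else 0.0)
    med = np.median(scores)
    mad = np.median(np.abs(scores - med))
    thr = med + max(c * mad, min_excess)
    rejected = [int(i) for i in np.where(scores > thr)[0]]
    kept = [int(i) for i in range(ny) if i not in rejected]
    if len(rejected) > 0.3 * ny:
        warnings.warn(f"{len(rejected)}/{ny} BM positions rejected — "
                      "volume likely unusable")
    return kept, rejected


def enface_projection(flat_volume: np.ndarray, window: DepthWindow,
                      axial_pitch_um: float, rpe_index: int,
                      rejected_rows: Sequence[int] = (),
                      fill: str = "nearest") -> EnFaceProjection:
    """Axial sum of a flattened volume over a depth window.

    Depth pixel p sits at (p - rpe_index) * pitch micrometres from the
    RPE peak; pixels with offset in [offset - width/2, offset + width/2)
    (half-open) are summed.  Rejected BM rows are either replaced by
    their nearest kept neighbour (``fill='nearest'``) or dropped
    (``fill='drop'``).
    """
    vol = np.asarray(flat_volume)
    ny, nx, nz = vol.shape
    rel_um = (np.arange(nz) - rpe_index) * axial_pitch_um
    lo = window.offset_um - window.width_um / 2.0
    hi = window.offset_um + window.width_um / 2.0
    sel = (rel_um >= lo) & (rel_um < hi)
    if not sel.any():
        raise ValueError(
            f"depth window [{lo:.0f}, {hi:.0f}) um relative to the RPE "
            f"does not intersect the volume")
    img = vol[:, :, sel].sum(axis=-1)
    rejected = sorted(set(int(r) for r in rejected_rows))
    if rejected:
        kept = np.array([i for i in range(ny) if i not in rejected])
        if kept.size == 0:
            raise ValueError("all BM rows rejected")
        if fill == "nearest":
            for r in rejected:
                img[r] = img[kept[np.argmin(np.abs(kept - r))]]
        elif fill == "drop":
            img = img[kept]
        else:
            raise ValueError("fill must be 'nearest' or 'drop'")
    return EnFaceProjection(image=img, window=window,
                            rejected_rows=rejected,
                            metadata={"axial_pitch_um": axial_pitch_um,
                                      "rpe_index": rpe_index,
                                      "fill": fill})


def filter_projection(image: np.ndarray, median_size: int = 3,
                      gaussian_sigma: float = 1.0) -> np.ndarray:
    """Median filter then Gaussian blur, in that order (the median kills
    isolated hot pixels before the Gaussian spreads them)."""
    out = np.asarray(image, dtype=float)
    if median_size and median_size > 1:
        out = ndimage.median_filter(out, size=median_size)
    if gaussian_sigma and gaussian_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=gaussian_sigma)
    return out


def mosaic(tiles: Sequence[np.ndarray],
           nominal_offsets: Sequence[tuple[float, float]],
           correlation_floor: float = 0.3) -> np.ndarray:
    """Stitch projections by translation registration + feather blending.

    Each tile is placed at its nominal (row, col) offset, refined by
    phase correlation against the running reference in the overlap
    region.  When the normalised correlation at the refined shift is
    below ``correlation_floor`` the nominal offset is used with a
    warning.  Overlaps are blended with linear feather weights
    (distance to the tile edge).
    """
    if len(tiles) < 2:
        raise ValueError("need at least 2 tiles")
    if len(nominal_offsets) != len(tiles):
        raise ValueError("one nominal offset per tile")

    def feather(shape):
        r = np.minimum(np.arange(shape[0]), np.arange(shape[0])[::-1]) + 1.0
        c = np.minimum(np.arange(shape[1]), np.arange(shape[1])[::-1]) + 1.0
        return np.minimum.outer(r, c)

    refined = [np.array(nominal_offsets[0], dtype=float)]
    ref_tile = tiles[0]
    for t, nom in zip(tiles[1:], nominal_offsets[1:]):
        nom = np.array(nom, dtype=float)
        # compare on the common grid implied by the nominal offset
        dr, dc = int(round(nom[0] - nominal_offsets[0][0])), \
            int(round(nom[1] - nominal_offsets[0][1]))
        r0, r1 = max(0, dr), min(ref_tile.shape[0], dr + t.shape[0])
        c0, c1 = max(0, dc), min(ref_tile.shape[1], dc + t.shape[1])
        if (r1 - r0) * (c1 - c0) < 0.1 * t.size:
            warnings.warn("overlap below 10%; using nominal offset")
            refined.append(nom)
            continue
        a = ref_tile[r0:r1, c0:c1]
        b = t[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        shift, _, _ = phase_cross_correlation(a, b, upsample_factor=10,
                                              normalization=None)
        bs = ndimage.shift(b, shift, order=1, mode="nearest")
        da = a - a.mean()
        db = bs - bs.mean()
        denom = np.sqrt((da ** 2).sum() * (db ** 2).sum())
        corr = float((da * db).sum() / denom) if denom > 0 else 0.0
        if corr < correlation_floor:
            warnings.warn(f"registration correlation {corr:.2f} below "
                          "floor; using nominal offset")
            refined.append(nom)
        else:
            refined.append(nom + shift)

    offs = np.array(refined)
    offs -= offs.min(axis=0)
    ends = offs + np.array([t.shape for t in tiles])
    H, W = np.ceil(ends.max(axis=0)).astype(int)
    acc = np.zeros((H, W))
    wacc = np.zeros((H, W))
    for t, o in zip(tiles, offs):
        r, c = int(round(o[0])), int(round(o[1]))
        w = feather(t.shape)
        acc[r:r + t.shape[0], c:c + t.shape[1]] += t * w
        wacc[r:r + t.shape[0], c:c + t.shape[1]] += w
    with np.errstate(invalid="ignore"):
        out = np.where(wacc > 0, acc / np.maximum(wacc, 1e-30), 0.0)
    return out
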