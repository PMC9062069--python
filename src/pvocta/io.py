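"""File formats: headerless raw binaries with JSON sidecars, TIFF stacks,
and normalised PNG previews.

Raw spectral volumes are stored as little-endian 16-bit unsigned samples,
sample-fastest then A-scan, repeat, BM-position (so ``dd`` and memmap
work without a header); every raw file travels with a ``.json`` sidecar
carrying dimensions, protocol, source model, quantisation scale and seed.
Float volumes (magnitude/phase, mean intensity, phase variance) are
32-bit TIFF stacks.  Projections are written as 16-bit TIFF plus an 8-bit
PNG preview whose percentile stretch is recorded in the sidecar, so the
preview is invertible on non-clipped pixels.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import tifffile

from .angio import AngioVolume
from .enface import EnFaceProjection
from .phantom import RawSpectraVolume
from .reconstruct import ComplexVolume

PathLike = Union[str, Path]


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_json(path: PathLike, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default,
                                     sort_keys=True))


def read_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# raw spectra volumes
# ---------------------------------------------------------------------------

def write_raw_volume(prefix: PathLike, raw: RawSpectraVolume) -> None:
    """Write ``<prefix>.raw`` (uint16 little-endian, sample-fastest) and
    ``<prefix>.json`` (dimensions, metadata, calibration fringe)."""
    prefix = Path(prefix)
    data = np.ascontiguousarray(raw.data.astype("<u2"))
    data.tofile(prefix.with_suffix(".raw"))
    sidecar = {
        "shape": list(raw.data.shape),
        "dtype": "<u2",
        "order": ["bm_position", "repeat", "a_scan", "sample"],
        "calibration_fringe": raw.calibration_fringe,
        "metadata": raw.metadata,
    }
    write_json(prefix.with_suffix(".json"), sidecar)


def read_raw_volume(prefix: PathLike) -> RawSpectraVolume:
    """Inverse of :func:`write_raw_volume`; the byte count of the binary
    must match the sidecar's dimensions exactly."""
    prefix = Path(prefix)
    sidecar = read_json(prefix.with_suffix(".json"))
    shape = tuple(sidecar["shape"])
    binpath = prefix.with_suffix(".raw")
    expected = int(np.prod(shape)) * 2
    actual = os.path.getsize(binpath)
    if actual != expected:
        raise ValueError(
            f"{binpath}: expected {expected} bytes for shape {shape}, "
            f"found {actual}")
    data = np.fromfile(binpath, dtype="<u2").reshape(shape)
    return RawSpectraVolume(
        data=data,
        calibration_fringe=np.asarray(sidecar["calibration_fringe"]),
        metadata=sidecar["metadata"])


# ---------------------------------------------------------------------------
# complex and angio volumes
# ---------------------------------------------------------------------------

def write_complex_volume(prefix: PathLike, volume: ComplexVolume) -> None:
    """Magnitude and phase as 32-bit float TIFF stacks + JSON metadata.

    The 4-D [pos][rep][x][z] array is stored as a stack of (pos*rep)
    B-scan images, page order position-major.
    """
    prefix = Path(prefix)
    ny, nrep, nx, nz = volume.data.shape
    mag = volume.magnitude.reshape(ny * nrep, nx, nz).astype(np.float32)
    ph = volume.phase.reshape(ny * nrep, nx, nz).astype(np.float32)
    tifffile.imwrite(f"{prefix}_magnitude.tif", mag)
    tifffile.imwrite(f"{prefix}_phase.tif", ph)
    write_json(prefix.with_suffix(".json"), {
        "shape": [ny, nrep, nx, nz],
        "axial_pitch_um": volume.axial_pitch_um,
        "metadata": volume.metadata,
    })


def read_complex_volume(prefix: PathLike) -> ComplexVolume:
    prefix = Path(prefix)
    side = read_json(prefix.with_suffix(".json"))
    ny, nrep, nx, nz = side["shape"]
    mag = tifffile.imread(f"{prefix}_magnitude.tif").reshape(ny, nrep, nx, nz)
    ph = tifffile.imread(f"{prefix}_phase.tif").reshape(ny, nrep, nx, nz)
    data = mag.astype(np.float64) * np.exp(1j * ph.astype(np.float64))
    return ComplexVolume(data=data, axial_pitch_um=side["axial_pitch_um"],
                         metadata=side["metadata"])


def write_angio(prefix: PathLike, angio: AngioVolume) -> None:
    """Mean-intensity and phase-variance stacks + JSON with the bulk
    offsets and mask statistics."""
    prefix = Path(prefix)
    tifffile.imwrite(f"{prefix}_mean_intensity.tif",
                     angio.mean_intensity.astype(np.float32))
    tifffile.imwrite(f"{prefix}_phase_variance.tif",
                     angio.phase_variance.astype(np.float32))
    tifffile.imwrite(f"{prefix}_mask.tif",
                     angio.mask.astype(np.uint8))
    write_json(prefix.with_suffix(".json"), {
        "shape": list(angio.mean_intensity.shape),
        "axial_pitch_um": angio.axial_pitch_um,
        "bulk_offsets": angio.bulk_offsets,
        "metadata": angio.metadata,
    })


def read_angio(prefix: PathLike) -> AngioVolume:
    prefix = Path(prefix)
    side = read_json(prefix.with_suffix(".json"))
    return AngioVolume(
        mean_intensity=tifffile.imread(f"{prefix}_mean_intensity.tif"
                                       ).astype(np.float64),
        phase_variance=tifffile.imread(f"{prefix}_phase_variance.tif"
                                       ).astype(np.float64),
        mask=tifffile.imread(f"{prefix}_mask.tif").astype(bool),
        bulk_offsets=np.asarray(side["bulk_offsets"]),
        axial_pitch_um=side["axial_pitch_um"],
        metadata=side["metadata"])


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def write_projection(prefix: PathLike, projection: EnFaceProjection,
                     percentiles: tuple[float, float] = (0.5, 99.5)) -> None:
    """16-bit TIFF (stretched), 8-bit PNG preview and JSON sidecar.

    The linear stretch maps the recorded (lo, hi) image percentiles to
    the full integer range; lo/hi are stored so the stretch can be
    inverted on non-clipped pixels.
    """
    prefix = Path(prefix)
    img = np.asarray(projection.image, dtype=float)
    lo, hi = np.percentile(img, percentiles)
    if hi <= lo:
        hi = lo + 1.0
    stretched = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    tifffile.imwrite(prefix.with_suffix(".tif"),
                     np.round(stretched * 65535).astype(np.uint16))
    iio.imwrite(prefix.with_suffix(".png"),
                np.round(stretched * 255).astype(np.uint8))
    write_json(prefix.with_suffix(".json"), {
        "window": {"offset_um": projection.window.offset_um,
                   "width_um": projection.window.width_um,
                   "name": projection.window.name},
        "rejected_rows": projection.rejected_rows,
        "filters": projection.filters,
        "stretch": {"percentiles": list(percentiles),
                    "lo": float(lo), "hi": float(hi)},
        "metadata": projection.metadata,
    })


def read_projection_image(prefix: PathLike) -> tuple[np.ndarray, dict]:
    """Read the 16-bit TIFF back onto the original scale using the
    recorded stretch (exact on non-clipped pixels up to quantisation)."""
    prefix = Path(prefix)
    side = read_json(prefix.with_suffix(".json"))
    s = side["stretch"]
    raw = tifffile.imread(prefix.with_suffix(".tif")).astype(float) / 65535.0
    return raw * (s["hi"] - s["lo"]) + s["lo"], side
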