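"""End-to-end pipeline: simulate (or load) -> reconstruct -> angiography
-> flatten -> en-face projections, with a JSON run manifest.

The manifest records the full configuration, the seed, and per-stage
statistics (counts, rejection lists, bulk-offset summaries, fit
residuals) so any output is reproducible from the manifest alone.  Stage
timings go to the logger, never into the manifest, which is therefore
bit-identical between runs with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as pio
from .angio import compute_angiography
from .enface import (DEPTH_WINDOWS, DepthWindow, enface_projection,
                     filter_projection, fit_zernike, flatten_volume,
                     reject_motion_bscans, rpe_reference_index, segment_rpe)
from .phantom import make_preset_phantom, simulate_volume
from .reconstruct import (DispersionModel, ReconstructionOptions,
                          reconstruct_volume)

log = logging.getLogger("pvocta")

_KNOWN_KEYS = {
    "preset", "raw_input", "output_dir", "seed",
    "window_family", "pad_length", "dispersion_a2", "dispersion_a3",
    "optimize_dispersion", "kappa", "n_bins", "n_shifts",
    "zernike_order", "windows", "median_size", "gaussian_sigma",
    "rejection_c", "rejection_fill", "save_raw", "save_complex",
}


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    preset: Optional[str] = "retina_small"   # phantom preset to simulate
    raw_input: Optional[str] = None          # or: path prefix of a raw volume
    output_dir: str = "pvocta_out"
    seed: int = 0
    # reconstruction
    window_family: str = "hann"
    pad_length: Optional[int] = None
    dispersion_a2: Optional[float] = None
    dispersion_a3: Optional[float] = None
    optimize_dispersion: bool = False
    # angiography
    kappa: float = 3.0
    n_bins: int = 64
    n_shifts: int = 4
    # enface
    zernike_order: int = 4
    windows: list[str] = field(default_factory=lambda: ["retina"])
    median_size: int = 3
    gaussian_sigma: float = 1.0
    rejection_c: float = 5.0
    rejection_fill: str = "nearest"
    # outputs
    save_raw: bool = False
    save_complex: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.preset is None and cfg.raw_input is None:
            raise ValueError("either preset or raw_input must be given")
        for w in cfg.windows:
            if w not in DEPTH_WINDOWS:
                raise ValueError(f"unknown depth window {w!r}; "
                                 f"available: {sorted(DEPTH_WINDOWS)}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write all artifacts.

    Returns the run manifest (also written to ``manifest.json`` in the
    output directory).  Raises with a stage-tagged message on failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                r = fn()
            except Exception as e:
                manifest["stages"][name] = {"status": "failed",
                                            "error": str(e)}
                pio.write_json(out / "manifest.json", manifest)
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") \
                    from e
            log.info("stage %s done in %.2fs", name,
                     time.perf_counter() - t0)
            return r
        return deco

    # --- input ---------------------------------------------------------
    if config.raw_input is not None:
        raw = stage("load")(lambda: pio.read_raw_volume(config.raw_input))
        truth = None
    else:
        def _sim():
            spec, source, protocol = make_preset_phantom(config.preset)
            return simulate_volume(spec, source, protocol, config.seed)
        raw, truth = stage("simulate")(_sim)
    manifest["stages"]["input"] = {
        "shape": list(raw.data.shape), "seed": config.seed,
        "preset": config.preset, "raw_input": config.raw_input}
    if config.save_raw:
        pio.write_raw_volume(out / "raw", raw)

    # --- reconstruction ------------------------------------------------
    disp = None
    if config.dispersion_a2 is not None or config.dispersion_a3 is not None:
        disp = DispersionModel(config.dispersion_a2 or 0.0,
                               config.dispersion_a3 or 0.0)
    opts = ReconstructionOptions(
        window=config.window_family, pad_length=config.pad_length,
        dispersion=disp, optimize_dispersion=config.optimize_dispersion)
    cv = stage("reconstruct")(lambda: reconstruct_volume(raw, opts))
    manifest["stages"]["reconstruct"] = {
        "axial_pitch_um": cv.axial_pitch_um,
        "depth_pixels": cv.n_depth,
        "dispersion": cv.metadata.get("dispersion"),
        "window": config.window_family}
    if config.save_complex:
        pio.write_complex_volume(out / "complex", cv)

    # --- angiography ---------------------------------------------------
    av = stage("angio")(lambda: compute_angiography(
        cv, kappa=config.kappa, n_bins=config.n_bins,
        n_shifts=config.n_shifts))
    manifest["stages"]["angio"] = {
        "mu_noise": av.metadata["mu_noise"],
        "sigma_noise": av.metadata["sigma_noise"],
        "masked_fraction": float(av.mask.mean()),
        "bulk_offset_abs_mean_rad": float(np.abs(av.bulk_offsets).mean()),
    }
    pio.write_angio(out / "angio", av)

    # --- flattening ----------------------------------------------------
    def _flatten():
        surf = segment_rpe(av.mean_intensity)
        fit = fit_zernike(surf, order=config.zernike_order)
        flat_int, shifts, ref = flatten_volume(av.mean_intensity,
                                               fit.fitted_depth_px)
        flat_pv, _, _ = flatten_volume(av.phase_variance,
                                       fit.fitted_depth_px,
                                       reference_index=ref)
        return surf, fit, flat_int, flat_pv, shifts, ref
    surf, fit, flat_int, flat_pv, shifts, ref = stage("flatten")(_flatten)
    rpe_idx = rpe_reference_index(flat_int)
    manifest["stages"]["flatten"] = {
        "valid_columns": surf.n_valid,
        "zernike_order": fit.order,
        "fit_residual_px": fit.inlier_residual_px,
        "reference_index": ref,
        "rpe_peak_index": rpe_idx}

    # --- motion rejection & projections --------------------------------
    kept, rejected = stage("reject")(
        lambda: reject_motion_bscans(av, c=config.rejection_c))
    manifest["stages"]["reject"] = {"rejected_rows": rejected,
                                    "n_kept": len(kept)}
    manifest["stages"]["enface"] = {}
    for wname in config.windows:
        window = DEPTH_WINDOWS[wname]
        proj = stage(f"enface:{wname}")(lambda w=window: enface_projection(
            flat_pv, w, av.axial_pitch_um, rpe_idx,
            rejected_rows=rejected, fill=config.rejection_fill))
        proj.image = filter_projection(proj.image, config.median_size,
                                       config.gaussian_sigma)
        proj.filters = [f"median{config.median_size}",
                        f"gaussian{config.gaussian_sigma}"]
        pio.write_projection(out / f"enface_{wname}", proj)
        manifest["stages"]["enface"][wname] = {
            "offset_um": window.offset_um, "width_um": window.width_um,
            "shape": list(proj.image.shape)}

    pio.write_json(out / "manifest.json", manifest)
    return manifest
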