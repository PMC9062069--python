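"""Raster OCTA scan-protocol modelling.

A raster OCT-angiography acquisition is described by a field of view, a
lateral step size in each scan direction, the number of repeated B-scans
per slow-scanner position (BM-scan), the spectral sample count per A-scan
and the sweep rate of the source.  From these the planner derives A-scan /
B-scan counts, acquisition time, raw data size and the spatial sampling
ratio relative to the beam spot.

Counts are derived by truncating extent/step toward zero (a 9 mm extent at
a 7 um step yields 1285 A-scans, not 1286), data sizes are decimal
gigabytes (1 GB = 1e9 bytes), and reported times are rounded to one
decimal minute or the nearest second.  These conventions reproduce the
printed arithmetic of published FDML and AngioPlex protocol tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ScanProtocol:
    """Geometry and timing of a raster OCTA acquisition.

    Parameters
    ----------
    fov_mm_x, fov_mm_y :
        Scan extent in millimetres along the fast (x) and slow (y) axes.
    step_um_x, step_um_y :
        Lateral scan step in micrometres.
    repeats :
        B-scans acquired per BM-scan (slow-scanner position); >= 1.
    samples_per_ascan :
        Spectral samples digitised per wavelength sweep.
    sweep_rate_hz :
        A-scan rate of the swept source in Hz.
    beam_diameter_um :
        1/e^2 beam spot diameter at the retina, used for sampling ratios.
    bscan_period_ms :
        Optional B-scan repetition period including fly-back.  When absent,
        timing is derived from the sweep rate with zero fly-back.
    bytes_per_sample :
        Storage bytes per spectral sample (12-bit samples in 16-bit
        containers -> 2).
    """

    fov_mm_x: float
    fov_mm_y: float
    step_um_x: float
    step_um_y: float
    repeats: int = 1
    samples_per_ascan: int = 1024
    sweep_rate_hz: float = 100e3
    beam_diameter_um: float = 14.0
    bscan_period_ms: Optional[float] = None
    bytes_per_sample: int = 2

    def __post_init__(self) -> None:
        for name in ("fov_mm_x", "fov_mm_y", "step_um_x", "step_um_y",
                     "sweep_rate_hz", "beam_diameter_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, "
                                 f"got {getattr(self, name)}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.samples_per_ascan < 1:
            raise ValueError("samples_per_ascan must be >= 1")
        if self.bscan_period_ms is not None and self.bscan_period_ms <= 0:
            raise ValueError("bscan_period_ms must be positive when given")
        if self.bytes_per_sample < 1:
            raise ValueError("bytes_per_sample must be >= 1")
        if self.a_scans_per_bscan < 1 or self.n_positions < 1:
            raise ValueError("extent/step must yield at least one sample "
                             "in each scan direction")

    @property
    def a_scans_per_bscan(self) -> int:
        # epsilon guards exact ratios against binary float representation
        return int(self.fov_mm_x * 1000.0 / self.step_um_x + 1e-9)

    @property
    def n_positions(self) -> int:
        return int(self.fov_mm_y * 1000.0 / self.step_um_y + 1e-9)

    @property
    def total_bscans(self) -> int:
        return self.repeats * self.n_positions

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanProtocol":
        return cls(**d)


@dataclass(frozen=True)
class AcquisitionPlan:
    """Derived counts, timing and data size for a :class:`ScanProtocol`."""

    a_scans_per_bscan: int
    n_positions: int
    total_bscans: int
    volume_time_s: float
    data_size_gb: float
    sampling_ratio_x: float
    sampling_ratio_y: float
    undersampled_x: bool
    undersampled_y: bool

    @property
    def volume_time_min_reported(self) -> float:
        """Acquisition time in minutes, rounded to one decimal."""
        return round(self.volume_time_s / 60.0, 1)

    @property
    def volume_time_s_reported(self) -> int:
        """Acquisition time rounded to the nearest second."""
        return _round_half_up(self.volume_time_s)

    @property
    def data_size_gb_reported(self) -> int:
        """Data size rounded to the nearest decimal gigabyte."""
        return _round_half_up(self.data_size_gb)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["volume_time_min_reported"] = self.volume_time_min_reported
        d["volume_time_s_reported"] = self.volume_time_s_reported
        d["data_size_gb_reported"] = self.data_size_gb_reported
        return d


def sampling_ratio(step_um: float, beam_diameter_um: float) -> tuple[float, bool]:
    """Scan step as a fraction of the 1/e^2 beam spot diameter.

    Returns the ratio rounded to two decimals and an ``undersampled`` flag
    set when the step exceeds half the spot diameter (the half-spot
    criterion below which capillary-scale features remain resolvable).
    """
    if step_um <= 0 or beam_diameter_um <= 0:
        raise ValueError("step and beam diameter must be positive")
    ratio = step_um / beam_diameter_um
    return round(ratio, 2), ratio > 0.5


def volume_time_from_period(protocol: ScanProtocol) -> float:
    """Volume acquisition time (s) from the B-scan repetition period.

    Raises ``ValueError`` when the protocol has no period: the caller must
    then fall back to the zero-fly-back derivation of
    :func:`plan_acquisition`.
    """
    if protocol.bscan_period_ms is None:
        raise ValueError("protocol has no bscan_period_ms; acquisition time "
                         "would be derived from the sweep rate without "
                         "fly-back — use plan_acquisition for that")
    return protocol.total_bscans * protocol.bscan_period_ms / 1000.0


def data_size_gb(protocol: ScanProtocol) -> float:
    """Raw data size in decimal gigabytes (1 GB = 1e9 bytes)."""
    n_bytes = (protocol.total_bscans * protocol.a_scans_per_bscan
               * protocol.samples_per_ascan * protocol.bytes_per_sample)
    return n_bytes / 1e9


def plan_acquisition(protocol: ScanProtocol) -> AcquisitionPlan:
    """Derive counts, acquisition time, data size and sampling ratios.

    When the protocol carries an explicit B-scan period (including
    fly-back) the volume time is ``total_bscans * period``; otherwise it is
    the pure sweep time ``total_bscans * a_scans / sweep_rate``.
    """
    if protocol.bscan_period_ms is not None:
        t = volume_time_from_period(protocol)
    else:
        t = (protocol.total_bscans * protocol.a_scans_per_bscan
             / protocol.sweep_rate_hz)
    rx, ux = sampling_ratio(protocol.step_um_x, protocol.beam_diameter_um)
    ry, uy = sampling_ratio(protocol.step_um_y, protocol.beam_diameter_um)
    return AcquisitionPlan(
        a_scans_per_bscan=protocol.a_scans_per_bscan,
        n_positions=protocol.n_positions,
        total_bscans=protocol.total_bscans,
        volume_time_s=t,
        data_size_gb=data_size_gb(protocol),
        sampling_ratio_x=rx,
        sampling_ratio_y=ry,
        undersampled_x=ux,
        undersampled_y=uy,
    )


# Published protocol presets.  FDML presets define the field of view as
# count x step exactly (the printed "5 mm" is the rounded 1024 x 5 um);
# AngioPlex presets likewise use count x step.
PRESETS: dict[str, ScanProtocol] = {
    # 1.7 MHz FDML swept source, 5 B-scan repeats, 12-bit samples.
    "fdml1": ScanProtocol(
        fov_mm_x=5.12, fov_mm_y=5.12, step_um_x=5.0, step_um_y=5.0,
        repeats=5, samples_per_ascan=1024, sweep_rate_hz=1.7e6,
        beam_diameter_um=14.0, bscan_period_ms=1.2),
    "fdml2": ScanProtocol(
        fov_mm_x=9.216, fov_mm_y=9.216, step_um_x=8.0, step_um_y=8.0,
        repeats=5, samples_per_ascan=1024, sweep_rate_hz=1.7e6,
        beam_diameter_um=14.0, bscan_period_ms=1.35),
    # 68 kHz commercial spectral-domain OCTA (OMAG) protocols.
    "angioplex1": ScanProtocol(
        fov_mm_x=2.94, fov_mm_y=2.94, step_um_x=12.0, step_um_y=12.0,
        repeats=4, samples_per_ascan=1024, sweep_rate_hz=68e3,
        beam_diameter_um=15.0, bscan_period_ms=3.8),
    "angioplex2": ScanProtocol(
        fov_mm_x=5.95, fov_mm_y=5.95, step_um_x=17.0, step_um_y=17.0,
        repeats=2, samples_per_ascan=1024, sweep_rate_hz=68e3,
        beam_diameter_um=15.0, bscan_period_ms=5.0),
}


def get_preset(name: str) -> ScanProtocol:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown protocol preset {name!r}; "
                       f"available: {sorted(PRESETS)}") from None
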