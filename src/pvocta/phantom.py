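"""Physics-based synthetic swept-source interferogram generator.

Forward model used throughout the test surface of this package: a layered
scattering phantom (a crude retina) is imaged by a swept source whose
spectral envelope, sample-index-to-wavenumber mapping, residual dispersion
and detection noise are all explicit and therefore recoverable by the
reconstruction chain.  Each recorded fringe is

    I(m) = S(k_m) * [ DC + sum_j 2 sqrt(r_j) cos(2 n k_m z_j
                                            + theta(k_m) + phi_bulk) ]
           + fixed_pattern(m) + noise(m)

with ``k_m`` the (possibly nonlinear) wavenumber at digitiser sample ``m``,
``z_j`` the geometric scatterer depths in tissue of refractive index ``n``,
``theta`` an injected dispersion phase, and ``phi_bulk`` a per-B-scan bulk
axial-motion phase.  Scatterers inside vessel voxels have their depths
re-drawn on every B-scan repeat (axial jitter of standard deviation
``sigma_flow``), which decorrelates the fringe phase between repeats — the
signal that phase-variance angiography detects.  The model is scalar and
single-scattering; see docs/methods.md for what it does and does not
emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .protocol import ScanProtocol

TWO_PI = 2.0 * math.pi
#: zero-padding ratio of the reconstruction (pad length = PAD_FACTOR * M)
PAD_FACTOR = 4
#: fraction of the 12-bit full scale used when quantising fringes
QUANT_HEADROOM = 0.9
QUANT_MAX = 4095


@dataclass(frozen=True)
class SourceModel:
    """Swept source spectrum, k-sampling and residual dispersion.

    The digitiser samples the sweep at ``samples_per_ascan`` points.  The
    sampled wavenumber span is ``span_factor`` times the FWHM k-bandwidth
    of the (Gaussian) spectral envelope, centred on ``2*pi/lambda0``; the
    mapping from sample index to wavenumber may be nonlinear:

        k(m) = k_start + span * g(u),   u = m/(M-1),
        g(u) = (u + c2 u^2 + c3 u^3) / (1 + c2 + c3)

    which is the identity for ``chirp2 = chirp3 = 0`` and monotone for
    moderate coefficients.  Residual dispersion is a polynomial phase on
    the normalised band coordinate xi = 2(k - k_center)/span in [-1, 1]:

        theta(xi) = a2 * xi^2 + a3 * xi^3   [rad]

    expressed at the band edge, so ``dispersion_a2 = 12`` means 12 rad of
    quadratic phase at the edges of the sampled band.
    """

    center_wavelength_um: float = 1.065
    fwhm_bandwidth_um: float = 0.080
    samples_per_ascan: int = 512
    span_factor: float = 2.0
    chirp2: float = 0.0
    chirp3: float = 0.0
    dispersion_a2: float = 0.0
    dispersion_a3: float = 0.0

    def __post_init__(self) -> None:
        if self.center_wavelength_um <= 0 or self.fwhm_bandwidth_um <= 0:
            raise ValueError("wavelength and bandwidth must be positive")
        if self.samples_per_ascan < 16:
            raise ValueError("samples_per_ascan must be >= 16")
        if self.span_factor <= 0:
            raise ValueError("span_factor must be positive")
        g = self._g(np.linspace(0.0, 1.0, 1024))
        if np.any(np.diff(g) <= 0):
            raise ValueError("k(m) must be strictly monotone; chirp "
                             "coefficients too large")

    # --- derived spectral geometry -------------------------------------
    @property
    def k0(self) -> float:
        """Centre wavenumber, rad/um."""
        return TWO_PI / self.center_wavelength_um

    @property
    def dk_fwhm(self) -> float:
        """FWHM of the envelope in k, rad/um."""
        return TWO_PI * self.fwhm_bandwidth_um / self.center_wavelength_um ** 2

    @property
    def k_span(self) -> float:
        return self.span_factor * self.dk_fwhm

    @property
    def k_start(self) -> float:
        return self.k0 - 0.5 * self.k_span

    @property
    def delta_k(self) -> float:
        """Uniform-grid k step after linearisation, rad/um."""
        return self.k_span / (self.samples_per_ascan - 1)

    def _g(self, u: np.ndarray) -> np.ndarray:
        c2, c3 = self.chirp2, self.chirp3
        return (u + c2 * u ** 2 + c3 * u ** 3) / (1.0 + c2 + c3)

    def k_of_sample(self, m: Optional[np.ndarray] = None) -> np.ndarray:
        """Wavenumber at each digitiser sample (the true, possibly
        nonlinear mapping the calibration step must recover)."""
        M = self.samples_per_ascan
        if m is None:
            m = np.arange(M, dtype=float)
        return self.k_start + self.k_span * self._g(m / (M - 1))

    def k_uniform(self) -> np.ndarray:
        return np.linspace(self.k_start, self.k_start + self.k_span,
                           self.samples_per_ascan)

    def envelope(self, k: np.ndarray) -> np.ndarray:
        return np.exp(-4.0 * math.log(2.0) * ((k - self.k0) / self.dk_fwhm) ** 2)

    def dispersion_phase(self, k: np.ndarray) -> np.ndarray:
        xi = 2.0 * (k - self.k0) / self.k_span
        return self.dispersion_a2 * xi ** 2 + self.dispersion_a3 * xi ** 3

    # --- depth geometry -------------------------------------------------
    def axial_pitch_um(self, n: float = 1.33, pad_factor: int = PAD_FACTOR) -> float:
        """Geometric depth per reconstructed pixel (tissue index n)."""
        pad = pad_factor * self.samples_per_ascan
        return math.pi / (n * self.delta_k * pad)

    def axial_range_um(self, n: float = 1.33) -> float:
        """One-sided (Nyquist) geometric depth range in tissue."""
        return math.pi / (2.0 * n * self.delta_k)

    def transform_limited_fwhm_um(self, n: float = 1.33) -> float:
        """Axial PSF FWHM of the untruncated Gaussian spectrum in tissue."""
        return (2.0 * math.log(2.0) / math.pi) * \
            self.center_wavelength_um ** 2 / (n * self.fwhm_bandwidth_um)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SourceModel":
        return cls(**d)


@dataclass(frozen=True)
class Layer:
    """A scattering slab: ``density`` scatterers per A-scan drawn
    uniformly within ``thickness_um`` around ``center_um`` (geometric
    tissue depth), each of power reflectivity ``reflectivity``."""
    center_um: float
    thickness_um: float
    reflectivity: float
    density: int
    is_rpe: bool = False


@dataclass(frozen=True)
class VesselTube:
    """Cylindrical vessel along the slow (y) axis at fractional fast-axis
    position ``x_frac``; scatterer depths inside the lumen are re-drawn
    every repeat with axial jitter ``sigma_flow_um``.  Running along the
    slow axis, the tube crosses every B-scan at the same few A-scan
    columns, as a vessel transecting the raster does."""
    x_frac: float
    depth_um: float
    radius_um: float
    sigma_flow_um: float
    reflectivity: float = 0.2
    density: int = 4


@dataclass(frozen=True)
class FlowSlab:
    """Rectangular flowing region (fractions of the lateral grid, depths in
    geometric um) for flow-contrast calibration."""
    x0_frac: float
    x1_frac: float
    y0_frac: float
    y1_frac: float
    z0_um: float
    z1_um: float
    sigma_flow_um: float
    reflectivity: float = 0.2
    density: int = 6


@dataclass(frozen=True)
class Saccade:
    """A rapid eye movement at one BM-position: the lateral content shifts
    by ``shift_steps`` and the fringe phase decorrelates between repeats."""
    bm_index: int
    shift_steps: int = 4


@dataclass
class PhantomSpec:
    """Layered reflectivity phantom with vessels, curvature and motion."""

    layers: list[Layer] = field(default_factory=list)
    vessels: list = field(default_factory=list)  # VesselTube | FlowSlab
    #: coefficients of the smooth depth-offset map s(X, Y) [um] on the
    #: normalised grid X, Y in [-1, 1]: (c0, cx, cy, cxx, cyy, cxy)
    surface_poly: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    #: per-B-scan axial random-walk step sigma [um]; the bulk phase is the
    #: cumulative walk converted to phase at band centre
    bulk_sigma_um: float = 0.0
    #: explicit per-B-scan axial displacement [um], overrides the walk
    bulk_motion_um: Optional[np.ndarray] = None
    saccades: list[Saccade] = field(default_factory=list)
    #: sub-resolution Gaussian interface roughness [um] added to every
    #: static scatterer depth: decorrelates speckle phase across columns
    #: (real interfaces are optically rough), so coherent sample structure
    #: cannot survive the volume-mean fixed-pattern estimate
    roughness_um: float = 0.25
    noise_sigma: float = 0.0
    fixed_pattern_amplitude: float = 0.0
    fixed_pattern_depth_um: float = 60.0
    dc_level: float = 5.0
    n: float = 1.33

    def surface_um(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        c0, cx, cy, cxx, cyy, cxy = self.surface_poly
        return c0 + cx * X + cy * Y + cxx * X ** 2 + cyy * Y ** 2 + cxy * X * Y

    def validate(self, source: SourceModel) -> None:
        zmax = source.axial_range_um(self.n)
        for lay in self.layers:
            if lay.center_um + lay.thickness_um / 2 > zmax:
                raise ValueError(
                    f"layer at {lay.center_um} um exceeds the axial range "
                    f"({zmax:.0f} um in tissue)")
        for v in self.vessels:
            deep = (v.depth_um + v.radius_um if isinstance(v, VesselTube)
                    else v.z1_um)
            if deep > zmax:
                raise ValueError("vessel deeper than axial range")


@dataclass
class RawSpectraVolume:
    """Acquired spectral fringes, quantised to 12 bits in 16-bit
    containers, ordered [BM-position][repeat][A-scan][sample]."""

    data: np.ndarray  # uint16
    calibration_fringe: np.ndarray  # float64 [M]
    metadata: dict

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def dequantized(self) -> np.ndarray:
        """Fringes back on the simulation's real-valued scale."""
        scale = self.metadata["quant_scale"]
        offset = self.metadata["quant_offset"]
        return (self.data.astype(np.float64) - offset) / scale


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must recover."""

    vessel_mask: np.ndarray        # bool [n_pos, n_ascans, depth_px]
    rpe_depth_um: np.ndarray       # float [n_pos, n_ascans], geometric
    rpe_depth_px: np.ndarray       # float [n_pos, n_ascans]
    bulk_phase_rad: np.ndarray     # float [n_pos, repeats]
    saccade_indices: list[int]
    axial_pitch_um: float


def quantize_12bit(volume: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Scale to ``QUANT_HEADROOM`` of the 12-bit range about mid-scale."""
    absmax = float(np.max(np.abs(volume)))
    if absmax == 0.0:
        absmax = 1.0
    scale = QUANT_HEADROOM * (QUANT_MAX / 2.0) / absmax
    offset = (QUANT_MAX + 1) / 2.0
    q = np.clip(np.round(volume * scale + offset), 0, QUANT_MAX)
    return q.astype(np.uint16), scale, offset


def simulate_calibration_fringe(source: SourceModel,
                                z_cal_um: Optional[float] = None) -> np.ndarray:
    """Single-reflector calibration fringe (k-clock) under the source
    envelope, sampled at the same (nonlinear) k(m) as the imaging data.

    ``z_cal_um`` is the optical path depth of the calibration mirror; the
    default places it at 25% of the optical Nyquist depth, giving well
    over ten fringe cycles across the sweep.
    """
    if z_cal_um is None:
        z_cal_um = 0.25 * math.pi / (2.0 * source.delta_k)
    k = source.k_of_sample()
    n_cycles = source.k_span * z_cal_um / math.pi
    if n_cycles < 10:
        raise ValueError(f"calibration depth too shallow: {n_cycles:.1f} "
                         "fringe cycles (< 10)")
    return source.envelope(k) * np.cos(2.0 * k * z_cal_um)


def _vessel_voxels(spec: PhantomSpec, protocol: ScanProtocol,
                   pitch_um: float, depth_px: int) -> np.ndarray:
    """Boolean vessel mask on the reconstructed voxel grid."""
    ny, nx = protocol.n_positions, protocol.a_scans_per_bscan
    mask = np.zeros((ny, nx, depth_px), dtype=bool)
    z_um = np.arange(depth_px) * pitch_um
    x_um = np.arange(nx) * protocol.step_um_x
    for v in spec.vessels:
        if isinstance(v, VesselTube):
            xc = v.x_frac * (nx - 1) * protocol.step_um_x
            r2 = ((x_um - xc) ** 2)[:, None] + ((z_um - v.depth_um) ** 2)[None, :]
            inside = r2 <= v.radius_um ** 2  # (nx, nz)
            mask |= inside[None, :, :]
        elif isinstance(v, FlowSlab):
            xs = slice(int(v.x0_frac * nx), int(v.x1_frac * nx))
            ys = slice(int(v.y0_frac * ny), int(v.y1_frac * ny))
            zin = (z_um >= v.z0_um) & (z_um < v.z1_um)
            sub = mask[ys, xs, :]
            sub |= zin[None, None, :]
            mask[ys, xs, :] = sub
        else:
            raise TypeError(f"unknown vessel type {type(v)!r}")
    return mask


def make_preset_phantom(name: str, seed: int = 0
                        ) -> tuple[PhantomSpec, SourceModel, ScanProtocol]:
    """Desk-scale phantom presets with known ground truth.

    ``mirror``
        A single fixed reflector — the point-spread-function target for
        calibration/dispersion tests.
    ``retina_small``
        64 x 64 lateral positions, 5 repeats, 512 spectral samples: three
        curved layers (the deepest, brightest one standing in for the
        RPE), two vessel tubes with axial flow jitter of lambda0/(8n),
        a bulk axial random walk of sigma = lambda0/16 per B-scan, weak
        detection noise and a fixed-pattern fringe.
    ``flow_bar``
        A rectangular flowing slab between two static slabs, for
        phase-variance contrast calibration.

    ``seed`` is not consumed here (presets are deterministic specs); it is
    accepted so callers can thread one value through to
    :func:`simulate_volume`.
    """
    lam0 = 1.065
    if name == "mirror":
        source = SourceModel(samples_per_ascan=512)
        protocol = ScanProtocol(fov_mm_x=0.04, fov_mm_y=0.01,
                                step_um_x=5.0, step_um_y=5.0,
                                repeats=2, samples_per_ascan=512,
                                sweep_rate_hz=1.7e6)
        spec = PhantomSpec(
            layers=[Layer(center_um=200.0, thickness_um=0.0,
                          reflectivity=1.0, density=1)],
            dc_level=2.0)
        return spec, source, protocol
    if name == "retina_small":
        source = SourceModel(samples_per_ascan=512)
        protocol = ScanProtocol(fov_mm_x=0.32, fov_mm_y=0.32,
                                step_um_x=5.0, step_um_y=5.0,
                                repeats=5, samples_per_ascan=512,
                                sweep_rate_hz=1.7e6)
        n = 1.33
        spec = PhantomSpec(
            layers=[
                Layer(center_um=260.0, thickness_um=60.0,
                      reflectivity=0.12, density=6),
                Layer(center_um=330.0, thickness_um=60.0,
                      reflectivity=0.12, density=6),
                # bright specular RPE band: one reflector per column (the
                # global roughness_um jitter decorrelates its phase across
                # columns, as real optically-rough interfaces do, so it
                # cannot survive the volume-mean fixed-pattern estimate)
                Layer(center_um=400.0, thickness_um=0.0,
                      reflectivity=3.0, density=1, is_rpe=True),
            ],
            vessels=[
                # 30 and 36 um lumen diameters: typical small retinal
                # arteriole / venule calibers
                VesselTube(x_frac=0.30, depth_um=290.0, radius_um=15.0,
                           sigma_flow_um=lam0 / (8.0 * n),
                           reflectivity=0.25, density=4),
                VesselTube(x_frac=0.65, depth_um=320.0, radius_um=18.0,
                           sigma_flow_um=lam0 / (8.0 * n),
                           reflectivity=0.25, density=4),
            ],
            surface_poly=(0.0, 0.0, 0.0, 18.0, 14.0, 0.0),
            bulk_sigma_um=lam0 / 16.0,
            noise_sigma=0.02,
            fixed_pattern_amplitude=0.5,
            fixed_pattern_depth_um=60.0,
            n=n)
        return spec, source, protocol
    if name == "flow_bar":
        source = SourceModel(samples_per_ascan=512)
        protocol = ScanProtocol(fov_mm_x=0.16, fov_mm_y=0.16,
                                step_um_x=5.0, step_um_y=5.0,
                                repeats=5, samples_per_ascan=512,
                                sweep_rate_hz=1.7e6)
        n = 1.33
        spec = PhantomSpec(
            layers=[
                Layer(center_um=125.0, thickness_um=120.0,
                      reflectivity=0.15, density=8),
                Layer(center_um=375.0, thickness_um=120.0,
                      reflectivity=0.15, density=8, is_rpe=True),
            ],
            vessels=[
                FlowSlab(x0_frac=0.25, x1_frac=0.75,
                         y0_frac=0.25, y1_frac=0.75,
                         z0_um=200.0, z1_um=300.0,
                         sigma_flow_um=lam0 / (8.0 * n),
                         reflectivity=0.2, density=6),
            ],
            noise_sigma=0.02,
            n=n)
        return spec, source, protocol
    raise KeyError(f"unknown phantom preset {name!r}; "
                   "available: mirror, retina_small, flow_bar")


def simulate_volume(spec: PhantomSpec, source: SourceModel,
                    protocol: ScanProtocol, seed: int
                    ) -> tuple[RawSpectraVolume, GroundTruth]:
    """Render a raw spectral-fringe volume and its ground truth.

    Deterministic: the same (spec, source, protocol, seed) produce a
    bit-identical volume.  Static scatterers are drawn once per lateral
    position and shared by all repeats; vessel scatterers are re-jittered
    axially on every repeat; the bulk-motion phase is constant within each
    B-scan.
    """
    spec.validate(source)
    rng = np.random.default_rng(seed)
    ny = protocol.n_positions
    nx = protocol.a_scans_per_bscan
    nrep = protocol.repeats
    M = source.samples_per_ascan
    if M != protocol.samples_per_ascan:
        raise ValueError("source.samples_per_ascan must match protocol")
    n = spec.n

    k = source.k_of_sample()                     # (M,)
    env = source.envelope(k)
    theta = source.dispersion_phase(k)
    pitch = source.axial_pitch_um(n)
    depth_px = PAD_FACTOR * M // 2

    # lateral normalised grid for the curvature map
    X = (np.arange(nx) / max(nx - 1, 1)) * 2.0 - 1.0
    Y = (np.arange(ny) / max(ny - 1, 1)) * 2.0 - 1.0
    surf = spec.surface_um(X[None, :], Y[:, None])   # (ny, nx)

    # --- static scatterers: one draw per (y, x), reused by all repeats ---
    # depths (ny, nx, J_static) and shared amplitudes (J_static,)
    amps_static = []
    z_static_parts = []
    for lay in spec.layers:
        J = lay.density
        if J == 0:
            continue
        if lay.thickness_um > 0:
            dz = rng.uniform(-0.5, 0.5, size=(ny, nx, J)) * lay.thickness_um
        else:
            dz = np.zeros((ny, nx, J))
        if spec.roughness_um > 0:
            dz = dz + rng.normal(0.0, spec.roughness_um, size=(ny, nx, J))
        z_static_parts.append(lay.center_um + dz + surf[:, :, None])
        amps_static.append(np.full(J, 2.0 * math.sqrt(lay.reflectivity)))
    if z_static_parts:
        z_static = np.concatenate(z_static_parts, axis=2)
        a_static = np.concatenate(amps_static)
    else:
        z_static = np.zeros((ny, nx, 0))
        a_static = np.zeros(0)

    # RPE truth: the layer marked is_rpe (fallback: brightest layer)
    rpe_layers = [l for l in spec.layers if l.is_rpe]
    if not rpe_layers and spec.layers:
        rpe_layers = [max(spec.layers, key=lambda l: l.reflectivity)]
    rpe_depth_um = (np.full((ny, nx), rpe_layers[0].center_um) + surf
                    if rpe_layers else np.full((ny, nx), np.nan))

    # --- vessel scatterer *sites* (fixed); depths re-drawn per repeat ----
    # grouped by BM row: list of (x indices, base depths (nsite, J), amp, sigma)
    sites_by_row: list[list] = [[] for _ in range(ny)]
    x_um = np.arange(nx) * protocol.step_um_x
    for v in spec.vessels:
        if isinstance(v, VesselTube):
            xc = v.x_frac * (nx - 1) * protocol.step_um_x
            xs = np.where(np.abs(x_um - xc) <= v.radius_um)[0]
            if xs.size == 0:
                continue
            half = np.sqrt(np.maximum(v.radius_um ** 2
                                      - (x_um[xs] - xc) ** 2, 0.0))
            J = v.density
            for iy in range(ny):
                zz = (v.depth_um
                      + rng.uniform(-1, 1, size=(xs.size, J))
                      * half[:, None]
                      + surf[iy, xs, None])
                sites_by_row[iy].append(
                    (xs, zz, 2.0 * math.sqrt(v.reflectivity),
                     v.sigma_flow_um))
        elif isinstance(v, FlowSlab):
            ys = np.arange(int(v.y0_frac * ny), int(v.y1_frac * ny))
            xs = np.arange(int(v.x0_frac * nx), int(v.x1_frac * nx))
            if ys.size == 0 or xs.size == 0:
                continue
            J = v.density
            for iy in ys:
                zz = (rng.uniform(v.z0_um, v.z1_um, size=(xs.size, J))
                      + surf[iy, xs, None])
                sites_by_row[iy].append(
                    (xs, zz, 2.0 * math.sqrt(v.reflectivity),
                     v.sigma_flow_um))

    # --- bulk motion ----------------------------------------------------
    n_bscans = ny * nrep
    if spec.bulk_motion_um is not None:
        walk = np.asarray(spec.bulk_motion_um, dtype=float)
        if walk.shape != (n_bscans,):
            raise ValueError(f"bulk_motion_um must have shape ({n_bscans},)")
    elif spec.bulk_sigma_um > 0:
        walk = np.cumsum(rng.normal(0.0, spec.bulk_sigma_um, size=n_bscans))
    else:
        walk = np.zeros(n_bscans)
    bulk_phase = 2.0 * n * source.k0 * walk           # rad, per B-scan
    saccade_set = {s.bm_index: s for s in spec.saccades}
    for s in spec.saccades:
        if not (0 <= s.bm_index < ny):
            raise ValueError("saccade bm_index out of range")

    # fixed pattern: a spurious non-interferometric fringe, identical in
    # every A-scan (optical depth fixed_pattern_depth_um)
    if spec.fixed_pattern_amplitude > 0:
        fp = spec.fixed_pattern_amplitude * env * np.cos(
            2.0 * k * spec.fixed_pattern_depth_um)
    else:
        fp = np.zeros(M)

    two_nk = 2.0 * n * k                              # (M,)
    volume = np.empty((ny, nrep, nx, M), dtype=np.float64)
    bulk_phase_truth = bulk_phase.reshape(ny, nrep).copy()

    for iy in range(ny):
        sac = saccade_set.get(iy)
        for ir in range(nrep):
            b = iy * nrep + ir
            phi_b = bulk_phase[b]
            if sac is None:
                # static content is shared by all repeats of the BM-scan
                z_stat = z_static[iy]                  # (nx, J)
            else:
                # a saccade sweeps the beam laterally between repeats:
                # each repeat images progressively shifted tissue, so the
                # speckle content itself decorrelates — a per-column phase
                # offset cannot undo it (unlike pure axial bulk motion)
                z_stat = z_static[(iy + sac.shift_steps * ir) % ny]
                phi_b = rng.uniform(-math.pi, math.pi)
                bulk_phase_truth[iy, ir] = phi_b
            # static part: phases (nx, J, M) summed over J
            if a_static.size:
                ph = two_nk[None, None, :] * z_stat[:, :, None] \
                    + theta[None, None, :] + phi_b
                ac = np.einsum("j,xjm->xm", a_static, np.cos(ph))
            else:
                ac = np.zeros((nx, M))
            # vessels: depths re-jittered per repeat
            for xs_i, zbase, amp, sig in sites_by_row[iy]:
                zj = zbase + (rng.normal(0.0, sig, size=zbase.shape)
                              if sig > 0 else 0.0)
                phv = two_nk[None, None, :] * zj[:, :, None] \
                    + theta[None, None, :] + phi_b
                np.add.at(ac, xs_i, amp * np.cos(phv).sum(axis=1))
            fringe = env[None, :] * (spec.dc_level + ac) + fp[None, :]
            if spec.noise_sigma > 0:
                fringe = fringe + rng.normal(0.0, spec.noise_sigma,
                                             size=fringe.shape)
            volume[iy, ir] = fringe

    qdata, scale, offset = quantize_12bit(volume)
    cal = simulate_calibration_fringe(source)

    metadata = {
        "protocol": protocol.to_dict(),
        "source": source.to_dict(),
        "n": n,
        "seed": int(seed),
        "quant_scale": scale,
        "quant_offset": offset,
        "axial_pitch_um": pitch,
    }
    raw = RawSpectraVolume(data=qdata, calibration_fringe=cal,
                           metadata=metadata)
    truth = GroundTruth(
        vessel_mask=_vessel_voxels(spec, protocol, pitch, depth_px),
        rpe_depth_um=rpe_depth_um,
        rpe_depth_px=rpe_depth_um / pitch,
        bulk_phase_rad=bulk_phase_truth,
        saccade_indices=sorted(saccade_set),
        axial_pitch_um=pitch,
    )
    return raw, truth
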