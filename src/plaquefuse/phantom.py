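"""Parametric ground-truth vessel phantom and synthetic data rendering.

The phantom is a straight tube with an elliptical cross-section, a
smooth cosine-bump stenosis, two side branches, and a fibrous cap of
known thickness field over a configurable (arc-length x angle) region.
From it the module renders (a) biplane silhouette contours at 76 µm
pixel quantization and (b) a polar OCT pullback with a bright wall band
between the luminal and abluminal borders, exponential attenuation
beyond, multiplicative speckle, and a linear per-frame rotation drift
emulating catheter twist.  Every downstream stage of the pipeline is
testable against the stored ground truth without clinical data.

A small smooth lumen-radius undulation (default 40 µm amplitude, 4 mm
period) is included by default and the vessel sits at a generic
off-axis position in the angiographic field: real coronary lumens are
not perfect cylinders and are not centered on the detector, and a
perfectly constant, centered silhouette would turn the angiographic
pixel quantization into a systematic rather than averaging error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coregister import Landmark
from .errors import ConfigurationError
from .geometry import SideBranch, VesselGeometry, ellipse_polar_radius
from .grids import BinGrid
from .oct_cap import OctPullback, Roi
from .vessel_recon import MIN_VIEW_SEPARATION_DEG, ProjectionContours

__all__ = ["CapField", "PhantomConfig", "PhantomTruth", "make_phantom_vessel",
           "render_biplane", "render_oct_pullback", "default_config"]

ANGIO_PIXEL_MM = 0.076      # angiographic pixel size
SCAN_DEPTH_MM = 4.3         # OCT radial scan depth


@dataclass(frozen=True)
class CapField:
    """Descriptor of the ground-truth cap thickness field (µm).

    kinds:
      * ``constant``      params: thickness_um
      * ``linear_ramp``   params: start_um, end_um (ramp along arc-length)
      * ``gaussian_dip``  params: base_um, min_um (dip centered in the
        cap region, sigma = one fifth of each region extent)
    """

    kind: str
    params: dict

    def __post_init__(self) -> None:
        kinds = ("constant", "linear_ramp", "gaussian_dip")
        if self.kind not in kinds:
            raise ConfigurationError(f"cap_thickness_field.kind must be one of {kinds}")
        required = {
            "constant": ("thickness_um",),
            "linear_ramp": ("start_um", "end_um"),
            "gaussian_dip": ("base_um", "min_um"),
        }[self.kind]
        for key in required:
            if key not in self.params:
                raise ConfigurationError(f"cap_thickness_field missing parameter {key}")
            if not self.params[key] > 0:
                raise ConfigurationError(f"cap_thickness_field.{key} must be > 0")


@dataclass(frozen=True)
class PhantomConfig:
    """Full parameterization of the synthetic vessel and its rendering."""

    tube_length_mm: float = 24.0
    base_radius_mm: float = 1.85
    stenosis_depth: float = 0.35        # fractional radius reduction at center
    stenosis_center_mm: float = 12.0
    stenosis_width_mm: float = 6.0      # half-support of the cosine bump
    ellipticity: float = 0.85           # b/a
    branch_positions_mm: tuple[float, float] = (3.0, 21.0)
    branch_angles_deg: tuple[float, float] = (60.0, 200.0)
    branch_diameters_mm: tuple[float, float] = (2.2, 1.8)
    center_offset_mm: tuple[float, float] = (0.337, -0.211)
    cap_s_range_mm: tuple[float, float] = (9.0, 15.0)
    cap_theta_range_deg: tuple[float, float] = (120.0, 260.0)
    cap_thickness_field: CapField = field(
        default_factory=lambda: CapField("gaussian_dip", {"base_um": 300.0, "min_um": 100.0}))
    rotation_drift_deg_per_frame: float = 0.5
    noise: float = 0.2                  # multiplicative speckle amplitude
    seed: int = 0
    # imaging rasters
    n_alines: int = 968
    n_radial: int = 504
    inter_frame_um: float = 200.0
    # lumen realism: smooth radius undulation (absolute amplitude)
    waviness_amplitude_mm: float = 0.04
    waviness_period_mm: float = 4.0
    # wall band rendered beyond the lumen where no cap is defined
    wall_band_um: float = 800.0

    def __post_init__(self) -> None:
        def bad(name: str, why: str):
            return ConfigurationError(f"PhantomConfig.{name}: {why}")

        if self.tube_length_mm <= 0:
            raise bad("tube_length_mm", "must be > 0")
        if self.base_radius_mm <= 0:
            raise bad("base_radius_mm", "must be > 0")
        if not 0 <= self.stenosis_depth < 1:
            raise bad("stenosis_depth", "must be in [0, 1)")
        if self.stenosis_depth > 0:
            lo = self.stenosis_center_mm - self.stenosis_width_mm
            hi = self.stenosis_center_mm + self.stenosis_width_mm
            if lo < 0 or hi > self.tube_length_mm:
                raise bad("stenosis_center_mm",
                          "stenosis_center +/- stenosis_width must lie inside the tube")
        if not 0 < self.ellipticity <= 1:
            raise bad("ellipticity", "must be in (0, 1]")
        if self.branch_positions_mm[0] == self.branch_positions_mm[1]:
            raise bad("branch_positions_mm", "branch positions must be distinct")
        for s in self.branch_positions_mm:
            if not 0 <= s <= self.tube_length_mm:
                raise bad("branch_positions_mm", f"position {s} outside the tube")
        for ang in self.branch_angles_deg:
            if not 0 <= ang < 360:
                raise bad("branch_angles_deg", "angles must be in [0, 360)")
        s0, s1 = self.cap_s_range_mm
        if not (0 <= s0 < s1 <= self.tube_length_mm):
            raise bad("cap_s_range_mm", "must be an increasing range inside the tube")
        if self.noise < 0:
            raise bad("noise", "must be >= 0")
        if self.n_alines < 8 or self.n_radial < 8:
            raise bad("n_alines/n_radial", "raster too small")
        if self.inter_frame_um <= 0:
            raise bad("inter_frame_um", "must be > 0")
        if not 0 <= self.waviness_amplitude_mm < 0.2 * self.base_radius_mm:
            raise bad("waviness_amplitude_mm",
                      "must be in [0, 0.2 * base_radius_mm)")

    @property
    def radial_pixel_um(self) -> float:
        return SCAN_DEPTH_MM * 1000.0 / self.n_radial

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.tube_length_mm * 1000.0 / self.inter_frame_um)) + 1


def default_config(**overrides) -> PhantomConfig:
    """The package's default study phantom.

    Keeps the clinical radial sampling (504 samples over 4.3 mm) but
    uses 360 A-lines per frame, a desk-scale angular sampling that
    leaves the thickness accuracy (set by the radial pixel) unchanged.
    """
    kwargs = dict(n_alines=360)
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Ground truth bundle: geometry, per-frame contours, rotation drift."""

    config: PhantomConfig
    geometry: VesselGeometry
    frame_z_mm: np.ndarray              # (n_frames,)
    rotation_offset_deg: np.ndarray     # (n_frames,) linear drift
    lumen_radius_um: np.ndarray         # (n_frames, n_alines), frame coords
    abluminal_radius_um: np.ndarray     # NaN outside the cap region

    def thickness_um(self, s_mm, theta_deg) -> np.ndarray:
        """True cap thickness at vessel coordinates; NaN outside the cap."""
        return _thickness_field(self.config, np.asarray(s_mm, float),
                                np.asarray(theta_deg, float))

    def thickness_map(self, grid: BinGrid) -> np.ndarray:
        """True thickness field at bin centers of a cut-open grid."""
        s = grid.s_centers()
        t = grid.theta_centers()
        ss, tt = np.meshgrid(s, t, indexing="ij")
        return self.thickness_um(ss, tt)

    def cap_roi(self, margin_deg: float = 5.0) -> Roi:
        """ROI annotation covering the cap across all cap frames, in OCT
        frame coordinates (accounts for the rotation drift)."""
        cfg = self.config
        dz = cfg.inter_frame_um / 1000.0
        f0 = int(math.ceil(cfg.cap_s_range_mm[0] / dz))
        f1 = int(math.floor(cfg.cap_s_range_mm[1] / dz))
        th0, th1 = cfg.cap_theta_range_deg
        offs = self.rotation_offset_deg[f0:f1 + 1]
        lo = th0 - offs.max() - margin_deg
        hi = th1 - offs.min() + margin_deg
        per_aline = 360.0 / cfg.n_alines
        a0 = int(math.floor(lo / per_aline)) % cfg.n_alines
        a1 = int(math.ceil(hi / per_aline)) % cfg.n_alines
        return Roi(frame_first=f0, frame_last=f1, aline_first=a0, aline_last=a1)

    def landmarks(self) -> list[Landmark]:
        """Side-branch landmark annotations in both modalities."""
        cfg = self.config
        dz = cfg.inter_frame_um / 1000.0
        out = []
        for i, br in enumerate(self.geometry.branches):
            frame = int(round(br.s_mm / dz))
            oct_orientation = (br.angle_deg - self.rotation_offset_deg[frame]) % 360.0
            out.append(Landmark(
                label=br.label or f"branch_{i}",
                frame_index=frame,
                s_mm=br.s_mm,
                map_orientation_deg=br.angle_deg,
                oct_orientation_deg=oct_orientation,
                kind="side_branch"))
        return out


def _radius_profile(cfg: PhantomConfig, s: np.ndarray) -> np.ndarray:
    """Major semi-axis along the vessel (mm)."""
    a = np.full_like(s, cfg.base_radius_mm, dtype=float)
    if cfg.stenosis_depth > 0:
        u = (s - cfg.stenosis_center_mm) / cfg.stenosis_width_mm
        bump = np.where(np.abs(u) <= 1.0, 0.5 * (1 + np.cos(np.pi * u)), 0.0)
        a = a * (1.0 - cfg.stenosis_depth * bump)
    if cfg.waviness_amplitude_mm > 0:
        a = a + cfg.waviness_amplitude_mm * np.sin(
            2 * np.pi * s / cfg.waviness_period_mm)
    return a


def _in_angular_range(theta_deg: np.ndarray, lo: float, hi: float) -> np.ndarray:
    width = (hi - lo) % 360.0
    if width == 0:
        width = 360.0
    return (theta_deg - lo) % 360.0 <= width


def _thickness_field(cfg: PhantomConfig, s: np.ndarray, theta: np.ndarray) -> np.ndarray:
    s0, s1 = cfg.cap_s_range_mm
    th0, th1 = cfg.cap_theta_range_deg
    inside = (s >= s0) & (s <= s1) & _in_angular_range(theta, th0, th1)
    f = cfg.cap_thickness_field
    if f.kind == "constant":
        t = np.full_like(np.asarray(s, float), f.params["thickness_um"])
    elif f.kind == "linear_ramp":
        frac = np.clip((s - s0) / (s1 - s0), 0, 1)
        t = f.params["start_um"] + frac * (f.params["end_um"] - f.params["start_um"])
    else:  # gaussian_dip
        sc = 0.5 * (s0 + s1)
        theta_width = (th1 - th0) % 360.0 or 360.0
        thc = (th0 + theta_width / 2.0) % 360.0
        dth = (theta - thc + 180.0) % 360.0 - 180.0
        sig_s = (s1 - s0) / 5.0
        sig_t = theta_width / 5.0
        dip = np.exp(-0.5 * ((s - sc) / sig_s) ** 2 - 0.5 * (dth / sig_t) ** 2)
        t = f.params["base_um"] - (f.params["base_um"] - f.params["min_um"]) * dip
    return np.where(inside, t, np.nan)


def make_phantom_vessel(config: PhantomConfig, ds_mm: float = 0.1) -> PhantomTruth:
    """Build the ground-truth bundle for a phantom configuration."""
    if ds_mm <= 0 or ds_mm > 0.2:
        raise ConfigurationError("ds_mm must be in (0, 0.2]")
    cfg = config
    n_geom = int(round(cfg.tube_length_mm / ds_mm)) + 1
    s = np.linspace(0.0, cfg.tube_length_mm, n_geom)
    a = _radius_profile(cfg, s)
    b = cfg.ellipticity * a
    x0, y0 = cfg.center_offset_mm
    centerline = np.column_stack([np.full(n_geom, x0), np.full(n_geom, y0), s])
    branches = [
        SideBranch(s_mm=cfg.branch_positions_mm[i],
                   angle_deg=cfg.branch_angles_deg[i],
                   diameter_mm=cfg.branch_diameters_mm[i],
                   label=("proximal_branch", "distal_branch")[i])
        for i in np.argsort(cfg.branch_positions_mm)
    ]
    geometry = VesselGeometry(s_mm=s, centerline_mm=centerline, a_mm=a, b_mm=b,
                              psi_deg=np.zeros(n_geom), branches=branches)

    n_frames = cfg.n_frames
    dz = cfg.inter_frame_um / 1000.0
    z = np.arange(n_frames) * dz
    offsets = cfg.rotation_drift_deg_per_frame * np.arange(n_frames)

    aline_angle = np.arange(cfg.n_alines) * 360.0 / cfg.n_alines
    theta_vessel = (aline_angle[None, :] + offsets[:, None]) % 360.0  # (F, A)
    a_f = _radius_profile(cfg, z)[:, None]
    b_f = cfg.ellipticity * a_f
    lumen_mm = ellipse_polar_radius(a_f, b_f, np.deg2rad(theta_vessel))
    lumen_um = lumen_mm * 1000.0
    thick = _thickness_field(cfg, np.broadcast_to(z[:, None], theta_vessel.shape),
                             theta_vessel)
    abluminal_um = lumen_um + thick

    truth = PhantomTruth(
        config=cfg, geometry=geometry, frame_z_mm=z,
        rotation_offset_deg=offsets, lumen_radius_um=lumen_um,
        abluminal_radius_um=abluminal_um)
    return truth


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_biplane(
    truth: PhantomTruth,
    view_angles: tuple[float, float] = (0.0, 90.0),
) -> tuple[ProjectionContours, ProjectionContours]:
    """Orthographic silhouette polylines of the lumen in two views.

    Edge positions are quantized to the angiographic pixel grid
    (76 µm); the longitudinal sampling pitch equals the pixel size.
    """
    aA, aB = view_angles
    d = abs(aA - aB) % 180.0
    if min(d, 180.0 - d) < MIN_VIEW_SEPARATION_DEG:
        raise ConfigurationError(
            f"view angles must differ by at least {MIN_VIEW_SEPARATION_DEG} deg; "
            f"got {aA} and {aB}")
    geom = truth.geometry
    s_pix = np.arange(0.0, geom.s_mm[-1] + 1e-9, ANGIO_PIXEL_MM)
    a = np.interp(s_pix, geom.s_mm, geom.a_mm)
    b = np.interp(s_pix, geom.s_mm, geom.b_mm)
    psi = np.deg2rad(np.interp(s_pix, geom.s_mm, geom.psi_deg))
    cx = np.interp(s_pix, geom.s_mm, geom.centerline_mm[:, 0])
    cy = np.interp(s_pix, geom.s_mm, geom.centerline_mm[:, 1])

    def _view(alpha_deg: float) -> ProjectionContours:
        alpha = np.deg2rad(alpha_deg)
        half = np.sqrt(a ** 2 * np.sin(alpha - psi) ** 2
                       + b ** 2 * np.cos(alpha - psi) ** 2)
        mid = -np.sin(alpha) * cx + np.cos(alpha) * cy
        q = ANGIO_PIXEL_MM
        left = np.round((mid - half) / q) * q
        right = np.round((mid + half) / q) * q
        return ProjectionContours(view_angle_deg=alpha_deg, s_mm=s_pix,
                                  y_left_mm=left, y_right_mm=right, pixel_mm=q)

    return _view(aA), _view(aB)


def render_oct_pullback(truth: PhantomTruth, config: PhantomConfig | None = None
                        ) -> OctPullback:
    """Render the polar OCT pullback for a phantom truth bundle.

    Radial intensity template per A-line: dark lumen (0.04), bright band
    of unit intensity between the luminal border and the abluminal cap
    border (or a default wall band where no cap is defined), then a
    darker exponentially attenuated region beyond.  Multiplicative
    speckle of the configured amplitude is applied; rendering is a pure
    function of (truth, config) and the seed.
    """
    cfg = config or truth.config
    pix = cfg.radial_pixel_um
    n_f, n_a = truth.lumen_radius_um.shape
    r = (np.arange(cfg.n_radial) + 0.5) * pix          # radial sample centers, µm

    lum = truth.lumen_radius_um[..., None]             # (F, A, 1)
    abl = truth.abluminal_radius_um.copy()
    no_cap = ~np.isfinite(abl)
    abl[no_cap] = truth.lumen_radius_um[no_cap] + cfg.wall_band_um
    abl = abl[..., None]

    intensity = np.empty((n_f, n_a, cfg.n_radial), dtype=np.float32)
    rr = r[None, None, :]
    tail = 0.45 * np.exp(-(rr - abl) / 500.0)
    intensity[:] = np.where(rr < lum, 0.04, np.where(rr < abl, 1.0, tail))

    if cfg.noise > 0:
        rng = np.random.default_rng(cfg.seed)
        g = rng.standard_normal(intensity.shape).astype(np.float32)
        np.clip(g, -3.0, 3.0, out=g)
        intensity *= 1.0 + cfg.noise * g
        np.clip(intensity, 0.0, None, out=intensity)

    return OctPullback(frames=intensity, radial_pixel_um=pix,
                       inter_frame_um=cfg.inter_frame_um)
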