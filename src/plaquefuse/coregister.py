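"""Co-registration of the OCT pullback with the angiographic geometry.

Two steps: *axial* registration maps OCT frame indices to centerline
arc-length through pairs of matched landmarks (side branches,
narrowings, pullback endpoints); *rotational* registration determines a
per-frame rotation offset from the orientations of two side branches in
both modalities, linearly interpolated in frame index between the two
anchors (constant outside), taking the shortest signed arc between the
anchor offsets.  OCT A-line ``i`` maps to angle ``i * 360 / n_alines``
degrees counterclockwise before the rotational offset is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, RegistrationError
from .grids import BinGrid, CapMap2D, bin_samples
from .oct_cap import ThicknessProfile

__all__ = ["Landmark", "Registration", "AgreementStats", "axial_map",
           "rotational_map", "resample_cap_to_grid", "length_agreement",
           "area_agreement", "wrap_angle_deg"]


def wrap_angle_deg(x):
    """Wrap angles to (-180, 180]."""
    w = np.asarray(x, dtype=float)
    out = (w + 180.0) % 360.0 - 180.0
    out = np.where(out == -180.0, 180.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Landmark:
    """A matched anatomical landmark in both modalities."""

    label: str
    frame_index: int
    s_mm: float
    kind: str = "side_branch"           # side_branch | narrowing | pullback_end
    map_orientation_deg: float | None = None   # angular position on the cut-open map
    oct_orientation_deg: float | None = None   # angular position in the OCT frame


@dataclass
class Registration:
    """Axial (frame -> arc-length) and rotational (frame -> offset) mapping."""

    anchor_frames: np.ndarray           # axial anchors, strictly increasing
    anchor_s_mm: np.ndarray
    rot_anchor_frames: tuple[int, int] | None = None
    rot_anchor_offsets_deg: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.anchor_frames = np.asarray(self.anchor_frames, dtype=float)
        self.anchor_s_mm = np.asarray(self.anchor_s_mm, dtype=float)
        if self.anchor_frames.size < 2:
            raise RegistrationError("axial registration needs >= 2 landmark pairs")
        if np.any(np.diff(self.anchor_frames) <= 0) or np.any(np.diff(self.anchor_s_mm) <= 0):
            raise RegistrationError(
                "landmark anchors must be strictly increasing in both frame and s")

    def frame_to_s(self, frames) -> np.ndarray | float:
        """Piecewise-linear interpolation through the anchors, linearly
        extrapolated beyond the first/last pair."""
        f = np.asarray(frames, dtype=float)
        fa, sa = self.anchor_frames, self.anchor_s_mm
        out = np.interp(f, fa, sa)
        lo = f < fa[0]
        hi = f > fa[-1]
        slope0 = (sa[1] - sa[0]) / (fa[1] - fa[0])
        slope1 = (sa[-1] - sa[-2]) / (fa[-1] - fa[-2])
        out = np.where(lo, sa[0] + (f - fa[0]) * slope0, out)
        out = np.where(hi, sa[-1] + (f - fa[-1]) * slope1, out)
        return float(out) if out.ndim == 0 else out

    def rotation_offset(self, frames) -> np.ndarray | float:
        """Per-frame rotation offset in degrees, wrapped to (-180, 180]."""
        if self.rot_anchor_frames is None:
            raise RegistrationError("rotational registration not set")
        f = np.asarray(frames, dtype=float)
        (fa, fb) = self.rot_anchor_frames
        (oa, ob) = self.rot_anchor_offsets_deg
        delta = wrap_angle_deg(ob - oa)   # shortest signed arc
        t = np.clip((f - fa) / (fb - fa), 0.0, 1.0)
        out = wrap_angle_deg(oa + t * delta)
        return float(out) if np.ndim(out) == 0 else out


def axial_map(pairs: list[Landmark]) -> Registration:
    """Axial registration through >= 2 matched landmark pairs."""
    if len(pairs) < 2:
        raise RegistrationError("axial registration needs >= 2 landmark pairs")
    pairs = sorted(pairs, key=lambda p: p.frame_index)
    frames = np.array([p.frame_index for p in pairs], dtype=float)
    s = np.array([p.s_mm for p in pairs], dtype=float)
    if np.any(np.diff(frames) <= 0):
        raise RegistrationError("landmark frames must be distinct")
    if np.any(np.diff(s) <= 0):
        raise RegistrationError("landmark arc-lengths must increase with frame index")
    return Registration(anchor_frames=frames, anchor_s_mm=s)


def rotational_map(branchA: Landmark, branchB: Landmark,
                   axial: Registration) -> Registration:
    """Add rotational registration from two side-branch orientations.

    The anchor offset at each branch frame is the cut-open-map
    orientation minus the OCT orientation, wrapped to (-180, 180]; in
    between, offsets are linear in frame index along the shortest arc,
    and constant beyond the anchors.
    """
    for br in (branchA, branchB):
        if br.map_orientation_deg is None or br.oct_orientation_deg is None:
            raise RegistrationError(
                f"landmark {br.label!r} lacks an orientation in one modality")
    if branchA.frame_index == branchB.frame_index:
        raise RegistrationError("rotational anchors must be at distinct frames")
    a, b = sorted((branchA, branchB), key=lambda p: p.frame_index)
    off_a = wrap_angle_deg(a.map_orientation_deg - a.oct_orientation_deg)
    off_b = wrap_angle_deg(b.map_orientation_deg - b.oct_orientation_deg)
    return Registration(
        anchor_frames=axial.anchor_frames, anchor_s_mm=axial.anchor_s_mm,
        rot_anchor_frames=(a.frame_index, b.frame_index),
        rot_anchor_offsets_deg=(off_a, off_b))


def resample_cap_to_grid(
    profiles: list[ThicknessProfile],
    reg: Registration,
    grid: BinGrid,
    n_alines: int,
) -> CapMap2D:
    """Place every valid thickness sample at its registered (s, theta)
    position and average per bin of the shared grid."""
    s_all, th_all, v_all = [], [], []
    for p in profiles:
        valid = p.valid
        if not np.any(valid):
            continue
        s = reg.frame_to_s(p.frame_index)
        off = reg.rotation_offset(p.frame_index)
        th = p.alines[valid] * 360.0 / n_alines + off
        s_all.append(np.full(int(valid.sum()), s))
        th_all.append(th)
        v_all.append(p.thickness_um[valid])
    if not s_all:
        values = np.full(grid.shape, np.nan)
        return CapMap2D(grid=grid, values=values, counts=np.zeros(grid.shape, int))
    values, counts = bin_samples(np.concatenate(s_all), np.concatenate(th_all),
                                 np.concatenate(v_all), grid)
    return CapMap2D(grid=grid, values=values, counts=counts)


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman style agreement between paired length measurements."""

    mean_abs_diff_mm: float
    pct_of_length: float
    bias_mm: float
    loa_mm: tuple[float, float]         # bias +/- 1.96 SD of the differences
    pearson_r: float


def length_agreement(oct_lengths_mm, angio_lengths_mm) -> AgreementStats:
    """Agreement statistics between paired OCT and angiographic lengths."""
    a = np.asarray(oct_lengths_mm, dtype=float)
    b = np.asarray(angio_lengths_mm, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("length lists must be paired 1D arrays")
    if a.size < 2:
        raise ConfigurationError("need >= 2 pairs for agreement statistics")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    mean_abs = float(np.mean(np.abs(d)))
    mean_len = float(np.mean((a + b) / 2.0))
    if np.std(a) == 0 or np.std(b) == 0:
        r = 1.0 if np.allclose(a, b) else float("nan")
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return AgreementStats(
        mean_abs_diff_mm=mean_abs,
        pct_of_length=100.0 * mean_abs / mean_len,
        bias_mm=bias,
        loa_mm=(bias - 1.96 * sd, bias + 1.96 * sd),
        pearson_r=r)


def area_agreement(oct_areas_mm2, recon_areas_mm2) -> float:
    """Pearson correlation between paired lumen areas from the two
    modalities."""
    a = np.asarray(oct_areas_mm2, dtype=float)
    b = np.asarray(recon_areas_mm2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ConfigurationError("need >= 3 paired areas")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ConfigurationError("area correlation undefined for zero variance")
    return float(stats.pearsonr(a, b).statistic)
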