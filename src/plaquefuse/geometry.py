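"""3D lumen geometry: centerline samples with elliptical cross-sections.

Conventions
-----------
* Arc-length ``s`` is 0 at the proximal end of the un-extended segment
  and increases distally (mm).
* The cross-section at each sample is an ellipse with semi-axes
  ``a >= b > 0`` (mm) and in-plane orientation ``psi`` (degrees) of the
  major axis, measured counterclockwise viewed from proximal to distal.
* The angular surface coordinate ``theta`` is 0 at the major axis of
  the first sample and increases counterclockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["SideBranch", "VesselGeometry", "section_area", "extend_inlets_outlets",
           "ellipse_polar_radius"]


@dataclass(frozen=True)
class SideBranch:
    """A side-branch take-off used as landmark and flow outlet."""

    s_mm: float
    angle_deg: float
    diameter_mm: float
    label: str = ""


@dataclass
class VesselGeometry:
    """Centerline samples with per-sample elliptical cross-sections."""

    s_mm: np.ndarray            # (N,) strictly increasing arc-length
    centerline_mm: np.ndarray   # (N, 3) points
    a_mm: np.ndarray            # (N,) major semi-axes
    b_mm: np.ndarray            # (N,) minor semi-axes
    psi_deg: np.ndarray         # (N,) major-axis orientation
    branches: list[SideBranch] = field(default_factory=list)
    is_extension: np.ndarray | None = None  # (N,) True on inlet/outlet extensions

    def __post_init__(self) -> None:
        self.s_mm = np.asarray(self.s_mm, dtype=float)
        self.centerline_mm = np.asarray(self.centerline_mm, dtype=float)
        self.a_mm = np.asarray(self.a_mm, dtype=float)
        self.b_mm = np.asarray(self.b_mm, dtype=float)
        self.psi_deg = np.asarray(self.psi_deg, dtype=float)
        if self.is_extension is None:
            self.is_extension = np.zeros(self.s_mm.shape, dtype=bool)
        else:
            self.is_extension = np.asarray(self.is_extension, dtype=bool)
        n = self.s_mm.size
        if self.centerline_mm.shape != (n, 3):
            raise ConfigurationError("centerline_mm must have shape (N, 3)")
        for name in ("a_mm", "b_mm", "psi_deg", "is_extension"):
            if getattr(self, name).shape != (n,):
                raise ConfigurationError(f"{name} must have shape (N,)")
        if np.any(np.diff(self.s_mm) <= 0):
            raise ConfigurationError("s_mm must be strictly increasing")
        if np.any(self.b_mm <= 0) or np.any(self.a_mm < self.b_mm):
            raise ConfigurationError("semi-axes must satisfy a >= b > 0")
        core_s = self.s_mm[~self.is_extension]
        for br in self.branches:
            if not (core_s[0] - 1e-9 <= br.s_mm <= core_s[-1] + 1e-9):
                raise ConfigurationError(
                    f"branch at s={br.s_mm} mm outside segment [{core_s[0]}, {core_s[-1]}]")

    @property
    def n_samples(self) -> int:
        return self.s_mm.size

    @property
    def length_mm(self) -> float:
        """Arc-length of the un-extended segment."""
        core = self.s_mm[~self.is_extension]
        return float(core[-1] - core[0])

    def equivalent_diameter_mm(self) -> np.ndarray:
        """Area-equivalent circular diameter 2*sqrt(a*b) per sample."""
        return 2.0 * np.sqrt(self.a_mm * self.b_mm)

    def interp_axes(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Semi-axes linearly interpolated at arbitrary arc-lengths."""
        s = np.asarray(s, dtype=float)
        return (np.interp(s, self.s_mm, self.a_mm),
                np.interp(s, self.s_mm, self.b_mm))


def ellipse_polar_radius(a: np.ndarray, b: np.ndarray, theta_rad: np.ndarray) -> np.ndarray:
    """Center-to-boundary distance of an ellipse at polar angle ``theta``.

    ``theta`` is measured from the major axis; r = ab / sqrt((b cos t)^2
    + (a sin t)^2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t = np.asarray(theta_rad, dtype=float)
    return a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def section_area(a_mm: float | np.ndarray, b_mm: float | np.ndarray) -> float | np.ndarray:
    """Cross-sectional lumen area of an elliptical section, pi*a*b (mm^2)."""
    a = np.asarray(a_mm, dtype=float)
    b = np.asarray(b_mm, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ConfigurationError("semi-axes must be positive")
    out = np.pi * a * b
    return float(out) if out.ndim == 0 else out


def extend_inlets_outlets(geom: VesselGeometry, factor: float = 5.0) -> VesselGeometry:
    """Add straight inlet/outlet extensions of ``factor`` x local mean radius.

    The appended samples carry the end cross-section unchanged and are
    flagged ``is_extension`` so that surface maps exclude them.  With
    ``factor == 0`` the geometry is returned unchanged.
    """
    if geom.n_samples < 2:
        raise ConfigurationError("geometry needs >= 2 samples to extend")
    if factor < 0:
        raise ConfigurationError("factor must be >= 0")
    if factor == 0:
        return geom

    ds = float(np.median(np.diff(geom.s_mm)))

    def _straight(end: int, direction: float) -> dict:
        r_mean = 0.5 * (geom.a_mm[end] + geom.b_mm[end])
        length = factor * r_mean
        n_new = max(int(np.ceil(length / ds)), 1)
        offs = direction * np.arange(1, n_new + 1) * (length / n_new)
        # tangent from the end pair of samples
        if direction < 0:
            tangent = geom.centerline_mm[0] - geom.centerline_mm[1]
        else:
            tangent = geom.centerline_mm[-1] - geom.centerline_mm[-2]
        tangent = tangent / np.linalg.norm(tangent)
        pts = geom.centerline_mm[end] + np.abs(offs)[:, None] * tangent
        return {"s": geom.s_mm[end] + offs, "pts": pts, "n": n_new, "end": end}

    pre = _straight(0, -1.0)
    post = _straight(geom.n_samples - 1, +1.0)

    s = np.concatenate([pre["s"][::-1], geom.s_mm, post["s"]])
    pts = np.vstack([pre["pts"][::-1], geom.centerline_mm, post["pts"]])
    a = np.concatenate([np.full(pre["n"], geom.a_mm[0]), geom.a_mm,
                        np.full(post["n"], geom.a_mm[-1])])
    b = np.concatenate([np.full(pre["n"], geom.b_mm[0]), geom.b_mm,
                        np.full(post["n"], geom.b_mm[-1])])
    psi = np.concatenate([np.full(pre["n"], geom.psi_deg[0]), geom.psi_deg,
                          np.full(post["n"], geom.psi_deg[-1])])
    ext = np.concatenate([np.ones(pre["n"], bool),
                          np.asarray(geom.is_extension),
                          np.ones(post["n"], bool)])
    return VesselGeometry(s, pts, a, b, psi, branches=list(geom.branches),
                          is_extension=ext)
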