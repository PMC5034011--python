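"""Wall shear stress on the reconstructed lumen surface.

Boundary flows follow empirical diameter-based scaling laws,
``Q = k * D^e``, both for the absolute inflow and for the outflow split
over bifurcations (split proportional to D^e of the daughters).  The
surface WSS field is the exact fully developed laminar solution of a
straight elliptical duct applied section-by-section: with volumetric
flow Q through a section of semi-axes a, b the axial pressure gradient
is ``G = 4 mu Q (a^2 + b^2) / (pi a^3 b^3)`` and the boundary shear
magnitude at ellipse parameter angle phi is

    tau(phi) = (G a^2 b^2 / (a^2 + b^2)) * sqrt(cos^2 phi / a^2 + sin^2 phi / b^2)

which reduces to the Hagen-Poiseuille value ``4 mu Q / (pi r^3)`` for a
circle.  This steady surrogate replaces volume-mesh CFD; externally
computed WSS samples can be imported instead and are interchangeable
downstream.  Maps are binned on the shared cut-open grid and optionally
normalized by their 50th percentile, which makes them invariant to a
global rescaling of the inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, NormalizationError
from .geometry import VesselGeometry
from .grids import BinGrid, WssMap2D, bin_samples

__all__ = ["HemoConfig", "FlowAssignment", "assign_flows", "surrogate_wss",
           "import_external_wss", "export_wss_samples", "bin_wss", "normalize_map"]


@dataclass(frozen=True)
class HemoConfig:
    """Blood and scaling-law parameters for the steady surrogate.

    viscosity_pa_s : dynamic viscosity of blood (Pa*s).
    flow_coeff_k : coefficient of Q = k * D^e with D in mm and Q in
        m^3/s; the default gives ~1 mL/s at D = 3 mm.
    flow_exponent_e : empirical coronary flow-diameter exponent.
    """

    viscosity_pa_s: float = 3.5e-3
    flow_coeff_k: float = 1.0e-6 / 3.0 ** 2.27
    flow_exponent_e: float = 2.27

    def __post_init__(self) -> None:
        if self.viscosity_pa_s <= 0:
            raise ConfigurationError("viscosity_pa_s must be > 0")
        if self.flow_exponent_e <= 0:
            raise ConfigurationError("flow_exponent_e must be > 0")
        if self.flow_coeff_k <= 0:
            raise ConfigurationError("flow_coeff_k must be > 0")


@dataclass
class FlowAssignment:
    """Flow through the main vessel between branch take-offs (m^3/s)."""

    inlet_q: float
    boundaries_s_mm: np.ndarray     # branch arc-lengths, ascending
    segment_q: np.ndarray           # len = len(boundaries) + 1
    branch_outflow_q: np.ndarray    # outflow through each branch
    branch_fraction: np.ndarray     # fraction of local flow taken by each branch

    def q_at(self, s_mm) -> np.ndarray | float:
        """Main-vessel flow at arc-length s."""
        idx = np.searchsorted(self.boundaries_s_mm, np.asarray(s_mm, float),
                              side="right")
        out = self.segment_q[idx]
        return float(out) if np.ndim(out) == 0 else out

    @property
    def outlet_q(self) -> float:
        return float(self.segment_q[-1])


def assign_flows(geom: VesselGeometry, cfg: HemoConfig | None = None) -> FlowAssignment:
    """Diameter-based scaling-law boundary flows with exact conservation.

    Inlet flow is ``k * D_inlet^e``; at every branch the local flow
    splits between the branch and the distal main vessel proportional
    to ``D^e`` of the two daughters.
    """
    cfg = cfg or HemoConfig()
    core = ~geom.is_extension
    d = geom.equivalent_diameter_mm()
    if np.any(d <= 0):
        raise ConfigurationError("zero or negative equivalent diameter in geometry")
    d_inlet = float(d[core][0])
    q = cfg.flow_coeff_k * d_inlet ** cfg.flow_exponent_e

    branches = sorted(geom.branches, key=lambda b: b.s_mm)
    boundaries, seg_q, br_q, br_frac = [], [q], [], []
    for br in branches:
        if br.diameter_mm <= 0:
            raise ConfigurationError(f"branch {br.label!r} has non-positive diameter")
        # distal main diameter just beyond the take-off
        after = geom.s_mm > br.s_mm
        d_main = float(d[after][0]) if np.any(after) else float(d[-1])
        wb = br.diameter_mm ** cfg.flow_exponent_e
        wm = d_main ** cfg.flow_exponent_e
        frac = wb / (wb + wm)
        q_branch = seg_q[-1] * frac
        boundaries.append(br.s_mm)
        br_q.append(q_branch)
        br_frac.append(frac)
        seg_q.append(seg_q[-1] - q_branch)   # conservation exact by construction
    return FlowAssignment(
        inlet_q=q,
        boundaries_s_mm=np.asarray(boundaries, float),
        segment_q=np.asarray(seg_q, float),
        branch_outflow_q=np.asarray(br_q, float),
        branch_fraction=np.asarray(br_frac, float))


def elliptical_duct_wss(a_mm, b_mm, q_m3s, mu_pa_s, phi_rad) -> np.ndarray:
    """Boundary shear magnitude of fully developed elliptical-duct flow (Pa)."""
    a = np.asarray(a_mm, float) * 1e-3
    b = np.asarray(b_mm, float) * 1e-3
    q = np.asarray(q_m3s, float)
    G = 4.0 * mu_pa_s * q * (a ** 2 + b ** 2) / (np.pi * a ** 3 * b ** 3)
    pref = G * a ** 2 * b ** 2 / (a ** 2 + b ** 2)
    return pref * np.sqrt(np.cos(phi_rad) ** 2 / a ** 2
                          + np.sin(phi_rad) ** 2 / b ** 2)


def surrogate_wss(
    geom: VesselGeometry,
    flows: FlowAssignment | None = None,
    cfg: HemoConfig | None = None,
    n_boundary: int = 360,
) -> pd.DataFrame:
    """Per-(s, theta) WSS samples on the un-extended lumen surface.

    Returns a DataFrame with columns ``s_mm``, ``theta_deg``,
    ``wss_pa``; ``theta`` is the surface polar angle of the boundary
    point (ellipse parameter angle mapped through the section
    orientation), so samples bin directly onto the shared grid.
    """
    cfg = cfg or HemoConfig()
    if flows is None:
        flows = assign_flows(geom, cfg)
    core = ~geom.is_extension
    phi = (np.arange(n_boundary) + 0.5) * 2.0 * np.pi / n_boundary
    rows_s, rows_t, rows_w = [], [], []
    a_all = geom.a_mm[core]
    b_all = geom.b_mm[core]
    psi_all = geom.psi_deg[core]
    s_all = geom.s_mm[core]
    q_all = np.atleast_1d(flows.q_at(s_all))
    for a, b, psi, s, q in zip(a_all, b_all, psi_all, s_all, q_all):
        tau = elliptical_duct_wss(a, b, q, cfg.viscosity_pa_s, phi)
        theta = (np.rad2deg(np.arctan2(b * np.sin(phi), a * np.cos(phi))) + psi) % 360.0
        rows_s.append(np.full(n_boundary, s))
        rows_t.append(theta)
        rows_w.append(tau)
    return pd.DataFrame({
        "s_mm": np.concatenate(rows_s),
        "theta_deg": np.concatenate(rows_t),
        "wss_pa": np.concatenate(rows_w),
    })


REQUIRED_WSS_COLUMNS = ("s_mm", "theta_deg", "wss_pa")


def import_external_wss(path) -> pd.DataFrame:
    """Load externally computed WSS samples (e.g. CFD results).

    The CSV must have columns s_mm, theta_deg, wss_pa; rows are sorted
    by (s, theta) and validated, making the result interchangeable with
    :func:`surrogate_wss` output.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_WSS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    bad = np.where(df["wss_pa"].to_numpy() < 0)[0]
    if bad.size:
        raise FormatError(f"{path}: negative WSS at row {int(bad[0]) + 2}")
    if not np.all(np.isfinite(df[list(REQUIRED_WSS_COLUMNS)].to_numpy())):
        raise FormatError(f"{path}: non-finite values")
    return (df[list(REQUIRED_WSS_COLUMNS)]
            .sort_values(["s_mm", "theta_deg"], kind="stable")
            .reset_index(drop=True))


def export_wss_samples(samples: pd.DataFrame, path) -> None:
    samples[list(REQUIRED_WSS_COLUMNS)].to_csv(path, index=False)


def bin_wss(samples: pd.DataFrame, grid: BinGrid) -> WssMap2D:
    """Arithmetic per-bin mean of the WSS samples on the cut-open grid."""
    values, counts = bin_samples(samples["s_mm"].to_numpy(),
                                 samples["theta_deg"].to_numpy(),
                                 samples["wss_pa"].to_numpy(), grid)
    return WssMap2D(grid=grid, values=values, counts=counts, normalized=False)


def normalize_map(wss_map: WssMap2D) -> WssMap2D:
    """Divide the map by its 50th percentile over counted bins."""
    counted = wss_map.counted_values()
    if counted.size == 0:
        raise NormalizationError("no counted bins to normalize")
    med = float(np.median(counted))
    if med <= 0:
        raise NormalizationError("50th percentile is zero; cannot normalize")
    return WssMap2D(grid=wss_map.grid, values=wss_map.values / med,
                    counts=wss_map.counts.copy(), normalized=True)
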