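"""Ground-truth comparison utilities for phantom studies.

These build the *designed* cut-open maps implied by a phantom truth
bundle — the cap thickness field sampled at exactly the frame/A-line
positions the pullback measures, and the surrogate WSS of the true
geometry — so that end-to-end results can be compared against them
bin-for-bin on the shared grid.
"""

from __future__ import annotations

import numpy as np

from .coregister import Registration, axial_map, resample_cap_to_grid, rotational_map
from .grids import BinGrid, CapMap2D, WssMap2D
from .hemodynamics import HemoConfig, assign_flows, bin_wss, surrogate_wss
from .oct_cap import ThicknessProfile
from .phantom import PhantomTruth
from .risk_fusion import RiskMap, RiskThresholds, build_risk_map

__all__ = ["truth_registration", "truth_cap_map", "truth_wss_map",
           "truth_risk_map", "dice"]


def truth_registration(truth: PhantomTruth) -> Registration:
    """Exact registration from the phantom's side-branch landmarks."""
    lms = truth.landmarks()
    return rotational_map(lms[0], lms[1], axial_map(lms))


def truth_cap_map(truth: PhantomTruth, grid: BinGrid,
                  reg: Registration | None = None) -> CapMap2D:
    """True thickness binned at the pullback's own sample positions."""
    reg = reg or truth_registration(truth)
    cfg = truth.config
    roi = truth.cap_roi()
    profiles = []
    for i in roi.frames():
        alines = roi.alines(cfg.n_alines)
        theta_vessel = (alines * 360.0 / cfg.n_alines
                        + truth.rotation_offset_deg[i])
        z = truth.frame_z_mm[i]
        t = truth.thickness_um(np.full(alines.size, z), theta_vessel)
        t = np.where(np.isfinite(t), t, cfg.wall_band_um)
        profiles.append(ThicknessProfile(alines=alines, thickness_um=t,
                                         frame_index=int(i), z_mm=z))
    return resample_cap_to_grid(profiles, reg, grid, cfg.n_alines)


def truth_wss_map(truth: PhantomTruth, grid: BinGrid,
                  hemo: HemoConfig | None = None) -> WssMap2D:
    """Surrogate WSS of the true geometry, binned on the grid."""
    hemo = hemo or HemoConfig()
    geom = truth.geometry
    return bin_wss(surrogate_wss(geom, assign_flows(geom, hemo), hemo), grid)


def truth_risk_map(truth: PhantomTruth, grid: BinGrid,
                   hemo: HemoConfig | None = None,
                   thresholds: RiskThresholds | None = None) -> RiskMap:
    """The designed risk map of the phantom on the shared grid."""
    return build_risk_map(truth_cap_map(truth, grid),
                          truth_wss_map(truth, grid, hemo),
                          thresholds or RiskThresholds())


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * np.count_nonzero(a & b) / denom)
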