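"""Fusion of cap-thickness and WSS maps into a four-level risk map.

A bin is *thin-cap* when cap thickness <= 151 µm and *high-WSS* when
WSS >= 1.7 Pa (both comparisons inclusive); the four combinations give

    LOW      thick cap, low WSS
    MED_WSS  thick cap, high WSS    (medium risk, hemodynamic)
    MED_CAP  thin cap,  low WSS     (medium risk, morphologic)
    HIGH     thin cap,  high WSS

Bins without cap data (the cap map covers the plaque ROI only, while
WSS covers the whole segment) are classified as if the cap were above
threshold and flagged, so they can only be LOW or MED_WSS; region area
fractions are reported both over all classified bins and over
cap-covered bins.  The threshold sensitivity analysis rebuilds the map
for each combination of cap/WSS threshold lists (defaults: the central
values +/- 7 %, rounded: 141/151/161 µm and 1.6/1.7/1.8 Pa) and reports
the relative area change of each region against the central map.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .errors import ConfigurationError, FusionError
from .grids import BinGrid, CapMap2D, WssMap2D

__all__ = ["RiskLevel", "RiskThresholds", "RiskMap", "SensitivityResult",
           "classify_bin", "build_risk_map", "region_fractions",
           "threshold_sensitivity", "RISK_PALETTE"]


class RiskLevel(IntEnum):
    NO_DATA = -1
    LOW = 0
    MED_WSS = 1
    MED_CAP = 2
    HIGH = 3


#: display palette: gray LOW, blue MED_WSS, yellow MED_CAP, red HIGH
RISK_PALETTE = {
    RiskLevel.LOW: "#b0b0b0",
    RiskLevel.MED_WSS: "#3b6fd4",
    RiskLevel.MED_CAP: "#e8c832",
    RiskLevel.HIGH: "#d43b3b",
    RiskLevel.NO_DATA: "#ffffff",
}


@dataclass(frozen=True)
class RiskThresholds:
    """Joint risk cutoffs: cap thickness (µm, upper) and WSS (Pa, lower)."""

    t_cap_um: float = 151.0
    t_wss_pa: float = 1.7

    def __post_init__(self) -> None:
        if self.t_cap_um <= 0 or self.t_wss_pa <= 0:
            raise ConfigurationError("risk thresholds must be > 0")


def classify_bin(cap_um: float, wss_pa: float,
                 t: RiskThresholds | None = None) -> RiskLevel:
    """Risk level of a single bin; NaN cap means *no cap measured* and is
    treated as above-threshold."""
    t = t or RiskThresholds()
    if wss_pa < 0 or not np.isfinite(wss_pa):
        raise ConfigurationError("wss_pa must be finite and >= 0")
    thin = np.isfinite(cap_um) and cap_um <= t.t_cap_um
    high = wss_pa >= t.t_wss_pa
    if thin and high:
        return RiskLevel.HIGH
    if thin:
        return RiskLevel.MED_CAP
    if high:
        return RiskLevel.MED_WSS
    return RiskLevel.LOW


def _classify_array(cap: np.ndarray, wss: np.ndarray, wss_covered: np.ndarray,
                    t: RiskThresholds) -> np.ndarray:
    levels = np.full(cap.shape, int(RiskLevel.NO_DATA), dtype=np.int8)
    thin = np.isfinite(cap) & (cap <= t.t_cap_um)
    high = wss_covered & (wss >= t.t_wss_pa)
    low = wss_covered & ~high
    levels[low & ~thin] = int(RiskLevel.LOW)
    levels[high & ~thin] = int(RiskLevel.MED_WSS)
    levels[low & thin] = int(RiskLevel.MED_CAP)
    levels[high & thin] = int(RiskLevel.HIGH)
    return levels


@dataclass
class RiskMap:
    """Per-bin four-level risk classification on the shared grid."""

    grid: BinGrid
    levels: np.ndarray                  # int8, RiskLevel values
    thresholds: RiskThresholds
    no_cap: np.ndarray                  # bins classified without cap data
    fractions: dict                     # over all classified bins
    fractions_cap_covered: dict         # over cap-covered bins only

    def level_mask(self, level: RiskLevel) -> np.ndarray:
        return self.levels == int(level)

    @property
    def classified(self) -> np.ndarray:
        return self.levels != int(RiskLevel.NO_DATA)


def _fractions(levels: np.ndarray, mask: np.ndarray) -> dict:
    total = int(mask.sum())
    if total == 0:
        raise FusionError("no classified bins to compute region fractions")
    return {
        lv.name: float(np.count_nonzero(levels[mask] == int(lv)) / total)
        for lv in (RiskLevel.LOW, RiskLevel.MED_WSS, RiskLevel.MED_CAP, RiskLevel.HIGH)
    }


def build_risk_map(capmap: CapMap2D, wssmap: WssMap2D,
                   t: RiskThresholds | None = None) -> RiskMap:
    """Fuse a cap map and a WSS map sharing one grid into a risk map."""
    if not isinstance(capmap, CapMap2D) or not isinstance(wssmap, WssMap2D):
        raise FusionError(
            "build_risk_map(capmap, wssmap): first argument must be the CapMap2D, "
            "second the WssMap2D")
    if capmap.grid != wssmap.grid:
        raise FusionError("cap and WSS maps must share one bin grid")
    t = t or RiskThresholds()
    levels = _classify_array(capmap.values, wssmap.values, wssmap.covered, t)
    classified = levels != int(RiskLevel.NO_DATA)
    no_cap = classified & ~capmap.covered
    cap_cov = classified & capmap.covered
    fractions = _fractions(levels, classified)
    frac_cap = _fractions(levels, cap_cov) if np.any(cap_cov) else {
        lv.name: float("nan") for lv in list(RiskLevel)[1:]}
    return RiskMap(grid=capmap.grid, levels=levels, thresholds=t, no_cap=no_cap,
                   fractions=fractions, fractions_cap_covered=frac_cap)


def region_fractions(risk_map: RiskMap) -> dict:
    """Area fraction of each risk level over classified bins (sums to 1)."""
    return _fractions(risk_map.levels, risk_map.classified)


@dataclass
class SensitivityResult:
    """Risk maps over the threshold grid and per-region area variability."""

    cap_list_um: tuple
    wss_list_pa: tuple
    central: RiskThresholds
    maps: dict                          # (t_cap, t_wss) -> RiskMap
    variability_pct: dict               # level name -> (min %, max %)

    @property
    def n_maps(self) -> int:
        return len(self.maps)


def threshold_sensitivity(
    capmap: CapMap2D,
    wssmap: WssMap2D,
    cap_list_um: tuple = (141.0, 151.0, 161.0),
    wss_list_pa: tuple = (1.6, 1.7, 1.8),
    central: RiskThresholds | None = None,
) -> SensitivityResult:
    """Rebuild the risk map for every threshold combination and report the
    relative area change of each region against the central map."""
    central = central or RiskThresholds()
    if len(cap_list_um) == 0 or len(wss_list_pa) == 0:
        raise ConfigurationError("threshold lists must be non-empty")
    if central.t_cap_um not in cap_list_um:
        raise ConfigurationError("central cap threshold missing from cap_list_um")
    if central.t_wss_pa not in wss_list_pa:
        raise ConfigurationError("central WSS threshold missing from wss_list_pa")

    maps = {}
    for tc in cap_list_um:
        for tw in wss_list_pa:
            maps[(tc, tw)] = build_risk_map(
                capmap, wssmap, RiskThresholds(t_cap_um=tc, t_wss_pa=tw))
    central_map = maps[(central.t_cap_um, central.t_wss_pa)]
    variability = {}
    for lv in (RiskLevel.LOW, RiskLevel.MED_WSS, RiskLevel.MED_CAP, RiskLevel.HIGH):
        c = central_map.fractions[lv.name]
        rel = []
        for m in maps.values():
            a = m.fractions[lv.name]
            if c > 0:
                rel.append(100.0 * (a - c) / c)
            else:
                rel.append(0.0 if a == c else float("inf"))
        variability[lv.name] = (float(min(rel)), float(max(rel)))
    return SensitivityResult(
        cap_list_um=tuple(cap_list_um), wss_list_pa=tuple(wss_list_pa),
        central=central, maps=maps, variability_pct=variability)
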