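"""Shared cut-open (arc-length x angle) bin grid and 2D scalar maps.

The vessel surface is parameterized by centerline arc-length ``s`` (mm,
0 at the proximal end of the un-extended segment) and circumferential
angle ``theta`` (degrees, counterclockwise viewed from proximal to
distal).  Wall shear stress and cap thickness are both binned onto the
same grid so that they can be fused bin-by-bin.

Bins are half-open: longitudinal row ``i`` covers ``[i*ds, (i+1)*ds)``
mm and angular column ``j`` covers ``[j*dtheta, (j+1)*dtheta)`` degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["BinGrid", "ScalarMap2D", "WssMap2D", "CapMap2D", "bin_samples"]


@dataclass(frozen=True)
class BinGrid:
    """Definition of the shared cut-open binning grid.

    Parameters
    ----------
    ds_mm : float
        Longitudinal bin spacing along the centerline, mm (default 0.2).
    dtheta_deg : float
        Angular bin width in degrees; must divide 360 (default 10).
    length_mm : float
        Total longitudinal extent covered by the grid, mm.
    """

    length_mm: float
    ds_mm: float = 0.2
    dtheta_deg: float = 10.0

    def __post_init__(self) -> None:
        if not self.ds_mm > 0:
            raise ConfigurationError("ds_mm must be > 0")
        if not self.length_mm > 0:
            raise ConfigurationError("length_mm must be > 0")
        ratio = 360.0 / self.dtheta_deg
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError("dtheta_deg must divide 360")

    @property
    def n_s(self) -> int:
        return int(np.ceil(self.length_mm / self.ds_mm - 1e-9))

    @property
    def n_theta(self) -> int:
        return int(round(360.0 / self.dtheta_deg))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_s, self.n_theta)

    def s_centers(self) -> np.ndarray:
        return (np.arange(self.n_s) + 0.5) * self.ds_mm

    def theta_centers(self) -> np.ndarray:
        return (np.arange(self.n_theta) + 0.5) * self.dtheta_deg

    def s_edges(self) -> np.ndarray:
        return np.arange(self.n_s + 1) * self.ds_mm

    def theta_edges(self) -> np.ndarray:
        return np.arange(self.n_theta + 1) * self.dtheta_deg


@dataclass
class ScalarMap2D:
    """A binned scalar field on a :class:`BinGrid`.

    ``values[i, j]`` is the arithmetic mean of the samples that fell in
    bin (i, j); bins with ``counts == 0`` hold NaN and are excluded from
    all statistics.
    """

    grid: BinGrid
    values: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.values.shape != self.grid.shape or self.counts.shape != self.grid.shape:
            raise ConfigurationError("map arrays must match grid shape")

    @property
    def covered(self) -> np.ndarray:
        """Boolean mask of bins that received at least one sample."""
        return self.counts > 0

    def counted_values(self) -> np.ndarray:
        return self.values[self.covered]


@dataclass
class WssMap2D(ScalarMap2D):
    """Binned wall shear stress map (Pa, or dimensionless once normalized)."""

    normalized: bool = False


@dataclass
class CapMap2D(ScalarMap2D):
    """Binned fibrous-cap thickness map (µm); uncovered bins mean *no cap*."""


def bin_samples(
    s_mm: np.ndarray,
    theta_deg: np.ndarray,
    values: np.ndarray,
    grid: BinGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """Average point samples onto the grid.

    Angles are wrapped into [0, 360); samples outside the longitudinal
    range of the grid are dropped.  Returns ``(means, counts)``; empty
    bins hold NaN.
    """
    s_mm = np.asarray(s_mm, dtype=float).ravel()
    theta = np.mod(np.asarray(theta_deg, dtype=float).ravel(), 360.0)
    values = np.asarray(values, dtype=float).ravel()
    if not (s_mm.shape == theta.shape == values.shape):
        raise ConfigurationError("s_mm, theta_deg and values must have equal length")

    keep = (s_mm >= 0) & (s_mm < grid.n_s * grid.ds_mm) & np.isfinite(values)
    s_mm, theta, values = s_mm[keep], theta[keep], values[keep]

    i = np.floor(s_mm / grid.ds_mm).astype(int)
    j = np.floor(theta / grid.dtheta_deg).astype(int)
    j = np.clip(j, 0, grid.n_theta - 1)  # theta == 360-eps rounding guard
    flat = i * grid.n_theta + j
    n_bins = grid.n_s * grid.n_theta
    counts = np.bincount(flat, minlength=n_bins)
    sums = np.bincount(flat, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means.reshape(grid.shape), counts.reshape(grid.shape)
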