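"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the path oracle
enumerates every admissible contour on a small grid, and the duct-flow
oracle solves the axial-velocity Poisson problem with finite
differences (Shortley-Weller boundary stencils) instead of using the
closed-form elliptical-duct solution.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve


def brute_force_path(cost: np.ndarray, lam: float, max_step: int, closed: bool):
    """Exhaustive search over all admissible paths of a small cost grid.

    Returns (best_cost, best_path).  The closed objective includes the
    wrap smoothness term and the wrap step bound.
    """
    n_cols, n_r = cost.shape
    steps = np.array(list(product(range(-max_step, max_step + 1),
                                  repeat=n_cols - 1)), dtype=int)
    if steps.size == 0:
        steps = np.zeros((1, 0), dtype=int)
    best_cost, best_path = np.inf, None
    cols = np.arange(n_cols)
    for r0 in range(n_r):
        radii = r0 + np.concatenate(
            [np.zeros((steps.shape[0], 1), int), np.cumsum(steps, axis=1)], axis=1)
        ok = np.all((radii >= 0) & (radii < n_r), axis=1)
        if closed:
            ok &= np.abs(radii[:, -1] - r0) <= max_step
        if not ok.any():
            continue
        rr = radii[ok]
        c = cost[cols[None, :], rr].sum(axis=1)
        c += lam * np.abs(np.diff(rr, axis=1)).sum(axis=1)
        if closed:
            c = c + lam * np.abs(rr[:, -1] - r0)
        i = int(np.argmin(c))
        if c[i] < best_cost - 1e-12:
            best_cost, best_path = float(c[i]), rr[i]
    return best_cost, best_path


def poisson_duct_shear(a_m: float, b_m: float, mu: float, G: float, n: int = 201):
    """Finite-difference solution of fully developed laminar duct flow.

    Solves ``mu * lap(w) = -G`` on the ellipse (a_m, b_m) with w = 0 on
    the boundary, using Shortley-Weller irregular stencils near the
    boundary.  Returns (tau_major, tau_minor, Q): the boundary shear
    magnitudes at the major/minor semi-axis endpoints (where the
    boundary normal aligns with a grid axis, evaluated by a one-sided
    second-order difference) and the volumetric flow from midpoint
    integration of w.  ``n`` must be odd so the axes lie on the grid.
    """
    if n % 2 == 0:
        n += 1
    x = np.linspace(-a_m, a_m, n)
    y = np.linspace(-b_m, b_m, n)
    hx, hy = x[1] - x[0], y[1] - y[0]
    X, Y = np.meshgrid(x, y, indexing="ij")
    inside = (X / a_m) ** 2 + (Y / b_m) ** 2 < 1.0 - 1e-12
    idx = -np.ones(n * n, int)
    ids = np.where(inside.ravel())[0]
    idx[ids] = np.arange(ids.size)
    n_unknown = ids.size

    def boundary_distance(x0, y0, dx, dy):
        qa = (dx / a_m) ** 2 + (dy / b_m) ** 2
        qb = 2 * (x0 * dx / a_m ** 2 + y0 * dy / b_m ** 2)
        qc = (x0 / a_m) ** 2 + (y0 / b_m) ** 2 - 1
        return (-qb + np.sqrt(qb * qb - 4 * qa * qc)) / (2 * qa)

    rows, cols, vals = [], [], []
    rhs = np.full(n_unknown, -G / mu)
    for k, flat in enumerate(ids):
        i, j = divmod(flat, n)
        x0, y0 = x[i], y[j]
        diag = 0.0
        for axis, h in ((0, hx), (1, hy)):
            d_plus = d_minus = h
            id_plus = id_minus = None
            for sgn in (1, -1):
                di, dj = (sgn, 0) if axis == 0 else (0, sgn)
                ii, jj = i + di, j + dj
                if 0 <= ii < n and 0 <= jj < n and inside[ii, jj]:
                    if sgn > 0:
                        id_plus = idx[ii * n + jj]
                    else:
                        id_minus = idx[ii * n + jj]
                else:
                    d = max(boundary_distance(
                        x0, y0, sgn * (axis == 0), sgn * (axis == 1)), 1e-6 * h)
                    if sgn > 0:
                        d_plus = d
                    else:
                        d_minus = d
            c_plus = 2.0 / (d_plus * (d_plus + d_minus))
            c_minus = 2.0 / (d_minus * (d_plus + d_minus))
            diag -= c_plus + c_minus
            if id_plus is not None:
                rows.append(k); cols.append(id_plus); vals.append(c_plus)
            if id_minus is not None:
                rows.append(k); cols.append(id_minus); vals.append(c_minus)
        rows.append(k); cols.append(k); vals.append(diag)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_unknown, n_unknown))
    w = spsolve(A, rhs)
    W = np.zeros(n * n)
    W[ids] = w
    W = W.reshape(n, n)

    j0 = i0 = n // 2  # y = 0 and x = 0 grid lines (n odd)
    dwdx = (3 * 0.0 - 4 * W[n - 2, j0] + W[n - 3, j0]) / (2 * hx)
    dwdy = (3 * 0.0 - 4 * W[i0, n - 2] + W[i0, n - 3]) / (2 * hy)
    tau_major = mu * abs(dwdx)
    tau_minor = mu * abs(dwdy)
    q = float(np.sum(W) * hx * hy)
    return tau_major, tau_minor, q
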