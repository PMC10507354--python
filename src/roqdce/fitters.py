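"""Classical standard-Tofts estimation baselines.

Nonlinear least squares (trust-region reflective, box-bounded to the
physiologic ranges) and variable projection (VARPRO), which exploits
that Ktrans enters linearly: for a candidate kep the basis
b_kep = Cp (*) exp(-kep t) gives the closed-form
Ktrans = <b, Ct> / <b, b>, leaving a 1-D search over kep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .core import KEP_RANGE, KTRANS_RANGE, DynamicCurve
from .pk import _exp_conv

__all__ = ["FitResult", "nlls_fit", "varpro_fit", "varpro_norm_error_batch"]

DEFAULT_INIT = (0.2, 1.0)  # mid-range physiologic start (Ktrans, kep), 1/min


@dataclass
class FitResult:
    ktrans: float
    kep: float
    ve: float
    residual_rmse: float
    norm_error: float
    converged: bool
    n_iter: int
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.ktrans, self.kep, self.ve])


def _result(ct: np.ndarray, model: np.ndarray, kt: float, kep: float,
            converged: bool, n_iter: int, degenerate: bool = False) -> FitResult:
    resid = ct - model
    rmse = float(np.sqrt(np.mean(resid**2)))
    peak = float(np.max(ct)) if np.max(ct) > 0 else 1.0
    return FitResult(
        ktrans=float(kt),
        kep=float(kep),
        ve=float(kt / kep),
        residual_rmse=rmse,
        norm_error=rmse / peak,
        converged=converged,
        n_iter=n_iter,
        degenerate=degenerate,
    )


def nlls_fit(ct: DynamicCurve, cp: DynamicCurve, init=None) -> FitResult:
    """Box-bounded nonlinear least-squares Tofts fit.

    Never raises on non-convergence; returns the best iterate with
    ``converged=False`` instead.
    """
    if ct.grid != cp.grid:
        raise ValueError("ct and cp are on different grids")
    dt_min = ct.grid.dt / 60.0
    y = ct.values
    cpv = cp.values
    if init is None:
        x0 = np.array(DEFAULT_INIT)
    else:
        x0 = np.array([init[0], init[1]], dtype=float)
    lb = np.array([KTRANS_RANGE[0], KEP_RANGE[0]])
    ub = np.array([KTRANS_RANGE[1], KEP_RANGE[1]])
    x0 = np.clip(x0, lb, ub)

    def resid(x):
        return x[0] * _exp_conv(cpv, x[1], dt_min) - y

    try:
        sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12)
        kt, kep = sol.x
        model = kt * _exp_conv(cpv, kep, dt_min)
        degenerate = not np.any(y > 0)
        return _result(y, model, kt, kep, bool(sol.success), int(sol.nfev), degenerate)
    except Exception:
        model = x0[0] * _exp_conv(cpv, x0[1], dt_min)
        return _result(y, model, x0[0], x0[1], False, 0)


def _projected(cpv: np.ndarray, y: np.ndarray, kep: float, dt_min: float) -> tuple[float, float]:
    """Closed-form Ktrans and projected residual SSQ for one candidate kep."""
    b = _exp_conv(cpv, kep, dt_min)
    bb = float(b @ b)
    if bb <= 0:
        return 0.0, float(y @ y)
    kt = float(b @ y) / bb
    kt = float(np.clip(kt, KTRANS_RANGE[0], KTRANS_RANGE[1]))
    r = y - kt * b
    return kt, float(r @ r)


def varpro_fit(
    ct: DynamicCurve,
    cp: DynamicCurve,
    kep_grid: np.ndarray | None = None,
) -> FitResult:
    """Variable-projection Tofts fit.

    Coarse search over a 64-point log-spaced kep bracket spanning the
    physiologic range, followed by bounded scalar refinement of the
    projected residual around the best bracket point.
    """
    if ct.grid != cp.grid:
        raise ValueError("ct and cp are on different grids")
    if kep_grid is not None and len(kep_grid) == 0:
        raise ValueError("empty kep search grid")
    dt_min = ct.grid.dt / 60.0
    y = ct.values
    cpv = cp.values
    grid = (
        np.asarray(kep_grid, dtype=float)
        if kep_grid is not None
        else np.logspace(np.log10(KEP_RANGE[0]), np.log10(KEP_RANGE[1]), 64)
    )
    ssq = np.array([_projected(cpv, y, k, dt_min)[1] for k in grid])
    j = int(np.argmin(ssq))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    n_iter = len(grid)
    if hi > lo:
        sol = minimize_scalar(
            lambda k: _projected(cpv, y, k, dt_min)[1],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        kep = float(sol.x)
        n_iter += int(sol.nfev)
    else:
        kep = float(grid[j])
    kt, _ = _projected(cpv, y, kep, dt_min)
    model = kt * _exp_conv(cpv, kep, dt_min)
    degenerate = not np.any(y > 0)
    return _result(y, model, kt, kep, True, n_iter, degenerate)


def varpro_norm_error_batch(
    ct_matrix: np.ndarray,
    cp_values: np.ndarray,
    dt_s: float,
    kep_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized Tofts fitting error (RMSE / peak) for many voxels at once.

    All voxels share one AIF, so the VARPRO bases can be precomputed per
    candidate kep and the projection vectorized. Used for cohort-scale
    screening with the same normalized-error definition as
    :func:`~roqdce.protocol.screen_voxel`.
    """
    ct_matrix = np.atleast_2d(np.asarray(ct_matrix, dtype=float))
    dt_min = dt_s / 60.0
    grid = (
        np.asarray(kep_grid, dtype=float)
        if kep_grid is not None
        else np.logspace(np.log10(KEP_RANGE[0]), np.log10(KEP_RANGE[1]), 64)
    )
    basis = _exp_conv(np.broadcast_to(cp_values, (len(grid), len(cp_values))).copy(),
                                grid, dt_min)  # (K, T)
    bb = np.maximum(np.sum(basis**2, axis=1), 1e-300)  # (K,)
    proj = ct_matrix @ basis.T  # (V, K)
    kt = np.clip(proj / bb[None, :], KTRANS_RANGE[0], KTRANS_RANGE[1])
    yy = np.sum(ct_matrix**2, axis=1, keepdims=True)
    ssq = yy - 2.0 * kt * proj + kt**2 * bb[None, :]
    best = np.min(ssq, axis=1)
    rmse = np.sqrt(np.maximum(best, 0.0) / ct_matrix.shape[1])
    peaks = np.maximum(ct_matrix.max(axis=1), 1e-300)
    return rmse / peaks
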