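"""Forward tracer-kinetic physics.

Population arterial input function (mixed-Gaussian plus
sigmoid-modulated exponential), the standard Tofts model
Ct(t) = Ktrans * Cp(t) (*) exp(-kep t), the spoiled gradient-echo
(FLASH) signal equation, and baseline signal normalization.

Rates are in 1/min; :class:`~roqdce.core.TimeGrid` stores seconds and
every operation converts internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import DynamicCurve, FlashParams, TimeGrid

__all__ = [
    "AIFModelParams",
    "population_aif",
    "tofts_forward",
    "tofts_forward_batch",
    "flash_signal",
    "signal_to_concentration",
    "ve_from_rates",
]


@dataclass(frozen=True)
class AIFModelParams:
    """Population AIF functional-form parameters.

    Two Gaussian bolus-passage terms plus an exponential washout
    modulated by a sigmoid, evaluated in minutes post bolus arrival:

        Cp(t) = sum_n A_n / (sigma_n sqrt(2 pi)) exp(-(t-T_n)^2 / (2 sigma_n^2))
                + alpha exp(-beta t) / (1 + exp(-s (t - tau)))

    Defaults are the published population values (amplitudes in
    mmol*min and mmol, times/widths in minutes, decay/steepness in
    1/min). The whole curve is multiplied by ``scale`` and shifted so
    Cp = 0 before ``bolus_arrival_s``.
    """

    a1: float = 0.809
    a2: float = 0.330
    t1: float = 0.17046
    t2: float = 0.365
    sigma1: float = 0.0563
    sigma2: float = 0.132
    alpha: float = 1.050
    beta: float = 0.1685
    s: float = 38.078
    tau: float = 0.483
    scale: float = 1.0
    bolus_arrival_s: float = 30.0

    def __post_init__(self) -> None:
        for name in ("sigma1", "sigma2", "beta", "s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"AIF parameter {name} must be positive")
        if self.scale < 0:
            raise ValueError("AIF scale must be non-negative")

    def perturbed(self, rng: np.random.Generator, rel: float = 0.2) -> "AIFModelParams":
        """Independently perturb each shape parameter by +/- ``rel`` (uniform)."""
        fields = ("a1", "a2", "t1", "t2", "sigma1", "sigma2", "alpha", "beta", "s", "tau")
        factors = rng.uniform(1.0 - rel, 1.0 + rel, size=len(fields))
        return replace(self, **{f: getattr(self, f) * k for f, k in zip(fields, factors)})


def _aif_closed_form(t_min: np.ndarray, p: AIFModelParams) -> np.ndarray:
    """Unscaled population form at times ``t_min`` (minutes after arrival)."""
    g1 = p.a1 / (p.sigma1 * np.sqrt(2 * np.pi)) * np.exp(-((t_min - p.t1) ** 2) / (2 * p.sigma1**2))
    g2 = p.a2 / (p.sigma2 * np.sqrt(2 * np.pi)) * np.exp(-((t_min - p.t2) ** 2) / (2 * p.sigma2**2))
    washout = p.alpha * np.exp(-p.beta * t_min) / (1.0 + np.exp(-p.s * (t_min - p.tau)))
    return g1 + g2 + washout


def population_aif(params: AIFModelParams, grid: TimeGrid) -> DynamicCurve:
    """Evaluate the population AIF on ``grid``.

    Causal: Cp(t) = 0 strictly before ``bolus_arrival_s``; scaled by
    ``params.scale``.
    """
    t_rel_min = (grid.times - params.bolus_arrival_s) / 60.0
    cp = np.where(t_rel_min >= 0, params.scale * _aif_closed_form(t_rel_min, params), 0.0)
    return DynamicCurve(grid, cp, kind="concentration")


def aif_peak_time_s(params: AIFModelParams, grid: TimeGrid) -> float:
    """Time (seconds) of the AIF maximum on the grid."""
    curve = population_aif(params, grid)
    return float(grid.times[int(np.argmax(curve.values))])


def _exp_conv_coeffs(kep: np.ndarray, dt_min: float):
    """Recursion coefficients of the exponential-integrator convolution.

    The convolution with exp(-kep t) of the piecewise-linear interpolant
    of Cp satisfies the exact recursion

        y_i = a y_{i-1} + A cp_{i-1} + B cp_i

    with a = exp(-kep h), u = (1 - a)/(kep h), B = (1 - u)/kep and
    A = u h - B (h = dt in minutes). As kep*h -> 0 both A and B tend to
    h/2, recovering the trapezoid rule.
    """
    kep = np.asarray(kep, dtype=float)
    h = dt_min
    a = np.exp(-kep * h)
    u = (1.0 - a) / (kep * h)
    B = (1.0 - u) / kep
    A = u * h - B
    return a, A, B


def _exp_conv(cp: np.ndarray, kep: float | np.ndarray, dt_min: float) -> np.ndarray:
    """Convolution of ``cp`` with exp(-kep t) along the last axis.

    Exact for a piecewise-linear Cp (exponential integrator); accurate
    to O(dt^2) of the interpolant for smooth inputs at any kep.
    """
    cp = np.asarray(cp, dtype=float)
    a, A, B = _exp_conv_coeffs(kep, dt_min)
    y = np.zeros(np.broadcast_shapes(cp.shape[:-1], np.shape(a)) + (cp.shape[-1],))
    for i in range(1, cp.shape[-1]):
        y[..., i] = a * y[..., i - 1] + A * cp[..., i - 1] + B * cp[..., i]
    return y


def tofts_forward(cp: DynamicCurve, ktrans: float, kep: float, grid: TimeGrid | None = None) -> DynamicCurve:
    """Standard Tofts forward model Ct = Ktrans * (Cp (*) exp(-kep t)).

    ``ktrans`` and ``kep`` in 1/min; the grid's seconds are converted.
    Quadrature: exponential integrator (exact for piecewise-linear Cp), so Ct(0) = 0.
    """
    if grid is not None and grid != cp.grid:
        raise ValueError("cp is not defined on the requested grid")
    if ktrans < 0:
        raise ValueError("ktrans must be >= 0")
    if kep <= 0:
        raise ValueError("kep must be > 0")
    dt_min = cp.grid.dt / 60.0
    ct = ktrans * _exp_conv(cp.values, kep, dt_min)
    return DynamicCurve(cp.grid, ct, kind="concentration")


def tofts_forward_batch(cp_values: np.ndarray, ktrans: np.ndarray, kep: np.ndarray, dt_s: float) -> np.ndarray:
    """Vectorized Tofts forward model.

    ``cp_values``: (n_steps,) or (m, n_steps); ``ktrans``/``kep``: (m,).
    Returns (m, n_steps).
    """
    ktrans = np.asarray(ktrans, dtype=float)
    y = _exp_conv(cp_values, kep, dt_s / 60.0)
    return ktrans[..., None] * y


def flash_signal(r1: DynamicCurve, fp: FlashParams) -> DynamicCurve:
    """Spoiled gradient-echo steady-state signal from an R1 = 1/T1 curve.

    S = m0 sin(a) (1 - E) / (1 - cos(a) E), E = exp(-TR * R1), with R1 in
    1/s and TR converted from ms to s. Strictly increasing in R1 and
    bounded by m0 sin(a).
    """
    if r1.kind != "R1":
        raise ValueError(f"expected an R1 curve, got kind {r1.kind!r}")
    if np.any(r1.values < 0):
        raise ValueError("R1 values must be non-negative")
    alpha = np.deg2rad(fp.flip_angle_deg)
    e = np.exp(-(fp.tr_ms / 1000.0) * r1.values)
    s = fp.m0 * np.sin(alpha) * (1.0 - e) / (1.0 - np.cos(alpha) * e)
    return DynamicCurve(r1.grid, s, kind="raw_signal")


def signal_to_concentration(s: DynamicCurve, s0: float) -> DynamicCurve:
    """Baseline-corrected, pre-contrast-normalized enhancement (S - S0)/S0.

    Used as a linear surrogate for concentration throughout; no
    T1-nonlinearity correction is applied.
    """
    if s0 <= 0:
        raise ValueError(f"baseline s0 must be positive, got {s0}")
    return DynamicCurve(s.grid, (s.values - s0) / s0, kind="normalized_signal")


def ve_from_rates(ktrans: float | np.ndarray, kep: float | np.ndarray) -> float | np.ndarray:
    """Fractional EES volume ve = Ktrans / kep."""
    kep_arr = np.asarray(kep, dtype=float)
    if np.any(kep_arr <= 0):
        raise ValueError("kep must be > 0 to derive ve")
    out = np.asarray(ktrans, dtype=float) / kep_arr
    return float(out) if out.ndim == 0 else out
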