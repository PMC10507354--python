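"""Core domain containers shared across the package.

Time is stored in seconds everywhere; tracer-kinetic rate constants
(Ktrans, kep) are in 1/min, the unit convention of the DCE literature.
Operations convert internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeGrid",
    "DynamicCurve",
    "PKParams",
    "FlashParams",
    "CurveKind",
]

#: allowed values for :attr:`DynamicCurve.kind`
CurveKind = ("concentration", "normalized_signal", "raw_signal", "R1")

# physiologic simulation ranges (1/min, 1/min, dimensionless)
KTRANS_RANGE = (0.01, 12.0)
KEP_RANGE = (0.01, 24.0)
VE_RANGE = (0.1, 0.8)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time axis t_i = t0 + i*dt, in seconds.

    Defaults give the 130-step, 2-s axis (260 s total) used for the
    high-temporal-resolution reference dynamics.
    """

    n_steps: int = 130
    dt: float = 2.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError(f"n_steps must be positive, got {self.n_steps}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, shape (n_steps,)."""
        return self.t0 + self.dt * np.arange(self.n_steps)

    @property
    def times_min(self) -> np.ndarray:
        """Sample times in minutes."""
        return self.times / 60.0

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return self.dt * (self.n_steps - 1)

    def nearest_index(self, t_s: float) -> int:
        """Index of the grid sample closest to ``t_s`` (seconds)."""
        idx = int(round((t_s - self.t0) / self.dt))
        if idx < 0 or idx >= self.n_steps:
            raise ValueError(
                f"time {t_s} s is outside the grid span "
                f"[{self.t0}, {self.t0 + self.duration}] s"
            )
        return idx


@dataclass
class DynamicCurve:
    """Values of a dynamic quantity on a :class:`TimeGrid`."""

    grid: TimeGrid
    values: np.ndarray
    kind: str = "concentration"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_steps,):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"length {self.grid.n_steps}"
            )
        if self.kind not in CurveKind:
            raise ValueError(f"unknown curve kind {self.kind!r}")

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "DynamicCurve":
        return DynamicCurve(self.grid, values, kind or self.kind)

    @property
    def peak(self) -> float:
        return float(np.max(self.values))

    def __len__(self) -> int:
        return self.grid.n_steps


def _check_same_grid(a: DynamicCurve, b: DynamicCurve) -> None:
    if a.grid != b.grid:
        raise ValueError("curves are defined on different time grids")


@dataclass(frozen=True)
class PKParams:
    """Standard Tofts parameter triple.

    ve is redundant (ve = ktrans / kep) and is derived on construction
    unless given, in which case consistency is enforced.
    """

    ktrans: float
    kep: float
    ve: float | None = None

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError(f"ktrans must be >= 0, got {self.ktrans}")
        if self.kep <= 0:
            raise ValueError(f"kep must be > 0, got {self.kep}")
        derived = self.ktrans / self.kep
        if self.ve is None:
            object.__setattr__(self, "ve", derived)
        elif abs(self.ve - derived) > 1e-9:
            raise ValueError(
                f"inconsistent triple: ve={self.ve} but ktrans/kep={derived}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.ktrans, self.kep, self.ve])


@dataclass(frozen=True)
class FlashParams:
    """Spoiled gradient-echo (FLASH) signal-equation parameters.

    Defaults correspond to the abdominal protocol emulated here:
    TR = 5.60 ms, flip angle = 10 degrees.
    """

    tr_ms: float = 5.60
    flip_angle_deg: float = 10.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError(f"tr_ms must be positive, got {self.tr_ms}")
        if not 0.0 < self.flip_angle_deg < 90.0:
            raise ValueError(
                f"flip angle must be in (0, 90) degrees, got {self.flip_angle_deg}"
            )
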