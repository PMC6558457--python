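"""One-way (tornado), threshold, and two-way sensitivity analyses.

All analyses perturb single point estimates over their literature ranges and
compare the arms on the base-case *deterministic* life-expectancy difference
(lobectomy minus SABR); the probabilistic machinery is deliberately not
involved, so every bar, root and region is a reproducible function of the
parameter table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .markov import cohort_life_expectancy
from .parameters import ESTIMATE_FIELDS, ParameterSet

__all__ = [
    "TornadoEntry",
    "ThresholdResult",
    "TwoWayGrid",
    "le_difference",
    "one_way",
    "tornado",
    "find_threshold",
    "two_way",
]


def le_difference(start_age: float, params: ParameterSet, overrides=None):
    """Deterministic life-expectancy difference, lobectomy minus SABR."""
    return cohort_life_expectancy("lobectomy", start_age, params, overrides) - \
        cohort_life_expectancy("sabr", start_age, params, overrides)


def _check_param(name: str) -> None:
    if name not in ESTIMATE_FIELDS:
        raise KeyError(f"unknown parameter {name!r}; expected one of {ESTIMATE_FIELDS}")


@dataclass(frozen=True)
class TornadoEntry:
    """The life-expectancy difference evaluated at one parameter's range ends."""

    parameter: str
    low_input: float
    high_input: float
    le_diff_at_low: float
    le_diff_at_high: float
    degenerate: bool = False

    @property
    def width(self) -> float:
        return abs(self.le_diff_at_high - self.le_diff_at_low)


def one_way(param: str, start_age: float, base: ParameterSet) -> TornadoEntry:
    """Evaluate the arm difference at one parameter's low and high range end,
    all other inputs fixed at base case.  A degenerate range yields a
    zero-width bar, flagged."""
    _check_param(param)
    est = getattr(base, param)
    if est.degenerate:
        diff = float(le_difference(start_age, base))
        return TornadoEntry(param, est.low, est.high, diff, diff, degenerate=True)
    lo, hi = le_difference(start_age, base, {param: np.array([est.low, est.high])})
    return TornadoEntry(param, est.low, est.high, float(lo), float(hi))


def tornado(start_age: float, base: ParameterSet,
            params: tuple[str, ...] | None = None) -> list[TornadoEntry]:
    """One-way entries for every (nondegenerate by default) parameter,
    sorted by descending bar width."""
    if params is None:
        params = tuple(n for n, e in base.estimates() if not e.degenerate)
    entries = [one_way(p, start_age, base) for p in params]
    return sorted(entries, key=lambda e: e.width, reverse=True)


@dataclass(frozen=True)
class ThresholdResult:
    """Root of the arm difference along one parameter, if any.

    ``root`` is None when the difference keeps one sign over the bracket
    (the parameter cannot flip the preferred strategy within its range).
    """

    parameter: str
    root: float | None
    bracket: tuple[float, float]
    tolerance: float
    le_diff_at_root: float | None = None

    @property
    def found(self) -> bool:
        return self.root is not None


def find_threshold(param: str, start_age: float, base: ParameterSet,
                   bracket: tuple[float, float] | None = None,
                   tolerance: float = 1e-4) -> ThresholdResult:
    """Bisection root of the life-expectancy difference as a function of one
    parameter, over ``bracket`` (default: the parameter's literature range)."""
    _check_param(param)
    est = getattr(base, param)
    if bracket is None:
        bracket = (est.low, est.high)
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must satisfy low < high")

    def f(x: float) -> float:
        return float(le_difference(start_age, base, {param: x}))

    f_lo, f_hi = f(lo), f(hi)
    if np.sign(f_lo) == np.sign(f_hi):
        return ThresholdResult(param, None, bracket, tolerance)
    root = float(bisect(f, lo, hi, xtol=tolerance))
    return ThresholdResult(param, root, bracket, tolerance, le_diff_at_root=f(root))


@dataclass(frozen=True)
class TwoWayGrid:
    """Preferred strategy over a grid of two parameters.

    ``preferred[i, j]`` is ``"lobectomy"``, ``"sabr"`` or ``"tie"`` for
    ``param_a = a_values[i]`` and ``param_b = b_values[j]``, by the sign of
    the deterministic life-expectancy difference (ties within ``tie_tol``)."""

    param_a: str
    param_b: str
    a_values: np.ndarray
    b_values: np.ndarray
    le_diff: np.ndarray
    preferred: np.ndarray
    tie_tol: float = 1e-6

    def to_frame(self) -> pd.DataFrame:
        aa, bb = np.meshgrid(self.a_values, self.b_values, indexing="ij")
        return pd.DataFrame(
            {
                self.param_a: aa.ravel(),
                self.param_b: bb.ravel(),
                "le_diff": self.le_diff.ravel(),
                "preferred": self.preferred.ravel(),
            }
        )


def two_way(param_a: str, param_b: str, start_age: float, base: ParameterSet,
            grid: int = 101, tie_tol: float = 1e-6,
            a_range: tuple[float, float] | None = None,
            b_range: tuple[float, float] | None = None) -> TwoWayGrid:
    """Map the preferred strategy over a ``grid`` x ``grid`` lattice spanning
    the two parameters' literature ranges (or explicit ranges)."""
    _check_param(param_a)
    _check_param(param_b)
    if param_a == param_b:
        raise ValueError("two_way needs two distinct parameters")
    est_a, est_b = getattr(base, param_a), getattr(base, param_b)
    a_lo, a_hi = a_range if a_range is not None else (est_a.low, est_a.high)
    b_lo, b_hi = b_range if b_range is not None else (est_b.low, est_b.high)
    a_values = np.linspace(a_lo, a_hi, grid)
    b_values = np.linspace(b_lo, b_hi, grid)
    aa, bb = np.meshgrid(a_values, b_values, indexing="ij")
    diff = le_difference(start_age, base, {param_a: aa.ravel(), param_b: bb.ravel()})
    diff = np.asarray(diff).reshape(grid, grid)
    preferred = np.where(diff > tie_tol, "lobectomy", np.where(diff < -tie_tol, "sabr", "tie"))
    return TwoWayGrid(param_a, param_b, a_values, b_values, diff, preferred, tie_tol)
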