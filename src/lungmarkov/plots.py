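"""Matplotlib figures for the standard outputs (all optional; every analysis
is usable without plotting)."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .markov import CohortTrace
from .sensitivity import TornadoEntry, TwoWayGrid
from .validation import StudyPoint

__all__ = ["plot_survival", "plot_tornado", "plot_two_way", "plot_validation"]


def plot_survival(traces: Sequence[CohortTrace], labels: Sequence[str] | None = None, ax=None):
    """Overall-survival curves of one or more cohort runs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels = labels or [f"{t.arm}, age {t.start_age:.0f}" for t in traces]
    for trace, label in zip(traces, labels):
        ax.step(np.arange(trace.n_cycles + 1), trace.alive, where="post", label=label)
    ax.set_xlabel("years since treatment")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    return ax


def plot_tornado(entries: Sequence[TornadoEntry], base_diff: float, ax=None):
    """Tornado diagram of the life-expectancy difference (lobectomy − SABR)."""
    entries = [e for e in entries if not e.degenerate]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(entries) + 1.5))
    ys = np.arange(len(entries))[::-1]
    for y, e in zip(ys, entries):
        lo = min(e.le_diff_at_low, e.le_diff_at_high)
        hi = max(e.le_diff_at_low, e.le_diff_at_high)
        ax.barh(y, hi - lo, left=lo, height=0.6, color="0.6")
    ax.axvline(base_diff, color="k", lw=1)
    ax.set_yticks(ys)
    ax.set_yticklabels([e.parameter for e in entries])
    ax.set_xlabel("life-expectancy difference (years)")
    return ax


def plot_two_way(grid: TwoWayGrid, ax=None):
    """Preferred-strategy regions over the two-parameter plane."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    code = np.where(grid.preferred == "lobectomy", 1.0,
                    np.where(grid.preferred == "sabr", 0.0, 0.5))
    ax.pcolormesh(grid.a_values, grid.b_values, code.T, cmap="Greys", vmin=-0.3, vmax=1.3,
                  shading="nearest")
    ax.set_xlabel(grid.param_a)
    ax.set_ylabel(grid.param_b)
    ax.set_title("dark: lobectomy preferred; light: SABR preferred")
    return ax


def plot_validation(curve: pd.DataFrame, points: Sequence[StudyPoint], ax=None):
    """Predicted OS-versus-age curve with observed study outcomes overlaid;
    the square marks the size-weighted mean of the studies."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["age"], curve["predicted_os"], "k-", label="model")
    if points:
        ages = [p.median_age for p in points]
        obs = [p.observed_os for p in points]
        sizes = np.array([p.n_patients for p in points])
        ax.plot(ages, obs, "o", color="0.6", label="studies")
        ax.plot(np.average(ages, weights=sizes), np.average(obs, weights=sizes),
                "ks", label="weighted mean")
    ax.set_xlabel("age at diagnosis")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    return ax
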