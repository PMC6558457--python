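"""Face validation of the model: predicted survival-versus-age curves with
observed outcomes from published cohorts overlaid.

Lobectomy series conventionally report five-year overall survival and SABR
series three-year overall survival, so those are the default horizons.  The
observed values are user-supplied (a small delimited table); the package
ships only synthetic examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .markov import run_cohort, survival_at
from .parameters import ParameterSet

__all__ = [
    "StudyPoint",
    "predicted_os_curve",
    "compare_to_studies",
    "read_study_points",
    "write_study_points",
]


@dataclass(frozen=True)
class StudyPoint:
    """One published cohort: overall survival at ``horizon`` years for a
    cohort whose median age was ``median_age``.  ``n_patients`` weighs the
    study in averages (1 if unknown)."""

    label: str
    median_age: float
    horizon: float
    observed_os: float
    n_patients: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.observed_os <= 1.0:
            raise ValueError("observed_os must be a probability")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")


def predicted_os_curve(arm: str, horizon: float, ages: Sequence[float],
                       params: ParameterSet) -> pd.DataFrame:
    """Model-predicted overall survival at ``horizon`` years for cohorts
    starting at each age; one deterministic cohort run per age."""
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 45.0) or np.any(ages > 85.0):
        raise ValueError("ages must lie in [45, 85]")
    if horizon > params.n_cycles:
        raise ValueError("horizon exceeds the model's cycle count")
    os = [survival_at(run_cohort(arm, age, params), horizon) for age in ages]
    return pd.DataFrame({"age": ages, "predicted_os": os})


def compare_to_studies(curve: pd.DataFrame, points: Sequence[StudyPoint],
                       weighted: bool = True) -> pd.DataFrame:
    """Deviation of each observed outcome from the predicted curve at the
    study's median age (linear interpolation in age).

    Returns a table with one row per study plus a ``mean`` row whose
    deviation is the size-weighted mean by default (``weighted=False`` for
    the unweighted mean).  Deviations are observed minus predicted.
    """
    points = list(points)
    if not points:
        raise ValueError("no study points supplied")
    ages = curve["age"].to_numpy()
    pred = curve["predicted_os"].to_numpy()
    lo, hi = ages.min(), ages.max()
    rows = []
    for pt in points:
        if not lo <= pt.median_age <= hi:
            raise ValueError(
                f"study {pt.label!r}: median age {pt.median_age} outside the "
                f"curve's age range [{lo}, {hi}]"
            )
        predicted = float(np.interp(pt.median_age, ages, pred))
        rows.append(
            {
                "label": pt.label,
                "median_age": pt.median_age,
                "observed_os": pt.observed_os,
                "predicted_os": predicted,
                "deviation": pt.observed_os - predicted,
                "n_patients": pt.n_patients,
            }
        )
    table = pd.DataFrame(rows)
    weights = table["n_patients"] if weighted else pd.Series(1.0, index=table.index)
    mean_dev = float(np.average(table["deviation"], weights=weights))
    mean_row = {
        "label": "mean",
        "median_age": float(np.average(table["median_age"], weights=weights)),
        "observed_os": float(np.average(table["observed_os"], weights=weights)),
        "predicted_os": float(np.average(table["predicted_os"], weights=weights)),
        "deviation": mean_dev,
        "n_patients": float(weights.sum()),
    }
    return pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)


def read_study_points(path: str | Path) -> list[StudyPoint]:
    """Read a delimited study table with header
    ``label,median_age,horizon,observed_os[,n_patients]``."""
    table = pd.read_csv(path)
    required = ["label", "median_age", "horizon", "observed_os"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"study table missing columns {missing}")
    if "n_patients" not in table.columns:
        table["n_patients"] = 1.0
    return [
        StudyPoint(str(r.label), float(r.median_age), float(r.horizon),
                   float(r.observed_os), float(r.n_patients))
        for r in table.itertuples()
    ]


def write_study_points(points: Sequence[StudyPoint], path: str | Path) -> None:
    pd.DataFrame([vars(p) for p in points]).to_csv(path, index=False)
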