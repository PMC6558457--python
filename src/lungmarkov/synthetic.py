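"""Synthetic inputs for exercising the whole pipeline without any downloads:
jittered parameter tables with the base case's point+range structure,
life-table overrides, and fake literature survival points.

These generators are the fixture backbone of the test suite.  Everything is
reproducible bit for bit from ``(seed, spec)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    ParameterSet,
    ProbabilityEstimate,
    load_parameters,
    save_parameters,
)
from .validation import StudyPoint, predicted_os_curve, write_study_points

__all__ = ["FixtureSpec", "make_parameter_table", "make_study_points",
           "make_life_table", "write_fixtures"]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic-data generators.

    ``jitter`` is the fraction of each literature range used when perturbing
    a point estimate (0 = exact base case, 1 = anywhere in the range);
    ``noise_sd`` is the standard deviation, in survival-probability units, of
    the noise added to synthetic study outcomes.
    """

    seed: int = 0
    jitter: float = 0.0
    n_study_points: int = 11
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.jitter <= 1.0:
            raise ValueError("jitter must lie in [0, 1]")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")


def make_parameter_table(spec: FixtureSpec, base: ParameterSet | None = None) -> ParameterSet:
    """A parameter set with every nondegenerate estimate drawn uniformly
    inside its range, shrunk by ``jitter`` around the point estimate.

    The point of the returned estimate moves; its low/high range is kept, so
    the result is again a valid input for every analysis.  ``jitter=0``
    returns the base case unchanged.
    """
    base = load_parameters() if base is None else base
    if spec.jitter == 0.0:
        return base
    rng = np.random.default_rng(spec.seed)
    changes = {}
    for name, est in base.estimates():
        if est.degenerate:
            continue
        lo = est.point - spec.jitter * (est.point - est.low)
        hi = est.point + spec.jitter * (est.high - est.point)
        changes[name] = ProbabilityEstimate(rng.uniform(lo, hi), est.low, est.high)
    return base.replace(**changes)


def make_study_points(arm: str, spec: FixtureSpec, params: ParameterSet,
                      horizon: float | None = None) -> list[StudyPoint]:
    """Fake literature outcomes: median ages uniform on [45, 85], observed
    survival = model prediction + Gaussian noise, clipped to [0, 1]."""
    if horizon is None:
        horizon = 5.0 if arm == "lobectomy" else 3.0
    rng = np.random.default_rng(spec.seed)
    ages = np.sort(rng.uniform(45.0, 85.0, size=spec.n_study_points))
    curve = predicted_os_curve(arm, horizon, ages, params)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_study_points) if spec.noise_sd else 0.0
    observed = np.clip(curve["predicted_os"].to_numpy() + noise, 0.0, 1.0)
    sizes = rng.integers(30, 500, size=spec.n_study_points)
    return [
        StudyPoint(f"synthetic-{arm}-{i:02d}", float(a), float(horizon), float(o), float(n))
        for i, (a, o, n) in enumerate(zip(ages, observed, sizes))
    ]


def make_life_table(spec: FixtureSpec, base: ParameterSet | None = None,
                    ages=None) -> pd.DataFrame:
    """A synthetic life table (``age,annual_mortality``) sampled from the
    packaged background curve with multiplicative lognormal noise."""
    base = load_parameters() if base is None else base
    ages = np.arange(45, 101, dtype=float) if ages is None else np.asarray(ages, float)
    rng = np.random.default_rng(spec.seed)
    values = base.bg_mortality(ages)
    if spec.noise_sd:
        values = np.clip(values * np.exp(rng.normal(0.0, spec.noise_sd, size=ages.size)), 0.0, 1.0)
    return pd.DataFrame({"age": ages, "annual_mortality": values})


def write_fixtures(spec: FixtureSpec, outdir: str | Path) -> list[Path]:
    """Write a complete synthetic input bundle: a parameter config, a life
    table, and one study-point table per arm.  Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = make_parameter_table(spec)
    written = []
    cfg = outdir / "parameters.yaml"
    save_parameters(params, cfg)
    written.append(cfg)
    lt = outdir / "life_table.csv"
    make_life_table(spec).to_csv(lt, index=False)
    written.append(lt)
    for arm in ("lobectomy", "sabr"):
        path = outdir / f"study_points_{arm}.csv"
        write_study_points(make_study_points(arm, spec, params), path)
        written.append(path)
    return written
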