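"""Model inputs: probability estimates, age-indexed mortality curves, and the
sampling distributions used by the probabilistic sensitivity analysis.

The packaged defaults describe a cohort of medically operable stage IA NSCLC
patients choosing between lobectomy and stereotactic ablative radiotherapy
(SABR).  Every input is either a :class:`ProbabilityEstimate` (a point value
with the low/high range found in the literature) or an :class:`AgeCurve`
(annual probability as a function of attained age).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "ProbabilityEstimate",
    "AgeCurve",
    "ParameterSet",
    "DistributionSpec",
    "load_parameters",
    "save_parameters",
    "load_life_table",
    "fit_psa_distribution",
]

INTERPOLATION_KINDS = ("log-linear", "linear", "step")


@dataclass(frozen=True)
class ProbabilityEstimate:
    """A probability with its literature range, ``low <= point <= high``.

    A degenerate estimate (``low == point == high``) is a fixed input that the
    probabilistic sensitivity analysis will not vary.
    """

    point: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        low = self.point if self.low is None else self.low
        high = self.point if self.high is None else self.high
        object.__setattr__(self, "low", float(low))
        object.__setattr__(self, "high", float(high))
        object.__setattr__(self, "point", float(self.point))
        if not (0.0 <= self.low <= self.point <= self.high <= 1.0):
            raise ValueError(
                f"invalid probability estimate: requires 0 <= low <= point <= "
                f"high <= 1, got point={self.point}, low={self.low}, high={self.high}"
            )

    @property
    def degenerate(self) -> bool:
        return self.low == self.high

    def to_dict(self) -> dict:
        return {"point": self.point, "low": self.low, "high": self.high}


@dataclass(frozen=True)
class AgeCurve:
    """Annual probability indexed by age, defined by anchors and an
    interpolation rule.

    ``log-linear`` interpolates linearly on the log scale between anchors
    (piecewise Gompertz), ``linear`` on the natural scale, and ``step`` holds
    each anchor value until the next anchor.  Outside the anchor span the
    curve continues on the same scale at the adjacent segment's rate, capped
    at 1.
    """

    anchor_ages: tuple[float, ...]
    anchor_values: tuple[float, ...]
    interpolation: str = "log-linear"

    def __post_init__(self) -> None:
        ages = tuple(float(a) for a in self.anchor_ages)
        vals = tuple(float(v) for v in self.anchor_values)
        object.__setattr__(self, "anchor_ages", ages)
        object.__setattr__(self, "anchor_values", vals)
        if len(ages) != len(vals) or len(ages) < 1:
            raise ValueError("anchor_ages and anchor_values must have equal, nonzero length")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("anchor ages must be strictly increasing")
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("anchor values must lie in [0, 1]")
        if self.interpolation not in INTERPOLATION_KINDS:
            raise ValueError(f"unknown interpolation kind {self.interpolation!r}")
        if self.interpolation == "log-linear" and any(v <= 0.0 for v in vals):
            raise ValueError("log-linear curves require strictly positive anchor values")

    def __call__(self, age):
        return self.evaluate(age)

    def evaluate(self, age):
        """Annual probability at ``age`` (scalar or array), in [0, 1]."""
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be non-negative")
        ages = np.asarray(self.anchor_ages)
        vals = np.asarray(self.anchor_values)
        if len(ages) == 1:
            out = np.full_like(age, vals[0])
            return out if out.ndim else float(out)
        if self.interpolation == "step":
            idx = np.clip(np.searchsorted(ages, age, side="right") - 1, 0, len(ages) - 1)
            out = vals[idx]
        else:
            y = np.log(vals) if self.interpolation == "log-linear" else vals
            out = np.interp(age, ages, y)
            # np.interp clamps; continue at edge-segment slope beyond the span
            lo_slope = (y[1] - y[0]) / (ages[1] - ages[0])
            hi_slope = (y[-1] - y[-2]) / (ages[-1] - ages[-2])
            out = np.where(age < ages[0], y[0] + (age - ages[0]) * lo_slope, out)
            out = np.where(age > ages[-1], y[-1] + (age - ages[-1]) * hi_slope, out)
            if self.interpolation == "log-linear":
                out = np.exp(out)
        # anchors are contractual: evaluation there returns the value exactly,
        # with no round trip through the interpolation scale
        idx = np.clip(np.searchsorted(ages, age), 0, len(ages) - 1)
        exact = ages[idx] == age
        out = np.where(exact, vals[idx], out)
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def scaled(self, factor: float) -> "AgeCurve":
        """A copy with every anchor value multiplied by ``factor`` (capped at 1)."""
        vals = tuple(min(1.0, v * factor) for v in self.anchor_values)
        return AgeCurve(self.anchor_ages, vals, self.interpolation)

    def to_dict(self) -> dict:
        return {
            "interpolation": self.interpolation,
            "anchor_ages": list(self.anchor_ages),
            "anchor_values": list(self.anchor_values),
        }


# estimate-valued fields, in the packaged file's order
ESTIMATE_FIELDS = (
    "mort_sabr",
    "mort_conv_rt",
    "mort_progression",
    "p_prog_lob",
    "p_prog_sabr",
    "frac_lr_lob",
    "frac_lr_sabr",
    "frac_rr_lob",
    "frac_rr_sabr",
    "p_salv_lr_sabr",
    "p_salv_rr_lob",
    "p_salv_rr_sabr",
    "p_salv_dm",
    "p_prog_post_salv_lr_sabr",
    "p_prog_post_salv_rr_lob",
    "p_prog_post_salv_rr_sabr",
    "p_pN_positive",
)
CURVE_FIELDS = ("bg_mortality", "mort_lobectomy")


@dataclass(frozen=True)
class ParameterSet:
    """The complete set of model inputs for both treatment arms.

    Attributes
    ----------
    bg_mortality
        Annual all-cause mortality of the general population, by attained age.
    mort_lobectomy
        90-day post-lobectomy mortality by age at operation; applied once, in
        the cycle the operation takes place (primary treatment or salvage).
    mort_sabr
        Procedure-related mortality of SABR, age-invariant, applied once.
    mort_conv_rt
        Procedure-related mortality of conventional radiotherapy, applied once
        per course (adjuvant or salvage).
    mort_progression
        Annual mortality of progressive disease under chemotherapy plus best
        supportive care.
    p_prog_lob, p_prog_sabr
        One-year probability of any first disease progression after primary
        treatment.
    frac_lr_*, frac_rr_*
        Fraction of first failures that are local-only, and regional-only plus
        local&regional; the distant fraction is the complement.
    p_salv_*
        Probability that a detected local / regional / distant failure
        receives radical salvage treatment.
    p_prog_post_salv_*
        One-year probability of progression after radical salvage.
    p_pN_positive
        Probability of pathologically positive nodes at lobectomy (adjuvant
        chemotherapy +/- radiotherapy pathway); no prevalence is published, so
        the default is 0.
    """

    bg_mortality: AgeCurve
    mort_lobectomy: AgeCurve
    mort_sabr: ProbabilityEstimate
    mort_conv_rt: ProbabilityEstimate
    mort_progression: ProbabilityEstimate
    p_prog_lob: ProbabilityEstimate
    p_prog_sabr: ProbabilityEstimate
    frac_lr_lob: ProbabilityEstimate
    frac_lr_sabr: ProbabilityEstimate
    frac_rr_lob: ProbabilityEstimate
    frac_rr_sabr: ProbabilityEstimate
    p_salv_lr_sabr: ProbabilityEstimate
    p_salv_rr_lob: ProbabilityEstimate
    p_salv_rr_sabr: ProbabilityEstimate
    p_salv_dm: ProbabilityEstimate
    p_prog_post_salv_lr_sabr: ProbabilityEstimate
    p_prog_post_salv_rr_lob: ProbabilityEstimate
    p_prog_post_salv_rr_sabr: ProbabilityEstimate
    p_pN_positive: ProbabilityEstimate
    n_cycles: int = 15
    cycle_length: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.cycle_length != 1.0:
            raise ValueError("only the one-year cycle length is supported")
        for arm in ("lob", "sabr"):
            flr = getattr(self, f"frac_lr_{arm}").point
            frr = getattr(self, f"frac_rr_{arm}").point
            if flr + frr > 1.0 + 1e-12:
                raise ValueError(
                    f"frac_lr_{arm} + frac_rr_{arm} exceeds 1; the distant "
                    "fraction is their complement"
                )

    def estimates(self) -> Iterator[tuple[str, ProbabilityEstimate]]:
        for name in ESTIMATE_FIELDS:
            yield name, getattr(self, name)

    def replace(self, **changes) -> "ParameterSet":
        """A copy with the named fields replaced.

        Probability fields accept either a :class:`ProbabilityEstimate` or a
        bare float (which becomes a degenerate estimate — convenient for
        sensitivity analyses that move a point value).
        """
        coerced = {}
        for key, value in changes.items():
            if key in ESTIMATE_FIELDS and not isinstance(value, ProbabilityEstimate):
                value = ProbabilityEstimate(float(value))
            coerced[key] = value
        return dataclasses.replace(self, **coerced)

    def to_dict(self) -> dict:
        return {
            "parameters": {name: est.to_dict() for name, est in self.estimates()},
            "curves": {name: getattr(self, name).to_dict() for name in CURVE_FIELDS},
            "model": {"n_cycles": self.n_cycles, "cycle_length": self.cycle_length},
        }


def _packaged_defaults() -> dict:
    text = (
        importlib.resources.files("lungmarkov")
        .joinpath("data/default_parameters.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def _parse_estimate(name: str, raw) -> ProbabilityEstimate:
    if isinstance(raw, (int, float)):
        raw = {"point": raw}
    if not isinstance(raw, dict):
        raise ValueError(f"parameter {name!r} must be a number or a point/low/high mapping")
    unknown = set(raw) - {"point", "low", "high"}
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in parameter {name!r}")
    if "point" not in raw:
        raise ValueError(f"parameter {name!r} has no point estimate")
    try:
        return ProbabilityEstimate(raw["point"], raw.get("low"), raw.get("high"))
    except ValueError as exc:
        raise ValueError(f"parameter {name!r}: {exc}") from None


def _parse_curve(name: str, raw) -> AgeCurve:
    if not isinstance(raw, dict):
        raise ValueError(f"curve {name!r} must be a mapping")
    unknown = set(raw) - {"interpolation", "anchor_ages", "anchor_values"}
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in curve {name!r}")
    try:
        return AgeCurve(
            tuple(raw["anchor_ages"]),
            tuple(raw["anchor_values"]),
            raw.get("interpolation", "log-linear"),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"curve {name!r}: {exc}") from None


def load_parameters(config_source: str | Path | dict | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a YAML config, defaulting every
    missing field from the packaged base case.

    ``config_source`` may be None (pure defaults), a path to a YAML file, a
    YAML string, or an already-parsed mapping.  Unknown keys are rejected with
    a named error; malformed YAML raises with the offending line.
    """
    if config_source is None:
        user: dict = {}
    elif isinstance(config_source, dict):
        user = config_source
    else:
        if isinstance(config_source, Path) or (
            isinstance(config_source, str)
            and config_source.strip() != ""
            and "\n" not in config_source
            and Path(config_source).is_file()
        ):
            text = Path(config_source).read_text()
        else:
            text = str(config_source)
        try:
            user = yaml.safe_load(io.StringIO(text)) or {}
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f" at line {mark.line + 1}" if mark is not None else ""
            raise ValueError(f"malformed config{where}: {exc}") from None
        if not isinstance(user, dict):
            raise ValueError("config must be a mapping at top level")

    unknown = set(user) - {"parameters", "curves", "model"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    base = _packaged_defaults()
    params_raw = dict(base["parameters"]) | dict(user.get("parameters") or {})
    curves_raw = dict(base["curves"]) | dict(user.get("curves") or {})
    model_raw = dict(base["model"]) | dict(user.get("model") or {})

    unknown = set(params_raw) - set(ESTIMATE_FIELDS)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    unknown = set(curves_raw) - set(CURVE_FIELDS)
    if unknown:
        raise ValueError(f"unknown curves: {sorted(unknown)}")
    unknown = set(model_raw) - {"n_cycles", "cycle_length"}
    if unknown:
        raise ValueError(f"unknown model settings: {sorted(unknown)}")

    kwargs: dict = {name: _parse_estimate(name, params_raw[name]) for name in ESTIMATE_FIELDS}
    kwargs |= {name: _parse_curve(name, curves_raw[name]) for name in CURVE_FIELDS}
    return ParameterSet(
        n_cycles=int(model_raw["n_cycles"]),
        cycle_length=float(model_raw["cycle_length"]),
        **kwargs,
    )


def save_parameters(params: ParameterSet, path: str | Path | None = None) -> str:
    """Serialize a :class:`ParameterSet` to YAML; returns the text and
    optionally writes it to ``path``.  ``load_parameters(save_parameters(p))``
    reproduces ``p`` field for field."""
    text = yaml.safe_dump(params.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_life_table(path: str | Path, interpolation: str = "log-linear") -> AgeCurve:
    """Read a delimited life table with header ``age,annual_mortality`` into
    an :class:`AgeCurve` (the usual override for ``bg_mortality``)."""
    table = pd.read_csv(path)
    expected = ["age", "annual_mortality"]
    if list(table.columns) != expected:
        raise ValueError(f"life table must have columns {expected}, got {list(table.columns)}")
    table = table.sort_values("age")
    return AgeCurve(tuple(table["age"]), tuple(table["annual_mortality"]), interpolation)


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution for one parameter in the probabilistic
    sensitivity analysis: ``point`` mass, ``beta``, or ``uniform``."""

    kind: str
    args: tuple[float, ...]

    def mean(self) -> float:
        if self.kind == "point":
            return self.args[0]
        if self.kind == "beta":
            a, b = self.args
            return a / (a + b)
        low, high = self.args
        return 0.5 * (low + high)

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "point":
            return np.full(size, self.args[0]) if size is not None else self.args[0]
        if self.kind == "beta":
            return rng.beta(*self.args, size=size)
        return rng.uniform(*self.args, size=size)

    def ppf(self, q):
        if self.kind == "point":
            return np.full_like(np.asarray(q, dtype=float), self.args[0])
        if self.kind == "beta":
            return stats.beta.ppf(q, *self.args)
        low, high = self.args
        return low + np.asarray(q, dtype=float) * (high - low)


def fit_psa_distribution(est: ProbabilityEstimate) -> DistributionSpec:
    """Fit the second-order sampling distribution for one estimate.

    Nondegenerate estimates get a Beta distribution whose mean equals the
    point estimate and whose 2.5%/97.5% quantiles approximate the literature
    range (fit numerically over the concentration).  Degenerate estimates, and
    points at exactly 0 or 1, are fixed (point mass).  If the range is
    inconsistent with the mean (point outside the open interval), the fit is
    infeasible and a Uniform(low, high) fallback is used, with a warning.
    """
    if est.degenerate or est.point in (0.0, 1.0):
        return DistributionSpec("point", (est.point,))
    if not (est.low < est.point < est.high):
        warnings.warn(
            f"range ({est.low}, {est.high}) inconsistent with mean {est.point}; "
            "falling back to a uniform distribution",
            stacklevel=2,
        )
        return DistributionSpec("uniform", (est.low, est.high))

    p = est.point

    def quantile_error(log_conc: float) -> float:
        conc = np.exp(log_conc)
        q_lo, q_hi = stats.beta.ppf([0.025, 0.975], conc * p, conc * (1.0 - p))
        return (q_lo - est.low) ** 2 + (q_hi - est.high) ** 2

    res = minimize_scalar(quantile_error, bounds=(np.log(1e-2), np.log(1e7)), method="bounded")
    conc = float(np.exp(res.x))
    return DistributionSpec("beta", (conc * p, conc * (1.0 - p)))
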