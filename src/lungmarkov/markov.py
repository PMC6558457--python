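"""Health states, transition rows, and the deterministic cohort engine.

Two arms are modelled.  After lobectomy (9 states) a patient is disease-free
until a first failure, which is regional (salvageable with radiotherapy) or
distant; after SABR (13 states) first failures are local (salvageable with
lobectomy), regional (salvageable with radiotherapy) or distant.  Unsalvaged
locoregional failures spend one cycle in an untreated-recurrence bridge and
then enter progressive disease; distant failures face progressive-disease
mortality from the cycle of detection.  Salvage takes two cycles (detection,
then the salvage procedure) before returning to a post-salvage disease-free
state with its own progression risk.  Death is the single absorbing state of
each arm and collects background mortality from every alive state.

Cycles are one year.  Within a cycle, competing risks combine as independent
events and death takes precedence over disease transitions.

All transition builders accept numpy arrays in place of scalar probabilities
and broadcast, which is what makes the probabilistic sensitivity analysis and
the two-way grids cheap: a whole batch of parameter draws is evaluated as one
stacked linear recursion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import ParameterSet

__all__ = [
    "ARMS",
    "HealthState",
    "StateSpace",
    "CohortTrace",
    "enumerate_states",
    "transition_row",
    "transition_matrix",
    "run_cohort",
    "life_expectancy",
    "survival_at",
    "cohort_survival",
    "cohort_life_expectancy",
]

ARMS = ("lobectomy", "sabr")

_LOBECTOMY_STATES = (
    # (name, absorbing, tunnel)
    ("initial", False, True),
    ("ned", False, False),
    ("adjuvant_therapy", False, True),
    ("rr_detected", False, True),
    ("salvage_rt", False, True),
    ("ned_post_salvage", False, False),
    ("progression", False, False),
    ("untreated_recurrence", False, True),
    ("death", True, False),
)

_SABR_STATES = (
    ("initial", False, True),
    ("ned", False, False),
    ("lr_detected", False, True),
    ("rr_detected", False, True),
    ("dm_detected", False, True),
    ("salvage_lobectomy", False, True),
    ("salvage_rt", False, True),
    ("ned_post_salvage_lr", False, False),
    ("ned_post_salvage_rr", False, False),
    ("progression", False, False),
    ("untreated_recurrence", False, True),
    ("bsc_terminal", False, True),
    ("death", True, False),
)


@dataclass(frozen=True)
class HealthState:
    arm: str
    name: str
    absorbing: bool = False
    tunnel: bool = False


@dataclass(frozen=True)
class StateSpace:
    arm: str
    states: tuple[HealthState, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.states)


def enumerate_states(arm: str) -> StateSpace:
    """The ordered health states of one arm: 9 for lobectomy, 13 for SABR.

    The SABR arm retains a best-supportive-care terminal bridge for parity
    with the published state diagram; under the packaged pathway it receives
    no inflow (distant failures are booked in the distant-metastasis
    detection state, which already carries progressive-disease mortality).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    spec = _LOBECTOMY_STATES if arm == "lobectomy" else _SABR_STATES
    return StateSpace(arm, tuple(HealthState(arm, n, a, t) for n, a, t in spec))


def _combine(*probs):
    """Probability that at least one of several independent risks fires."""
    alive = 1.0
    for p in probs:
        alive = alive * (1.0 - np.asarray(p, dtype=float))
    return 1.0 - alive


def _resolve(params: ParameterSet, overrides: Mapping[str, object] | None = None) -> dict:
    """Point values of every estimate (plus the two curves), with optional
    scalar-or-array overrides for the probabilistic analyses."""
    rp: dict = {name: est.point for name, est in params.estimates()}
    rp["bg_mortality"] = params.bg_mortality
    rp["mort_lobectomy"] = params.mort_lobectomy
    if overrides:
        for key, value in overrides.items():
            if key not in rp:
                raise KeyError(f"unknown parameter {key!r}")
            rp[key] = value
    return rp


def transition_matrix(space: StateSpace, attained_age: float, params, overrides=None):
    """The one-cycle transition matrix at ``attained_age``.

    ``params`` may be a :class:`ParameterSet` or an already-resolved mapping
    of probabilities (scalars or broadcastable arrays).  Returns an array of
    shape ``batch + (S, S)`` whose rows sum to 1.
    """
    rp = _resolve(params, overrides) if isinstance(params, ParameterSet) else dict(params)
    if np.any(np.asarray(rp["p_salv_dm"]) != 0.0):
        raise ValueError(
            "p_salv_dm must be 0: the state graph has no distant-salvage pathway"
        )
    sabr = space.arm == "sabr"
    bg = rp["bg_mortality"](attained_age)
    op_mort = rp["mort_lobectomy"](attained_age)

    p_prog = rp["p_prog_sabr"] if sabr else rp["p_prog_lob"]
    flr = rp["frac_lr_sabr"] if sabr else rp["frac_lr_lob"]
    frr = rp["frac_rr_sabr"] if sabr else rp["frac_rr_lob"]
    fdm = 1.0 - np.asarray(flr) - np.asarray(frr)
    slr = rp["p_salv_lr_sabr"] if sabr else 0.0  # no local-salvage pathway after lobectomy
    srr = rp["p_salv_rr_sabr"] if sabr else rp["p_salv_rr_lob"]
    post_rr = rp["p_prog_post_salv_rr_sabr"] if sabr else rp["p_prog_post_salv_rr_lob"]

    batch = np.broadcast_shapes(
        *(np.shape(rp[k]) for k in ("mort_progression", "p_prog_lob", "p_prog_sabr",
                                    "frac_lr_sabr", "frac_rr_lob", "frac_rr_sabr",
                                    "p_salv_lr_sabr", "p_salv_rr_lob", "p_salv_rr_sabr",
                                    "p_prog_post_salv_lr_sabr", "p_prog_post_salv_rr_lob",
                                    "p_prog_post_salv_rr_sabr", "mort_sabr", "p_pN_positive"))
    )
    n = len(space)
    T = np.zeros(batch + (n, n))
    ix = space.index

    def put(i: int, j: int, prob) -> None:
        T[..., i, j] = T[..., i, j] + prob

    death = ix("death")
    prog = ix("progression")

    # initial: procedure mortality (90-day for lobectomy, by age at operation)
    proc = rp["mort_sabr"] if sabr else op_mort
    d = _combine(proc, bg)
    put(ix("initial"), death, d)
    if sabr:
        put(ix("initial"), ix("ned"), 1.0 - d)
    else:
        pn = rp["p_pN_positive"]
        put(ix("initial"), ix("adjuvant_therapy"), (1.0 - d) * pn)
        put(ix("initial"), ix("ned"), (1.0 - d) * (1.0 - pn))
        d_adj = _combine(rp["mort_conv_rt"], bg)
        put(ix("adjuvant_therapy"), death, d_adj)
        put(ix("adjuvant_therapy"), ix("ned"), 1.0 - d_adj)

    # disease-free: background death, else progress or stay
    alive = 1.0 - np.asarray(bg, dtype=float)
    fail = alive * np.asarray(p_prog)
    put(ix("ned"), death, bg * np.ones(batch))
    put(ix("ned"), ix("ned"), alive * (1.0 - np.asarray(p_prog)))
    unsalvaged_lrr = np.asarray(flr) * (1.0 - np.asarray(slr)) + np.asarray(frr) * (
        1.0 - np.asarray(srr)
    )
    put(ix("ned"), ix("untreated_recurrence"), fail * unsalvaged_lrr)
    put(ix("ned"), ix("rr_detected"), fail * np.asarray(frr) * np.asarray(srr))
    if sabr:
        put(ix("ned"), ix("lr_detected"), fail * np.asarray(flr) * np.asarray(slr))
        put(ix("ned"), ix("dm_detected"), fail * fdm)
    else:
        put(ix("ned"), prog, fail * fdm)  # distant failure: progression at once

    # detection year of a salvageable failure, then the salvage procedure
    put(ix("rr_detected"), death, bg * np.ones(batch))
    put(ix("rr_detected"), ix("salvage_rt"), (1.0 - bg) * np.ones(batch))
    d_srt = _combine(rp["mort_conv_rt"], bg)
    put(ix("salvage_rt"), death, d_srt)
    if sabr:
        put(ix("lr_detected"), death, bg * np.ones(batch))
        put(ix("lr_detected"), ix("salvage_lobectomy"), (1.0 - bg) * np.ones(batch))
        d_slob = _combine(op_mort, bg)
        put(ix("salvage_lobectomy"), death, d_slob)
        put(ix("salvage_lobectomy"), ix("ned_post_salvage_lr"), 1.0 - d_slob)
        put(ix("salvage_rt"), ix("ned_post_salvage_rr"), 1.0 - d_srt)
        ned_post = (("ned_post_salvage_lr", rp["p_prog_post_salv_lr_sabr"]),
                    ("ned_post_salvage_rr", post_rr))
    else:
        put(ix("salvage_rt"), ix("ned_post_salvage"), 1.0 - d_srt)
        ned_post = (("ned_post_salvage", post_rr),)

    for name, p_post in ned_post:
        put(ix(name), death, bg * np.ones(batch))
        put(ix(name), prog, (1.0 - bg) * np.asarray(p_post))
        put(ix(name), ix(name), (1.0 - bg) * (1.0 - np.asarray(p_post)))

    # untreated locoregional recurrence: one bridge year, then progression
    put(ix("untreated_recurrence"), death, bg * np.ones(batch))
    put(ix("untreated_recurrence"), prog, (1.0 - bg) * np.ones(batch))

    # progressive disease: chemotherapy + best supportive care mortality
    d_prog = _combine(rp["mort_progression"], bg)
    put(prog, death, d_prog)
    put(prog, prog, 1.0 - d_prog)
    if sabr:
        put(ix("dm_detected"), death, d_prog)
        put(ix("dm_detected"), prog, 1.0 - d_prog)
        put(ix("bsc_terminal"), death, d_prog)
        put(ix("bsc_terminal"), prog, 1.0 - d_prog)

    put(death, death, np.ones(batch))

    sums = T.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-10):
        raise RuntimeError("transition rows failed to normalize after hazard combination")
    return T


def transition_row(state: HealthState, attained_age: float, params: ParameterSet,
                   overrides=None) -> np.ndarray:
    """One state's transition distribution at ``attained_age``, ordered as
    ``enumerate_states(state.arm).names``; sums to 1."""
    if attained_age < 0:
        raise ValueError("attained_age must be non-negative")
    space = enumerate_states(state.arm)
    T = transition_matrix(space, attained_age, params, overrides)
    return T[..., space.index(state.name), :]


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions of one deterministic cohort run.

    ``occupancy[t, s]`` is the fraction of the starting cohort in state ``s``
    at the start of cycle ``t`` (row 0 is a point mass on the initial state).
    """

    arm: str
    start_age: float
    states: tuple[str, ...]
    occupancy: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        """Alive fraction at each cycle boundary (1 - death occupancy)."""
        return 1.0 - self.occupancy[:, self.states.index("death")]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.occupancy, columns=list(self.states))
        frame.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        frame["alive"] = self.alive
        frame["attained_age"] = self.start_age + frame["cycle"]
        return frame


def run_cohort(arm: str, start_age: float, params: ParameterSet) -> CohortTrace:
    """Follow a cohort deterministically over the model horizon (15 one-year
    cycles by default), starting from the treatment decision at ``start_age``."""
    if not 45.0 <= start_age <= 85.0:
        raise ValueError("start_age must lie in [45, 85]")
    space = enumerate_states(arm)
    occ = np.zeros((params.n_cycles + 1, len(space)))
    occ[0, space.index("initial")] = 1.0
    for t in range(params.n_cycles):
        T = transition_matrix(space, start_age + t, params)
        occ[t + 1] = occ[t] @ T
    return CohortTrace(arm, float(start_age), space.names, occ)


def life_expectancy(trace: CohortTrace) -> float:
    """Half-cycle-corrected life expectancy in years: the trapezoidal sum
    0.5*S(0) + S(1) + ... + S(n-1) + 0.5*S(n) of the alive fractions."""
    s = trace.alive
    return float(0.5 * s[0] + s[1:-1].sum() + 0.5 * s[-1])


def survival_at(trace: CohortTrace, t: float) -> float:
    """Overall survival at ``t`` years; integer times read the trace, others
    interpolate linearly between cycle boundaries."""
    if not 0.0 <= t <= trace.n_cycles:
        raise ValueError(f"t={t} outside the simulated horizon [0, {trace.n_cycles}]")
    return float(np.interp(t, np.arange(trace.n_cycles + 1), trace.alive))


def cohort_survival(arm: str, start_age: float, params: ParameterSet,
                    overrides: Mapping[str, object] | None = None) -> np.ndarray:
    """Alive fractions over the horizon, vectorized over any array-valued
    parameter overrides; shape ``batch + (n_cycles + 1,)``."""
    space = enumerate_states(arm)
    rp = _resolve(params, overrides)
    T0 = transition_matrix(space, start_age, rp)
    batch = T0.shape[:-2]
    occ = np.zeros(batch + (len(space),))
    occ[..., space.index("initial")] = 1.0
    death = space.index("death")
    out = [np.ones(batch)]
    for t in range(params.n_cycles):
        T = T0 if t == 0 else transition_matrix(space, start_age + t, rp)
        occ = np.einsum("...i,...ij->...j", occ, T)
        out.append(1.0 - occ[..., death])
    return np.stack(out, axis=-1)


def cohort_life_expectancy(arm: str, start_age: float, params: ParameterSet,
                           overrides: Mapping[str, object] | None = None):
    """Half-cycle-corrected life expectancy, vectorized over overrides."""
    s = cohort_survival(arm, start_age, params, overrides)
    le = 0.5 * s[..., 0] + s[..., 1:-1].sum(axis=-1) + 0.5 * s[..., -1]
    return float(le) if le.ndim == 0 else le
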