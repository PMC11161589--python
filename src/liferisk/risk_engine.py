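"""Composition of smoothed annual transition probabilities into absolute risks.

Two modes are provided and never silently substituted for one another:

* fixed-path — the product formula 1 - prod(1 - pi_a), conditioning on the
  subject remaining in the start state until the target transition; this is
  the headline remaining-lifetime risk.
* marginal — the (start, target) entry of the ordered product of annual
  transition matrices, accumulating probability through every path; only
  defined for absorbing targets (CAD, Death).

Treatment is a constant per-year relative risk reduction RR applied to
every target-destination transition probability before composition, for
subjects not already on a statin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .coefficient_smoothing import SmootherConfig, smooth_table
from .ehr_timeline import COVARIATE_NAMES, expand_cohort
from .state_space import (
    CAD,
    DEATH,
    STATES,
    State,
    destination_states,
)
from .transition_fitting import CoefficientTable, fit_all, predict_annual_probability

__all__ = [
    "Profile",
    "RiskQuery",
    "RiskResult",
    "TransitionMatrix",
    "annual_transition_row",
    "interval_risk",
    "remaining_lifetime_risk",
    "treated_interval_risk",
    "absolute_risk_reduction",
    "build_transition_matrix",
    "marginal_interval_risk",
    "bootstrap_projection",
    "compute_risk",
    "DEFAULT_RR",
    "DEFAULT_L",
]

logger = logging.getLogger(__name__)

DEFAULT_RR = 0.20
DEFAULT_L = 80

_STATE_INDEX = {s.label: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class Profile:
    """Covariate profile, frozen at query time during projection."""

    sex: int = 0
    prs: float = 0.0
    smoker: int = 0
    statin_use: int = 0
    antihtn_use: int = 0

    def vector(self, covariates: Sequence[str]) -> np.ndarray:
        return np.array([1.0] + [float(getattr(self, c)) for c in covariates])


@dataclass(frozen=True)
class RiskQuery:
    profile: Profile
    start_state: State
    start_age: int
    end_age: int = DEFAULT_L
    target_state: State = CAD
    treatment_rr: float = DEFAULT_RR
    treated: bool = False
    mode: str = "fixed-path"  # or "marginal"

    def __post_init__(self) -> None:
        if not self.start_age < self.end_age:
            raise ValueError(f"start_age {self.start_age} must be < end_age {self.end_age}")
        if not 0.0 <= self.treatment_rr <= 1.0:
            raise ValueError("treatment_rr must lie in [0, 1]")
        if self.mode not in ("fixed-path", "marginal"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class RiskResult:
    risk: float
    per_age_probs: tuple
    se: Optional[float] = None
    n_boot: int = 0


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic annual matrix over the full state alphabet."""

    age: int
    matrix: np.ndarray  # (10, 10), rows ordered as STATES

    def prob(self, from_state: State, to_state: State) -> float:
        return float(self.matrix[_STATE_INDEX[from_state.label], _STATE_INDEX[to_state.label]])


def _cell_prob(
    table: CoefficientTable,
    profile_vec: np.ndarray,
    from_state: State,
    to_state: State,
    age: int,
) -> float:
    if not table.has_cell(from_state, to_state, age):
        return 0.0
    beta, _, _, _ = table.cell(from_state, to_state, age)
    return predict_annual_probability(beta, profile_vec)


def annual_transition_row(
    table: CoefficientTable,
    profile: Profile,
    from_state: State,
    age: int,
    rr: float = 0.0,
    target_state: State = CAD,
) -> dict[State, float]:
    """Probability over successor states for one profile, state, and age.

    Off-diagonal entries come from the smoothed logistic coefficients; the
    self-transition is the complement.  If the off-diagonal sum exceeds 1
    the entries are rescaled to sum to 1 (self-entry 0) with a warning.
    ``rr`` > 0 multiplies the ``target_state`` entry by (1 - rr) before the
    complement is taken.
    """
    if from_state.absorbing:
        return {from_state: 1.0}
    vec = profile.vector(table.covariates)
    probs: dict[State, float] = {}
    total = 0.0
    for k in destination_states(from_state):
        pi = _cell_prob(table, vec, from_state, k, age)
        if rr > 0.0 and k == target_state:
            pi *= 1.0 - rr
        probs[k] = pi
        total += pi
    if total > 1.0:
        logger.warning(
            "off-diagonal sum %.6f > 1 for %s at age %d; rescaling", total, from_state, age
        )
        probs = {k: v / total for k, v in probs.items()}
        probs[from_state] = 0.0
    else:
        probs[from_state] = 1.0 - total
    return probs


def interval_risk(per_age_probs: Sequence[float]) -> float:
    """1 - prod(1 - pi_a); empty interval gives 0."""
    probs = np.asarray(per_age_probs, dtype=float)
    if probs.size == 0:
        return 0.0
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("annual probabilities must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - probs))


def _per_age_target_probs(table: CoefficientTable, query: RiskQuery) -> np.ndarray:
    rr = query.treatment_rr if query.treated else 0.0
    out = np.empty(query.end_age - query.start_age)
    for i, age in enumerate(range(query.start_age, query.end_age)):
        row = annual_transition_row(
            table, query.profile, query.start_state, age, rr=rr, target_state=query.target_state
        )
        out[i] = row.get(query.target_state, 0.0)
    return out


def _validate_treated(query: RiskQuery) -> None:
    if query.treated and query.profile.statin_use:
        raise ValueError(
            "treated projection applies only to subjects not already on a statin "
            "(profile has statin_use = 1)"
        )


def compute_risk(table: CoefficientTable, query: RiskQuery) -> RiskResult:
    """Evaluate one risk query against a smoothed coefficient table."""
    _validate_treated(query)
    if query.start_state.absorbing or query.start_state == CAD:
        if query.start_state == query.target_state:
            return RiskResult(risk=1.0, per_age_probs=())
        raise ValueError(
            f"start state {query.start_state.label} is absorbing; risk query rejected"
        )
    if query.mode == "marginal":
        risk = marginal_interval_risk(table, query)
        return RiskResult(risk=risk, per_age_probs=())
    probs = _per_age_target_probs(table, query)
    return RiskResult(risk=interval_risk(probs), per_age_probs=tuple(probs))


def remaining_lifetime_risk(
    table: CoefficientTable, query: RiskQuery, max_age: int = DEFAULT_L
) -> RiskResult:
    """Interval risk with the horizon forced to the maximum age of life."""
    return compute_risk(table, replace(query, end_age=max_age))


def treated_interval_risk(table: CoefficientTable, query: RiskQuery) -> RiskResult:
    """Risk with each annual target probability scaled by (1 - RR)."""
    return compute_risk(table, replace(query, treated=True))


def absolute_risk_reduction(table: CoefficientTable, query: RiskQuery) -> float:
    """Untreated minus treated risk; nonnegative for RR in [0, 1]."""
    untreated = compute_risk(table, replace(query, treated=False)).risk
    treated = compute_risk(table, replace(query, treated=True)).risk
    return untreated - treated


def build_transition_matrix(
    table: CoefficientTable,
    profile: Profile,
    age: int,
    rr: float = 0.0,
    target_state: State = CAD,
) -> TransitionMatrix:
    """Full annual matrix; absorbing rows are unit vectors."""
    n = len(STATES)
    M = np.zeros((n, n))
    for j in STATES:
        ji = _STATE_INDEX[j.label]
        if j.absorbing:
            M[ji, ji] = 1.0
            continue
        row = annual_transition_row(table, profile, j, age, rr=rr, target_state=target_state)
        for k, v in row.items():
            M[ji, _STATE_INDEX[k.label]] = v
        # CAD has no fitted self cell when CAD->Death is not modelled
        if j == CAD and not table.has_cell(CAD, DEATH, age):
            M[ji, :] = 0.0
            M[ji, ji] = 1.0
    return TransitionMatrix(age=age, matrix=M)


def marginal_interval_risk(table: CoefficientTable, query: RiskQuery) -> float:
    """(start, target) entry of the left-to-right product of annual matrices."""
    if not (query.target_state.absorbing or query.target_state == CAD):
        raise ValueError("marginal mode is restricted to the absorbing targets CAD and Death")
    _validate_treated(query)
    rr = query.treatment_rr if query.treated else 0.0
    prod = np.eye(len(STATES))
    for age in range(query.start_age, query.end_age):
        T = build_transition_matrix(
            table, query.profile, age, rr=rr, target_state=query.target_state
        )
        prod = prod @ T.matrix
    return float(prod[_STATE_INDEX[query.start_state.label], _STATE_INDEX[query.target_state.label]])


def bootstrap_projection(
    records: Sequence,
    query: RiskQuery,
    n_boot: int,
    seed: int,
    age_range: tuple[int, int] = (40, DEFAULT_L),
    covariates: Sequence[str] = COVARIATE_NAMES,
    smoother: Optional[SmootherConfig] = None,
    index_sampler=None,
) -> RiskResult:
    """Person-level bootstrap of the full fit -> smooth -> project pipeline.

    Resamples whole persons with replacement, refits and re-smooths per
    replicate, and reports the mean and standard error of the projected
    risk across valid replicates.  Replicates in which the query's key
    transition cannot be smoothed at all are recorded as missing.
    ``index_sampler(rng, n) -> indices`` overrides the resampling draw
    (e.g. for degenerate identity resampling in tests).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    smoother = smoother or SmootherConfig()
    rng = np.random.default_rng(seed)
    records = list(records)
    n = len(records)
    risks = []
    for _ in range(n_boot):
        idx = index_sampler(rng, n) if index_sampler else rng.integers(0, n, size=n)
        sample = [records[i] for i in idx]
        py = expand_cohort(sample, age_lo=age_range[0], age_hi=age_range[1])
        raw = fit_all(py, age_range=age_range, covariates=covariates)
        try:
            smoothed = smooth_table(raw, smoother)
            res = compute_risk(smoothed, query)
        except ValueError as exc:
            logger.warning("bootstrap replicate unusable: %s", exc)
            continue
        key = (query.start_state.label, query.target_state.label)
        if key in smoothed.unavailable:
            logger.warning("bootstrap replicate missing key transition %s", key)
            continue
        risks.append(res.risk)
    if not risks:
        raise RuntimeError("no valid bootstrap replicate")
    arr = np.asarray(risks)
    se = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return RiskResult(risk=float(arr.mean()), per_age_probs=(), se=se, n_boot=len(arr))
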