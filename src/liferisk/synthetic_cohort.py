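"""Synthetic longitudinal cohorts with known ground-truth transition models.

Trajectories are simulated year by year: each person's successor state is a
categorical draw from the ground-truth annual transition row implied by the
generating coefficient functions, honoring the restricted topology,
absorbing states, censoring, staggered first observation, and medication
initiation.  Because the generating model is expressed as a coefficient
table, the exact ground-truth risk of any query is available through the
same risk algebra the engine uses — the parameter-recovery oracle for the
whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .ehr_timeline import COVARIATE_NAMES, PersonRecord
from .risk_engine import Profile, RiskQuery, RiskResult, compute_risk
from .state_space import (
    CAD,
    DEATH,
    STATES,
    State,
    STATE_BY_LABEL,
    allowed,
    destination_states,
)
from .transition_fitting import INTERCEPT, CoefficientTable

__all__ = ["GeneratorConfig", "simulate_cohort", "ground_truth_table", "ground_truth_risk"]

CoefValue = Union[float, Callable[[float], float]]

_PROFILE_GRID = [
    Profile(sex=s, prs=p, smoker=sm, statin_use=st, antihtn_use=ah)
    for s in (0, 1)
    for p in (-3.0, 0.0, 3.0)
    for sm in (0, 1)
    for st in (0, 1)
    for ah in (0, 1)
]


@dataclass
class GeneratorConfig:
    """Ground truth and sampling distributions for one synthetic cohort.

    ``coefficients`` maps (from_label, to_label) -> {term: value-or-callable};
    transitions not listed have probability zero.  Terms are the intercept
    plus any subset of the standard covariates.
    """

    n_persons: int
    seed: int
    coefficients: Mapping[tuple, Mapping[str, CoefValue]]
    age_lo: int = 40
    age_hi: int = 80
    sim_start_age: int = 40  # state accumulation can begin before age_lo
    first_obs_median: float = 24.3
    first_obs_spread: float = 0.45  # lognormal sigma of (first_obs - 16)
    censor_lo: float = 60.0
    censor_hi: float = 80.0
    enroll_lo: float = 40.0
    enroll_hi: float = 69.0
    sex_p: float = 0.5
    smoker_p: float = 0.1
    statin_hazard: float = 0.0  # annual initiation probability from age_lo on
    antihtn_hazard: float = 0.0
    double_diagnosis_rate: float = 0.0  # same-year second diagnosis injection
    birth_year: int = 1950

    def __post_init__(self) -> None:
        if self.n_persons < 0:
            raise ValueError("n_persons must be nonnegative")
        for (f, t), terms in self.coefficients.items():
            if f not in STATE_BY_LABEL or t not in STATE_BY_LABEL:
                raise ValueError(f"unknown state in transition ({f!r}, {t!r})")
            if f == t or not allowed(f, t):
                raise ValueError(f"({f}, {t}) is not an allowed non-self transition")
            unknown = set(terms) - {INTERCEPT, *COVARIATE_NAMES}
            if unknown:
                raise ValueError(f"unknown coefficient term(s) {sorted(unknown)}")

    # -- ground truth as a coefficient table --------------------------------

    def beta_vector(self, from_label: str, to_label: str, age: float) -> Optional[np.ndarray]:
        terms = self.coefficients.get((from_label, to_label))
        if terms is None:
            return None
        beta = np.zeros(1 + len(COVARIATE_NAMES))
        names = (INTERCEPT, *COVARIATE_NAMES)
        for i, name in enumerate(names):
            v = terms.get(name, 0.0)
            beta[i] = v(age) if callable(v) else float(v)
        return beta

    def validate(self) -> None:
        """Reject configs whose implied annual rows can exceed probability 1.

        Checked on a grid of extreme covariate profiles at every age; names
        the offending (from-state, age) on failure.
        """
        from_labels = {f for (f, _) in self.coefficients}
        profiles = np.array([p.vector(COVARIATE_NAMES) for p in _PROFILE_GRID])
        for f in from_labels:
            dests = [t for (ff, t) in self.coefficients if ff == f]
            for age in range(min(self.sim_start_age, self.age_lo), self.age_hi):
                total = np.zeros(len(profiles))
                for t in dests:
                    eta = profiles @ self.beta_vector(f, t, age)
                    total += 1.0 / (1.0 + np.exp(-eta))
                if np.any(total > 1.0):
                    raise ValueError(
                        f"generating model implies off-diagonal sum "
                        f"{total.max():.4f} > 1 for ({f}, age {age})"
                    )


def ground_truth_table(
    config: GeneratorConfig, age_range: Optional[tuple[int, int]] = None
) -> CoefficientTable:
    """Materialize the generating coefficients as a smoothed-variant table."""
    lo, hi = age_range or (config.age_lo, config.age_hi)
    names = (INTERCEPT, *COVARIATE_NAMES)
    rows: dict[str, list] = {c: [] for c in CoefficientTable.COLUMNS}
    for (f, t) in config.coefficients:
        for age in range(lo, hi):
            beta = config.beta_vector(f, t, age)
            for i, name in enumerate(names):
                rows["from"].append(f)
                rows["to"].append(t)
                rows["age"].append(age)
                rows["term"].append(name)
                rows["beta"].append(beta[i])
                rows["se"].append(1.0)
                rows["n_at_risk"].append(0)
                rows["n_events"].append(0)
                rows["variant"].append("smoothed")
    return CoefficientTable(pd.DataFrame(rows), variant="smoothed", covariates=COVARIATE_NAMES)


def ground_truth_risk(config: GeneratorConfig, query: RiskQuery) -> RiskResult:
    """Exact risk under the generating model — no fitting involved."""
    lo = min(config.sim_start_age, query.start_age)
    table = ground_truth_table(config, (lo, max(config.age_hi, query.end_age)))
    return compute_risk(table, query)


def _draw_med_start(rng: np.random.Generator, n: int, hazard: float, age_lo: int, age_hi: int):
    """Per-person initiation age under a constant annual hazard, or None."""
    starts = np.full(n, np.nan)
    if hazard > 0:
        waits = rng.geometric(hazard, size=n)  # 1 means initiation in the first year
        ages = age_lo + waits - 1
        starts = np.where(ages < age_hi, ages.astype(float), np.nan)
    return starts


def simulate_cohort(config: GeneratorConfig, validate: bool = True) -> list[PersonRecord]:
    """Simulate ``config.n_persons`` longitudinal records.

    Bit-identical for a fixed seed.  The per-age loop is vectorized over
    persons grouped by current state.
    """
    if validate:
        config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    if n == 0:
        return []

    sex = rng.binomial(1, config.sex_p, size=n)
    prs = rng.standard_normal(n)
    smoker = rng.binomial(1, config.smoker_p, size=n)
    first_obs = 16.0 + rng.lognormal(np.log(config.first_obs_median - 16.0), config.first_obs_spread, size=n)
    censor = rng.uniform(config.censor_lo, config.censor_hi, size=n)
    first_obs = np.minimum(first_obs, censor)
    enroll = np.minimum(rng.uniform(config.enroll_lo, config.enroll_hi, size=n), censor)
    statin_start = _draw_med_start(rng, n, config.statin_hazard, config.age_lo, config.age_hi)
    antihtn_start = _draw_med_start(rng, n, config.antihtn_hazard, config.age_lo, config.age_hi)

    state_idx = {s.label: i for i, s in enumerate(STATES)}
    cur = np.zeros(n, dtype=int)  # everyone starts Health
    dx_ages: list[dict] = [dict() for _ in range(n)]
    death_age = np.full(n, np.nan)

    # destinations per from-state, restricted to those with generating betas
    dest_of: dict[int, list[State]] = {}
    for j in STATES:
        if j.absorbing:
            continue
        dests = [k for k in destination_states(j) if (j.label, k.label) in config.coefficients]
        if dests:
            dest_of[state_idx[j.label]] = dests

    def enter_state(person: int, old: State, new: State, event_age: int) -> None:
        """Record the diagnoses / death implied by moving old -> new at event_age."""
        if new == DEATH:
            death_age[person] = event_age
        elif new == CAD:
            dx_ages[person]["CAD"] = event_age
        else:
            for cond in new.rf_set - old.rf_set:
                dx_ages[person][cond] = event_age
        cur[person] = state_idx[new.label]

    for age in range(config.sim_start_age, config.age_hi):
        active = np.flatnonzero((censor >= age + 1) & np.isnan(death_age))
        if active.size == 0:
            break
        statin_use = (statin_start[active] <= age) & ~np.isnan(statin_start[active])
        antihtn_use = (antihtn_start[active] <= age) & ~np.isnan(antihtn_start[active])
        X = np.column_stack(
            [
                np.ones(active.size),
                sex[active],
                prs[active],
                smoker[active],
                statin_use.astype(float),
                antihtn_use.astype(float),
            ]
        )
        u = rng.uniform(size=active.size)
        extra = (
            rng.uniform(size=active.size) < config.double_diagnosis_rate
            if config.double_diagnosis_rate > 0
            else np.zeros(active.size, dtype=bool)
        )
        cur_snapshot = cur[active].copy()  # one transition per year
        for ji, dests in dest_of.items():
            rows = np.flatnonzero(cur_snapshot == ji)
            if rows.size == 0:
                continue
            j_state = STATES[ji]
            pis = np.empty((rows.size, len(dests)))
            for d, k in enumerate(dests):
                beta = config.beta_vector(j_state.label, k.label, age)
                eta = np.clip(X[rows] @ beta, -30, 30)
                pis[:, d] = 1.0 / (1.0 + np.exp(-eta))
            cum = np.cumsum(pis, axis=1)
            draw = u[rows]
            moved = draw < cum[:, -1]
            dest_choice = (draw[:, None] < cum).argmax(axis=1)
            for r, d, uval in zip(rows[moved], dest_choice[moved], draw[moved]):
                person = int(active[r])
                k = dests[d]
                # optional same-year second diagnosis, exercising skip handling
                if (
                    extra[r]
                    and k not in (CAD, DEATH)
                    and k.level == j_state.level + 1
                ):
                    supersets = [
                        s
                        for s in STATES
                        if s.level == k.level + 1 and k.rf_set < s.rf_set
                    ]
                    if supersets:
                        k = supersets[int(uval * 1e6) % len(supersets)]
                enter_state(person, j_state, k, age + 1)

    records = []
    width = len(str(max(n - 1, 1)))
    for i in range(n):
        effective_censor = censor[i] if np.isnan(death_age[i]) else min(censor[i], death_age[i])
        records.append(
            PersonRecord(
                person_id=f"p{i:0{width}d}",
                sex=int(sex[i]),
                prs=float(prs[i]),
                birth_year=config.birth_year,
                first_obs_age=float(min(first_obs[i], effective_censor)),
                censor_age=float(censor[i]),
                smoker=int(smoker[i]),
                dx_age={c: float(a) for c, a in dx_ages[i].items()},
                death_age=None if np.isnan(death_age[i]) else float(death_age[i]),
                statin_start_age=None if np.isnan(statin_start[i]) else float(statin_start[i]),
                antihtn_start_age=None if np.isnan(antihtn_start[i]) else float(antihtn_start[i]),
                enroll_age=float(enroll[i]),
            )
        )
    return records
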