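"""Model-assessment battery.

Stratified calibration RMSE, net reclassification components, threshold-age
analysis, interval expansion for time-dependent evaluation, time-dependent
concordance, cumulative AUROC / precision-recall, and proportion standard
errors.  Comparator risk scores (e.g. published 10-/30-year equations) are
consumed as externally supplied per-person-per-age columns; their equations
are not re-implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreSeries",
    "ExpandedInterval",
    "NEVER",
    "stratified_rmse",
    "nri_components",
    "proportion_se",
    "threshold_age",
    "expand_intervals",
    "time_dependent_concordance",
    "compare_concordance",
    "cumulative_auc_pr",
    "EvaluationReport",
]

#: sentinel returned by threshold_age when the score never exceeds the threshold
NEVER = None

EVALUATION_HORIZON = 80


@dataclass(frozen=True)
class ScoreSeries:
    """Per-age score values for one person while at risk."""

    person_id: str
    scores: Mapping[int, float]  # age -> score
    score_name: str = "score"

    def at(self, age: int) -> Optional[float]:
        return self.scores.get(age)


@dataclass(frozen=True)
class ExpandedInterval:
    person_id: str
    age_start: int
    age_stop: int  # half-open [age_start, age_stop)
    flags: tuple  # per-score threshold-exceeded indicators, constant in interval
    event: bool  # event has occurred by age_start


# ---------------------------------------------------------------------------
# calibration


def stratified_rmse(
    predicted: np.ndarray,
    observed: np.ndarray,
    sex: np.ndarray,
    prs: np.ndarray,
    prs_cuts: Optional[tuple[float, float]] = None,
) -> float:
    """Calibration RMSE over sex x PRS-group strata, in percent.

    Strata are sex crossed with PRS groups (<20%, 20-80%, >80%); the error
    in each stratum is the empirical incidence minus the mean predicted
    risk.  ``prs_cuts`` supplies externally computed (training-set)
    quantile cut points; by default the 20th/80th percentiles of ``prs``.
    Empty strata are excluded.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    sex = np.asarray(sex)
    prs = np.asarray(prs, dtype=float)
    if prs_cuts is None:
        prs_cuts = (float(np.quantile(prs, 0.2)), float(np.quantile(prs, 0.8)))
    lo, hi = prs_cuts
    prs_group = np.where(prs < lo, 0, np.where(prs <= hi, 1, 2))
    errors = []
    for s in np.unique(sex):
        for g in (0, 1, 2):
            mask = (sex == s) & (prs_group == g)
            if not np.any(mask):
                continue
            errors.append(observed[mask].mean() - predicted[mask].mean())
    if not errors:
        raise ValueError("no populated stratum")
    return float(np.sqrt(np.mean(np.square(errors))) * 100.0)


# ---------------------------------------------------------------------------
# net reclassification


def proportion_se(p_hat: float, n: int) -> float:
    """Standard error of a sample proportion, sqrt(p(1-p)/n)."""
    return math.sqrt(p_hat * (1.0 - p_hat) / n)


def nri_components(
    model_risk: np.ndarray,
    comparator_risk: np.ndarray,
    outcomes: np.ndarray,
    lifetime_threshold: float = 0.10,
    comparator_threshold: float = 0.05,
    symmetric_model_threshold: bool = False,
):
    """Event / non-event net reclassification of the model vs a comparator.

    As printed, the event numerator's down-classification term uses the
    *comparator* threshold for the model score (model < 5%); setting
    ``symmetric_model_threshold`` uses the lifetime threshold (10%)
    symmetrically instead.  Returns a dict with components, overall NRI,
    and proportion standard errors; a component with no eligible subjects
    is reported as None.
    """
    m = np.asarray(model_risk, dtype=float)
    c = np.asarray(comparator_risk, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    lt = lifetime_threshold
    ct = comparator_threshold
    model_down_cut = lt if symmetric_model_threshold else ct

    n_event = int(y.sum())
    n_nonevent = int((~y).sum())

    def comp(mask, up, down, n):
        if n == 0:
            return None, None
        p_up = int((mask & up).sum()) / n
        p_down = int((mask & down).sum()) / n
        value = p_up - p_down
        return value, proportion_se(abs(value), n)

    up_event = (m > lt) & (c < ct)
    down_event = (m < model_down_cut) & (c > ct)
    nri_event, se_event = comp(y, up_event, down_event, n_event)

    up_nonevent = (m < lt) & (c > ct)
    down_nonevent = (m > lt) & (c < ct)
    nri_nonevent, se_nonevent = comp(~y, up_nonevent, down_nonevent, n_nonevent)

    overall = None
    if nri_event is not None and nri_nonevent is not None:
        overall = nri_event + nri_nonevent
    return {
        "nri_event": nri_event,
        "nri_event_se": se_event,
        "nri_nonevent": nri_nonevent,
        "nri_nonevent_se": se_nonevent,
        "overall": overall,
    }


# ---------------------------------------------------------------------------
# threshold ages and interval expansion


def threshold_age(series: ScoreSeries, threshold: float) -> Optional[int]:
    """Smallest age with score strictly above ``threshold``; None if never."""
    if not series.scores:
        raise ValueError("score series is empty")
    for age in sorted(series.scores):
        if series.scores[age] > threshold:
            return age
    return NEVER


def expand_intervals(
    person_id: str,
    obs_start: int,
    obs_end: int,
    threshold_ages: Sequence[Optional[int]],
    event_age: Optional[int] = None,
    horizon_end: int = EVALUATION_HORIZON,
    enroll_age: Optional[int] = None,
) -> list[ExpandedInterval]:
    """Divide one person's follow-up into nonoverlapping intervals.

    Cut points fall at each threshold-crossing age and at the event age;
    flags are constant within each interval.  Follow-up is left-censored at
    ``enroll_age``: crossings before it enter with their flag already set.
    After an event the final interval runs to ``horizon_end``; otherwise
    follow-up stops at min(obs_end, horizon_end).
    """
    start = max(obs_start, enroll_age if enroll_age is not None else obs_start)
    if event_age is not None and event_age < start:
        raise ValueError(
            f"person {person_id}: event at {event_age} precedes follow-up start {start}"
        )
    end = horizon_end if event_age is not None else min(obs_end, horizon_end)
    if end <= start:
        return []
    cuts = {start}
    for ta in threshold_ages:
        if ta is not None and start < ta < end:
            cuts.add(ta)
    if event_age is not None and start < event_age < end:
        cuts.add(event_age)
    bounds = sorted(cuts) + [end]
    intervals = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        flags = tuple(ta is not None and ta <= a for ta in threshold_ages)
        event = event_age is not None and event_age <= a
        intervals.append(
            ExpandedInterval(person_id=person_id, age_start=a, age_stop=b, flags=flags, event=event)
        )
    return intervals


# ---------------------------------------------------------------------------
# concordance


def _concordance_stat(
    scores: Mapping[str, Mapping[int, float]],
    event_ages: Mapping[str, Optional[int]],
    censor_ages: Mapping[str, int],
    persons: Sequence[str],
) -> tuple[float, int]:
    """Harrell's C over comparable pairs at event ages using current scores."""
    concordant = 0.0
    pairs = 0
    for i in persons:
        t = event_ages.get(i)
        if t is None:
            continue
        s_i = scores[i].get(t)
        if s_i is None:
            continue
        for j in persons:
            if j == i:
                continue
            t_j = event_ages.get(j)
            # j is at risk at t: not yet failed and not yet censored
            still_at_risk = (t_j is None or t_j > t) and censor_ages[j] > t
            if not still_at_risk:
                continue
            s_j = scores[j].get(t)
            if s_j is None:
                continue
            pairs += 1
            if s_i > s_j:
                concordant += 1.0
            elif s_i == s_j:
                concordant += 0.5
    return concordant, pairs


def time_dependent_concordance(
    score_series: Sequence[ScoreSeries],
    event_ages: Mapping[str, Optional[int]],
    censor_ages: Mapping[str, int],
    n_boot: int = 0,
    seed: int = 0,
) -> dict:
    """Time-dependent Harrell's C with optional person-level bootstrap CI.

    At each event age the failing subject's current score is compared with
    the current scores of everyone still at risk; ties count one half.
    Returns ``{"c": ..., "n_pairs": ..., "ci": (lo, hi) | None,
    "boot": samples | None}``; C is None when no comparable pair exists.
    """
    scores = {s.person_id: dict(s.scores) for s in score_series}
    persons = sorted(scores)
    concordant, pairs = _concordance_stat(scores, event_ages, censor_ages, persons)
    if pairs == 0:
        return {"c": None, "n_pairs": 0, "ci": None, "boot": None}
    c = concordant / pairs
    ci = None
    boot = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        samples = []
        for _ in range(n_boot):
            resample = list(rng.choice(persons, size=len(persons), replace=True))
            conc_b, pairs_b = _concordance_stat(scores, event_ages, censor_ages, resample)
            if pairs_b > 0:
                samples.append(conc_b / pairs_b)
        boot = np.asarray(samples)
        if len(boot):
            ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))
    return {"c": c, "n_pairs": pairs, "ci": ci, "boot": boot}


def compare_concordance(boot_a: np.ndarray, boot_b: np.ndarray) -> dict:
    """Two-sided Z-test on the bootstrap difference of two C-indexes."""
    from scipy import stats

    diff = np.asarray(boot_a, dtype=float) - np.asarray(boot_b, dtype=float)
    se = diff.std(ddof=1)
    if se == 0:
        return {"z": 0.0 if diff.mean() == 0 else math.inf, "p": 1.0 if diff.mean() == 0 else 0.0}
    z = diff.mean() / se
    p = 2.0 * stats.norm.sf(abs(z))
    return {"z": float(z), "p": float(p)}


# ---------------------------------------------------------------------------
# cumulative discrimination


def cumulative_auc_pr(scores: np.ndarray, outcomes: np.ndarray) -> tuple[float, float]:
    """Rank-based AUROC (ties 0.5) and interpolated precision-recall area.

    ``outcomes`` is cumulative case/control status at one age; both classes
    must be present.
    """
    from sklearn.metrics import auc, precision_recall_curve, roc_auc_score

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    auroc = float(roc_auc_score(y, scores))
    precision, recall, _ = precision_recall_curve(y, scores)
    pr_area = float(auc(recall, precision))
    return auroc, pr_area


@dataclass
class EvaluationReport:
    """Container for one evaluation run, serializable to delimited text."""

    rmse_pct: Optional[float] = None
    nri: dict = field(default_factory=dict)
    threshold_ages: dict = field(default_factory=dict)  # score_name -> {person: age|None}
    concordance: dict = field(default_factory=dict)  # score_name -> result dict
    auc: dict = field(default_factory=dict)  # score_name -> (auroc, pr)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.rmse_pct is not None:
            rows.append(("rmse_pct", "", self.rmse_pct))
        for k, v in self.nri.items():
            rows.append((f"nri_{k}" if not k.startswith("nri") else k, "", v))
        for name, res in self.concordance.items():
            rows.append(("c_index", name, res.get("c")))
            if res.get("ci"):
                rows.append(("c_index_lo", name, res["ci"][0]))
                rows.append(("c_index_hi", name, res["ci"][1]))
        for name, (auroc, pr) in self.auc.items():
            rows.append(("auroc", name, auroc))
            rows.append(("pr_area", name, pr))
        return pd.DataFrame(rows, columns=["metric", "score", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")
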