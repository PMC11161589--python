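"""Per-age, per-transition logistic regression on the at-risk set.

Each legal non-self transition j -> k gets, at every integer age, its own
binary logistic fit (one-vs-rest among rows currently in state j), giving a
vector of log-odds coefficients with standard errors.  Self-transitions are
never fitted: they are the complement of the fitted destinations.

Cells that cannot support a fit (no events, no non-events, too few rows,
perfect separation, non-convergence) are recorded as *unfit sentinels*:
beta absent (NaN) and an infinite-variance standard error, so that the
downstream smoother gives them exactly zero weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ehr_timeline import COVARIATE_NAMES, PersonYear
from .state_space import NONABSORBING_STATES, CAD, State, destination_states

__all__ = [
    "CoefficientTable",
    "FitResult",
    "fit_logistic",
    "fit_transition_age",
    "fit_all",
    "predict_annual_probability",
    "UnfitCellError",
]

logger = logging.getLogger(__name__)

INTERCEPT = "intercept"

#: standard-error sentinel for unfit cells; weight 1/se^2 is exactly 0
SE_SENTINEL = np.inf

MAX_ITER = 100
LL_TOL = 1e-8


class UnfitCellError(LookupError):
    """Raised when a prediction is requested from an unfit coefficient cell."""


@dataclass
class FitResult:
    beta: np.ndarray  # NaN when unfit
    se: np.ndarray  # inf when unfit
    n_at_risk: int
    n_events: int
    converged: bool

    @property
    def unfit(self) -> bool:
        return not self.converged


def _sentinel(p: int, n: int, events: int) -> FitResult:
    return FitResult(
        beta=np.full(p, np.nan),
        se=np.full(p, SE_SENTINEL),
        n_at_risk=n,
        n_events=events,
        converged=False,
    )


def fit_logistic(X: np.ndarray, y: np.ndarray) -> FitResult:
    """Maximum-likelihood logistic fit by Newton-Raphson.

    Returns an unfit sentinel on degenerate outcomes, perfect separation
    (diverging coefficients), or non-convergence within ``MAX_ITER``
    iterations at log-likelihood tolerance ``LL_TOL``.
    """
    n, p = X.shape
    events = int(y.sum())
    if events == 0 or events == n or n < p + 1:
        return _sentinel(p, n, events)
    beta = np.zeros(p)
    # start the intercept at the empirical logit; column 0 is the intercept
    frac = events / n
    beta[0] = np.log(frac / (1.0 - frac))
    ll_old = -np.inf
    for _ in range(MAX_ITER):
        eta = X @ beta
        eta = np.clip(eta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return _sentinel(p, n, events)
        beta = beta + step
        if abs(ll - ll_old) < LL_TOL:
            if np.max(np.abs(beta)) > 25.0:
                logger.warning("perfect separation suspected; marking cell unfit")
                return _sentinel(p, n, events)
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                return _sentinel(p, n, events)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            if not np.all(np.isfinite(se)) or np.any(se == 0.0):
                return _sentinel(p, n, events)
            if np.max(se) > 50.0:  # flat likelihood: (quasi-)separation
                logger.warning("perfect separation suspected; marking cell unfit")
                return _sentinel(p, n, events)
            return FitResult(beta=beta, se=se, n_at_risk=n, n_events=events, converged=True)
        ll_old = ll
    logger.warning("logistic fit did not converge in %d iterations", MAX_ITER)
    return _sentinel(p, n, events)


def _design(rows: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    X = np.empty((len(rows), len(covariates) + 1))
    X[:, 0] = 1.0
    for i, name in enumerate(covariates, start=1):
        X[:, i] = rows[name].to_numpy(dtype=float)
    return X


def fit_transition_age(
    rows: "pd.DataFrame | Sequence[PersonYear]",
    to_state: State,
    covariates: Sequence[str] = COVARIATE_NAMES,
) -> FitResult:
    """Fit one (from-state, age) cell for destination ``to_state``.

    ``rows`` must share a single from-state and age; the outcome is the
    indicator of moving to ``to_state`` next year.
    """
    df = _rows_to_frame(rows)
    if len(df):
        if df["age"].nunique() != 1 or df["from_state"].nunique() != 1:
            raise ValueError("rows must share one from_state and one age")
    y = (df["to_state"] == to_state.label).to_numpy(dtype=float)
    X = _design(df, covariates)
    return fit_logistic(X, y)


def _rows_to_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    return pd.DataFrame(
        {
            "person_id": [r.person_id for r in rows],
            "age": [r.age for r in rows],
            "from_state": [r.from_state.label for r in rows],
            "to_state": [r.to_state.label for r in rows],
            **{c: [getattr(r, c) for r in rows] for c in COVARIATE_NAMES},
        }
    )


class CoefficientTable:
    """Per (from_state, to_state, age, term) logistic coefficients.

    Backed by a tidy DataFrame with columns
    ``from, to, age, term, beta, se, n_at_risk, n_events, variant``.
    Unfit cells carry beta = NaN, se = inf.
    """

    COLUMNS = ["from", "to", "age", "term", "beta", "se", "n_at_risk", "n_events", "variant"]

    def __init__(self, frame: pd.DataFrame, variant: str, covariates: Sequence[str]):
        self.frame = frame.reset_index(drop=True)
        self.variant = variant
        self.covariates = tuple(covariates)
        self.terms = (INTERCEPT,) + self.covariates
        self.unavailable: tuple = ()  # transitions with no fit at any age
        self._cells: dict = {}
        grouped = self.frame.groupby(["from", "to", "age"], sort=False)
        for key, g in grouped:
            g = g.set_index("term")
            beta = g["beta"].reindex(list(self.terms)).to_numpy(dtype=float)
            se = g["se"].reindex(list(self.terms)).to_numpy(dtype=float)
            self._cells[key] = (beta, se, int(g["n_at_risk"].iloc[0]), int(g["n_events"].iloc[0]))

    # -- accessors ----------------------------------------------------------

    def transitions(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for f, t, _ in self._cells:
            seen[(f, t)] = None
        return list(seen)

    def ages(self) -> list[int]:
        return sorted({a for _, _, a in self._cells})

    def has_cell(self, from_state: State, to_state: State, age: int) -> bool:
        return (from_state.label, to_state.label, age) in self._cells

    def cell(self, from_state: State, to_state: State, age: int):
        """(beta, se, n_at_risk, n_events) for one cell; KeyError if absent."""
        return self._cells[(from_state.label, to_state.label, age)]

    def is_unfit(self, from_state: State, to_state: State, age: int) -> bool:
        beta, _, _, _ = self.cell(from_state, to_state, age)
        return bool(np.any(~np.isfinite(beta)))

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        df = self.frame.copy()
        df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "CoefficientTable":
        df = pd.read_csv(path, na_values=["NA"], keep_default_na=False, float_precision="round_trip")
        df["age"] = df["age"].astype(int)
        variant = df["variant"].iloc[0] if len(df) else "raw"
        terms = list(dict.fromkeys(df["term"]))
        covariates = [t for t in terms if t != INTERCEPT]
        return cls(df, variant=variant, covariates=covariates)


def fit_all(
    person_years: pd.DataFrame,
    age_range: tuple[int, int] = (40, 80),
    covariates: Sequence[str] = COVARIATE_NAMES,
    include_cad_to_death: bool = False,
) -> CoefficientTable:
    """Fit every (allowed transition, age) cell over ``age_range``.

    Rows flagged ``skip`` (multi-event years that jump a level) are kept in
    the at-risk denominator but never count as events for any single-step
    destination, matching the restricted one-step topology.
    """
    lo, hi = age_range
    if lo >= hi:
        raise ValueError(f"age_range must be increasing, got {age_range}")
    covariates = tuple(covariates)
    terms = [INTERCEPT, *covariates]
    p = len(terms)

    from_states = [s for s in NONABSORBING_STATES if s is not CAD]
    if include_cad_to_death:
        from_states.append(CAD)

    records: dict[str, list] = {c: [] for c in CoefficientTable.COLUMNS}
    df = person_years[person_years["at_risk"]]
    groups = {key: g for key, g in df.groupby(["from_state", "age"], sort=False)}

    for j in from_states:
        dests = destination_states(j)
        for age in range(lo, hi):
            g = groups.get((j.label, age))
            for k in dests:
                if g is None or len(g) == 0:
                    res = _sentinel(p, 0, 0)
                else:
                    X = _design(g, covariates)
                    y = ((g["to_state"] == k.label) & (~g["skip"])).to_numpy(dtype=float)
                    res = fit_logistic(X, y)
                for t_i, term in enumerate(terms):
                    records["from"].append(j.label)
                    records["to"].append(k.label)
                    records["age"].append(age)
                    records["term"].append(term)
                    records["beta"].append(res.beta[t_i])
                    records["se"].append(res.se[t_i])
                    records["n_at_risk"].append(res.n_at_risk)
                    records["n_events"].append(res.n_events)
                    records["variant"].append("raw")
    frame = pd.DataFrame(records)
    return CoefficientTable(frame, variant="raw", covariates=covariates)


def predict_annual_probability(beta: np.ndarray, profile: np.ndarray) -> float:
    """Inverse-logit of the linear predictor ``profile @ beta``.

    ``profile`` includes the leading intercept 1.  Raises
    :class:`UnfitCellError` when the cell is an unfit sentinel.
    """
    beta = np.asarray(beta, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if beta.shape != profile.shape:
        raise ValueError(f"beta {beta.shape} and profile {profile.shape} not conformable")
    if np.any(~np.isfinite(beta)):
        raise UnfitCellError("coefficient cell is unfit; use the smoothed table")
    eta = float(profile @ beta)
    if eta >= 0:
        return 1.0 / (1.0 + np.exp(-eta))
    e = np.exp(eta)
    return float(e / (1.0 + e))
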