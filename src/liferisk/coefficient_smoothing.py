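"""Locally weighted smoothing of raw coefficient series across age.

Each covariate's raw coefficient series (one value per age, per transition)
is smoothed by weighted local polynomial regression.  The weight of a
neighboring age combines a cubic distance decay, 1 - (D/w)^3, with the
inverse variance of the raw estimate, so noisy cells (small at-risk sets)
contribute proportionately less; unfit sentinel cells have infinite
variance and contribute exactly nothing.  Near the edges of the age grid
the window is widened to mitigate boundary bias.

Note the distance kernel is the plain cubic decay rather than the
classical tricube (1 - (D/w)^3)^3; a config switch selects the classical
kernel for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .transition_fitting import INTERCEPT, CoefficientTable

__all__ = [
    "SmootherConfig",
    "tricube_inverse_variance_weights",
    "smooth_series",
    "smooth_table",
    "EmptyWindowError",
]

logger = logging.getLogger(__name__)


class EmptyWindowError(ValueError):
    """No neighbor with positive weight inside the smoothing window."""


@dataclass(frozen=True)
class SmootherConfig:
    window_width: float = 10.0
    degree: int = 2
    boundary_extension: float = 5.0
    classical_tricube: bool = False

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if self.degree < 0:
            raise ValueError("degree must be nonnegative")
        if self.boundary_extension < 0:
            raise ValueError("boundary_extension must be nonnegative")


def _adjusted_window(target_age: float, grid_lo: float, grid_hi: float, cfg: SmootherConfig) -> float:
    near_edge = (
        target_age - grid_lo <= cfg.boundary_extension
        or grid_hi - target_age <= cfg.boundary_extension
    )
    return cfg.window_width + cfg.boundary_extension if near_edge else cfg.window_width


def tricube_inverse_variance_weights(
    target_age: float,
    neighbor_ages: np.ndarray,
    neighbor_variances: np.ndarray,
    config: SmootherConfig,
    grid_bounds: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Weight vector over ``neighbor_ages`` for one target age.

    weight_i = (1 - (D_i / w)^3) / sigma_i^2 for D_i within the (possibly
    boundary-extended) window, 0 outside.  Infinite variances (unfit cells)
    get weight exactly 0.  Raises :class:`EmptyWindowError` when no
    neighbor has positive weight.
    """
    ages = np.asarray(neighbor_ages, dtype=float)
    var = np.asarray(neighbor_variances, dtype=float)
    if grid_bounds is None:
        grid_bounds = (float(ages.min()), float(ages.max()))
    w = _adjusted_window(target_age, grid_bounds[0], grid_bounds[1], config)
    D = np.abs(ages - target_age)
    dist = 1.0 - (D / w) ** 3
    if config.classical_tricube:
        dist = dist**3
    dist = np.where(D <= w, np.maximum(dist, 0.0), 0.0)
    with np.errstate(divide="ignore"):
        inv_var = np.where(np.isfinite(var) & (var > 0), 1.0 / var, 0.0)
    weights = dist * inv_var
    if not np.any(weights > 0):
        raise EmptyWindowError(
            f"no neighbor with positive weight within window {w} of age {target_age}"
        )
    return weights


def _wls_at(
    target_age: float,
    ages: np.ndarray,
    values: np.ndarray,
    weights: np.ndarray,
    degree: int,
) -> float:
    """Weighted polynomial fit in an age-centered basis, evaluated at the center."""
    mask = weights > 0
    a = ages[mask] - target_age
    y = values[mask]
    wts = weights[mask]
    d = degree
    # need d+1 distinct support ages for a degree-d fit; otherwise reduce
    n_support = len(np.unique(a))
    if n_support < d + 1:
        d = n_support - 1
        logger.warning(
            "rank-deficient window at age %s: reducing degree to %d", target_age, d
        )
    X = np.vander(a, d + 1, increasing=True)
    sw = np.sqrt(wts)
    coef, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
    return float(coef[0])  # centered basis: intercept is the value at target_age


def smooth_series(
    ages: np.ndarray,
    values: np.ndarray,
    variances: np.ndarray,
    config: SmootherConfig,
) -> np.ndarray:
    """Smooth one raw coefficient series over its age grid.

    NaN values must carry infinite variance (unfit sentinels); the output
    is defined at every grid age, borrowing across neighbors.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    variances = np.asarray(variances, dtype=float)
    bounds = (float(ages.min()), float(ages.max()))
    out = np.empty_like(values)
    finite = np.isfinite(variances) & (variances > 0)
    for i, a in enumerate(ages):
        try:
            wts = tricube_inverse_variance_weights(a, ages, variances, config, grid_bounds=bounds)
        except EmptyWindowError:
            # no fit neighbor inside the window: borrow the nearest fit cell
            nearest = np.flatnonzero(finite)[np.argmin(np.abs(ages[finite] - a))]
            logger.warning(
                "empty smoothing window at age %s; borrowing nearest fit age %s",
                a,
                ages[nearest],
            )
            out[i] = values[nearest]
            continue
        out[i] = _wls_at(a, ages, np.nan_to_num(values), wts, config.degree)
    return out


def smooth_table(raw: CoefficientTable, config: SmootherConfig) -> CoefficientTable:
    """Smooth every (transition, term) series of a raw table.

    Sentinel cells are replaced by values borrowed from fit neighbors.  A
    transition unfit at *every* age cannot be smoothed and is dropped from
    the output; the risk engine treats such transitions as probability 0.
    """
    frames = []
    unavailable = []
    raw_df = raw.frame
    for (f, t), g in raw_df.groupby(["from", "to"], sort=False):
        wide_beta = g.pivot_table(index="age", columns="term", values="beta", dropna=False)
        wide_se = g.pivot_table(index="age", columns="term", values="se", dropna=False)
        counts = g.drop_duplicates("age").set_index("age")[["n_at_risk", "n_events"]]
        ages = wide_beta.index.to_numpy(dtype=float)
        if not np.any(np.isfinite(wide_se[INTERCEPT].to_numpy(dtype=float))):
            unavailable.append((f, t))
            logger.warning("transition %s->%s has no fit at any age; marked unavailable", f, t)
            continue
        out = g.copy()
        for term in raw.terms:
            beta = wide_beta[term].to_numpy(dtype=float)
            var = wide_se[term].to_numpy(dtype=float) ** 2
            smoothed = smooth_series(ages, beta, var, config)
            sm_by_age = dict(zip(wide_beta.index, smoothed))
            sel = out["term"] == term
            out.loc[sel, "beta"] = out.loc[sel, "age"].map(sm_by_age)
        out["variant"] = "smoothed"
        out["n_at_risk"] = out["age"].map(counts["n_at_risk"])
        out["n_events"] = out["age"].map(counts["n_events"])
        frames.append(out)
    if not frames:
        raise ValueError("no transition in the table could be smoothed")
    frame = pd.concat(frames, ignore_index=True)
    table = CoefficientTable(frame, variant="smoothed", covariates=raw.covariates)
    table.unavailable = tuple(unavailable)
    return table
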