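"""Propensity scores, standardized-mortality-ratio weights and balance.

The propensity score e(x) = P(exposed | x) comes from a main-effects
logistic model of exposure on all baseline covariates (BMI as its ordinal
category coded with integer scores).  Standardized mortality ratio weighting
(SMRW) targets the treated population (the ATT): exposed members receive
weight 1, controls the propensity odds e/(1 - e), so the weighted control
group mirrors the exposed covariate profile.  Balance is assessed with
standardized differences, reported control-minus-exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

_EPS = 1e-10


def _design_matrix(covariates: pd.DataFrame, columns=None):
    if columns is None:
        columns = [c for c in covariates.columns if c not in ("member_id", "bmi")]
    zero_var = [c for c in columns if covariates[c].nunique(dropna=True) < 2]
    if zero_var:
        logger.info("zero-variance covariates excluded from the propensity model: %s", zero_var)
    columns = [c for c in columns if c not in zero_var]
    X = covariates[columns].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("propensity model requires a complete covariate table")
    return X, columns


def fit_propensity(covariates: pd.DataFrame, exposed, columns=None):
    """Propensity scores from a main-effects logistic model.

    Perfect separation (fitted probabilities collapsing to 0/1) triggers a
    ridge-stabilized refit with a warning; returned scores are strictly
    inside (0, 1).
    """
    exposed = np.asarray(exposed, dtype=int)
    X, used = _design_matrix(covariates, columns)
    model = LogisticRegression(C=np.inf, max_iter=2000)
    model.fit(X, exposed)
    scores = model.predict_proba(X)[:, 1]
    if scores.min() < _EPS or scores.max() > 1 - _EPS or np.abs(model.coef_).max() > 30:
        logger.warning("propensity model near-separated; refitting with ridge stabilization")
        model = LogisticRegression(C=1.0, max_iter=2000)
        model.fit(X, exposed)
        scores = model.predict_proba(X)[:, 1]
    return np.clip(scores, _EPS, 1 - _EPS)


def compute_smrw(scores, exposed) -> np.ndarray:
    """SMRW weights: 1 for exposed, propensity odds e/(1-e) for controls."""
    scores = np.asarray(scores, dtype=float)
    if (scores <= 0).any() or (scores >= 1).any():
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    exposed = np.asarray(exposed, dtype=bool)
    return np.where(exposed, 1.0, scores / (1.0 - scores))


def truncate_weights(weights, exposed, percentile=99.0) -> np.ndarray:
    """Optional percentile truncation of control weights for extreme scores."""
    weights = np.asarray(weights, dtype=float).copy()
    ctl = ~np.asarray(exposed, dtype=bool)
    if ctl.any():
        cap = np.percentile(weights[ctl], percentile)
        weights[ctl] = np.minimum(weights[ctl], cap)
    return weights


def standardized_difference(values, exposed, weights=None, binary=None) -> float:
    """Standardized difference, control minus exposed.

    Continuous: (m0 - m1) / sqrt((s1^2 + s0^2) / 2) with (weighted) means and
    variances; binary: (p0 - p1) / sqrt((p1(1-p1) + p0(1-p0)) / 2).  Rows
    with missing values are dropped (pre-imputation diagnostics).
    """
    values = np.asarray(values, dtype=float)
    exposed = np.asarray(exposed, dtype=bool)
    weights = np.ones(len(values)) if weights is None else np.asarray(weights, dtype=float)
    keep = ~np.isnan(values)
    values, exposed, weights = values[keep], exposed[keep], weights[keep]
    if not exposed.any() or exposed.all():
        raise ValueError("both groups must be non-empty")
    if binary is None:
        binary = set(np.unique(values)) <= {0.0, 1.0}

    def moments(mask):
        w = weights[mask]
        v = values[mask]
        mean = np.average(v, weights=w)
        var = np.average((v - mean) ** 2, weights=w)
        return mean, var

    m1, v1 = moments(exposed)
    m0, v0 = moments(~exposed)
    if binary:
        v1, v0 = m1 * (1 - m1), m0 * (1 - m0)
    denom = np.sqrt((v1 + v0) / 2.0)
    if denom == 0:
        if m1 == m0:
            return 0.0
        raise ValueError("zero pooled variance with unequal means: degenerate covariate")
    return float((m0 - m1) / denom)


@dataclass
class PropensityWeighter:
    """sklearn-style estimator bundling propensity fit and SMRW.

    ``fit(covariates, exposed)`` populates ``propensity_``, ``weights_`` and
    ``columns_`` (covariates actually used by the model).
    """

    truncate_percentile: float | None = None

    def get_params(self, deep=True):
        return {"truncate_percentile": self.truncate_percentile}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, covariates: pd.DataFrame, exposed):
        exposed = np.asarray(exposed, dtype=bool)
        _, self.columns_ = _design_matrix(covariates)
        self.propensity_ = fit_propensity(covariates, exposed, self.columns_)
        weights = compute_smrw(self.propensity_, exposed)
        if self.truncate_percentile is not None:
            weights = truncate_weights(weights, exposed, self.truncate_percentile)
        self.weights_ = weights
        return self


def balance_table(raw_covariates, stack, weights_per_imputation, exposed) -> pd.DataFrame:
    """Per-covariate unweighted StdDiff plus min/max weighted StdDiff across
    imputations (the Table-2-style balance diagnostic)."""
    exposed = np.asarray(exposed, dtype=bool)
    if len(stack.tables) != len(weights_per_imputation):
        raise ValueError("one weight vector per imputation is required")
    columns = [c for c in stack.tables[0].columns if c not in ("member_id", "bmi")]
    rows = []
    for col in columns:
        if raw_covariates[col].nunique(dropna=True) < 2:
            continue
        unweighted = standardized_difference(raw_covariates[col], exposed)
        weighted = [
            standardized_difference(table[col], exposed, weights=w)
            for table, w in zip(stack.tables, weights_per_imputation)
        ]
        rows.append(
            {
                "covariate": col,
                "stddiff_unweighted": unweighted,
                "stddiff_weighted_min": min(weighted),
                "stddiff_weighted_max": max(weighted),
                "abs_weighted_max": max(abs(v) for v in weighted),
            }
        )
    return pd.DataFrame(rows)
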