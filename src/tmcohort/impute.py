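"""Fully conditional specification (FCS) multiple imputation and Rubin's rules.

Missingness in this design is restricted to the BMI category (ordinal, six
levels) and smoking status (binary).  Each FCS sweep refits, per incomplete
variable, a statsmodels component model on the originally observed rows —
logistic regression for binary targets, proportional-odds ordinal logistic
for ordinal targets — draws a parameter vector from the approximate
posterior N(beta_hat, cov_hat), and samples the missing cells from the
implied predictive distribution.  Predictors are all other covariates plus
the event indicator and log follow-up time; zero-variance predictors are
dropped before fitting (mirroring covariates that never occur).  Component
models that fail to converge fall back to a ridge-stabilized fit with a
warning; as a last resort a variable is drawn from its observed margin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

logger = logging.getLogger(__name__)


@dataclass
class ImputationModelSpec:
    """Configuration of the FCS imputation."""

    m: int = 20
    n_cycles: int = 10
    binary_targets: tuple[str, ...] = ("smoking",)
    ordinal_targets: tuple[str, ...] = ("bmi_category",)
    exclude: tuple[str, ...] = ("member_id", "bmi")  # identifiers / raw duplicates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("number of imputations m must be >= 2")


@dataclass
class ImputedStack:
    """m completed covariate tables plus bookkeeping."""

    tables: list
    dropped_predictors: list = field(default_factory=list)
    seeds: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tables)


def _posterior_draw(rng, params, cov):
    try:
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(params)))
    except np.linalg.LinAlgError:
        chol = np.diag(np.sqrt(np.maximum(np.diag(cov), 1e-10)))
    return params + chol @ rng.standard_normal(len(params))


def _fit_logistic(y, X, ridge=False):
    if ridge:
        # ridge-stabilized: quadratic penalty keeps the information matrix
        # invertible under separation
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit_regularized(alpha=1.0, L1_wt=0.0)
        params = np.asarray(res.params)
        mu = expit(X @ params)
        w = np.clip(mu * (1 - mu), 1e-6, None)
        info = (X * w[:, None]).T @ X + np.eye(X.shape[1])
        cov = np.linalg.inv(info)
        return params, cov
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(cov)) and np.abs(params).max() < 30):
        raise np.linalg.LinAlgError("unstable logistic fit")
    return params, cov


def _impute_binary(rng, y, X, miss):
    obs = ~miss
    if y[obs].nunique() < 2:
        p = float(y[obs].mean()) if obs.any() else 0.5
        return (rng.random(miss.sum()) < p).astype(float)
    Xo = X[obs.to_numpy()]
    try:
        params, cov = _fit_logistic(y[obs].to_numpy(dtype=float), Xo)
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("logistic component model unstable; ridge fallback")
        params, cov = _fit_logistic(y[obs].to_numpy(dtype=float), Xo, ridge=True)
    beta = _posterior_draw(rng, params, cov)
    p = expit(X[miss.to_numpy()] @ beta)
    return (rng.random(miss.sum()) < p).astype(float)


def _impute_ordinal(rng, y, X, miss):
    obs = ~miss
    yo = y[obs]
    levels = np.sort(yo.unique())
    if len(levels) < 2:
        only = levels[0] if len(levels) else 0.0
        return np.full(miss.sum(), float(only))
    # drop the intercept column: OrderedModel parameterizes thresholds itself
    Xo = X[obs.to_numpy()][:, 1:]
    Xm = X[miss.to_numpy()][:, 1:]
    code = pd.Categorical(yo, categories=levels, ordered=True).codes.astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(code, Xo, distr="logit")
            res = model.fit(method="lbfgs", maxiter=200, disp=False)
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if not (np.all(np.isfinite(params)) and np.all(np.isfinite(cov))):
            raise np.linalg.LinAlgError("unstable ordinal fit")
        beta = _posterior_draw(rng, params, cov)
        k = Xo.shape[1]
        slope, thresh_raw = beta[:k], beta[k:]
        # statsmodels transform: first threshold free, the rest exp-increments
        thresh = np.cumsum(np.concatenate([[thresh_raw[0]], np.exp(thresh_raw[1:])]))
        eta = Xm @ slope
        cum = expit(thresh[None, :] - eta[:, None])  # P(Y <= level_j | x)
        cum = np.hstack([cum, np.ones((len(eta), 1))])
        probs = np.diff(np.hstack([np.zeros((len(eta), 1)), cum]), axis=1)
        probs = np.clip(probs, 0, None)
        probs /= probs.sum(axis=1, keepdims=True)
        draws = (rng.random(len(eta))[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        return levels[np.minimum(draws, len(levels) - 1)].astype(float)
    except (np.linalg.LinAlgError, ValueError, RuntimeError):
        logger.warning("ordinal component model unstable; drawing from the observed margin")
        freq = yo.value_counts(normalize=True).sort_index()
        return rng.choice(freq.index.to_numpy(dtype=float), size=miss.sum(), p=freq.to_numpy())


class FCSImputer:
    """Chained-equation imputer for cohort covariate tables.

    sklearn-style estimator: ``fit(covariates, followups)`` populates
    ``imputations_`` (list of m completed tables), ``dropped_predictors_``
    and ``seeds_``.
    """

    def __init__(self, m=20, n_cycles=10, binary_targets=("smoking",),
                 ordinal_targets=("bmi_category",), exclude=("member_id", "bmi"), seed=0):
        self.m = m
        self.n_cycles = n_cycles
        self.binary_targets = tuple(binary_targets)
        self.ordinal_targets = tuple(ordinal_targets)
        self.exclude = tuple(exclude)
        self.seed = seed

    def get_params(self, deep=True):
        return {
            "m": self.m,
            "n_cycles": self.n_cycles,
            "binary_targets": self.binary_targets,
            "ordinal_targets": self.ordinal_targets,
            "exclude": self.exclude,
            "seed": self.seed,
        }

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, covariates: pd.DataFrame, followups: pd.DataFrame | None = None):
        """Run m independent FCS chains; missing cells must be confined to
        the declared binary/ordinal targets."""
        spec = ImputationModelSpec(
            m=self.m,
            n_cycles=self.n_cycles,
            binary_targets=self.binary_targets,
            ordinal_targets=self.ordinal_targets,
            exclude=self.exclude,
            seed=self.seed,
        )
        data = covariates.reset_index(drop=True).copy()
        targets = [c for c in (*spec.ordinal_targets, *spec.binary_targets) if c in data]
        stray = [
            c
            for c in data.columns
            if c not in targets and c not in spec.exclude and data[c].isna().any()
        ]
        if stray:
            raise ValueError(f"missingness outside the declared targets: {stray}")

        predictors = [c for c in data.columns if c not in spec.exclude and c not in targets]
        if followups is not None:
            fu = followups.reset_index(drop=True)
            data["_event"] = fu["event"].to_numpy(dtype=float)
            days = (fu["end"] - fu["start"]).to_numpy(dtype=float)
            data["_log_followup"] = np.log1p(days)
            predictors += ["_event", "_log_followup"]

        dropped = [c for c in predictors if data[c].nunique(dropna=True) < 2]
        if dropped:
            logger.info("zero-variance predictors excluded from the imputation model: %s", dropped)
        predictors = [c for c in predictors if c not in dropped]

        miss = {t: data[t].isna() for t in targets}
        root = np.random.SeedSequence(spec.seed)
        children = root.spawn(spec.m)
        tables, seeds = [], []
        for child in children:
            rng = np.random.default_rng(child)
            seeds.append(child.entropy)
            work = data.copy()
            # initialize by random draws from the observed margin
            for t in targets:
                obs_vals = work.loc[~miss[t], t].to_numpy(dtype=float)
                if miss[t].any() and len(obs_vals):
                    work.loc[miss[t], t] = rng.choice(obs_vals, size=miss[t].sum())
                elif miss[t].any():
                    work.loc[miss[t], t] = 0.0
            n_cycles = spec.n_cycles if any(m.any() for m in miss.values()) else 0
            for _ in range(n_cycles):
                for t in targets:
                    if not miss[t].any():
                        continue
                    others = [o for o in targets if o != t]
                    cols = predictors + others
                    X = np.column_stack(
                        [np.ones(len(work))] + [work[c].to_numpy(dtype=float) for c in cols]
                    )
                    if t in spec.binary_targets:
                        work.loc[miss[t], t] = _impute_binary(rng, data[t], X, miss[t])
                    else:
                        work.loc[miss[t], t] = _impute_ordinal(rng, data[t], X, miss[t])
            tables.append(work[covariates.columns.tolist()] if followups is not None else work)
        self.imputations_ = tables
        self.dropped_predictors_ = dropped
        self.seeds_ = seeds
        return self

    def fit_transform(self, covariates, followups=None) -> ImputedStack:
        self.fit(covariates, followups)
        return ImputedStack(self.imputations_, self.dropped_predictors_, self.seeds_)


def fcs_impute(covariates, followups, spec: ImputationModelSpec | None = None) -> ImputedStack:
    """Functional wrapper over :class:`FCSImputer`."""
    spec = spec or ImputationModelSpec()
    imputer = FCSImputer(
        m=spec.m,
        n_cycles=spec.n_cycles,
        binary_targets=spec.binary_targets,
        ordinal_targets=spec.ordinal_targets,
        exclude=spec.exclude,
        seed=spec.seed,
    )
    return imputer.fit_transform(covariates, followups)


def rubin_pool(estimates, variances, alpha=0.05):
    """Pool point estimates and variances across imputations by Rubin's rules.

    Returns a dict with the pooled estimate, within/between/total variance,
    degrees of freedom and the (1 - alpha) confidence interval.  Total
    variance T = W + (1 + 1/m) B with W the mean within-imputation variance
    and B the between-imputation sample variance.
    """
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if estimates.shape != variances.shape or estimates.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-d sequences")
    m = len(estimates)
    if m < 2:
        raise ValueError("Rubin pooling requires m >= 2 imputations")
    pooled = float(estimates.mean())
    w = float(variances.mean())
    b = float(estimates.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        q = stats.t.ppf(1 - alpha / 2, df)
    else:
        df = np.inf
        q = stats.norm.ppf(1 - alpha / 2)
    half = q * np.sqrt(t)
    return {
        "estimate": pooled,
        "within_variance": w,
        "between_variance": b,
        "total_variance": t,
        "df": float(df),
        "ci_lower": pooled - half,
        "ci_upper": pooled + half,
    }
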