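"""Weighted Cox proportional hazards, weighted Kaplan-Meier, Rubin pooling.

The hazard-ratio estimate is a weighted Cox partial-likelihood fit with
exposure as the sole covariate: covariate adjustment is carried entirely by
the standardized-mortality-ratio weights.  Ties are handled by the Breslow
approximation by default (Efron available); the reported confidence interval
uses a robust (sandwich) variance built from weighted score residuals, since
weighting invalidates the naive information-based variance.  The
one-parameter maximizer is implemented here directly — Newton iteration on
the weighted partial likelihood — which keeps the ties method and the
weighted sandwich explicit; an external implementation serves as a
cross-check in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .impute import rubin_pool

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoxFit:
    log_hr: float
    var_model: float
    var_robust: float
    ties: str
    n_events: int
    n_members: int
    analysis: str = ""

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    def ci(self, alpha=0.05, robust=True):
        se = np.sqrt(self.var_robust if robust else self.var_model)
        q = stats.norm.ppf(1 - alpha / 2)
        return float(np.exp(self.log_hr - q * se)), float(np.exp(self.log_hr + q * se))


@dataclass(frozen=True)
class PooledHazardResult:
    log_hr: float
    total_variance: float
    hr: float
    ci_lower: float
    ci_upper: float
    m: int
    analysis: str = ""


def _partial_likelihood_parts(beta, t, d, x, w, ties):
    """Weighted partial log-likelihood, score and information at beta."""
    order = np.argsort(t, kind="stable")
    t, d, x, w = t[order], d[order], x[order], w[order]
    r = w * np.exp(beta * x)
    rx = r * x
    rxx = rx * x
    # suffix sums over the risk set {j : t_j >= t}
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum(rx[::-1])[::-1]
    s2 = np.cumsum(rxx[::-1])[::-1]
    # first position of each unique time
    first = np.zeros(len(t), dtype=np.int64)
    new = np.concatenate([[True], t[1:] != t[:-1]])
    first[new] = np.nonzero(new)[0]
    first = np.maximum.accumulate(first)

    loglik = score = info = 0.0
    ev = np.nonzero(d > 0)[0]
    if ties == "breslow":
        S0, S1, S2 = s0[first[ev]], s1[first[ev]], s2[first[ev]]
        wi = w[ev]
        loglik = float(np.sum(wi * beta * x[ev] - wi * np.log(S0)))
        score = float(np.sum(wi * (x[ev] - S1 / S0)))
        info = float(np.sum(wi * (S2 / S0 - (S1 / S0) ** 2)))
        return loglik, score, info, (t, d, x, w, s0, s1, first)
    if ties != "efron":
        raise ValueError("ties must be 'breslow' or 'efron'")
    # Efron: group tied events
    ev_times, inverse = np.unique(t[ev], return_inverse=True)
    for k, te in enumerate(ev_times):
        members = ev[inverse == k]
        dk = len(members)
        wk = w[members]
        ws = wk.sum()
        pos = first[members[0]]
        S0, S1, S2 = s0[pos], s1[pos], s2[pos]
        rD = np.sum(w[members] * np.exp(beta * x[members]))
        r1D = np.sum(w[members] * np.exp(beta * x[members]) * x[members])
        r2D = np.sum(w[members] * np.exp(beta * x[members]) * x[members] ** 2)
        loglik += float(np.sum(wk * beta * x[members]))
        for ell in range(dk):
            phi = ell / dk
            s0l = S0 - phi * rD
            s1l = S1 - phi * r1D
            s2l = S2 - phi * r2D
            loglik -= (ws / dk) * np.log(s0l)
            info += (ws / dk) * (s2l / s0l - (s1l / s0l) ** 2)
        score += float(np.sum(wk * x[members])) - sum(
            (ws / dk) * ((S1 - (ell / dk) * r1D) / (S0 - (ell / dk) * rD)) for ell in range(dk)
        )
    return loglik, score, info, (t, d, x, w, s0, s1, first)


def _robust_variance(beta, info, sorted_parts):
    """Sandwich variance from weighted score residuals (Breslow form)."""
    t, d, x, w, s0, s1, first = sorted_parts
    ev = np.nonzero(d > 0)[0]
    if not len(ev):
        return np.nan
    xbar_all = s1 / s0
    # weighted event mass per unique event time
    ev_pos = first[ev]
    wd = np.zeros(len(t))
    np.add.at(wd, ev_pos, w[ev])
    inc0 = np.where(wd > 0, wd / s0, 0.0)
    inc1 = np.where(wd > 0, wd * xbar_all / s0, 0.0)
    c0 = np.cumsum(inc0)
    c1 = np.cumsum(inc1)
    # value at each subject's own (possibly tied) time position
    pos_self = first.copy()
    # cumulative through the subject's time = value at the LAST index of its tie group
    last = np.zeros(len(t), dtype=np.int64)
    new = np.concatenate([t[1:] != t[:-1], [True]])
    last_idx = np.nonzero(new)[0]
    prev = -1
    for li in last_idx:
        last[prev + 1 : li + 1] = li
        prev = li
    C0 = c0[last]
    C1 = c1[last]
    u = d * (x - xbar_all[pos_self]) - np.exp(beta * x) * (x * C0 - C1)
    meat = float(np.sum((w * u) ** 2))
    return meat / info**2 if info > 0 else np.nan


def weighted_cox(
    followups: pd.DataFrame,
    exposed,
    weights=None,
    ties_method: str = "breslow",
    analysis: str | None = None,
) -> CoxFit:
    """Weighted Cox fit with exposure as the sole covariate.

    ``followups`` needs columns start/end/event; duration = end - start in
    days.  Raises when there are no events; warns and reports a bounded
    estimate under a monotone likelihood (all events in one group).
    """
    if not len(followups):
        raise ValueError("no follow-up records")
    t = (followups["end"] - followups["start"]).to_numpy(dtype=float)
    d = followups["event"].to_numpy(dtype=float)
    x = np.asarray(exposed, dtype=float)
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("hazard ratio inestimable: no events")

    beta = 0.0
    bounded = False
    for _ in range(60):
        _, score, info, parts = _partial_likelihood_parts(beta, t, d, x, w, ties_method)
        if info <= 0:
            break
        step = np.clip(score / info, -2.0, 2.0)
        beta += step
        if abs(beta) > 15.0:
            bounded = True
            beta = float(np.sign(beta) * 15.0)
            break
        if abs(step) < 1e-12:
            break
    if bounded or (d[x == 1].sum() == 0 or d[x == 0].sum() == 0):
        logger.warning(
            "monotone partial likelihood (all events in one group); estimate bounded"
        )
    _, _, info, parts = _partial_likelihood_parts(beta, t, d, x, w, ties_method)
    var_model = 1.0 / info if info > 0 else np.nan
    var_robust = _robust_variance(beta, info, parts)
    if analysis is None:
        analysis = str(followups["analysis"].iloc[0]) if "analysis" in followups.columns else ""
    return CoxFit(
        log_hr=float(beta),
        var_model=float(var_model),
        var_robust=float(var_robust),
        ties=ties_method,
        n_events=n_events,
        n_members=len(t),
        analysis=analysis,
    )


def weighted_km(followups: pd.DataFrame, exposed, weights=None) -> pd.DataFrame:
    """Weighted product-limit survival curves per group.

    Returns long-format (group, time, survival) pairs; unit weights reduce to
    the classical Kaplan-Meier estimator.
    """
    if not len(followups):
        raise ValueError("no follow-up records")
    t = (followups["end"] - followups["start"]).to_numpy(dtype=float)
    d = followups["event"].to_numpy(dtype=float)
    exposed = np.asarray(exposed, dtype=bool)
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=float)
    frames = []
    for label, mask in (("exposed", exposed), ("control", ~exposed)):
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=d[mask], weights=w[mask])
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {"group": label, "time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)


def km_discrepancy(curves: list[pd.DataFrame]) -> float:
    """Max sup-difference between survival curves across imputations,
    evaluated per group on the union time grid (step interpolation)."""
    worst = 0.0
    for group in ("exposed", "control"):
        series = []
        for frame in curves:
            sub = frame[frame["group"] == group]
            if len(sub):
                series.append(sub.set_index("time")["survival"])
        if len(series) < 2:
            continue
        grid = np.unique(np.concatenate([s.index.to_numpy() for s in series]))
        vals = np.column_stack([s.reindex(grid).ffill().fillna(1.0).to_numpy() for s in series])
        worst = max(worst, float((vals.max(axis=1) - vals.min(axis=1)).max()))
    return worst


def pool_across_imputations(fits: list[CoxFit]) -> PooledHazardResult:
    """Rubin pooling of per-imputation weighted Cox fits (robust variances)."""
    if not fits:
        raise ValueError("no fits to pool")
    labels = {f.analysis for f in fits}
    if len(labels) > 1:
        raise ValueError(f"inconsistent analysis labels across fits: {sorted(labels)}")
    pooled = rubin_pool([f.log_hr for f in fits], [f.var_robust for f in fits])
    return PooledHazardResult(
        log_hr=pooled["estimate"],
        total_variance=pooled["total_variance"],
        hr=float(np.exp(pooled["estimate"])),
        ci_lower=float(np.exp(pooled["ci_lower"])),
        ci_upper=float(np.exp(pooled["ci_upper"])),
        m=len(fits),
        analysis=fits[0].analysis,
    )


def subgroup_analysis(
    followups: pd.DataFrame,
    tables: list[pd.DataFrame],
    weights_per_imputation: list[np.ndarray],
    exposed,
    covariate: str,
    levels=None,
):
    """Per-level pooled hazard ratios for a baseline-covariate subgroup.

    Weights are reused from the full-cohort propensity fit (no per-subgroup
    refit).  Subgroup membership may vary across imputations when the
    defining covariate was imputed.  Levels with no events in some
    imputation are flagged inestimable rather than dropped silently.
    """
    exposed = np.asarray(exposed, dtype=bool)
    if levels is None:
        levels = sorted(pd.unique(pd.concat([t[covariate] for t in tables]).dropna()))
    results = {}
    for level in levels:
        fits = []
        estimable = True
        for table, w in zip(tables, weights_per_imputation):
            mask = (table[covariate].to_numpy() == level)
            if not mask.any():
                raise ValueError(f"subgroup level {level!r} is empty")
            sub = followups[mask]
            if sub["event"].sum() == 0 or not (exposed[mask].any() and (~exposed[mask]).any()):
                estimable = False
                break
            try:
                fits.append(
                    weighted_cox(sub, exposed[mask], weights=w[mask], analysis="subgroup")
                )
            except ValueError:
                estimable = False
                break
        if not estimable:
            results[level] = "inestimable"
        elif len(fits) == 1:
            f = fits[0]
            lo, hi = f.ci()
            results[level] = PooledHazardResult(
                f.log_hr, f.var_robust, f.hr, lo, hi, 1, "subgroup"
            )
        else:
            results[level] = pool_across_imputations(fits)
    return results


def forest_table(results: dict) -> pd.DataFrame:
    """Forest-plot-style summary table.

    ``results`` maps a scenario label to a dict with keys events,
    person_years, rate_per_100py and a :class:`PooledHazardResult` under
    'pooled'.
    """
    if not results:
        raise ValueError("no results to tabulate")
    rows = []
    for label, res in results.items():
        pooled = res["pooled"]
        rows.append(
            {
                "analysis": label,
                "events_exposed": res.get("events_exposed"),
                "events_control": res.get("events_control"),
                "person_years_exposed": res.get("person_years_exposed"),
                "person_years_control": res.get("person_years_control"),
                "rate_exposed_per_100py": res.get("rate_exposed_per_100py"),
                "rate_control_per_100py": res.get("rate_control_per_100py"),
                "hr": pooled.hr,
                "ci_lower": pooled.ci_lower,
                "ci_upper": pooled.ci_upper,
            }
        )
    return pd.DataFrame(rows)
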