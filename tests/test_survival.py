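"""Weighted Cox against independent oracles; KM, pooling, subgroups."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter

from tmcohort import (
    forest_table,
    km_discrepancy,
    pool_across_imputations,
    rubin_pool,
    subgroup_analysis,
    weighted_cox,
    weighted_km,
)
from tmcohort.survival import CoxFit, PooledHazardResult


def _toy_followups():
    """Ten records, three events, no ties; exposure is the sole covariate."""
    return (
        pd.DataFrame(
            {
                "start": 0,
                "end": [5, 8, 11, 14, 17, 20, 23, 26, 29, 32],
                "event": [True, False, True, False, False, True, False, False, False, False],
            }
        ),
        np.array([1, 0, 1, 1, 0, 0, 0, 1, 0, 1]),
    )


def _grid_search_breslow(t, d, x, w, lo=-4, hi=4):
    """Independent oracle: directly maximize the weighted Breslow partial
    likelihood over a refined grid."""

    def loglik(beta):
        ll = 0.0
        for i in range(len(t)):
            if d[i]:
                risk = t >= t[i]
                s0 = np.sum(w[risk] * np.exp(beta * x[risk]))
                ll += w[i] * (beta * x[i] - np.log(s0))
        return ll

    grid = np.linspace(lo, hi, 2001)
    best = grid[np.argmax([loglik(b) for b in grid])]
    for _ in range(8):
        lo, hi = best - (hi - lo) / 100, best + (hi - lo) / 100
        grid = np.linspace(lo, hi, 201)
        best = grid[np.argmax([loglik(b) for b in grid])]
    return best


class TestWeightedCox:
    def test_unit_weight_fit_matches_grid_search_oracle(self):
        fu, x = _toy_followups()
        fit = weighted_cox(fu, x)
        t = (fu["end"] - fu["start"]).to_numpy(dtype=float)
        oracle = _grid_search_breslow(t, fu["event"].to_numpy(), x, np.ones(len(x)))
        assert fit.log_hr == pytest.approx(oracle, abs=1e-6)

    def test_weighted_fit_matches_grid_search_oracle(self):
        fu, x = _toy_followups()
        w = np.array([1.0, 0.5, 2.0, 1.0, 0.3, 1.5, 1.0, 0.7, 1.2, 0.4])
        fit = weighted_cox(fu, x, weights=w)
        t = (fu["end"] - fu["start"]).to_numpy(dtype=float)
        oracle = _grid_search_breslow(t, fu["event"].to_numpy(), x, w)
        assert fit.log_hr == pytest.approx(oracle, abs=1e-6)

    def test_matches_lifelines_without_ties(self):
        """Dual-route check: with unit weights and no ties, Breslow and Efron
        coincide and the estimate and robust variance must agree with the
        external implementation."""
        fu, x = _toy_followups()
        fit = weighted_cox(fu, x)
        frame = pd.DataFrame(
            {"t": (fu["end"] - fu["start"]), "e": fu["event"].astype(int), "x": x}
        )
        cph = CoxPHFitter()
        cph.fit(frame, duration_col="t", event_col="e", robust=True)
        assert fit.log_hr == pytest.approx(cph.params_["x"], abs=1e-5)
        assert np.sqrt(fit.var_robust) == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_efron_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(0)
        n = 120
        x = rng.integers(0, 2, n).astype(float)
        t = rng.integers(1, 15, n).astype(float)  # heavy ties
        e = rng.random(n) < 0.5
        fu = pd.DataFrame({"start": 0.0, "end": t, "event": e})
        fit = weighted_cox(fu, x, ties_method="efron")
        frame = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
        cph = CoxPHFitter()
        cph.fit(frame, duration_col="t", event_col="e")
        assert fit.log_hr == pytest.approx(cph.params_["x"], abs=1e-4)
        assert np.sqrt(fit.var_model) == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_symmetric_groups_give_hr_one(self):
        fu = pd.DataFrame(
            {
                "start": 0,
                "end": [10, 20, 30, 40, 10, 20, 30, 40],
                "event": [True, False, True, False] * 2,
            }
        )
        x = np.r_[np.ones(4), np.zeros(4)]
        fit = weighted_cox(fu, x)
        assert fit.log_hr == pytest.approx(0.0, abs=1e-10)

    def test_no_events_inestimable(self):
        fu = pd.DataFrame({"start": [0, 0], "end": [10, 20], "event": [False, False]})
        with pytest.raises(ValueError, match="no events"):
            weighted_cox(fu, np.array([1, 0]))

    def test_monotone_likelihood_bounded_with_warning(self, caplog):
        fu = pd.DataFrame(
            {"start": 0, "end": [5, 6, 30, 40], "event": [True, True, False, False]}
        )
        with caplog.at_level("WARNING", logger="tmcohort.survival"):
            fit = weighted_cox(fu, np.array([1, 1, 0, 0]))
        assert np.isfinite(fit.log_hr) and abs(fit.log_hr) <= 15
        assert any("monotone" in m for m in caplog.messages)

    def test_ci_exp_log_consistency(self):
        fu, x = _toy_followups()
        fit = weighted_cox(fu, x)
        lo, hi = fit.ci()
        se = np.sqrt(fit.var_robust)
        assert np.log(lo) == pytest.approx(fit.log_hr - 1.959963984540054 * se)
        assert np.log(hi) == pytest.approx(fit.log_hr + 1.959963984540054 * se)


class TestWeightedKM:
    def test_no_events_flat_curve(self):
        fu = pd.DataFrame({"start": 0, "end": [10, 20], "event": [False, False]})
        km = weighted_km(fu, np.array([True, False]))
        assert (km["survival"] == 1.0).all()

    def test_unit_weights_match_reference_km(self):
        rng = np.random.default_rng(1)
        t = rng.integers(1, 50, 60).astype(float)
        e = rng.random(60) < 0.6
        fu = pd.DataFrame({"start": 0.0, "end": t, "event": e})
        exposed = np.ones(60, dtype=bool)
        km = weighted_km(fu, exposed)
        ref = KaplanMeierFitter().fit(t, e)
        ours = km.set_index("time")["survival"]
        theirs = ref.survival_function_.iloc[:, 0]
        joined = pd.concat([ours, theirs], axis=1).ffill().dropna()
        assert np.allclose(joined.iloc[:, 0], joined.iloc[:, 1], atol=1e-10)

    def test_smrw_shifts_control_curve_toward_exposed(self, complete_claims):
        """On confounded data the SMRW-weighted control survival curve moves
        toward the exposed curve relative to the unweighted control curve."""
        from tmcohort import StudyDesignConfig, assemble_cohort, default_code_dictionary
        from tmcohort.covariates import extract_covariates_bulk
        from tmcohort.followup import FollowUpBuilder
        from tmcohort.weighting import PropensityWeighter

        config, dataset = complete_claims
        design = StudyDesignConfig(seed=config.seed)
        members, _ = assemble_cohort(dataset, design)
        cov = extract_covariates_bulk(members, dataset, default_code_dictionary(), design)
        exposed = (members["group"] == "exposed").to_numpy()
        w = PropensityWeighter().fit(cov.drop(columns=["bmi"]), exposed).weights_
        fu = FollowUpBuilder(members, dataset, design).itt()
        km_u = weighted_km(fu, exposed)
        km_w = weighted_km(fu, exposed, weights=w)

        def surv_at(km, group, t):
            sub = km[(km["group"] == group) & (km["time"] <= t)]
            return sub["survival"].iloc[-1]

        t = 500
        s_exp = surv_at(km_u, "exposed", t)
        s_ctl = surv_at(km_u, "control", t)
        s_wctl = surv_at(km_w, "control", t)
        assert abs(s_wctl - s_exp) < abs(s_ctl - s_exp)

    def test_discrepancy_zero_for_identical_curves(self):
        fu = pd.DataFrame(
            {"start": 0, "end": [10, 20, 30], "event": [True, False, True]}
        )
        km = weighted_km(fu, np.array([True, True, False]))
        assert km_discrepancy([km, km]) == 0.0


class TestPooling:
    def test_identical_fits_reduce_to_single_fit_ci(self):
        fit = CoxFit(0.2, 0.01, 0.02, "breslow", 30, 100, "ITT")
        pooled = pool_across_imputations([fit, fit, fit])
        lo, hi = fit.ci()
        assert pooled.hr == pytest.approx(fit.hr)
        assert pooled.ci_lower == pytest.approx(lo)
        assert pooled.ci_upper == pytest.approx(hi)

    def test_hand_set_fits_pool_by_rubin_arithmetic(self):
        f1 = CoxFit(0.1, 0.01, 0.04, "breslow", 30, 100, "ITT")
        f2 = CoxFit(0.3, 0.01, 0.02, "breslow", 30, 100, "ITT")
        pooled = pool_across_imputations([f1, f2])
        ref = rubin_pool([0.1, 0.3], [0.04, 0.02])
        assert pooled.log_hr == pytest.approx(ref["estimate"])
        assert pooled.total_variance == pytest.approx(ref["total_variance"])
        assert pooled.ci_lower == pytest.approx(np.exp(ref["ci_lower"]))

    def test_inconsistent_labels_rejected(self):
        f1 = CoxFit(0.1, 0.01, 0.04, "breslow", 30, 100, "ITT")
        f2 = CoxFit(0.3, 0.01, 0.02, "breslow", 30, 100, "PP-0")
        with pytest.raises(ValueError, match="inconsistent"):
            pool_across_imputations([f1, f2])


class TestSubgroupsAndForest:
    def _fixture(self):
        rng = np.random.default_rng(2)
        n = 400
        x = rng.integers(0, 2, n).astype(bool)
        t = rng.exponential(300, n).clip(1, 900)
        e = rng.random(n) < 0.3
        fu = pd.DataFrame({"start": 0.0, "end": t, "event": e, "analysis": "ITT"})
        table = pd.DataFrame({"female": rng.integers(0, 2, n).astype(float)})
        w = np.ones(n)
        return fu, x, table, w

    def test_whole_cohort_subgroup_equals_primary(self):
        fu, x, table, w = self._fixture()
        table["all"] = 1.0
        res = subgroup_analysis(fu, [table], [w], x, "all")
        primary = weighted_cox(fu, x, weights=w)
        assert res[1.0].hr == pytest.approx(primary.hr)

    def test_level_with_no_events_flagged_inestimable(self):
        fu, x, table, w = self._fixture()
        table["odd"] = 0.0
        table.loc[0, "odd"] = 1.0
        fu.loc[0, "event"] = False
        res = subgroup_analysis(fu, [table], [w], x, "odd")
        assert res[1.0] == "inestimable"

    def test_sex_subgroups_both_estimable(self):
        fu, x, table, w = self._fixture()
        res = subgroup_analysis(fu, [table], [w], x, "female")
        assert set(res) == {0.0, 1.0}
        for out in res.values():
            assert isinstance(out, PooledHazardResult)

    def test_forest_table_rows_and_error_path(self):
        pooled = PooledHazardResult(0.0, 0.01, 1.0, 0.8, 1.2, 2, "ITT")
        results = {
            label: {
                "pooled": pooled,
                "events_exposed": 10,
                "events_control": 50,
                "person_years_exposed": 100.0,
                "person_years_control": 500.0,
                "rate_exposed_per_100py": 10.0,
                "rate_control_per_100py": 10.0,
            }
            for label in ("ITT", "PP-0")
        }
        frame = forest_table(results)
        assert list(frame["analysis"]) == ["ITT", "PP-0"]
        with pytest.raises(ValueError, match="no results"):
            forest_table({})
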