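import numpy as np
import pandas as pd
import pytest

from ionsig.survival import (
    ConvergenceError,
    SurvivalError,
    cox_fit,
    encode_covariates,
    kaplan_meier,
    logrank_test,
    stratified_hazards,
)
from ionsig.signature import SignatureModel, median_split, risk_scores
from ionsig.simulate import SimulationConfig, simulate_cohort
from conftest import make_cohort


class TestKaplanMeier:
    def test_all_censored_gives_unit_survival(self):
        curve = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.survival_at(10.0) == 1.0

    def test_two_events_product_limit(self):
        curve = kaplan_meier([1.0, 2.0], [1, 1])
        assert curve.survival_at(1.0) == pytest.approx(0.5)
        assert curve.survival_at(2.0) == pytest.approx(0.0)

    def test_mixed_events_and_censoring_by_hand(self):
        # events at 1 and 3, censored at 2 and 4:
        # S(1) = 3/4, S(3) = 3/4 * (1 - 1/2) = 3/8
        curve = kaplan_meier([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        assert curve.survival_at(1.0) == pytest.approx(3 / 4)
        assert curve.survival_at(3.5) == pytest.approx(3 / 8)
        np.testing.assert_array_equal(curve.at_risk, [4, 2])

    def test_closed_form_product_on_random_fixture(self, rng):
        times = rng.integers(1, 15, size=30).astype(float)
        events = rng.integers(0, 2, size=30)
        curve = kaplan_meier(times, events)
        s = 1.0
        for t, r, d in zip(curve.event_times, curve.at_risk, curve.events):
            s *= 1 - d / r
            assert curve.survival_at(t) == pytest.approx(s, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(SurvivalError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups_give_null(self):
        t, e = [1.0, 2.0, 3.0], [1, 0, 1]
        chi2, p, df = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)
        assert df == 1

    def test_hand_computed_statistic(self):
        # A events at 1,2; B events at 3,4:
        # O_A - E_A = 2 - (1/2 + 1/3) = 7/6; V = 1/4 + 2/9
        chi2, _, _ = logrank_test([1.0, 2.0], [1, 1], [3.0, 4.0], [1, 1])
        expected = (7 / 6) ** 2 / (1 / 4 + 2 / 9)
        assert chi2 == pytest.approx(expected, abs=1e-9)

    def test_label_swap_symmetry(self, rng):
        ta, tb = rng.exponential(5, 20), rng.exponential(3, 25)
        ea, eb = rng.integers(0, 2, 20), np.ones(25, dtype=int)
        assert logrank_test(ta, ea, tb, eb)[0] == pytest.approx(
            logrank_test(tb, eb, ta, ea)[0]
        )

    def test_zero_events_rejected(self):
        with pytest.raises(SurvivalError):
            logrank_test([1.0], [0], [2.0], [0])


def efron_loglik_oracle(betas, times, events, x):
    """Direct textbook Efron partial log-likelihood for one covariate,
    evaluated on a vector of candidate coefficients."""
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    ll = np.zeros_like(betas)
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        deaths = [i for i, (ti, ei) in enumerate(zip(times, events)) if ti == t and ei]
        risk = [i for i, ti in enumerate(times) if ti >= t]
        d = len(deaths)
        exp_bx = np.exp(betas[:, None] * np.asarray(x)[None, :])
        sum_risk = exp_bx[:, risk].sum(axis=1)
        sum_dead = exp_bx[:, deaths].sum(axis=1)
        ll += betas * sum(x[i] for i in deaths)
        for l in range(d):
            ll -= np.log(sum_risk - (l / d) * sum_dead)
    return ll


class TestCoxFit:
    def test_symmetric_groups_give_unit_hazard_ratio(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 0, 1, 1, 0]
        design = pd.DataFrame({"x": [0.0, 0, 0, 1, 1, 1]})
        fit = cox_fit(times, events, design)
        assert fit.summary.loc["x", "coef"] == pytest.approx(0.0, abs=1e-10)
        assert fit.summary.loc["x", "hr"] == pytest.approx(1.0)

    def test_matches_grid_search_of_efron_likelihood(self):
        times = [2.0, 3.0, 3.0, 5.0, 7.0, 9.0]
        events = [1, 1, 1, 0, 1, 0]
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        fit = cox_fit(times, events, pd.DataFrame({"x": x}))
        grid = np.arange(-5.0, 5.0, 1e-4)
        lls = efron_loglik_oracle(grid, times, events, x)
        best = grid[int(np.argmax(lls))]
        assert fit.summary.loc["x", "coef"] == pytest.approx(best, abs=1e-4)

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines import CoxPHFitter

        n = 80
        x1, x2 = rng.normal(size=n), rng.integers(0, 2, n).astype(float)
        times = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x1 - 0.3 * x2)))
        events = (rng.random(n) < 0.8).astype(int)
        fit = cox_fit(times, events, pd.DataFrame({"x1": x1, "x2": x2}))
        df = pd.DataFrame({"t": times, "e": events, "x1": x1, "x2": x2})
        ref = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(
            fit.summary["coef"], ref.params_[["x1", "x2"]], atol=1e-5
        )
        np.testing.assert_allclose(
            fit.summary["se"], ref.standard_errors_[["x1", "x2"]], atol=1e-5
        )

    def test_flipping_binary_coding_reciprocates_hazard_ratio(self):
        times = [2.0, 3.0, 4.0, 5.0, 7.0, 9.0, 11.0, 13.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        x = np.array([1.0, 0, 1, 0, 1, 0, 0, 1])
        a = cox_fit(times, events, pd.DataFrame({"x": x}))
        b = cox_fit(times, events, pd.DataFrame({"x": 1 - x}))
        assert a.summary.loc["x", "hr"] == pytest.approx(
            1 / b.summary.loc["x", "hr"], rel=1e-8
        )
        assert a.summary.loc["x", "ci_low"] == pytest.approx(
            1 / b.summary.loc["x", "ci_high"], rel=1e-6
        )

    def test_efron_equals_breslow_without_ties(self, rng):
        n = 40
        times = rng.permutation(n).astype(float) + 1  # all distinct
        events = rng.integers(0, 2, n)
        events[0] = 1
        x = rng.normal(size=n)
        a = cox_fit(times, events, pd.DataFrame({"x": x}), ties="efron")
        b = cox_fit(times, events, pd.DataFrame({"x": x}), ties="breslow")
        assert a.summary.loc["x", "coef"] == pytest.approx(
            b.summary.loc["x", "coef"], abs=1e-10
        )

    def test_efron_and_breslow_differ_with_ties(self):
        times = [1.0, 1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 1, 1, 1, 1, 0, 1, 0]
        x = pd.DataFrame({"x": [1.0, 1, 0, 1, 0, 0, 1, 0]})
        a = cox_fit(times, events, x, ties="efron")
        b = cox_fit(times, events, x, ties="breslow")
        assert a.summary.loc["x", "coef"] != pytest.approx(
            b.summary.loc["x", "coef"], abs=1e-6
        )

    def test_constant_covariate_rejected(self):
        with pytest.raises(SurvivalError, match="constant"):
            cox_fit([1.0, 2.0], [1, 1], pd.DataFrame({"x": [1.0, 1.0]}))

    def test_complete_separation_names_covariate(self):
        # every x=1 subject dies before any x=0 event: monotone likelihood
        times = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        events = [1, 1, 1, 1, 1, 1]
        design = pd.DataFrame({"sep": [1.0, 1, 1, 0, 0, 0]})
        with pytest.raises(ConvergenceError, match="sep"):
            cox_fit(times, events, design)

    def test_zero_events_rejected(self):
        with pytest.raises(SurvivalError):
            cox_fit([1.0, 2.0], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))


class TestEncodeCovariates:
    def _clinical(self):
        return make_cohort(
            np.zeros((1, 4)), ["A"], ["S0", "S1", "S2", "S3"],
            clinical={
                "grade": [2.0, 3.0, 1.0, 3.0],
                "age_years": [45.0, 61.0, 50.0, 70.0],
                "er_status": ["positive", "negative", "positive", "positive"],
                "pr_status": ["positive", None, "negative", "positive"],
                "node_status": ["negative"] * 4,
                "size_class": ["lt_T3", "ge_T3", "lt_T3", "ge_T3"],
                "time": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 0, 1],
            },
        ).clinical

    def _labels(self):
        return pd.Series(["positive", "negative", "negative", "positive"],
                         index=["S0", "S1", "S2", "S3"])

    def test_contrast_codings(self):
        design = encode_covariates(self._clinical(), self._labels(),
                                   covariates=("ic30", "grade3", "er", "size"))
        assert list(design["grade3"]) == [0.0, 1.0, 0.0, 1.0]
        assert list(design["ic30"]) == [1.0, 0.0, 0.0, 1.0]
        assert list(design["er"]) == [1.0, 0.0, 1.0, 1.0]
        assert list(design["size"]) == [0.0, 1.0, 0.0, 1.0]

    def test_unknown_pr_dropped_listwise(self):
        design = encode_covariates(self._clinical(), self._labels(),
                                   covariates=("ic30", "pr"))
        assert list(design.index) == ["S0", "S2", "S3"]

    def test_entirely_unknown_covariate_rejected(self):
        clin = self._clinical().copy()
        clin["p53_status"] = pd.NA
        with pytest.raises(SurvivalError):
            encode_covariates(clin, self._labels(), covariates=("ic30", "p53"))


@pytest.fixture(scope="module")
def scored_cohort():
    cohort, _ = simulate_cohort(SimulationConfig(seed=5, n_samples=200), "S")
    scored = median_split(risk_scores(SignatureModel.ic30(), cohort))
    return cohort, scored.labels


class TestStratifiedHazards:

    def test_whole_cohort_stratum_equals_univariate_fit(self, scored_cohort):
        cohort, labels = scored_cohort
        table = stratified_hazards(
            cohort, labels, stratifiers={"all": [("all", lambda c: c["grade"] > 0)]}
        )
        clin = cohort.clinical
        design = pd.DataFrame({"ic30": (labels == "positive").astype(float)})
        ref = cox_fit(clin["time"], clin["event"], design)
        assert table.loc[0, "hr"] == pytest.approx(ref.summary.loc["ic30", "hr"])

    def test_standard_six_factors_produce_rows(self, scored_cohort):
        cohort, labels = scored_cohort
        table = stratified_hazards(cohort, labels)
        assert set(table["factor"]) == {"age", "node", "size", "grade", "er", "pr"}
        assert (table["hr"] > 0).all()

    def test_stratum_without_events_skipped(self, scored_cohort, caplog):
        cohort, labels = scored_cohort
        strat = {"odd": [("no-such-grade", lambda c: c["grade"] > 5)]}
        with caplog.at_level("WARNING", logger="ionsig"):
            table = stratified_hazards(cohort, labels, stratifiers=strat)
        assert table.empty and "skipped" in caplog.text

    def test_effect_confined_to_er_positive_stratum(self, rng):
        # hazard depends on the label only among ER-positive samples
        n = 400
        er = np.where(rng.random(n) < 0.5, "positive", "negative")
        label = pd.Series(np.where(rng.random(n) < 0.5, "positive", "negative"),
                          index=[f"S{j}" for j in range(n)])
        rate = 0.1 * np.exp(np.log(3.0) * ((label == "positive") & (er == "positive")))
        times = rng.exponential(1 / rate)
        cohort = make_cohort(
            rng.normal(size=(1, n)), ["A"], list(label.index),
            clinical={"er_status": er, "time": times, "event": np.ones(n, dtype=int)},
        )
        table = stratified_hazards(
            cohort, label,
            stratifiers={"er": [("ER negative", lambda c: c["er_status"] == "negative"),
                                ("ER positive", lambda c: c["er_status"] == "positive")]},
        ).set_index("stratum")
        assert table.loc["ER positive", "hr"] > table.loc["ER negative", "hr"]
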