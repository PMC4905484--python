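"""Dichotomization, Kaplan-Meier, log-rank and Cox regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from plasmir.errors import DataError, DesignError, FitError, GroupError
from plasmir.io import SampleTable
from plasmir.survival import (
    breslow_partial_loglik,
    build_design,
    cox_fit,
    dichotomize_by_mean,
    km_curve,
    logrank,
)


class TestDichotomize:
    @pytest.mark.parametrize(
        "levels,expected",
        [
            ([1.0, 3.0], ["low", "high"]),
            ([0.0, 1.0, 5.0], ["low", "low", "high"]),
        ],
    )
    def test_mean_split(self, levels, expected):
        assert list(dichotomize_by_mean(levels)) == expected

    def test_boundary_value_goes_low_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = dichotomize_by_mean([2.0, 2.0, 2.0])
        assert list(labels) == ["low", "low", "low"]

    def test_nonfinite_levels_rejected(self):
        with pytest.raises(DataError):
            dichotomize_by_mean([1.0, np.nan, 2.0])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_curve([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(curve.at_risk, [3, 2, 1])

    def test_product_limit_with_censoring(self):
        # event at 1 (3 at risk), censored at 2, event at 3 (1 at risk)
        curve = km_curve([1, 2, 3], [1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2.5) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        curve = km_curve([5, 7, 9], [0, 0, 0])
        np.testing.assert_allclose(curve.survival, 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            km_curve([], [])

    def test_no_censoring_equals_empirical_on_random_data(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 60).round(1)
        curve = km_curve(times, np.ones(60, int))
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx((times > t).mean())


class TestLogrank:
    def test_hand_computed_hypergeometric_terms(self):
        # groups {1,2} vs {3,4}, all events: O_A=2, E_A=5/6, Var=17/36
        res = logrank([1, 2, 3, 4], [1, 1, 1, 1], ["a", "a", "b", "b"])
        assert res.chi_square == pytest.approx(49 / 17, abs=1e-6)

    def test_identical_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 0, 1, 1, 1, 0, 1, 1]
        res = logrank(times, events, ["a"] * 4 + ["b"] * 4)
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)

    def test_group_relabeling_is_immaterial(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        labels = np.array(["a"] * 20 + ["b"] * 20)
        r1 = logrank(times, events, labels)
        r2 = logrank(times, events, np.where(labels == "a", "b", "a"))
        assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-10)

    def test_one_group_rejected(self):
        with pytest.raises(GroupError):
            logrank([1, 2], [1, 1], ["a", "a"])

    def test_permutation_p_close_to_chi_square_p(self):
        rng = np.random.default_rng(2)
        times = np.r_[rng.exponential(10, 40), rng.exponential(14, 40)]
        events = rng.uniform(size=80) < 0.7
        labels = np.array(["a"] * 40 + ["b"] * 40)
        res = logrank(times, events.astype(int), labels,
                      n_permutations=2000, seed=0)
        assert abs(res.p_permutation - res.p_value) < 0.02

    def test_internal_statistic_agrees_with_lifelines(self):
        from plasmir.survival import _logrank_chi2
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 50).round(1)  # induces ties
        events = rng.integers(0, 2, 50)
        in_a = rng.integers(0, 2, 50).astype(np.int8)
        if in_a.all() or not in_a.any():
            in_a[0] = 1 - in_a[0]
        res = logrank(times, events, np.where(in_a == 1, "a", "b"))
        assert _logrank_chi2(times.astype(float), events, in_a) == \
            pytest.approx(res.chi_square, rel=1e-6)


class TestBuildDesign:
    @staticmethod
    def _samples(rows):
        return SampleTable(pd.DataFrame(rows))

    def test_contrast_coding_rows(self):
        st = self._samples([
            {"sample_id": "p1", "cohort": "validation", "group": "IV",
             "sex": "female", "age": 60, "cea": 7.0, "chemotherapy": 1,
             "os_time": 12.0, "os_event": 1},
            {"sample_id": "p2", "cohort": "validation", "group": "I",
             "sex": "male", "age": 50, "cea": 3.0, "chemotherapy": 0,
             "os_time": 20.0, "os_event": 0},
            {"sample_id": "p3", "cohort": "validation", "group": "II",
             "sex": "male", "age": 55, "cea": 5.0, "chemotherapy": 0,
             "os_time": 18.0, "os_event": 0},
        ])
        marker = pd.Series(["high", "low", "low"],
                           index=["p1", "p2", "p3"])
        design, times, events, dropped = build_design(st, {"mkr": marker})
        assert design.loc["p1"].tolist() == [1, 1, 1, 1, 1, 1]
        assert design.loc["p2"].tolist() == [0, 0, 0, 0, 0, 0]
        # CEA exactly 5 falls in the <=5 arm; age 55 in the >=55 arm
        assert design.loc["p3", "cea_gt5"] == 0
        assert design.loc["p3", "age_ge55"] == 1
        assert dropped == []

    def test_patients_with_missing_fields_dropped_with_report(self):
        st = self._samples([
            {"sample_id": "p1", "cohort": "validation", "group": "III",
             "sex": "male", "age": 60, "cea": 7.0, "chemotherapy": 1,
             "os_time": 12.0, "os_event": 1},
            {"sample_id": "p2", "cohort": "validation", "group": "III",
             "sex": "male", "age": 61, "cea": None, "chemotherapy": 1,
             "os_time": 15.0, "os_event": 0},
        ])
        design, _, _, dropped = build_design(st)
        assert dropped == ["p2"]
        assert list(design.index) == ["p1"]

    def test_all_dropped_raises(self):
        st = self._samples([
            {"sample_id": "p1", "cohort": "validation", "group": "III",
             "sex": "male", "age": 60, "cea": None, "chemotherapy": 1,
             "os_time": 12.0, "os_event": 1},
        ])
        with pytest.raises(DesignError):
            build_design(st)


class TestCoxFit:
    def test_exchangeable_groups_have_unit_risk_ratio(self):
        times = np.r_[[1, 2, 3, 4, 5.0], [1, 2, 3, 4, 5.0]]
        events = np.ones(10, int)
        x = pd.DataFrame({"g": [0] * 5 + [1] * 5})
        fit = cox_fit(x, times, events)
        assert abs(fit.table.iloc[0]["coef"]) < 1e-6
        assert fit.table.iloc[0]["risk_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_partial_likelihood_maximizer(self):
        # 6 subjects, untied times: the fitted coefficient must agree
        # with a 1-D maximization of the Breslow partial log-likelihood
        times = np.array([3.0, 5.0, 7.0, 2.0, 11.0, 13.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        res = minimize_scalar(
            lambda b: -breslow_partial_loglik(np.r_[b], x[:, None],
                                              times, events),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.table.iloc[0]["coef"] == pytest.approx(res.x, abs=1e-3)

    def test_no_events_rejected(self):
        with pytest.raises(FitError):
            cox_fit(pd.DataFrame({"x": [0.0, 1.0]}), [1, 2], [0, 0])

    def test_constant_covariate_rejected(self):
        with pytest.raises(FitError):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}),
                    [1, 2, 3], [1, 1, 0])

    def test_risk_ratio_tracks_event_rate_imbalance(self):
        # higher hazard contrast between arms -> larger fitted RR
        rrs = []
        for hr in (1.0, 2.0, 4.0):
            rng = np.random.default_rng(10)
            x = np.r_[np.zeros(150), np.ones(150)]
            lam = 0.05 * hr**x
            t = rng.exponential(1 / lam)
            fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(300, int))
            rrs.append(fit.table.iloc[0]["risk_ratio"])
        assert rrs[0] < rrs[1] < rrs[2]
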