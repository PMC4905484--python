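"""Reference selection criteria and ΔCt/−ΔΔCt arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plasmir.errors import (
    EmptyMatrixError,
    NeutralityError,
    NormalizationError,
    SelectionError,
)
from plasmir.io import CtMatrix
from plasmir.normalization import (
    DeltaDeltaCtNormalizer,
    ReferenceSelector,
    delta_ct,
    filter_zero_variance,
    reference_neutrality,
    relative_expression,
    select_reference,
    shortlist_references,
)

from conftest import make_samples


def _ct(values: np.ndarray, assays=None, samples=None, **kw) -> CtMatrix:
    values = np.asarray(values, float)
    assays = assays or [f"m{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(values.shape[1])]
    return CtMatrix(pd.DataFrame(values, index=assays, columns=samples), **kw)


class TestZeroVarianceFilter:
    def test_flat_assay_removed_variable_retained(self):
        ct = _ct([[40, 40, 40], [30, 30, 30.01]])
        filtered, removed = filter_zero_variance(ct)
        assert removed == ["m0"]
        assert filtered.assay_ids == ["m1"]

    def test_all_flat_raises(self):
        ct = _ct([[40, 40], [25, 25]])
        with pytest.raises(EmptyMatrixError):
            filter_zero_variance(ct)


class TestShortlist:
    def test_lowest_sd_ranks_first(self):
        rng = np.random.default_rng(0)
        base = 25 + rng.normal(0, 1.5, (10, 20))  # SD ~1.5 each
        base[3] = 28 + rng.normal(0, 0.1, 20)     # the one stable assay
        ct = _ct(base)
        short = shortlist_references(ct, k=3)
        assert short.iloc[0]["assay"] == "m3"
        # direct SD oracle: reported sd_ct equals numpy's sample SD
        for row in short.itertuples():
            np.testing.assert_allclose(
                row.sd_ct, ct.values.loc[row.assay].std(ddof=1)
            )

    def test_low_yield_and_undetected_assays_excluded(self):
        values = np.full((3, 4), 25.0)
        values[0] += np.array([0, 0.01, 0, 0.01])
        values[1] = [36, 36.01, 36, 36.02]       # mean Ct over threshold
        values[2] = [25, 25.01, 41.0, 25.02]     # one undetected well
        ct = _ct(values)
        with pytest.warns(UserWarning, match="eligible"):
            short = shortlist_references(ct, k=3, max_mean_ct=35.0)
        assert list(short["assay"]) == ["m0"]

    def test_all_over_threshold_gives_empty_shortlist(self):
        ct = _ct(36 + np.random.default_rng(1).normal(0, 0.2, (4, 6)))
        with pytest.warns(UserWarning):
            short = shortlist_references(ct, k=2, max_mean_ct=35.0)
        assert short.empty


class TestNeutrality:
    def test_identical_group_multisets_are_neutral(self):
        block = np.array([24.0, 25.0, 26.0, 27.0])
        values = np.tile(block, 5)[None, :]
        ct = _ct(values)
        samples = make_samples({"control": 4, "I": 4, "II": 4, "III": 4, "IV": 4})
        p_cancer, p_overall = reference_neutrality(ct, samples, "m0")
        assert p_cancer >= 0.99
        assert p_overall >= 0.99

    def test_stage_shift_detected(self):
        # +3-cycle shift in stage IV only at sigma=0.1: the overall
        # Kruskal-Wallis must reject at 0.01 in essentially every draw
        rng = np.random.default_rng(42)
        samples = make_samples({"control": 10, "I": 10, "II": 10, "III": 10,
                                "IV": 10})
        hits = 0
        reps = 200
        for _ in range(reps):
            row = 25 + rng.normal(0, 0.1, 50)
            row[40:] += 3.0
            ct = _ct(row[None, :], samples=samples.sample_ids)
            _, p_overall = reference_neutrality(ct, samples, "m0")
            hits += p_overall < 0.01
        assert hits == reps

    def test_missing_control_group_raises(self):
        ct = _ct(np.random.default_rng(0).normal(25, 1, (1, 8)))
        samples = make_samples({"I": 4, "II": 4})
        with pytest.raises(NeutralityError, match="control"):
            reference_neutrality(ct, samples, "m0")


class TestSelectReference:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        samples = make_samples({"control": 10, "I": 10, "II": 10, "III": 10,
                                "IV": 10})
        values = 28 + rng.normal(0, 1.2, (12, 50))
        values[5] = 26 + rng.normal(0, 0.1, 50)   # planted stable card A
        values[11] = 27 + rng.normal(0, 0.1, 50)  # planted stable card B
        card = pd.Series(["A"] * 6 + ["B"] * 6,
                         index=[f"m{i}" for i in range(12)])
        return _ct(values, card=card), samples

    def test_planted_stable_assay_chosen_per_card(self):
        ct, samples = self._cohort()
        report = select_reference(ct, samples, k=3)
        assert report.chosen == {"A": "m5", "B": "m11"}
        assert (report.shortlist.groupby("card")["sd_ct"]
                .apply(lambda s: s.is_monotonic_increasing).all())

    def test_impossible_alpha_raises_with_shortlist_detail(self):
        ct, samples = self._cohort()
        with pytest.raises(SelectionError, match="p_cancer"):
            select_reference(ct, samples, k=3, alpha=1.0)

    def test_estimator_exposes_fitted_attributes(self):
        ct, samples = self._cohort()
        sel = ReferenceSelector(k=3).fit(ct, samples)
        assert sel.chosen_ == {"A": "m5", "B": "m11"}
        assert {"p_cancer", "p_overall", "passed"} <= set(sel.shortlist_.columns)
        assert sel.get_params()["k"] == 3


class TestDeltaCt:
    def test_arithmetic_by_definition(self):
        ct = _ct([[30.0, 32.0], [25.0, 26.0]], assays=["t", "ref"])
        dct = delta_ct(ct, "ref")
        assert dct.loc["t", "s1"] == 5.0
        assert dct.loc["t", "s2"] == 6.0
        assert (dct.loc["ref"] == 0).all()

    def test_duplicate_wells_collapsed_before_subtraction(self):
        values = pd.DataFrame(
            [[29.8, 30.2, 28.0, 28.0], [25.0, 25.0, 25.0, 25.0]],
            index=["t", "ref"],
            columns=["s1|1", "s1|2", "s2|1", "s2|2"],
        )
        ct = CtMatrix(values=values, sample_of=pd.Series(
            ["s1", "s1", "s2", "s2"], index=values.columns))
        dct = delta_ct(ct, "ref", collapse_duplicates=True)
        assert dct.loc["t", "s1"] == pytest.approx(5.0)

    def test_undetected_reference_well_names_sample(self):
        ct = _ct([[30.0, 30.0], [25.0, 41.0]], assays=["t", "ref"])
        with pytest.raises(NormalizationError, match="s2"):
            delta_ct(ct, "ref")


class TestRelativeExpression:
    def test_known_arithmetic(self):
        samples = make_samples({"control": 2, "IV": 1})
        ct = _ct([[29.0, 31.0, 31.0], [25.0, 25.0, 25.0]],
                 assays=["t", "ref"], samples=samples.sample_ids)
        expr = relative_expression(delta_ct(ct, "ref"), samples)
        # baseline mean dCt = 5; sample s3 dCt = 6 -> ddCt = 1 -> level -1
        assert expr.values.loc["t", "s3"] == pytest.approx(-1.0)
        assert expr.values.loc["t", ["s1", "s2"]].mean() == pytest.approx(0.0)

    def test_matches_bruteforce_loops(self):
        rng = np.random.default_rng(3)
        samples = make_samples({"control": 5, "II": 7})
        ct = _ct(rng.uniform(20, 35, (20, 12)), samples=samples.sample_ids)
        ref = ct.assay_ids[0]
        expr = relative_expression(delta_ct(ct, ref), samples)
        ctrl = samples.ids_in_groups(["control"])
        for a in ct.assay_ids:
            for s in ct.sample_ids:
                dct = ct.values.loc[a, s] - ct.values.loc[ref, s]
                base = np.mean([ct.values.loc[a, c] - ct.values.loc[ref, c]
                                for c in ctrl])
                assert expr.values.loc[a, s] == pytest.approx(
                    -(dct - base), abs=1e-12
                )

    def test_baseline_group_empty_raises(self):
        samples = make_samples({"II": 3})
        ct = _ct(np.full((2, 3), 25.0) + np.arange(3),
                 assays=["t", "ref"], samples=samples.sample_ids)
        with pytest.raises(NormalizationError, match="control"):
            relative_expression(delta_ct(ct, "ref"), samples)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(shift=st.floats(-5, 5), seed=st.integers(0, 100))
    def test_per_sample_ct_offset_cancels(self, shift, seed):
        # adding a constant to every Ct of one sample is a pure technical
        # (loading) effect; relative levels must be unchanged
        rng = np.random.default_rng(seed)
        samples = make_samples({"control": 3, "I": 3})
        values = rng.uniform(22, 34, (5, 6))
        ct = _ct(values, samples=samples.sample_ids)
        shifted = values.copy()
        shifted[:, 2] += shift
        ct2 = _ct(shifted, samples=samples.sample_ids)
        e1 = relative_expression(delta_ct(ct, "m0"), samples)
        e2 = relative_expression(delta_ct(ct2, "m0"), samples)
        np.testing.assert_allclose(e1.values, e2.values, atol=1e-9)

    def test_one_extra_cycle_lowers_level_by_one(self):
        samples = make_samples({"control": 3, "I": 1})
        values = np.vstack([np.full(4, 30.0), np.full(4, 25.0)])
        bumped = values.copy()
        bumped[0, 3] += 1.0
        e1 = relative_expression(
            delta_ct(_ct(values, assays=["t", "r"],
                         samples=samples.sample_ids), "r"), samples)
        e2 = relative_expression(
            delta_ct(_ct(bumped, assays=["t", "r"],
                         samples=samples.sample_ids), "r"), samples)
        assert (e2.values.loc["t", "s4"] - e1.values.loc["t", "s4"]
                ) == pytest.approx(-1.0)


class TestNormalizerEstimator:
    def test_fit_transform_equals_functional_path(self):
        rng = np.random.default_rng(9)
        samples = make_samples({"control": 4, "III": 4})
        ct = _ct(rng.uniform(20, 35, (6, 8)), samples=samples.sample_ids)
        norm = DeltaDeltaCtNormalizer(reference="m0").fit(ct, samples)
        expr = norm.transform(ct)
        expected = relative_expression(delta_ct(ct, "m0"), samples)
        np.testing.assert_allclose(expr.values, expected.values, atol=1e-12)
        assert norm.get_params()["reference"] == "m0"
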