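import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_beta, make_sheet
from demkin.datamodel import PairedDesign
from demkin.diffmeth import (
    PairedDifferentialModel,
    VariancePrior,
    bh_adjust,
    call_demethylated,
    classify_demethylation_magnitude,
    cohort_methylation_summary,
    estimate_variance_prior,
    group_delta_beta,
    moderated_paired_test,
    single_sample_delta_sets,
    trigamma_inverse,
)
from oracles import bh_stepup_oracle, variance_prior_oracle


def _design(n, prefix="P"):
    return PairedDesign(
        patients=tuple(f"{prefix}{i}" for i in range(n)),
        t1_samples=tuple(f"t1_{i}" for i in range(n)),
        t0_samples=tuple(f"t0_{i}" for i in range(n)),
    )


def _frame(t1_values, t0_values, design):
    """Build a feature x sample frame from (features x patients) arrays."""
    t1 = np.atleast_2d(np.asarray(t1_values, dtype=float))
    t0 = np.atleast_2d(np.asarray(t0_values, dtype=float))
    data = np.hstack([t1, t0])
    cols = list(design.t1_samples) + list(design.t0_samples)
    return pd.DataFrame(data, columns=cols)


class TestModeratedPairedTest:
    def test_zero_prior_df_reduces_to_ordinary_t(self):
        design = _design(3)
        df = _frame([[-1.0, -2.0, -3.0]], [[0.0, 0.0, 0.0]], design)
        res = moderated_paired_test(df, design, prior_override=(0.0, 1.0))
        # textbook one-sample t: mean -2, sd 1, n 3 -> -2*sqrt(3)
        assert res["mod_t"].iloc[0] == pytest.approx(-2.0 * math.sqrt(3.0), abs=1e-12)

    def test_zero_prior_matches_scipy_on_random_features(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        design = _design(8)
        diffs = rng.normal(size=(500, 8))
        df = _frame(diffs, np.zeros_like(diffs), design)
        res = moderated_paired_test(df, design, prior_override=(0.0, 1.0))
        t_ref, p_ref = stats.ttest_1samp(diffs, 0.0, axis=1)
        np.testing.assert_allclose(res["mod_t"].to_numpy(), t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p"].to_numpy(), p_ref, atol=1e-10)

    def test_constant_zero_feature_yields_p_one_under_shrinkage(self):
        rng = np.random.default_rng(1)
        design = _design(6)
        diffs = rng.normal(size=(50, 6))
        diffs[0] = 0.0
        df = _frame(diffs, np.zeros_like(diffs), design)
        res = moderated_paired_test(df, design)
        assert res["mean_diff"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)
        assert res.attrs["prior_d0"] > 0  # other features lend variance

    def test_hyperparameters_match_independent_moment_oracle(self):
        rng = np.random.default_rng(7)
        n = 8
        design = _design(n)
        # heterogeneous true variances (scaled inverse chi-square, d0=4)
        # so the fitted prior df is finite
        true_var = 4.0 / rng.chisquare(4.0, size=500)
        diffs = rng.normal(size=(500, n)) * np.sqrt(true_var)[:, None]
        s2 = diffs.var(axis=1, ddof=1)
        prior = estimate_variance_prior(s2, n - 1)
        d0_ref, s2_0_ref = variance_prior_oracle(s2, n - 1)
        assert prior.d0 == pytest.approx(d0_ref, rel=1e-8)
        assert prior.s2_0 == pytest.approx(s2_0_ref, rel=1e-8)
        # and per-feature p agrees with direct evaluation of the formulas
        res = moderated_paired_test(_frame(diffs, np.zeros_like(diffs), design), design)
        from scipy import stats

        s2_post = (d0_ref * s2_0_ref + (n - 1) * s2) / (d0_ref + n - 1)
        t_ref = diffs.mean(axis=1) / np.sqrt(s2_post / n)
        p_ref = 2 * stats.t.sf(np.abs(t_ref), n - 1 + d0_ref)
        np.testing.assert_allclose(res["mod_t"].to_numpy(), t_ref, atol=1e-8)
        np.testing.assert_allclose(res["p"].to_numpy(), p_ref, atol=1e-8)

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(11)
        design = _design(8)
        diffs = rng.normal(size=(2000, 8))
        res = moderated_paired_test(_frame(diffs, np.zeros_like(diffs), design), design)
        frac = float((res["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_single_patient_rejected(self):
        design = _design(1)
        df = _frame([[1.0]], [[0.0]], design)
        with pytest.raises(ValueError, match=">= 2"):
            moderated_paired_test(df, design)

    def test_all_zero_variance_rejected(self):
        design = _design(4)
        diffs = np.ones((10, 4))  # identical differences everywhere
        with pytest.raises(ValueError, match="variance"):
            moderated_paired_test(_frame(diffs, np.zeros_like(diffs), design), design)

    def test_trigamma_inverse_round_trip(self):
        from scipy import special

        for x in (0.01, 0.5, 1.0, 7.0, 300.0):
            y = float(special.polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-8)


class TestBHAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(1, 9))
            p = np.round(rng.random(n), 3)  # rounding creates ties
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        p = rng.random(20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDeltaBetaAndCalls:
    def test_group_delta_beta_arithmetic(self):
        design = _design(2)
        beta = make_beta(
            [[0.7, 0.8, 0.9, 0.9]],
            cpgs=["cg1"],
            samples=list(design.t1_samples) + list(design.t0_samples),
        )
        db = group_delta_beta(beta, design)
        assert db["cg1"] == pytest.approx(-0.15)

    def test_group_delta_beta_matches_brute_force(self):
        rng = np.random.default_rng(9)
        design = _design(5)
        vals = rng.random((40, 10))
        beta = make_beta(
            vals, samples=list(design.t1_samples) + list(design.t0_samples)
        )
        db = group_delta_beta(beta, design)
        manual = np.mean(vals[:, :5] - vals[:, 5:], axis=1)
        np.testing.assert_allclose(db.to_numpy(), manual, atol=1e-12)

    @pytest.mark.parametrize(
        "adj_p,delta,included",
        [(0.01, -0.15, True), (0.01, -0.10, False), (0.06, -0.5, False)],
    )
    def test_call_thresholds_are_strict(self, adj_p, delta, included):
        idx = pd.Index(["cg1"])
        out = call_demethylated(
            pd.Series([delta], index=idx), pd.Series([adj_p], index=idx)
        )
        assert ("cg1" in out) is included

    def test_swapped_design_turns_demethylation_into_remethylation(self):
        rng = np.random.default_rng(13)
        design = _design(4)
        vals = rng.random((30, 8))
        beta = make_beta(vals, samples=list(design.t1_samples) + list(design.t0_samples))
        swapped = PairedDesign(
            patients=design.patients,
            t1_samples=design.t0_samples,
            t0_samples=design.t1_samples,
        )
        db = group_delta_beta(beta, design)
        db_sw = group_delta_beta(beta, swapped)
        adj = pd.Series(0.001, index=db.index)
        assert call_demethylated(db_sw, adj, direction="hypo") == call_demethylated(
            db, adj, direction="hyper"
        )

    def test_raising_threshold_never_enlarges_call_set(self):
        rng = np.random.default_rng(17)
        db = pd.Series(rng.uniform(-0.5, 0.5, 200))
        adj = pd.Series(rng.random(200))
        prev = call_demethylated(db, adj, delta_threshold=0.05)
        for thr in (0.1, 0.2, 0.3):
            cur = call_demethylated(db, adj, delta_threshold=thr)
            assert cur <= prev
            prev = cur

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10))
    def test_adjusted_p_never_below_raw_p(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)


class TestSingleSampleSets:
    def _sheet_and_beta(self):
        sheet = make_sheet(
            [
                ("P1_d0", "P1", "d0", 1, "blast", "unknown"),
                ("P1_d8", "P1", "d8", 1, "blast", "unknown"),
                ("P2_d0", "P2", "d0", 1, "blast", "unknown"),
                ("P2_d8", "P2", "d8", 1, "blast", "unknown"),
                ("P3_d0", "P3", "d0", 1, "blast", "unknown"),
            ]
        )
        beta = make_beta(
            [
                [0.90, 0.75, 0.90, 0.86, 0.9],  # P1 delta -0.15; P2 delta -0.04
                [0.50, 0.48, 0.50, 0.10, 0.5],  # P2 delta -0.40
            ],
            cpgs=["cgA", "cgB"],
            samples=["P1_d0", "P1_d8", "P2_d0", "P2_d8", "P3_d0"],
        )
        return sheet, beta

    def test_per_patient_calls_and_omissions(self):
        sheet, beta = self._sheet_and_beta()
        sets, omitted = single_sample_delta_sets(beta, sheet, "d8", "d0")
        assert sets == {"P1": {"cgA"}, "P2": {"cgB"}}
        assert omitted == ["P3"]

    def test_sizes_track_generator_truth(self, small_cohort, small_filtered):
        sets, _ = single_sample_delta_sets(
            small_filtered, small_cohort.sheet, "d8", "d0"
        )
        truth = small_cohort.truth.demethylated_d8
        obs = np.array([len(sets[p]) for p in sorted(sets)])
        exp = np.array([len(truth[p]) for p in sorted(sets)])
        rho = np.corrcoef(obs, exp)[0, 1]
        assert rho > 0.9


class TestMagnitudeAndSummary:
    @pytest.mark.parametrize(
        "count,category",
        [(150_000, "strong"), (20_000, "limited"), (100_000, "intermediate")],
    )
    def test_magnitude_bins(self, count, category):
        assert classify_demethylation_magnitude(count) == category

    def test_constant_matrix_median(self):
        sheet = make_sheet(
            [
                ("P1_d0", "P1", "d0", 1, "blast", "unknown"),
                ("P1_d8", "P1", "d8", 1, "blast", "unknown"),
            ]
        )
        beta = make_beta([[0.8, 0.8], [0.8, 0.8]], samples=["P1_d0", "P1_d8"])
        summ = cohort_methylation_summary(beta, sheet)
        assert summ.median_beta["d0"] == pytest.approx(0.8)
        assert summ.median_beta["d8"] == pytest.approx(0.8)

    def test_four_value_median(self):
        vals = np.array([0.1, 0.2, 0.9, 1.0])
        assert float(np.median(vals)) == pytest.approx(0.55)
        sheet = make_sheet(
            [
                ("P1_d0", "P1", "d0", 1, "blast", "unknown"),
                ("P1_d8", "P1", "d8", 1, "blast", "unknown"),
            ]
        )
        beta = make_beta(
            np.column_stack([vals, vals]), samples=["P1_d0", "P1_d8"]
        )
        summ = cohort_methylation_summary(beta, sheet)
        assert summ.median_beta["d0"] == pytest.approx(0.55)

    def test_heavily_methylated_cpgs_demethylate_more(self, default_cohort):
        from demkin.datamodel import filter_cpgs

        filt = filter_cpgs(default_cohort.beta, default_cohort.annotation)
        summ = cohort_methylation_summary(filt, default_cohort.sheet)
        assert (
            summ.call_rate_by_baseline_bin["(0.5,1]"]
            > summ.call_rate_by_baseline_bin["[0,0.5]"]
        )


class TestPairedDifferentialModel:
    def test_fit_results_are_internally_consistent(self, small_cohort, small_filtered):
        design = small_cohort.sheet.paired_design("d8", "d0")
        res = PairedDifferentialModel(small_filtered, design).fit()
        t = res.table
        assert np.all(t["adj_p"].to_numpy() >= t["p"].to_numpy() - 1e-15)
        called = res.demethylated_set()
        assert called == call_demethylated(t["delta_beta"], t["adj_p"])
        assert "patients: 6" in res.summary()

    def test_signature_cpgs_are_recovered_groupwise(self, small_cohort, small_filtered):
        design = small_cohort.sheet.paired_design("d8", "d0")
        res = PairedDifferentialModel(small_filtered, design).fit()
        sig = small_cohort.truth.signature_cpg_ids
        called = res.demethylated_set()
        assert len(called & sig) / len(sig) >= 0.9
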