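"""BH adjustment, NAP calls, severity/direction, permutation FDR."""

import numpy as np
import pandas as pd
import pytest

from napmap import calling
from napmap.calling import (
    adjust_bh,
    call_naps,
    classify_direction,
    classify_severity,
    permutation_fdr,
    run_association,
    structure_correlations,
    summarize_effects,
    ttest_fallback,
)
from conftest import make_manual_table


def bh_oracle(pvals):
    """Independent step-up implementation for cross-checking."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, pvals[idx] * m / rank)
        adj[idx] = prev
    return adj


def _results_frame(pvals, line="L1", testable=None):
    n = len(pvals)
    return pd.DataFrame(
        {
            "line_id": [line] * n,
            "gene": ["G"] * n,
            "parameter_id": [f"p{i}" for i in range(n)],
            "beta": 1.0,
            "percent_change": 10.0,
            "z_score": 1.0,
            "p_raw": pvals,
            "p_bh": np.nan,
            "method": "lmm",
            "n_mut": 3,
            "n_wt": 50,
            "testable": testable if testable is not None else [True] * n,
        }
    )


class TestAdjustBH:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.001, 1.0], [0.002, 1.0]),
        ],
    )
    def test_worked_step_up_cases(self, pvals, expected):
        out = adjust_bh(_results_frame(pvals))
        assert out["p_bh"].to_numpy() == pytest.approx(expected)

    def test_random_vectors_match_independent_oracle(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(2, 40))
            out = adjust_bh(_results_frame(p))
            assert out["p_bh"].to_numpy() == pytest.approx(bh_oracle(p))

    def test_adjusted_at_least_raw_and_at_most_one(self, rng):
        p = rng.random(100)
        out = adjust_bh(_results_frame(p))
        assert (out["p_bh"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_bh"] <= 1.0).all()

    def test_per_parameter_family(self):
        df = pd.concat(
            [_results_frame([0.01, 0.5], line="L1"),
             _results_frame([0.02, 0.5], line="L2")],
            ignore_index=True,
        )
        out = adjust_bh(df, family="per_parameter")
        # p0 family = {0.01, 0.02}: adjusted {0.02, 0.02}
        p0 = out[out["parameter_id"] == "p0"]["p_bh"].to_numpy()
        assert p0 == pytest.approx([0.02, 0.02])

    def test_untestable_rows_left_unadjusted(self):
        df = _results_frame([0.01, np.nan], testable=[True, False])
        out = adjust_bh(df)
        assert np.isnan(out["p_bh"].iloc[1])
        assert out["p_bh"].iloc[0] == pytest.approx(0.01)


class TestTtestFallback:
    def test_textbook_values(self):
        table = make_manual_table({"WT": [10, 11, 12], "L1": [8, 9, 10]},
                                  background="other")
        row = ttest_fallback(table, "L1", "p1")
        assert row["method"] == "ttest"
        # t = -2.449, df = 4
        assert row["p_raw"] == pytest.approx(0.0705, abs=2e-3)

    def test_identical_groups_p_one(self):
        table = make_manual_table({"WT": [5, 6, 7], "L1": [5, 6, 7]},
                                  background="other")
        assert ttest_fallback(table, "L1", "p1")["p_raw"] == pytest.approx(1.0)

    def test_single_mutant_not_testable(self):
        table = make_manual_table({"WT": [5, 6, 7], "L1": [5.0]},
                                  background="other")
        row = ttest_fallback(table, "L1", "p1")
        assert not row["testable"] and np.isnan(row["p_raw"])

    def test_run_association_routes_other_backgrounds_to_ttest(self):
        table = make_manual_table({"WT": [10, 11, 12], "L1": [8, 9, 10]},
                                  background="other")
        res = run_association(table)
        assert (res["method"] == "ttest").all()


class TestSummarizeEffects:
    def test_direct_arithmetic(self):
        table = make_manual_table({"WT": [9.0, 10.0, 11.0], "L1": [8.0, 8.0, 8.0]})
        pc, z = summarize_effects(table, "L1", "p1")
        assert pc == pytest.approx(-20.0)
        assert z == pytest.approx(-2.0)  # sd_wt = 1

    def test_no_change_is_zero(self):
        table = make_manual_table({"WT": [9.0, 10.0, 11.0], "L1": [10.0, 10.0, 10.0]})
        pc, z = summarize_effects(table, "L1", "p1")
        assert pc == 0.0 and z == 0.0

    def test_zero_wt_sd_flagged_undefined(self):
        table = make_manual_table({"WT": [10.0, 10.0, 10.0], "L1": [12.0, 12.0]})
        pc, z = summarize_effects(table, "L1", "p1")
        assert pc == pytest.approx(20.0) and np.isnan(z)

    def test_invariant_to_batch_relabeling(self):
        dates = {"WT": ["2009-01-05", "2009-02-02", "2009-03-02"],
                 "L1": ["2009-01-05", "2009-02-02", "2009-03-02"]}
        t1 = make_manual_table({"WT": [9.0, 10, 11], "L1": [8.0, 9, 10]}, dates=dates)
        t2 = t1.copy()
        t2["necropsy_date"] = t2["necropsy_date"].map(
            {"2009-01-05": "2010-05-01", "2009-02-02": "2010-06-01",
             "2009-03-02": "2010-07-01"}
        )
        assert summarize_effects(t1, "L1", "p1") == summarize_effects(t2, "L1", "p1")


class TestSeverityAndDirection:
    @pytest.mark.parametrize(
        "changes,expected",
        [
            ([-15.2], "moderate"),
            ([727.0], "very_severe"),
            ([-5.0, 45.0], "very_severe"),
            ([9.99], "mild"),
            ([10.0], "moderate"),
            ([20.0], "severe"),
            ([39.999], "severe"),
            ([40.0], "very_severe"),
        ],
    )
    def test_bands_half_open_on_max_magnitude(self, changes, expected):
        assert classify_severity(changes) == expected

    def test_empty_severity_rejected(self):
        with pytest.raises(ValueError):
            classify_severity([])

    @pytest.mark.parametrize(
        "changes,expected",
        [
            ([-12.0, -71.0], "decrease"),
            ([-16.0, 633.0], "bidirectional"),
            ([5.0], "increase"),
        ],
    )
    def test_direction_classes(self, changes, expected):
        assert classify_direction(changes) == expected

    def test_exact_zero_change_rejected(self):
        with pytest.raises(ValueError):
            classify_direction([0.0, 5.0])


class TestCallNaps:
    def _adjusted(self, signal_cohort, threshold_cat):
        table, _ = signal_cohort
        return adjust_bh(run_association(table)), threshold_cat

    def test_no_significant_means_no_nap(self, small_catalogue):
        res = adjust_bh(_results_frame([0.5, 0.9]))
        res["parameter_id"] = small_catalogue["parameter_id"].iloc[:2].to_numpy()
        calls = call_naps(res, small_catalogue)
        assert not calls["is_nap"].iloc[0]
        assert calls["severity"].iloc[0] is None

    def test_categories_from_catalogue(self, small_catalogue):
        res = adjust_bh(_results_frame([1e-6, 0.9]))
        pids = small_catalogue["parameter_id"].iloc[:2].to_numpy()
        res["parameter_id"] = pids
        calls = call_naps(res, small_catalogue)
        expected = small_catalogue.loc[pids[0], "category"]
        assert calls["categories_affected"].iloc[0] == expected

    def test_monotone_in_threshold(self, signal_cohort, small_catalogue):
        table, _ = signal_cohort
        res = adjust_bh(run_association(table))
        strict = set(call_naps(res, small_catalogue, 0.05)
                     .query("is_nap")["line_id"])
        loose = set(call_naps(res, small_catalogue, 0.1)
                    .query("is_nap")["line_id"])
        assert strict <= loose

    def test_threshold_validated(self, small_catalogue):
        res = adjust_bh(_results_frame([0.5]))
        res["parameter_id"] = [small_catalogue["parameter_id"].iloc[0]]
        with pytest.raises(ValueError):
            call_naps(res, small_catalogue, threshold=1.5)

    def test_unadjusted_results_rejected(self, small_catalogue):
        res = _results_frame([0.5])
        res["parameter_id"] = [small_catalogue["parameter_id"].iloc[0]]
        with pytest.raises(ValueError):
            call_naps(res, small_catalogue)


class TestPermutationFdr:
    def test_deterministic_under_seed(self, null_cohort):
        table, _ = null_cohort
        a = permutation_fdr(table, n_perm=2, seed=5)
        b = permutation_fdr(table, n_perm=2, seed=5)
        assert a.null_counts == b.null_counts and a.observed == b.observed

    def test_null_cohort_consistent_with_permutations(self, null_cohort):
        table, _ = null_cohort
        fc = permutation_fdr(table, n_perm=20, seed=1)
        assert abs(fc.observed - fc.null_mean) <= max(2 * fc.null_sd, 2.0)


class TestStructureCorrelations:
    def _table_with_driver(self):
        rng = np.random.default_rng(0)
        driver = rng.lognormal(0, 0.2, 60)
        t = make_manual_table({"WT": list(driver)}, parameter="total_brain_area")
        t["B+0.98:cortex_01"] = 2.0 * driver
        t["B+0.98:cortex_02"] = 5.0 * driver
        return t

    def test_exact_multiples_correlate_raw_then_vanish_normalized(self):
        t = self._table_with_driver()
        raw = structure_correlations(t, normalize=False)
        assert raw.loc["B+0.98:cortex_01", "B+0.98:cortex_02"] == pytest.approx(1.0)
        norm = structure_correlations(t, normalize=True)
        v = norm.loc["B+0.98:cortex_01", "B+0.98:cortex_02"]
        assert np.isnan(v)  # both become constant after removing the driver

    def test_diagonal_and_symmetry(self, null_cohort):
        table, _ = null_cohort
        c = structure_correlations(table)
        assert np.allclose(np.diag(c.to_numpy()), 1.0)
        assert np.nanmax(np.abs(c.to_numpy() - c.to_numpy().T)) < 1e-12

    def test_constant_column_reported_missing(self):
        t = self._table_with_driver()
        t["B+0.98:cortex_03"] = 7.0
        c = structure_correlations(t, normalize=False)
        assert c["B+0.98:cortex_03"].drop("B+0.98:cortex_03").isna().all()
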