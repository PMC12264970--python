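"""Benchmark accuracy statistics: UE/AUE, consensus, splits, fits, signs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rbfebench as rb
from rbfebench.benchmark import add_unsigned_error

from tests._oracles import ols_normal_equations


def _tiny_table(ddg_exp, calc_higher, calc_lower):
    rows = []
    for i, (e, ch, cl) in enumerate(zip(ddg_exp, calc_higher, calc_lower)):
        rows.append({"pair_id": f"p{i}", "affinity": "higher", "ddg_exp": e, "ddg_calc": ch,
                     "source_consistency": "same"})
        rows.append({"pair_id": f"p{i}", "affinity": "lower", "ddg_exp": e, "ddg_calc": cl,
                     "source_consistency": "same"})
    return pd.DataFrame(rows)


class TestUnsignedErrorAndAue:
    def test_basic_values_and_symmetry(self):
        assert rb.unsigned_error(4.0, 4.0) == 0.0
        assert rb.unsigned_error(2.5, 4.0) == 1.5
        assert rb.unsigned_error(-2.5, -4.0) == rb.unsigned_error(2.5, 4.0)

    def test_aue_constant_and_two_point(self):
        res = rb.aue([1.0, 1.0, 1.0], n_boot=100)
        assert res.aue == 1.0 and res.se == 0.0
        assert rb.aue([0.0, 2.0], n_boot=100).aue == 1.0

    def test_bootstrap_se_matches_analytic_se_of_mean(self):
        rng = np.random.default_rng(1)
        mu, n = 1.5, 200
        ues = rng.exponential(mu, size=n)
        res = rb.aue(ues, n_boot=10000, seed=2)
        analytic = ues.std(ddof=1) / np.sqrt(n)  # ≈ μ/√n for exponentials
        assert res.se == pytest.approx(analytic, rel=0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rb.aue([])


class TestConsensusAndBestSet:
    def test_consensus_is_per_pair_mean(self):
        t = _tiny_table([4.0], [1.0], [3.0])
        assert rb.consensus_ddg(t).iloc[0] == 2.0
        t = _tiny_table([4.0], [2.5], [2.5])
        assert rb.consensus_ddg(t).iloc[0] == 2.5

    def test_consensus_ue_bounded_by_worst_individual(self):
        t = _tiny_table([4.0, 5.0], [3.6, 6.9], [2.1, 4.5])
        cons_ue = (rb.consensus_ddg(t) - t.groupby("pair_id")["ddg_exp"].first()).abs()
        worst = add_unsigned_error(t).groupby("pair_id")["ue"].max()
        assert (cons_ue <= worst + 1e-12).all()

    def test_best_set_picks_least_deviation(self):
        t = _tiny_table([4.0], [4.4], [5.9])  # UEs 0.4 and 1.9
        best = rb.best_set_select(t)
        assert best.iloc[0]["affinity"] == "higher"
        assert rb.best_set_aue(t, n_boot=10).aue == pytest.approx(0.4)

    def test_tie_goes_to_higher_affinity_structure(self):
        t = _tiny_table([4.0], [3.0], [5.0])  # both UE = 1
        assert rb.best_set_select(t).iloc[0]["affinity"] == "higher"

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_consensus_le_all_values_on_arbitrary_tables(self, seed):
        # |mean error| ≤ mean |error| per pair (convexity), so the
        # consensus AUE never exceeds the all-values AUE — on any table.
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        t = _tiny_table(
            rng.uniform(2.7, 6.6, n),
            rng.normal(4.0, 2.5, n),
            rng.normal(4.0, 2.5, n),
        )
        cons = rb.consensus_aue(t, n_boot=10).aue
        allv = rb.pooled_aue(t, n_boot=10).aue
        assert cons <= allv + 1e-12

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_ordering_best_le_consensus_le_all_on_benchmark_tables(self, seed):
        # With the two estimates' errors same-signed within a pair — the
        # correlated-error regime benchmark data sits in and the generator
        # reproduces — the best ≤ consensus ≤ all-values ordering is exact.
        # (Opposite-sign errors can break the first inequality: errors +e
        # and −e cancel in the consensus while the best-set UE stays e.)
        tab = rb.gen_benchmark_table(
            rb.BenchmarkGenSpec(n_pairs=25, noise_sd=0.3, flip_prob=0.0, seed=seed)
        )
        best = rb.best_set_aue(tab, n_boot=10).aue
        cons = rb.consensus_aue(tab, n_boot=10).aue
        allv = rb.pooled_aue(tab, n_boot=10).aue
        assert best <= cons + 1e-12 <= allv + 2e-12


class TestSplits:
    def test_single_class_leaves_other_absent(self):
        t = _tiny_table([4.0, 5.0], [4.2, 5.1], [4.8, 5.4])
        t = t[t["affinity"] == "higher"]
        out = rb.split_by_affinity(t, n_boot=10)
        assert "higher" in out and "lower" not in out

    def test_planted_affinity_offset_recovered(self):
        tab = rb.gen_benchmark_table(
            rb.BenchmarkGenSpec(n_pairs=400, affinity_offset=0.5, noise_sd=0.2,
                                flip_prob=0.0, seed=3)
        )
        out = rb.split_by_affinity(tab, n_boot=2000, seed=0)
        diff = out["lower"].aue - out["higher"].aue
        se = np.hypot(out["lower"].se, out["higher"].se)
        assert diff == pytest.approx(0.5, abs=3 * se)

    def test_permuted_labels_show_no_class_difference(self):
        tab = rb.gen_benchmark_table(
            rb.BenchmarkGenSpec(n_pairs=400, affinity_offset=0.5, noise_sd=0.2,
                                flip_prob=0.0, seed=4)
        )
        rng = np.random.default_rng(0)
        tab = tab.assign(affinity=rng.permutation(tab["affinity"].to_numpy()))
        out = rb.split_by_affinity(tab, n_boot=2000, seed=0)
        diff = abs(out["lower"].aue - out["higher"].aue)
        se = np.hypot(out["lower"].se, out["higher"].se)
        assert diff < 3 * se

    def test_source_and_cross_splits_cover_all_records(self):
        tab = rb.gen_benchmark_table(rb.BenchmarkGenSpec(n_pairs=100, seed=5))
        out = rb.split_by_source(tab, n_boot=10)
        assert sum(v.n for v in out.values()) == len(tab)
        cross = rb.split_by_affinity_and_source(tab, n_boot=10)
        assert sum(v.n for v in cross.values()) == len(tab)


class TestFitAndNominalResolution:
    def test_collinear_points_fit_exactly(self):
        res = np.array([1.0, 2.0, 3.0, 4.0])
        fit = rb.fit_ue_resolution(res, 0.5 * res + 0.3)
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(0.3)

    def test_four_point_instance_matches_normal_equations(self):
        x = np.array([1.0, 1.5, 2.5, 3.0])
        y = np.array([0.8, 1.4, 1.1, 2.3])
        fit = rb.fit_ue_resolution(x, y)
        slope, intercept, se_s, se_i = ols_normal_equations(x, y)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.se_slope == pytest.approx(se_s)
        assert fit.se_intercept == pytest.approx(se_i)

    def test_equal_resolutions_rejected(self):
        with pytest.raises(ValueError):
            rb.fit_ue_resolution([2.0, 2.0, 2.0], [1.0, 1.2, 1.4])

    def test_binned_aue_uses_centered_windows(self):
        res = np.array([1.0, 1.05, 1.5, 2.0])
        ue = np.array([1.0, 2.0, 3.0, 4.0])
        binned = rb.binned_aue(res, ue, half_width=0.1)
        row = binned[binned["res"] == 1.0].iloc[0]
        assert row["aue"] == pytest.approx(1.5) and row["n"] == 2
        assert binned[binned["res"] == 1.5].iloc[0]["n"] == 1

    def test_nominal_resolution_inverts_the_line(self):
        fit = rb.FitResult(slope=0.5, intercept=0.5, se_slope=0.0, se_intercept=0.0)
        assert rb.nominal_resolution(fit.predict(2.0), fit).value == pytest.approx(2.0)
        assert rb.nominal_resolution(1.9, fit).value == pytest.approx(2.8)

    def test_nominal_resolution_monotone_and_censored(self):
        fit = rb.FitResult(slope=0.6, intercept=0.4, se_slope=0.0, se_intercept=0.0)
        a = rb.nominal_resolution(1.0, fit).value
        b = rb.nominal_resolution(2.0, fit).value
        assert b > a
        capped = rb.nominal_resolution(10.0, fit, max_res=3.0)
        assert capped.censored and capped.value == 3.0
        assert str(capped).startswith(">")

    def test_non_positive_slope_rejected(self):
        fit = rb.FitResult(slope=-0.1, intercept=0.5, se_slope=0.0, se_intercept=0.0)
        with pytest.raises(ValueError):
            rb.nominal_resolution(1.0, fit)


class TestSignAccuracy:
    def test_all_positive_and_half_positive(self):
        acc, se = rb.sign_accuracy([1.0, 2.0, 0.5], n_boot=100)
        assert acc == 100.0 and se == 0.0
        acc, _ = rb.sign_accuracy([1.0, -1.0, 2.0, -2.0], n_boot=100)
        assert acc == 50.0

    def test_zero_counts_as_incorrect(self):
        acc, _ = rb.sign_accuracy([0.0, 1.0], n_boot=100)
        assert acc == 50.0

    def test_nonpositive_experimental_rejected(self):
        with pytest.raises(ValueError):
            rb.sign_accuracy([1.0], ddg_exp=[-4.0])

    def test_planted_flip_rate_recovered(self):
        tab = rb.gen_benchmark_table(
            rb.BenchmarkGenSpec(n_pairs=400, flip_prob=0.3, seed=6)
        )
        acc, _ = rb.sign_accuracy(tab["ddg_calc"], tab["ddg_exp"], n_boot=100)
        n = len(tab)
        ci = 3 * 100 * np.sqrt(0.3 * 0.7 / n)
        assert acc == pytest.approx(70.0, abs=ci)


class TestTableIO:
    def test_round_trip_and_validation(self, tmp_path):
        tab = rb.gen_benchmark_table(rb.BenchmarkGenSpec(n_pairs=10, seed=7))
        path = tmp_path / "bench.csv"
        rb.write_benchmark_table(tab, path)
        back = rb.read_benchmark_table(path)
        assert len(back) == len(tab)
        pd.testing.assert_series_equal(back["ddg_calc"], tab["ddg_calc"].reset_index(drop=True))

    def test_negative_experimental_rejected_on_read(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({
            "pair_id": ["p0"], "ddg_exp": [-4.0], "ddg_calc": [1.0], "affinity": ["higher"],
        }).to_csv(path, index=False)
        with pytest.raises(ValueError):
            rb.read_benchmark_table(path)
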