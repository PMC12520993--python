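"""Normalization, LFC, Z-scores, empirical FDR and sensor calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pegsensor import screen_stats as ss
from pegsensor import simdata


def counts_frame(data, samples):
    return pd.DataFrame(data, columns=samples)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = counts_frame(
            {"a": [10, 20, 30], "b": [10, 20, 30]}, ["a", "b"]
        )
        factors = ss.size_factors(counts)
        assert factors["a"] == pytest.approx(1.0)
        assert factors["b"] == pytest.approx(1.0)

    def test_doubled_sample_ratio_two(self):
        rng = np.random.default_rng(0)
        a = rng.integers(50, 500, 40)
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        factors = ss.size_factors(counts)
        # oracle: direct median-of-ratios on the toy matrix
        ref = np.sqrt(a * 2 * a)
        expect_a = np.median(a / ref)
        expect_b = np.median(2 * a / ref)
        scale = np.sqrt(expect_a * expect_b)
        assert factors["b"] / factors["a"] == pytest.approx(2.0)
        assert factors["a"] == pytest.approx(expect_a / scale)

    def test_single_design_degenerate_case(self):
        counts = pd.DataFrame({"a": [10], "b": [30]})
        factors = ss.size_factors(counts)
        assert factors["b"] / factors["a"] == pytest.approx(3.0)
        assert np.exp(np.log(factors).mean()) == pytest.approx(1.0)

    def test_no_all_positive_design_falls_back_with_warning(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.warns(UserWarning, match="total-count"):
            ss.size_factors(counts)


class TestComputeLfc:
    def test_fourfold_change_is_about_two(self):
        # many stable designs pin the size factors at 1; one design changes
        rng = np.random.default_rng(2)
        stable = rng.integers(50, 400, 30)
        counts = pd.DataFrame(
            {s: np.concatenate(([100], stable)) for s in ("c1", "c2", "c3")}
            | {s: np.concatenate(([400], stable)) for s in ("t1", "t2", "t3")}
        )
        res = ss.compute_lfc(counts, ["c1", "c2", "c3"], ["t1", "t2", "t3"])
        assert res["lfc"].iloc[0] == pytest.approx(
            np.log2(401) - np.log2(101), abs=0.02
        )

    def test_low_control_mean_excluded_but_retained(self):
        rng = np.random.default_rng(3)
        stable = rng.integers(50, 400, 30)
        counts = pd.DataFrame(
            {s: np.concatenate(([9], stable)) for s in ("c1", "c2")}
            | {s: np.concatenate(([95], stable)) for s in ("t1", "t2")}
        )
        res = ss.compute_lfc(counts, ["c1", "c2"], ["t1", "t2"])
        assert not res["passed_count_filter"].iloc[0]
        assert np.isnan(res["lfc"].iloc[0])
        assert len(res) == 31

    def test_all_equal_samples_give_zero_lfc(self):
        counts = pd.DataFrame(
            {s: [120, 80, 40] for s in ["c1", "c2", "t1", "t2"]}
        )
        res = ss.compute_lfc(counts, ["c1", "c2"], ["t1", "t2"])
        assert np.allclose(res["lfc"], 0.0)

    def test_empty_partition_fatal(self):
        counts = pd.DataFrame({"c1": [1]})
        with pytest.raises(ValueError, match="non-empty"):
            ss.compute_lfc(counts, [], ["c1"])


class TestZscores:
    def frame(self, lfc):
        return pd.DataFrame({"lfc": lfc})

    def test_closed_form_three_values(self):
        out = ss.zscores(self.frame([-1.0, 0.0, 1.0]))
        assert list(out["zscore"].round(4)) == [-1.2247, 0.0, 1.2247]

    def test_location_invariance(self):
        a = ss.zscores(self.frame([-1.0, 0.5, 2.0, 3.0]))["zscore"]
        b = ss.zscores(self.frame([4.0, 5.5, 7.0, 8.0]))["zscore"]
        assert np.allclose(a, b)

    def test_subset_mean_zero(self):
        rng = np.random.default_rng(1)
        out = ss.zscores(self.frame(rng.normal(2.0, 1.0, 50)))
        assert out["zscore"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_too_few_designs_fatal(self):
        with pytest.raises(ValueError, match="at least 2"):
            ss.zscores(self.frame([1.0]))


class TestEmpiricalFdr:
    def test_top_design_p_is_one_over_hundred(self):
        lfc = [5.0] + list(np.linspace(-1, 1, 99))
        df = pd.DataFrame(
            {"lfc": lfc}, index=[f"d{i}" for i in range(100)]
        )
        silent = [f"d{i}" for i in range(1, 100)]
        out = ss.empirical_fdr(df, silent)
        assert out["p_emp"].loc["d0"] == pytest.approx(0.01)

    def test_zero_lfc_has_p_one(self):
        lfc = [0.0] + list(np.linspace(-1, 1, 99))
        df = pd.DataFrame({"lfc": lfc}, index=[f"d{i}" for i in range(100)])
        out = ss.empirical_fdr(df, [f"d{i}" for i in range(1, 100)])
        assert out["p_emp"].loc["d0"] == pytest.approx(1.0)

    def test_bh_matches_textbook_oracle(self):
        # 10 designs at p=0.01, 90 at p=1.0 -> the 10 get fdr 0.1
        lfc = [10.0] * 10 + [0.0] * 90
        silent_lfc = list(np.abs(np.linspace(0.01, 0.99, 99)))
        df = pd.DataFrame(
            {"lfc": lfc + silent_lfc},
            index=[f"d{i}" for i in range(100)] + [f"s{i}" for i in range(99)],
        )
        out = ss.empirical_fdr(df, [f"s{i}" for i in range(99)])
        # the ten top designs exceed every silent control: p = 1/100
        assert np.allclose(out["p_emp"].iloc[:10], 0.01)
        # textbook BH by hand: p * n / rank, monotonized
        p = out["p_emp"].dropna().to_numpy()
        order = np.argsort(p)
        n = len(p)
        adjusted = np.minimum.accumulate(
            (p[order] * n / (np.arange(n) + 1))[::-1]
        )[::-1]
        expect = np.empty(n)
        expect[order] = np.minimum(adjusted, 1.0)
        assert np.allclose(out["fdr"].dropna().to_numpy(), expect)

    def test_too_few_silent_controls_fatal(self):
        df = pd.DataFrame({"lfc": [0.0] * 30}, index=[f"d{i}" for i in range(30)])
        with pytest.raises(ValueError, match="silent controls"):
            ss.empirical_fdr(df, ["d1", "d2"])


class TestSensorCalibration:
    def build(self, n=120, seed=4, n_silent=40):
        rng = np.random.default_rng(seed)
        index = [f"d{i}" for i in range(n)]
        results = pd.DataFrame(
            {"lfc": rng.normal(0, 1, n)}, index=index
        )
        editing = pd.DataFrame(
            {
                "n_sensor_reads": rng.integers(5, 200, n),
                "correct_pct": rng.uniform(0, 60, n),
            },
            index=index,
        )
        silent = index[:n_silent]
        return results, editing, silent

    def test_threshold_boundary_9_9_fails_10_passes(self):
        results, editing, silent = self.build()
        editing.loc["d50", "correct_pct"] = 9.9
        editing.loc["d51", "correct_pct"] = 10.0
        editing.loc[["d50", "d51"], "n_sensor_reads"] = 100
        out = ss.sensor_calibrate(results, editing, silent, 10.0, 10)
        assert not out.loc["d50", "passed_calibration"]
        assert out.loc["d51", "passed_calibration"]

    def test_too_few_sensor_reads_fails_regardless_of_pct(self):
        results, editing, silent = self.build()
        editing.loc["d60"] = {"n_sensor_reads": 8, "correct_pct": 95.0}
        out = ss.sensor_calibrate(results, editing, silent, 10.0, 10)
        assert not out.loc["d60", "passed_calibration"]

    def test_sweep_counts_non_increasing(self):
        results, editing, silent = self.build(n=600, n_silent=300)
        sweep = ss.threshold_sweep(
            results, editing, silent, thresholds=(0, 2, 10, 20, 50)
        )
        considered = sweep["n_considered"].tolist()
        assert considered == sorted(considered, reverse=True)
        sig = sweep["n_significant"].tolist()
        assert sig == sorted(sig, reverse=True)


class TestBestPerVariant:
    def build(self):
        results = pd.DataFrame(
            {
                "lfc": [1.0, 2.0, 0.5, 3.0],
                "zscore": [0.5, 1.0, 0.2, 2.0],
                "sensor_correct_pct": [5.0, 22.0, 15.0, 15.0],
                "sensor_reads": [100, 100, 500, 200],
                "passed_calibration": [True, True, True, True],
            },
            index=["v1_pe01", "v1_pe02", "v2_pe01", "v2_pe02"],
        )
        variant_of = pd.Series(
            ["v1", "v1", "v2", "v2"], index=results.index
        )
        rank_of = pd.Series([1, 2, 1, 2], index=results.index)
        return results, variant_of, rank_of

    def test_argmax_editing_selected(self):
        results, variant_of, rank_of = self.build()
        out = ss.best_per_variant(results, None, variant_of, rank_of)
        assert out.loc["v1", "best_design_id"] == "v1_pe02"

    def test_tie_breaks_by_read_count(self):
        results, variant_of, rank_of = self.build()
        out = ss.best_per_variant(results, None, variant_of, rank_of)
        assert out.loc["v2", "best_design_id"] == "v2_pe01"

    def test_variant_without_calibrated_design_emitted_null(self):
        results, variant_of, rank_of = self.build()
        results.loc[["v2_pe01", "v2_pe02"], "passed_calibration"] = False
        out = ss.best_per_variant(results, None, variant_of, rank_of)
        assert out.loc["v2", "best_design_id"] is None
        assert out.loc["v2", "n_designs_passing"] == 0


class TestCorrelate:
    def test_identity_and_antitone(self):
        t = pd.DataFrame({"x": [1, 2, 3, 4], "y": [-1, -2, -3, -4]})
        t["target"] = t["x"]
        out = ss.correlate(t, "target", ["x", "y"]).set_index("feature")
        assert out.loc["x", "coefficient"] == pytest.approx(1.0)
        assert out.loc["y", "coefficient"] == pytest.approx(-1.0)

    def test_tied_ranks_match_hand_ranked_oracle(self):
        # 5-point toy set with a tie in x: average ranks by hand
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [10.0, 30.0, 20.0, 50.0, 40.0]
        rank_x = [1, 2.5, 2.5, 4, 5]
        rank_y = [1, 3, 2, 5, 4]
        expect = np.corrcoef(rank_x, rank_y)[0, 1]
        out = ss.correlate(
            pd.DataFrame({"x": x, "target": y}), "target", ["x"]
        )
        assert out["coefficient"].iloc[0] == pytest.approx(expect)

    def test_fewer_than_three_pairs_reported_missing(self):
        t = pd.DataFrame({"x": [1.0, 2.0], "target": [1.0, 2.0]})
        out = ss.correlate(t, "target", ["x"])
        assert np.isnan(out["coefficient"].iloc[0])


class TestDeltaZ:
    def make_variants(self):
        return pd.DataFrame(
            {"variant_zscore": [1.5, 0.0, -1.0]},
            index=pd.Index(["v1", "v2", "v3"], name="variant_id"),
        )

    def test_subtraction(self):
        ext = pd.DataFrame({"variant_id": ["v1"], "zscore": [-0.5]})
        out = ss.delta_z(self.make_variants(), ext)
        assert out.loc["v1", "delta_z"] == pytest.approx(2.0)

    def test_identical_tables_give_zero(self):
        ext = pd.DataFrame(
            {"variant_id": ["v1", "v2", "v3"], "zscore": [1.5, 0.0, -1.0]}
        )
        out = ss.delta_z(self.make_variants(), ext)
        assert np.allclose(out["delta_z"], 0.0)

    def test_missing_external_entry_flagged_not_dropped(self):
        ext = pd.DataFrame({"variant_id": ["v1"], "zscore": [0.0]})
        out = ss.delta_z(self.make_variants(), ext)
        assert len(out) == 3
        assert out.loc["v2", "delta_z_missing"]
        assert np.isnan(out.loc["v2", "delta_z"])


class TestSimulationProperties:
    def run_screen(self, manifest, seed, effect_sd=0.3, null_fraction=0.5,
                   depth=300):
        truth = simdata.SimTruth.generate(
            manifest, seed=seed, depth=depth, effect_sd=effect_sd,
            null_fraction=null_fraction,
        )
        counts, summaries, design_truth = simdata.simulate_counts(
            manifest, truth, seed=seed
        )
        results = ss.compute_lfc(
            counts, ["ctrl_r1", "ctrl_r2", "ctrl_r3"],
            ["trt_r1", "trt_r2", "trt_r3"],
        )
        editing = ss.summarize_editing(
            summaries, ["trt_r1", "trt_r2", "trt_r3"]
        )
        silent = manifest.loc[manifest["vclass"] == "silent", "design_id"]
        return results, editing, silent, design_truth.set_index("design_id")

    def test_true_lfc_recovered_with_small_bias(self, small_screen_library):
        """Parameter recovery: mean LFC error below 0.1 log2 units at
        depth >= 500x with 3 replicates per arm."""
        _, _, manifest = small_screen_library
        results, _, _, truth = self.run_screen(manifest, seed=9, depth=500)
        joined = results.dropna(subset=["lfc"]).join(truth["true_lfc"])
        bias = (joined["lfc"] - joined["true_lfc"]).mean()
        assert abs(bias) < 0.1

    def test_calibration_improves_truth_correlation_on_average(
        self, small_screen_library
    ):
        """Mean Spearman(LFC, true effect) over 10 seeds is non-decreasing
        as the minimum sensor-editing threshold rises 0% -> 50%."""
        _, _, manifest = small_screen_library
        thresholds = (0.0, 2.0, 10.0, 20.0, 50.0)
        rows = []
        for seed in range(10):
            results, editing, silent, truth = self.run_screen(
                manifest, seed=100 + seed
            )
            sweep = ss.threshold_sweep(
                results, editing, silent, thresholds=thresholds,
                truth_effect=truth["effect"],
            )
            rows.append(sweep["spearman_lfc_vs_effect"].to_numpy())
        mean_rho = np.vstack(rows).mean(axis=0)
        assert np.all(np.diff(mean_rho) >= -1e-9), mean_rho

    def test_null_screen_controls_fdr(self, small_screen_library):
        """With every effect zero the fraction of designs at fdr < 0.05
        stays at or below nominal (plus binomial error) over 10 seeds."""
        _, _, manifest = small_screen_library
        n_sig = n_total = 0
        for seed in range(10):
            results, editing, silent, _ = self.run_screen(
                manifest, seed=200 + seed, effect_sd=0.0, depth=150
            )
            out = ss.sensor_calibrate(results, editing, silent, 0.0, 0)
            considered = out["passed_calibration"]
            n_total += int(considered.sum())
            n_sig += int(((out["fdr"] < 0.05) & considered).sum())
        se = np.sqrt(0.05 * 0.95 / n_total)
        assert n_sig / n_total <= 0.05 + 2 * se
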