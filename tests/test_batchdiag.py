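"""Per-kit quality metrics, ratio tails, subset PCA, bimodality, concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from conftest import make_calls, make_samples
from varbatch.batchdiag import (
    estimate_capture_efficiency,
    fit_aaf_bimodality,
    maf_concordance,
    partition_tails,
    per_kit_control_maf,
    per_variant_batch_metrics,
    subset_pca_separation,
)
from varbatch.core import KITS
from varbatch.simdata import SimConfig, simulate_dataset


def _two_kit_samples(n_a: int, n_b: int):
    return make_samples(["C1"] * n_a + ["C2"] * n_b)


class TestBatchMetrics:
    def test_single_het_gives_balanced_aaf(self):
        gt = np.array([[1, 1]], dtype=np.int8)
        calls = make_calls(gt, depth=10)  # AD = (5, 5)
        samples = _two_kit_samples(1, 1)
        m = per_variant_batch_metrics(calls, samples)
        assert m.loc[0, "mean_aaf_KitA"] == pytest.approx(0.5)
        assert np.log2(m.loc[0, "mean_aaf_KitA"]) == pytest.approx(-1.0)
        assert m.loc[0, "log2_aaf"] == pytest.approx(0.0)

    def test_log2_ratio_arithmetic(self):
        gt = np.array([[1] * 4], dtype=np.int8)
        calls = make_calls(gt, depth=16)
        calls.ad_alt[0] = [8, 8, 2, 2]  # KitA AAF 0.5, KitB AAF 0.125
        calls.ad_ref[0] = 16 - calls.ad_alt[0]
        samples = _two_kit_samples(2, 2)
        m = per_variant_batch_metrics(calls, samples)
        assert m.loc[0, "log2_aaf"] == pytest.approx(2.0)

    def test_biased_kit_het_aaf_matches_capture_model(self):
        # c=0.3 gives per-read alt probability 0.3/1.3 ~ 0.2308 among true hets
        cfg = SimConfig(
            n_per_center=(150, 200, 200), n_variants=40, n_causal=0,
            n_biased_causal=0, n_biased_null=40, c_biased=0.3,
            base_error=0.0, mean_depth={"KitA": 60.0, "KitB": 60.0}, seed=6,
        )
        truth, samples, calls = simulate_dataset(cfg)
        kit_b = (samples["kit"] == "KitB").to_numpy()
        het = (truth.genotypes == 1) & kit_b[None, :] & (calls.dp > 0)
        aaf = calls.ad_alt / np.maximum(calls.dp, 1)
        assert np.nanmean(aaf[het]) == pytest.approx(0.3 / 1.3, abs=0.01)

    def test_missing_kit_leaves_metric_undefined(self):
        gt = np.array([[1, -1]], dtype=np.int8)
        calls = make_calls(gt)
        samples = _two_kit_samples(1, 1)
        m = per_variant_batch_metrics(calls, samples)
        assert np.isnan(m.loc[0, "mean_gq_KitB"])
        assert np.isnan(m.loc[0, "log2_gq"])


class TestPartitionTails:
    def _metrics(self, values):
        df = pd.DataFrame({"variant_key": [f"v{i}" for i in range(len(values))]})
        for metric in ("gq", "dp", "aaf"):
            df[f"log2_{metric}"] = values
        return df

    def test_hundred_distinct_values_split_5_90_5(self):
        rng = np.random.default_rng(0)
        df = self._metrics(rng.permutation(100).astype(float))
        tails = partition_tails(df)
        counts = tails["tail_aaf"].value_counts()
        assert counts["left5"] == 5 and counts["right5"] == 5
        assert counts["middle90"] == 90

    def test_identical_values_have_zero_width_tails(self):
        df = self._metrics(np.zeros(50))
        tails = partition_tails(df)
        assert (tails["tail_aaf"] == "middle90").all()
        assert not tails["tail_any"].any()

    def test_requires_enough_defined_ratios(self):
        df = self._metrics(np.full(10, 1.0))
        with pytest.raises(ValueError):
            partition_tails(df)

    def test_planted_bias_lands_in_aaf_tails(self):
        hits = total = 0
        for seed in range(5):
            cfg = SimConfig(
                n_per_center=(200, 150, 100), n_variants=300, n_causal=0,
                n_biased_causal=0, n_biased_null=15, seed=seed,
            )
            truth, samples, calls = simulate_dataset(cfg)
            m = per_variant_batch_metrics(calls, samples)
            tails = partition_tails(m)
            member = tails["tail_aaf"].to_numpy()
            hits += (member[truth.biased_idx] != "middle90").sum()
            total += len(truth.biased_idx)
        assert hits / total >= 0.9


class TestSubsetPcaSeparation:
    def test_random_kit_labels_score_near_zero(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            gt = np.random.default_rng(seed).binomial(2, 0.3, (40, 200)).astype(np.int8)
            calls = make_calls(gt)
            samples = _two_kit_samples(100, 100)
            score = subset_pca_separation(calls, samples, np.arange(40))
            assert abs(score) < 0.05

    def test_kit_exclusive_genotypes_separate_clearly(self):
        n_a, n_b = 80, 80
        rng = np.random.default_rng(2)
        gt = np.zeros((20, n_a + n_b), dtype=np.int8)
        gt[:, :n_a] = rng.binomial(2, 0.5, (20, n_a))  # polymorphic only in KitA
        calls = make_calls(gt)
        samples = _two_kit_samples(n_a, n_b)
        score = subset_pca_separation(calls, samples, np.arange(20))
        assert score > 0.5

    def test_subset_too_small_rejected(self):
        calls = make_calls(np.zeros((3, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            subset_pca_separation(calls, _two_kit_samples(2, 2), np.array([0]))


class TestBimodality:
    def test_single_gaussian_not_flagged(self):
        rng = np.random.default_rng(3)
        fit = fit_aaf_bimodality(rng.normal(-1.0, 0.5, size=500))
        assert not fit.bimodal
        assert fit.bic_one <= fit.bic_two + 10

    def test_well_separated_mixture_recovered(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate(
            [rng.normal(-1.0, 0.4, 400), rng.normal(-6.0, 0.6, 200)]
        )
        fit = fit_aaf_bimodality(vals)
        assert fit.bimodal
        assert fit.means[0] == pytest.approx(-6.0, abs=0.5)
        assert fit.means[1] == pytest.approx(-1.0, abs=0.5)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_nonfinite_values_dropped_with_count(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(-1, 0.3, 100), [np.nan, -np.inf]])
        fit = fit_aaf_bimodality(vals)
        assert fit.n_dropped == 2


class TestMafConcordance:
    def test_printed_example_winner_is_unbiased_kit(self):
        # unbiased-kit control MAF 0.056 vs biased-kit 0.006, reference 0.0906
        kit_mafs = pd.DataFrame(
            {"variant_key": ["v1"], "maf_KitA": [0.056], "maf_KitB": [0.006]}
        )
        df, summary = maf_concordance(kit_mafs, {"v1": 0.0906})
        assert df.loc[0, "winner"] == "KitA"
        assert summary["wins_KitA"] == 1

    def test_equal_distances_tie(self):
        kit_mafs = pd.DataFrame(
            {"variant_key": ["v1"], "maf_KitA": [0.08], "maf_KitB": [0.12]}
        )
        df, _ = maf_concordance(kit_mafs, {"v1": 0.10})
        assert df.loc[0, "winner"] == "none"

    def test_absent_reference_variants_skipped(self):
        kit_mafs = pd.DataFrame(
            {"variant_key": ["v1", "v2"], "maf_KitA": [0.1, 0.1], "maf_KitB": [0.2, 0.2]}
        )
        _, summary = maf_concordance(kit_mafs, {"v1": 0.1})
        assert summary["skipped"] == 1

    def test_unbiased_kits_split_winners_evenly(self):
        # equal-sized kits, no bias: winner is sampling noise, ~50/50
        cfg = SimConfig(
            n_per_center=(400, 200, 200), n_variants=400, n_causal=0,
            n_biased_causal=0, n_biased_null=0, seed=8,
        )
        truth, samples, calls = simulate_dataset(cfg)
        kit_mafs = per_kit_control_maf(calls, samples)
        ref = dict(zip(calls.variant_keys(), truth.population_maf()))
        _, summary = maf_concordance(kit_mafs, ref)
        wins = summary["wins_KitA"], summary["wins_KitB"]
        assert binomtest(wins[0], sum(wins), 0.5).pvalue > 0.01


class TestCaptureEfficiency:
    def test_balanced_het_implies_unit_efficiency(self):
        gt = np.array([[1, 1]], dtype=np.int8)
        calls = make_calls(gt, depth=10)
        samples = _two_kit_samples(1, 1)
        est = estimate_capture_efficiency(calls, samples, "KitA")
        assert est.loc[0, "c_hat"] == pytest.approx(1.0)

    def test_one_third_aaf_implies_half_efficiency(self):
        gt = np.array([[1]], dtype=np.int8)
        calls = make_calls(gt, depth=9)
        calls.ad_alt[0] = [3]
        calls.ad_ref[0] = [6]
        samples = make_samples(["C1"])
        est = estimate_capture_efficiency(calls, samples, "KitA")
        assert est.loc[0, "c_hat"] == pytest.approx(0.5)

    def test_no_carriers_undefined(self):
        gt = np.zeros((1, 4), dtype=np.int8)
        calls = make_calls(gt)
        est = estimate_capture_efficiency(calls, _two_kit_samples(2, 2), "KitB")
        assert np.isnan(est.loc[0, "c_hat"])


class TestGqContrast:
    def test_biased_kit_has_lower_gq_at_planted_variants(self):
        lower = total = 0
        for seed in range(3):
            cfg = SimConfig(
                n_per_center=(150, 120, 80), n_variants=120, n_causal=0,
                n_biased_causal=0, n_biased_null=20, seed=seed,
            )
            truth, samples, calls = simulate_dataset(cfg)
            m = per_variant_batch_metrics(calls, samples)
            ga = m["mean_gq_KitA"].to_numpy()[truth.biased_idx]
            gb = m["mean_gq_KitB"].to_numpy()[truth.biased_idx]
            lower += (gb < ga).sum()
            total += len(truth.biased_idx)
        assert binomtest(lower, total, alternative="greater").pvalue < 1e-4
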