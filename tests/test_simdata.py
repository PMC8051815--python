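"""Generator behaviour: population model, read model, caller, emission."""

import subprocess

import numpy as np
import pytest
from scipy.stats import binom, binomtest

from varbatch import io as vio
from varbatch.core import KITS, MISSING
from varbatch.simdata import (
    SimConfig,
    alt_read_probability,
    call_genotypes,
    emit_dataset,
    simulate_cohort,
    simulate_dataset,
)


class TestSimulateCohort:
    def test_fst_zero_degenerates_to_ancestral_frequency(self):
        cfg = SimConfig(
            n_per_center=(30, 30, 30), n_variants=40, k_subpops=3, fst=0.0,
            n_causal=0, n_biased_causal=0, n_biased_null=0, seed=1,
        )
        truth, _ = simulate_cohort(cfg)
        assert np.allclose(truth.subpop_freqs, truth.ancestral_maf[:, None])

    def test_causal_variants_enrich_case_maf_in_truth(self):
        # planted odds ratios must raise the alt frequency among cases
        wins = 0
        for seed in range(10):
            cfg = SimConfig(
                n_per_center=(1400, 1400, 1200), n_variants=30, n_causal=2,
                causal_or=2.0, causal_maf_range=(0.15, 0.25),
                n_biased_causal=0, n_biased_null=0, seed=seed,
            )
            truth, samples = simulate_cohort(cfg)
            y = samples["phenotype"].to_numpy() == "case"
            for i in truth.causal_idx:
                g = truth.genotypes[i]
                if g[y].mean() > g[~y].mean():
                    wins += 1
        assert wins == 20

    def test_same_seed_reproduces_truth_exactly(self):
        cfg = SimConfig(n_per_center=(20, 20, 20), n_variants=25, n_causal=2,
                        n_biased_causal=1, n_biased_null=1, seed=5)
        t1, s1 = simulate_cohort(cfg)
        t2, s2 = simulate_cohort(cfg)
        assert np.array_equal(t1.genotypes, t2.genotypes)
        assert np.array_equal(t1.capture_c, t2.capture_c)
        assert s1.equals(s2)

    def test_kit_is_deterministic_function_of_center(self, tiny_cohort):
        _, _, samples, _ = tiny_cohort
        assert (samples.loc[samples.center == "C1", "kit"] == "KitA").all()
        assert (samples.loc[samples.center != "C1", "kit"] == "KitB").all()

    def test_genotypes_are_valid_dosages(self, tiny_cohort):
        _, truth, _, _ = tiny_cohort
        assert set(np.unique(truth.genotypes)) <= {0, 1, 2}

    @pytest.mark.parametrize(
        "bad",
        [
            {"k_subpops": 0},
            {"n_per_center": (0, 10, 10)},
            {"fst": 1.0},
            {"prevalence": 0.0},
            {"n_biased_causal": 5, "n_causal": 2},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        cfg = SimConfig(**bad)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_unattainable_prevalence_raises(self):
        cfg = SimConfig(
            n_per_center=(20, 20, 20), n_variants=10, n_causal=0,
            n_biased_causal=0, n_biased_null=0,
            subpop_logit_shift=[-100.0, -100.0, -100.0], k_subpops=3,
            prevalence=0.999, seed=0,
        )
        with pytest.raises(ValueError, match="prevalence"):
            simulate_cohort(cfg)


class TestReadModel:
    def test_het_alt_probability_unbiased(self):
        assert alt_read_probability(np.array([1]), np.array([1.0]), 0.0)[0] == 0.5

    def test_het_alt_fraction_matches_closed_form_monte_carlo(self):
        # at capture efficiency c the het alt-read fraction is c/(1+c)
        rng = np.random.default_rng(42)
        pi = alt_read_probability(np.array([1]), np.array([0.3]), 0.0)[0]
        draws = rng.random(100_000) < pi
        expected = 0.3 / 1.3
        assert pi == pytest.approx(expected, abs=1e-12)
        assert draws.mean() == pytest.approx(expected, abs=3 * 0.5 / np.sqrt(1e5))

    def test_caller_matches_bruteforce_likelihoods(self):
        eps = 0.01
        ad_ref, ad_alt = np.array([10]), np.array([0])
        g, gq = call_genotypes(ad_ref, ad_alt, eps)
        liks = np.array(
            [binom.pmf(0, 10, p) for p in (eps, 0.5, 1 - eps)]
        )
        post = liks / liks.sum()
        assert g[0] == 0
        expected_gq = min(round(-10 * np.log10(1 - post[0])), 99)
        assert gq[0] == expected_gq

    def test_caller_prefers_het_for_balanced_reads(self):
        g, gq = call_genotypes(np.array([15]), np.array([14]), 0.005)
        assert g[0] == 1 and gq[0] > 30

    def test_unbiased_het_aaf_centers_on_half(self):
        cfg = SimConfig(
            n_per_center=(80, 60, 60), n_variants=60, fst=0.0, k_subpops=1,
            n_causal=0, n_biased_causal=0, n_biased_null=0,
            base_error=0.0, seed=3,
        )
        truth, samples, calls = simulate_dataset(cfg)
        het = truth.genotypes == 1
        aaf = calls.ad_alt / np.maximum(calls.dp, 1)
        vals = aaf[het & (calls.dp > 0)]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.5) < 3 * max(se, 1e-4)

    def test_biased_kit_depresses_called_maf(self):
        # paired one-sided sign test over planted variants, several seeds
        from varbatch.qc import folded_maf

        worse = total = 0
        for seed in range(5):
            cfg = SimConfig(
                n_per_center=(150, 120, 80), n_variants=60, n_causal=0,
                n_biased_causal=0, n_biased_null=24, c_biased=0.05, seed=seed,
            )
            truth, samples, calls = simulate_dataset(cfg)
            kit_b = (samples["kit"] == "KitB").to_numpy()
            for i in truth.biased_idx:
                maf_a = folded_maf(calls.gt[[i]][:, ~kit_b])[0]
                maf_b = folded_maf(calls.gt[[i]][:, kit_b])[0]
                total += 1
                if maf_b < maf_a:
                    worse += 1
        assert binomtest(worse, total, alternative="greater").pvalue < 1e-6

    def test_capture_efficiency_estimator_recovers_c_from_allele_balance(self):
        cfg = SimConfig(
            n_per_center=(100, 150, 150), n_variants=30, n_causal=0,
            n_biased_causal=0, n_biased_null=30, c_biased=0.4,
            mean_depth={"KitA": 60.0, "KitB": 60.0}, base_error=0.0, seed=9,
        )
        truth, samples, calls = simulate_dataset(cfg)
        from varbatch.batchdiag import estimate_capture_efficiency

        est = estimate_capture_efficiency(
            calls, samples, "KitB", het_mask=truth.genotypes == 1
        )
        assert abs(est["c_hat"].mean() - 0.4) < 0.05

    def test_missing_when_depth_below_floor(self):
        cfg = SimConfig(
            n_per_center=(40, 30, 30), n_variants=40, n_causal=0,
            n_biased_causal=0, n_biased_null=0,
            mean_depth={"KitA": 3.0, "KitB": 3.0}, min_call_depth=4, seed=2,
        )
        _, _, calls = simulate_dataset(cfg)
        low = calls.dp < 4
        assert (calls.gt[low] == MISSING).all()
        assert (calls.gq[calls.gt == MISSING] == MISSING).all()


class TestEmitDataset:
    def test_empty_variant_list_gives_header_only_vcf(self, tmp_path):
        from conftest import make_calls, make_samples

        calls = make_calls(np.zeros((0, 3), dtype=np.int8))
        samples = make_samples(["C1", "C2", "C3"])[:3]
        samples["sample_id"] = calls.samples
        paths = emit_dataset(calls, samples, None, tmp_path)
        text = paths["vcf"].read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert all(line.startswith("#") for line in text.splitlines() if line)

    def test_roundtrip_preserves_genotype_matrix(self, tiny_cohort, tmp_path):
        _, truth, samples, calls = tiny_cohort
        paths = emit_dataset(calls, samples, truth, tmp_path)
        back = vio.read_vcf(paths["vcf"])
        assert np.array_equal(back.gt, calls.gt)
        assert np.array_equal(back.ad_alt, calls.ad_alt)
        meta = vio.read_metadata(paths["metadata"])
        assert meta["sample_id"].tolist() == calls.samples

    def test_output_parses_under_external_vcf_tools(self, tmp_path):
        cfg = SimConfig(
            n_per_center=(40, 30, 30), n_variants=50, n_causal=0,
            n_biased_causal=0, n_biased_null=0, seed=4,
        )
        truth, samples, calls = simulate_dataset(cfg)
        paths = emit_dataset(calls, samples, truth, tmp_path)
        proc = subprocess.run(
            ["bcftools", "view", "-H", str(paths["vcf"])],
            capture_output=True,
            text=True,
        )
        assert proc.returncode == 0, proc.stderr
        assert len(proc.stdout.strip().splitlines()) == 50
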