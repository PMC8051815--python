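"""Synthetic two-kit / three-center case-control exome cohort generator.

The generator emulates the design that motivates the pipeline: three
sequencing centers, where Center 1 uses capture kit A and Centers 2 and 3
share kit B; several latent subpopulations with Balding–Nichols allele
frequencies; a logistic disease model with a handful of causal variants; and
— the crux — variant-specific allelic capture bias.  Capture efficiency ``c``
is the relative probability that an alternative-allele template is captured
versus a reference template, so a heterozygote sequenced with efficiency c
yields alt reads with probability c/(1+c).  c < 1 therefore both depresses
the alternative allele fraction and, through genotype calling, causes allele
dropout in the biased kit — the mechanism behind kit-exclusive association
signals.

Read counts are drawn per sample x variant: total depth is negative binomial
with a kit-specific mean (scaled by (1+c)/2 for hets and by c for alt
homozygotes, reflecting the loss of alt templates), each read is alt with
probability pi(g, c, eps), and genotypes are re-called by maximum binomial
likelihood over the three canonical alt fractions {eps, 1/2, 1-eps} with a
flat prior.  GQ is the phred-scaled complement of the called genotype's
posterior, capped at 99.  Calls with depth below a floor are set missing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .core import CENTERS, KIT_OF_CENTER, KITS, MISSING, CallMatrix

# age model used only by the optional age-adjusted association model: cases
# are older than controls, so age confounds with phenotype by design.
AGE_MEAN_CONTROL = 72.0
AGE_MEAN_CASE = 78.0
AGE_SD = 8.0

_CHROMS = [str(c) for c in range(1, 23)]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the three-center / two-kit study design at reduced scale:
    center sizes keep the 4427:3260:2217 ratio, causal odds ratios and
    control-side minor allele frequencies sit in the range implied by the
    study's top-variant table, and the biased-kit capture efficiency of 0.01
    puts the depressed AAF mode near log2(AAF) ~ -6.
    """

    n_per_center: tuple[int, int, int] = (1788, 1317, 895)
    n_variants: int = 1000
    k_subpops: int = 3
    fst: float = 0.01
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    causal_maf_range: tuple[float, float] = (0.05, 0.12)
    prevalence: float = 0.5
    n_causal: int = 10
    causal_or: float | list[float] = 4.0
    n_biased_causal: int = 7
    n_biased_null: int = 8
    c_biased: float = 0.01
    biased_kit: str = "KitB"
    mean_depth: dict[str, float] = field(default_factory=lambda: {"KitA": 40.0, "KitB": 40.0})
    depth_dispersion: float = 8.0
    base_error: float = 0.005
    min_call_depth: int = 4
    n_vqsr_fail: int = 0
    subpop_logit_shift: list[float] | None = None
    major_locus_index: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.k_subpops < 1:
            raise ValueError("k_subpops must be >= 1")
        if len(self.n_per_center) != 3 or any(n <= 0 for n in self.n_per_center):
            raise ValueError("n_per_center must be three positive counts")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        for lo, hi in (self.ancestral_maf_range, self.causal_maf_range):
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError("MAF ranges must satisfy 0 < lo <= hi < 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_causal < 0 or self.n_causal > self.n_variants:
            raise ValueError("n_causal out of range")
        if self.n_biased_causal > self.n_causal:
            raise ValueError("n_biased_causal exceeds n_causal")
        if self.n_biased_causal + self.n_biased_null > self.n_variants:
            raise ValueError("more biased variants than variants")
        if not 0.0 < self.c_biased <= 1.0:
            raise ValueError("c_biased must be in (0, 1]")
        if self.biased_kit not in KITS:
            raise ValueError(f"biased_kit must be one of {KITS}")
        if any(d <= 0 for d in self.mean_depth.values()):
            raise ValueError("mean depths must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if not 0.0 <= self.base_error < 0.5:
            raise ValueError("base_error must be in [0, 0.5)")
        if self.min_call_depth < 1:
            raise ValueError("min_call_depth must be >= 1")
        if self.subpop_logit_shift is not None and len(self.subpop_logit_shift) != self.k_subpops:
            raise ValueError("subpop_logit_shift length must equal k_subpops")

    def causal_betas(self) -> np.ndarray:
        ors = self.causal_or
        if np.isscalar(ors):
            ors = [float(ors)] * self.n_causal
        if len(ors) != self.n_causal:
            raise ValueError("causal_or list length must equal n_causal")
        return np.log(np.asarray(ors, dtype=float))


@dataclass
class TruthTable:
    """Simulation ground truth used by recovery tests and diagnostics."""

    genotypes: np.ndarray  # (m, n) int8 alt dosage
    subpop_freqs: np.ndarray  # (m, k)
    sample_subpop: np.ndarray  # (n,) int
    causal_idx: np.ndarray  # indices into variants
    causal_beta: np.ndarray  # per-variant log odds (len m)
    capture_c: np.ndarray  # (m, 2) efficiency per kit, columns ordered as KITS
    biased_idx: np.ndarray
    ancestral_maf: np.ndarray  # (m,)

    def population_maf(self) -> np.ndarray:
        """True cohort-wide alt-allele frequency, folded to the minor allele."""
        f = self.genotypes.mean(axis=1) / 2.0
        return np.minimum(f, 1.0 - f)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "genotypes": self.genotypes.tolist(),
            "subpop_freqs": self.subpop_freqs.tolist(),
            "sample_subpop": self.sample_subpop.tolist(),
            "causal_idx": self.causal_idx.tolist(),
            "causal_beta": self.causal_beta.tolist(),
            "capture_c": self.capture_c.tolist(),
            "biased_idx": self.biased_idx.tolist(),
            "ancestral_maf": self.ancestral_maf.tolist(),
        }
        Path(path).write_text(json.dumps(obj, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        obj = json.loads(Path(path).read_text())
        return cls(
            genotypes=np.asarray(obj["genotypes"], dtype=np.int8),
            subpop_freqs=np.asarray(obj["subpop_freqs"], dtype=float),
            sample_subpop=np.asarray(obj["sample_subpop"], dtype=int),
            causal_idx=np.asarray(obj["causal_idx"], dtype=int),
            causal_beta=np.asarray(obj["causal_beta"], dtype=float),
            capture_c=np.asarray(obj["capture_c"], dtype=float),
            biased_idx=np.asarray(obj["biased_idx"], dtype=int),
            ancestral_maf=np.asarray(obj["ancestral_maf"], dtype=float),
        )


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _balding_nichols(rng, p: np.ndarray, fst: float, k: int) -> np.ndarray:
    """Subpopulation frequencies around ancestral p at divergence F_ST."""
    if fst == 0.0:
        return np.repeat(p[:, None], k, axis=1)
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a[:, None], b[:, None], size=(len(p), k))


def _solve_intercept(linear: np.ndarray, prevalence: float) -> float:
    """Bisect the logistic intercept so mean risk equals the target prevalence."""

    def gap(b0: float) -> float:
        return float(expit(b0 + linear).mean() - prevalence)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("target prevalence unattainable for the given effects")
    return brentq(gap, lo, hi, xtol=1e-10)


def simulate_cohort(config: SimConfig) -> tuple[TruthTable, pd.DataFrame]:
    """Draw ground-truth genotypes, sample metadata, and phenotypes.

    Genotypes are Hardy-Weinberg draws from each sample's subpopulation
    frequency.  Phenotype follows an additive logistic model over the causal
    variants, with the intercept solved numerically to hit the configured
    prevalence; optional per-subpopulation intercept shifts create
    population-structure confounding.
    """
    config.validate()
    rng_freq, rng_geno, rng_meta, rng_pheno = _rngs(config.seed, 4)

    m, k = config.n_variants, config.k_subpops
    lo, hi = config.ancestral_maf_range
    p_anc = rng_freq.uniform(lo, hi, size=m)

    causal_idx = np.sort(rng_freq.choice(m, size=config.n_causal, replace=False))
    clo, chi = config.causal_maf_range
    p_anc[causal_idx] = rng_freq.uniform(clo, chi, size=config.n_causal)

    subpop_freqs = _balding_nichols(rng_freq, p_anc, config.fst, k)
    np.clip(subpop_freqs, 1e-6, 1.0 - 1e-6, out=subpop_freqs)

    n = int(sum(config.n_per_center))
    sample_subpop = rng_geno.integers(0, k, size=n)
    geno = rng_geno.binomial(2, subpop_freqs[:, sample_subpop]).astype(np.int8)

    beta = np.zeros(m)
    beta[causal_idx] = config.causal_betas()

    linear = beta[causal_idx] @ geno[causal_idx].astype(float)
    if config.subpop_logit_shift is not None:
        linear = linear + np.asarray(config.subpop_logit_shift)[sample_subpop]
    b0 = _solve_intercept(linear, config.prevalence)
    y = rng_pheno.random(n) < expit(b0 + linear)

    centers = np.repeat(CENTERS, config.n_per_center)
    major = config.major_locus_index
    if major is None and len(causal_idx):
        major = int(causal_idx[0])
    apoe_cov = geno[major].astype(int) if major is not None else np.zeros(n, dtype=int)

    age = np.where(
        y,
        rng_meta.normal(AGE_MEAN_CASE, AGE_SD, size=n),
        rng_meta.normal(AGE_MEAN_CONTROL, AGE_SD, size=n),
    ).round(1)

    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "center": centers,
            "kit": [KIT_OF_CENTER[c] for c in centers],
            "sex": rng_meta.choice(["M", "F"], size=n),
            "phenotype": np.where(y, "case", "control"),
            "apoe_cov": apoe_cov,
            "age": age,
        }
    )

    capture_c = np.ones((m, 2))
    n_bias = config.n_biased_causal + config.n_biased_null
    biased_idx = np.array([], dtype=int)
    if n_bias > 0:
        bc = rng_freq.choice(causal_idx, size=config.n_biased_causal, replace=False)
        noncausal = np.setdiff1d(np.arange(m), causal_idx)
        bn = rng_freq.choice(noncausal, size=config.n_biased_null, replace=False)
        biased_idx = np.sort(np.concatenate([bc, bn]))
        capture_c[biased_idx, KITS.index(config.biased_kit)] = config.c_biased

    truth = TruthTable(
        genotypes=geno,
        subpop_freqs=subpop_freqs,
        sample_subpop=sample_subpop,
        causal_idx=causal_idx,
        causal_beta=beta,
        capture_c=capture_c,
        biased_idx=biased_idx,
        ancestral_maf=p_anc,
    )
    return truth, samples


def alt_read_probability(g: np.ndarray, c: np.ndarray, eps: float) -> np.ndarray:
    """P(read is alt | genotype g, capture efficiency c, base error eps).

    Hets contribute alt templates with relative weight c, so the alt-read
    probability is c/(1+c) before sequencing error.
    """
    g = np.asarray(g)
    het = c / (1.0 + c) * (1.0 - eps) + 1.0 / (1.0 + c) * eps
    return np.select([g == 0, g == 1], [np.broadcast_to(eps, het.shape), het], default=1.0 - eps)


def _depth_scale(g: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Relative template availability: hets lose half the alt templates
    proportionally to (1-c)/2, alt homozygotes scale fully with c."""
    return np.select([g == 0, g == 1], [np.ones_like(c), (1.0 + c) / 2.0], default=c)


def call_genotypes(
    ad_ref: np.ndarray, ad_alt: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-prior maximum-binomial-likelihood genotype calls.

    Candidate alt fractions are {eps, 1/2, 1-eps}.  Returns (called dosage,
    GQ) where GQ = round(-10 log10(1 - posterior of the call)), capped at 99.
    """
    p = np.clip(np.array([eps, 0.5, 1.0 - eps]), 1e-12, 1.0 - 1e-12)
    ll = (
        ad_alt[..., None] * np.log(p)
        + ad_ref[..., None] * np.log1p(-p)
    )
    g = np.argmax(ll, axis=-1).astype(np.int8)
    log_post = ll - logsumexp(ll, axis=-1, keepdims=True)
    post = np.exp(np.take_along_axis(log_post, g[..., None].astype(int), axis=-1))[..., 0]
    gq = np.minimum(
        np.round(-10.0 * np.log10(np.clip(1.0 - post, 1e-12, 1.0))), 99
    ).astype(np.int16)
    return g, gq


def _variant_positions(m: int, rng) -> pd.DataFrame:
    """Exome-like site table: sites laid sequentially along chromosomes 1-22
    with 2-10 kb spacing, alternating transition/transversion alleles."""
    per_chrom = int(np.ceil(m / len(_CHROMS)))
    chroms, positions = [], []
    for ch in _CHROMS:
        steps = rng.integers(2_000, 10_000, size=per_chrom)
        pos = 10_000 + np.cumsum(steps)
        chroms.extend([ch] * per_chrom)
        positions.extend(pos.tolist())
        if len(chroms) >= m:
            break
    pairs_ti = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    pairs_tv = [("A", "C"), ("C", "G"), ("G", "T"), ("T", "A")]
    # transition-rich composition (Ti/Tv ~ 4 among called sites);
    # at desk-scale variant counts the per-sample Ti/Tv estimate is noisy, so
    # the cohort mean must sit well above the 2.75 QC floor
    kinds = rng.random(m) < 0.80
    refs, alts = [], []
    for i in range(m):
        pool = pairs_ti if kinds[i] else pairs_tv
        r, a = pool[int(rng.integers(len(pool)))]
        refs.append(r)
        alts.append(a)
    return pd.DataFrame(
        {"chrom": chroms[:m], "pos": positions[:m], "ref": refs, "alt": alts}
    )


def simulate_calls(
    truth: TruthTable,
    samples: pd.DataFrame,
    config: SimConfig,
    chunk_rows: int = 512,
) -> CallMatrix:
    """Simulate read support and re-call genotypes for the whole cohort."""
    config.validate()
    m, n = truth.genotypes.shape
    if len(samples) != n:
        raise ValueError("truth/sample dimensions inconsistent")
    rng_pos, rng_reads, rng_vq = _rngs(config.seed, 7)[4:7]

    kit_idx = samples["kit"].map({k: i for i, k in enumerate(KITS)}).to_numpy()
    d_kit = np.array([config.mean_depth[k] for k in KITS])[kit_idx]  # (n,)
    eps = config.base_error
    disp = config.depth_dispersion

    gt = np.empty((m, n), dtype=np.int8)
    gq = np.empty((m, n), dtype=np.int16)
    ad_ref = np.empty((m, n), dtype=np.int32)
    ad_alt = np.empty((m, n), dtype=np.int32)

    for start in range(0, m, chunk_rows):
        sl = slice(start, min(start + chunk_rows, m))
        g = truth.genotypes[sl].astype(np.int16)
        c = truth.capture_c[sl][:, kit_idx]  # (b, n)
        mean = d_kit[None, :] * _depth_scale(g, c)
        dp = rng_reads.negative_binomial(disp, disp / (disp + mean))
        pi = alt_read_probability(g, c, eps)
        alt = rng_reads.binomial(dp, pi)
        ref = dp - alt
        called, quals = call_genotypes(ref, alt, eps)
        low = dp < config.min_call_depth
        called = np.where(low, MISSING, called).astype(np.int8)
        quals = np.where(low, MISSING, quals).astype(np.int16)
        gt[sl], gq[sl] = called, quals
        ad_ref[sl], ad_alt[sl] = ref.astype(np.int32), alt.astype(np.int32)

    sites = _variant_positions(m, rng_pos)
    vqslod = np.abs(rng_vq.normal(4.0, 2.0, size=m)) + 0.01
    if config.n_vqsr_fail > 0:
        fail = rng_vq.choice(m, size=config.n_vqsr_fail, replace=False)
        vqslod[fail] = -np.abs(rng_vq.normal(2.0, 1.0, size=config.n_vqsr_fail)) - 0.01
    sites["vqslod"] = np.round(vqslod, 4)

    return CallMatrix(
        sites=sites,
        samples=samples["sample_id"].tolist(),
        gt=gt,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        dp=(ad_ref + ad_alt),
        gq=gq,
    )


def emit_dataset(
    calls: CallMatrix,
    samples: pd.DataFrame,
    truth: TruthTable | None,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the VCF + metadata TSV (+ truth JSON) bundle for a cohort."""
    from . import io as vio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "metadata": outdir / "samples.tsv",
    }
    vio.write_vcf(calls, paths["vcf"])
    vio.write_metadata(samples, paths["metadata"])
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        truth.to_json(paths["truth"])
    return paths


def simulate_dataset(config: SimConfig) -> tuple[TruthTable, pd.DataFrame, CallMatrix]:
    """Convenience wrapper: cohort truth -> read-level calls in one step."""
    truth, samples = simulate_cohort(config)
    calls = simulate_calls(truth, samples, config)
    return truth, samples, calls
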