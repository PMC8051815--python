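"""Sample-level QC, variant-level association filters, and PCA-set pruning.

Default thresholds are the study's printed values: per-sample SNP call rate
> 95%, depth >= 10x at >= 90% of called variants, exonic Ti/Tv > 2.75;
variant retention for association requires VQSLOD > 0, Hardy-Weinberg exact
p >= 1e-6 in controls, and >= 10 alt-supporting reads across the cohort; the
ancestry-PCA set additionally drops MAF < 5%, HWE p < 1e-4, configured
high-variability regions, and one of each variant pair with dosage r^2 > 0.2
inside 0.1 Mb windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, CallMatrix, is_transition

log = logging.getLogger(__name__)

_TIE_REL_TOL = 1e-9  # relative slack when comparing heterozygote-count probabilities


@dataclass
class QCThresholds:
    snp_call_rate: float = 0.95
    depth_fraction: float = 0.90
    depth_min: int = 10
    titv_floor: float = 2.75
    hwe_assoc_p: float = 1e-6
    cohort_alt_reads: int = 10
    vqslod_floor: float = 0.0
    prune_maf: float = 0.05
    prune_hwe_p: float = 1e-4
    ld_r2: float = 0.2
    ld_window_bp: int = 100_000
    # 0-based half-open (chrom, start, end); empty for synthetic genomes
    excluded_regions: list[tuple[str, int, int]] = field(default_factory=list)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed one (two-sided "probability <= observed" summation).  The
    distribution over the heterozygote count h, for n_r minor alleles among
    2N, is evaluated with the standard multiplicative recurrence.
    Monomorphic tables return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_alt = 2 * n_aa + n_Aa
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0

    # heterozygote counts share the parity of the rare-allele count
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = np.zeros(n_rare + 1)
    probs[mid] = 1.0
    het = mid
    while het >= 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    het = mid
    while het <= n_rare - 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2) * (het + 1))
        het += 2
    probs /= probs.sum()

    obs = min(n_Aa, n_rare)  # fold to the rare allele
    p = probs[np.nonzero(probs <= probs[obs] * (1.0 + _TIE_REL_TOL))].sum()
    return float(min(p, 1.0))


def genotype_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant (hom-ref, het, hom-alt) counts over called genotypes."""
    n0 = (gt == 0).sum(axis=1)
    n1 = (gt == 1).sum(axis=1)
    n2 = (gt == 2).sum(axis=1)
    return n0, n1, n2


def hwe_p_per_variant(gt: np.ndarray) -> np.ndarray:
    n0, n1, n2 = genotype_counts(gt)
    out = np.ones(gt.shape[0])
    for i in range(gt.shape[0]):
        tot = n0[i] + n1[i] + n2[i]
        if tot > 0:
            out[i] = hwe_exact_p(int(n0[i]), int(n1[i]), int(n2[i]))
    return out


def folded_maf(gt: np.ndarray) -> np.ndarray:
    """Minor allele frequency from called genotypes (NaN if none called)."""
    called = gt != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, gt, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = alt / (2.0 * n_called)
    f = np.where(n_called > 0, f, np.nan)
    return np.minimum(f, 1.0 - f)


def sample_qc(
    calls: CallMatrix,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Per-sample pass/fail with reasons (call rate, depth profile, Ti/Tv)."""
    if calls.n_variants < 1:
        raise ValueError("sample QC needs at least one variant")
    th = thresholds or QCThresholds()
    called = calls.gt != MISSING
    call_rate = called.mean(axis=0)

    deep = (calls.dp >= th.depth_min) & called
    with np.errstate(invalid="ignore", divide="ignore"):
        depth_frac = deep.sum(axis=0) / called.sum(axis=0)

    ti_mask = np.array(
        [is_transition(r, a) for r, a in zip(calls.sites["ref"], calls.sites["alt"])]
    )
    carrier = (calls.gt >= 1) & called
    ti = carrier[ti_mask].sum(axis=0).astype(float)
    tv = carrier[~ti_mask].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        titv = np.where(tv > 0, ti / tv, np.where(ti > 0, np.inf, np.nan))

    rows = []
    for j, sid in enumerate(calls.samples):
        reasons = []
        if call_rate[j] <= th.snp_call_rate:
            reasons.append("call_rate")
        if not np.isnan(depth_frac[j]) and depth_frac[j] < th.depth_fraction:
            reasons.append("depth")
        if not np.isnan(titv[j]) and titv[j] <= th.titv_floor:
            reasons.append("titv")
        rows.append(
            {
                "sample_id": sid,
                "call_rate": call_rate[j],
                "depth_fraction": depth_frac[j],
                "titv": titv[j],
                "pass": not reasons,
                "reasons": ",".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def _is_biallelic_snp(sites: pd.DataFrame) -> np.ndarray:
    ok_len = (sites["ref"].str.len() == 1) & (sites["alt"].str.len() == 1)
    bases = {"A", "C", "G", "T"}
    ok_base = sites["ref"].isin(bases) & sites["alt"].isin(bases)
    return (ok_len & ok_base).to_numpy()


def variant_filters(
    calls: CallMatrix,
    control_mask: np.ndarray,
    thresholds: QCThresholds | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Association-analysis variant retention.

    Returns (indices of retained variants, per-filter exclusion counts).  The
    filters are evaluated independently, so application order cannot change
    the retained set; a variant failing several filters increments each
    count.
    """
    th = thresholds or QCThresholds()
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.sum() == 0:
        raise ValueError("control subset is empty")

    fail_snp = ~_is_biallelic_snp(calls.sites)
    fail_vqsr = ~(calls.sites["vqslod"].to_numpy() > th.vqslod_floor)
    fail_alt = calls.ad_alt.sum(axis=1) < th.cohort_alt_reads
    hwe_p = hwe_p_per_variant(calls.gt[:, control_mask])
    fail_hwe = hwe_p < th.hwe_assoc_p

    counts = {
        "not_biallelic_snp": int(fail_snp.sum()),
        "vqsr": int(fail_vqsr.sum()),
        "hwe_controls": int(fail_hwe.sum()),
        "alt_support": int(fail_alt.sum()),
    }
    retained = np.flatnonzero(~(fail_snp | fail_vqsr | fail_alt | fail_hwe))
    return retained, counts


def _in_excluded_region(sites: pd.DataFrame, regions) -> np.ndarray:
    out = np.zeros(len(sites), dtype=bool)
    chrom = sites["chrom"].astype(str).to_numpy()
    pos0 = sites["pos"].to_numpy() - 1  # regions are 0-based half-open
    for ch, start, end in regions:
        out |= (chrom == str(ch)) & (pos0 >= start) & (pos0 < end)
    return out


def build_pruned_set(
    calls: CallMatrix,
    control_mask: np.ndarray,
    thresholds: QCThresholds | None = None,
) -> np.ndarray:
    """High-quality quasi-independent variant set for genotype PCA.

    Starting from variants passing :func:`variant_filters`, drops MAF below
    the floor, all-sample HWE failures, configured excluded regions, then
    greedily scans left-to-right per chromosome keeping the earlier variant
    of any pair with dosage r^2 above the ceiling within the bp window.
    """
    th = thresholds or QCThresholds()
    retained, _ = variant_filters(calls, control_mask, th)

    maf = folded_maf(calls.gt[retained])
    keep = maf >= th.prune_maf
    hwe_all = hwe_p_per_variant(calls.gt[retained][keep])
    idx = retained[keep][hwe_all >= th.prune_hwe_p]
    if th.excluded_regions:
        excl = _in_excluded_region(calls.sites.iloc[idx], th.excluded_regions)
        idx = idx[~excl]
    if len(idx) == 0:
        return idx

    sub = calls.subset_variants(idx)
    dos = sub.dosage(mean_impute=True).astype(np.float32)
    dos -= dos.mean(axis=1, keepdims=True)
    norms = np.sqrt((dos**2).sum(axis=1))

    order = np.lexsort((sub.sites["pos"].to_numpy(), sub.sites["chrom"].astype(str).to_numpy()))
    kept_local: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    chroms = sub.sites["chrom"].astype(str).to_numpy()
    poss = sub.sites["pos"].to_numpy()
    for i in order:
        ch, pos = chroms[i], poss[i]
        window = kept_by_chrom.setdefault(ch, [])
        # retain only window members within range (positions scanned in order)
        while window and poss[window[0]] < pos - th.ld_window_bp:
            window.pop(0)
        drop = False
        if norms[i] > 0:
            for j in window:
                if norms[j] == 0:
                    continue
                r = float(dos[i] @ dos[j]) / (norms[i] * norms[j])
                if r * r > th.ld_r2:
                    drop = True
                    break
        if not drop:
            window.append(i)
            kept_local.append(i)
    return np.sort(idx[np.array(kept_local, dtype=int)])
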