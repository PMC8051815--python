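"""Variant-level batch diagnostics between capture kits.

For every variant the module compares the two capture kits on mean genotype
quality (GQ), mean depth (DP), and mean alternative allele fraction (AAF =
alt reads / total reads per sample), summarised as log2(kit A / kit B)
ratios.  The variants in the extreme tails of any ratio distribution (5% at
each end by default) are the candidates for kit-driven artefacts; their
genotypes are then examined by subset PCA (does restricting PCA to these
variants separate samples by kit?), by a two-component Gaussian mixture on
log2 mean AAF (the depressed-capture mode sits well below the balanced-het
mode), by concordance of per-kit control MAFs against an external reference,
and by a direct estimate of capture efficiency c from heterozygote allele
balance, using AAF/(1-AAF) whose expectation is c for a het sequenced with
relative alt-template capture c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .core import KITS, MISSING, CallMatrix
from .structure import genotype_pca

log = logging.getLogger(__name__)

METRICS = ("gq", "dp", "aaf")


@dataclass
class BimodalityFit:
    means: np.ndarray  # ordered ascending
    sds: np.ndarray
    weights: np.ndarray
    bimodal: bool
    separation: float  # |mu2 - mu1| in pooled-sd units
    bic_one: float
    bic_two: float
    n_dropped: int = 0


def per_variant_batch_metrics(
    calls: CallMatrix,
    samples: pd.DataFrame,
    aaf_mode: str = "carriers",
) -> pd.DataFrame:
    """Per-variant per-kit mean GQ/DP/AAF and their log2(KitA/KitB) ratios.

    ``aaf_mode='carriers'`` averages AAF over samples with at least one
    alt-supporting read (per-carrier allele balance); ``'covered'`` averages
    over all samples with nonzero depth.  GQ and DP are averaged over samples
    with a called genotype.  A metric is left undefined (NaN) for a kit with
    no eligible samples; log2 ratios require both kit means to be positive.
    """
    if aaf_mode not in ("carriers", "covered"):
        raise ValueError("aaf_mode must be 'carriers' or 'covered'")
    kit = samples["kit"].to_numpy()
    present = {k: (kit == k) for k in KITS}
    if not all(m.any() for m in present.values()):
        raise ValueError("both capture kits must be represented")

    called = calls.gt != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = np.where(calls.dp > 0, calls.ad_alt / np.maximum(calls.dp, 1), np.nan)
    if aaf_mode == "carriers":
        eligible = calls.ad_alt >= 1
    else:
        eligible = calls.dp > 0

    out = {"variant_key": calls.variant_keys()}
    for k, mask in present.items():
        ck = called[:, mask]
        nk = ck.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"mean_gq_{k}"] = np.where(
                nk > 0, np.where(ck, calls.gq[:, mask], 0).sum(axis=1) / nk, np.nan
            )
            out[f"mean_dp_{k}"] = np.where(
                nk > 0, np.where(ck, calls.dp[:, mask], 0).sum(axis=1) / nk, np.nan
            )
        ek = eligible[:, mask]
        mk = ek.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"mean_aaf_{k}"] = np.where(
                mk > 0, np.nansum(np.where(ek, aaf[:, mask], 0.0), axis=1) / mk, np.nan
            )
        out[f"n_{k}"] = nk
        out[f"n_aaf_{k}"] = mk
    df = pd.DataFrame(out)
    a, b = KITS
    for metric in METRICS:
        ma, mb = df[f"mean_{metric}_{a}"], df[f"mean_{metric}_{b}"]
        ok = (ma > 0) & (mb > 0)
        df[f"log2_{metric}"] = np.where(ok, np.log2(ma / mb), np.nan)
    n_undef = int(df[[f"log2_{m}" for m in METRICS]].isna().any(axis=1).sum())
    if n_undef:
        log.info("batch metrics: %d variants with undefined ratios", n_undef)
    return df


def partition_tails(metrics: pd.DataFrame, tail_frac: float = 0.05) -> pd.DataFrame:
    """Tail membership per metric plus the any-metric union.

    Membership is left5/middle90/right5 by strict comparison against the
    empirical tail quantiles, so identical ratios produce zero-width (empty)
    tails.  ``tail_any`` marks variants in either tail of any metric.
    """
    defined = metrics[[f"log2_{m}" for m in METRICS]].notna().sum().min()
    if defined < 20:
        raise ValueError("need >= 20 variants with defined ratios")
    out = metrics[["variant_key"]].copy()
    any_tail = np.zeros(len(metrics), dtype=bool)
    for metric in METRICS:
        v = metrics[f"log2_{metric}"].to_numpy()
        finite = np.isfinite(v)
        lo = np.quantile(v[finite], tail_frac)
        hi = np.quantile(v[finite], 1.0 - tail_frac)
        member = np.where(
            finite & (v < lo), "left5", np.where(finite & (v > hi), "right5", "middle90")
        )
        member = np.where(finite, member, "undefined")
        out[f"tail_{metric}"] = member
        any_tail |= finite & ((v < lo) | (v > hi))
    out["tail_any"] = any_tail
    return out


def subset_pca_separation(
    calls: CallMatrix,
    samples: pd.DataFrame,
    variant_subset: np.ndarray,
    random_state: int = 0,
) -> float:
    """Mean silhouette of kit labels on the first two PCs of a variant subset.

    Scores near zero mean the subset carries no kit signal; scores toward 1
    mean genotypes at these variants separate samples by capture kit.
    """
    variant_subset = np.asarray(variant_subset)
    if variant_subset.dtype == bool:
        variant_subset = np.flatnonzero(variant_subset)
    if len(variant_subset) < 2:
        raise ValueError("variant subset must contain at least 2 variants")
    sub = calls.subset_variants(variant_subset)
    pca = genotype_pca(sub, n_components=2, random_state=random_state)
    coords = pca.coords[:, : min(2, pca.coords.shape[1])]
    labels = samples["kit"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("need both kits present")
    return float(silhouette_score(coords, labels))


def fit_aaf_bimodality(
    log2_aaf: np.ndarray,
    random_state: int = 0,
    n_init: int = 20,
) -> BimodalityFit:
    """Two-component Gaussian mixture on log2 mean AAF values.

    The bimodality flag requires each component to carry >= 5% weight, the
    means to sit more than two pooled standard deviations apart, and the
    two-component model to win on BIC.
    """
    v = np.asarray(log2_aaf, dtype=float)
    finite = np.isfinite(v)
    n_dropped = int((~finite).sum())
    v = v[finite].reshape(-1, 1)
    if len(v) < 50:
        raise ValueError("need >= 50 finite values")
    gm1 = GaussianMixture(1, random_state=random_state).fit(v)
    gm2 = GaussianMixture(2, n_init=n_init, random_state=random_state).fit(v)
    order = np.argsort(gm2.means_.ravel())
    means = gm2.means_.ravel()[order]
    sds = np.sqrt(gm2.covariances_.ravel()[order])
    weights = gm2.weights_.ravel()[order]
    pooled = float(np.sqrt(weights @ (sds**2)))
    separation = float((means[1] - means[0]) / pooled) if pooled > 0 else np.inf
    bic_one, bic_two = float(gm1.bic(v)), float(gm2.bic(v))
    bimodal = bool(weights.min() >= 0.05 and separation > 2.0 and bic_two < bic_one)
    return BimodalityFit(
        means=means,
        sds=sds,
        weights=weights,
        bimodal=bimodal,
        separation=separation,
        bic_one=bic_one,
        bic_two=bic_two,
        n_dropped=n_dropped,
    )


def per_kit_control_maf(
    calls: CallMatrix, samples: pd.DataFrame
) -> pd.DataFrame:
    """Folded MAF among control samples, separately per capture kit."""
    ctrl = (samples["phenotype"] == "control").to_numpy()
    out = {"variant_key": calls.variant_keys()}
    for k in KITS:
        mask = ctrl & (samples["kit"] == k).to_numpy()
        gt = calls.gt[:, mask]
        called = gt != MISSING
        n = called.sum(axis=1)
        alt = np.where(called, gt, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = alt / (2.0 * n)
        f = np.where(n > 0, f, np.nan)
        out[f"maf_{k}"] = np.minimum(f, 1.0 - f)
    return pd.DataFrame(out)


def maf_concordance(
    kit_mafs: pd.DataFrame,
    ref_maf: dict[str, float],
) -> tuple[pd.DataFrame, dict]:
    """Which kit's control MAF better matches the external reference.

    Distances are absolute differences of folded MAFs.  The summary reports
    per-kit winner counts, skipped variants (absent from the reference), and
    a two-sided sign-test p for a 50/50 winner split.
    """
    a, b = KITS
    rows = []
    n_skipped = 0
    for _, row in kit_mafs.iterrows():
        key = row["variant_key"]
        if key not in ref_maf:
            n_skipped += 1
            continue
        ref = ref_maf[key]
        da, db = abs(row[f"maf_{a}"] - ref), abs(row[f"maf_{b}"] - ref)
        if np.isnan(da) or np.isnan(db):
            n_skipped += 1
            continue
        winner = "none" if abs(da - db) < 1e-12 else (a if da < db else b)
        rows.append(
            {"variant_key": key, f"dist_{a}": da, f"dist_{b}": db, "winner": winner}
        )
    df = pd.DataFrame(rows, columns=["variant_key", f"dist_{a}", f"dist_{b}", "winner"])
    wins_a = int((df["winner"] == a).sum()) if len(df) else 0
    wins_b = int((df["winner"] == b).sum()) if len(df) else 0
    decided = wins_a + wins_b
    sign_p = float(binomtest(wins_a, decided, 0.5).pvalue) if decided else np.nan
    summary = {
        f"wins_{a}": wins_a,
        f"wins_{b}": wins_b,
        "ties": int((df["winner"] == "none").sum()) if len(df) else 0,
        "skipped": n_skipped,
        "sign_test_p": sign_p,
    }
    return df, summary


def estimate_capture_efficiency(
    calls: CallMatrix,
    samples: pd.DataFrame,
    kit: str,
    het_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant capture efficiency c from heterozygote allele balance.

    For each het carrier, AAF/(1-AAF) estimates the relative alt-template
    capture rate; the per-variant estimate averages this over carriers in
    the requested kit.  ``het_mask`` (variants x samples) selects carriers —
    pass truth heterozygosity when available, otherwise called hets are
    used.  Carriers with AAF = 1 have an unbounded ratio and are excluded
    with a count.
    """
    if kit not in KITS:
        raise ValueError(f"unknown kit {kit!r}")
    in_kit = (samples["kit"] == kit).to_numpy()
    if het_mask is None:
        het_mask = calls.gt == 1
    het = het_mask & in_kit[None, :] & (calls.dp > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = calls.ad_alt / np.maximum(calls.dp, 1)
    finite = het & (aaf < 1.0)
    ratio = np.where(finite, aaf / np.maximum(1.0 - aaf, 1e-300), 0.0)
    n = finite.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_hat = np.where(n > 0, ratio.sum(axis=1) / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {
            "variant_key": calls.variant_keys(),
            "c_hat": c_hat,
            "n_carriers": n,
            "n_unbounded": (het & ~(aaf < 1.0)).sum(axis=1),
        }
    )
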