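"""Shared containers for multi-sample genotype call sets.

The pipeline's in-memory representation is column-major over variants: a
:class:`CallMatrix` holds one 2-D array per FORMAT field (variants x samples)
plus a site table, which keeps whole-cohort operations (per-kit means, allele
counts, dosage extraction) vectorised.  :class:`VariantSite` is a light
single-site view used by the VCF reader/writer and in small fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CENTERS = ("C1", "C2", "C3")
KITS = ("KitA", "KitB")
#: capture kit is a deterministic function of sequencing center (confounded
#: by design: one center uses KitA, the other two share KitB).
KIT_OF_CENTER = {"C1": "KitA", "C2": "KitB", "C3": "KitB"}

MISSING = -1  # sentinel for missing genotype / GQ

SAMPLE_COLUMNS = ("sample_id", "center", "kit", "sex", "phenotype", "apoe_cov")

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in _TRANSITIONS


@dataclass
class VariantSite:
    """One biallelic SNP with per-sample calls.

    ``gt`` is the alt-allele dosage (0/1/2, ``-1`` missing); ``gq`` is -1
    where the genotype is missing.  ``ad_ref + ad_alt == dp`` by construction
    in the simulator and is enforced on read.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vqslod: float
    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class CallMatrix:
    """Cohort-level call set: site table + per-FORMAT-field matrices.

    Arrays are shaped (n_variants, n_samples); ``samples`` gives the column
    order.  ``sites`` has columns chrom, pos, ref, alt, vqslod.
    """

    sites: pd.DataFrame
    samples: list[str]
    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray

    def __post_init__(self) -> None:
        m, n = self.gt.shape
        if len(self.sites) != m or len(self.samples) != n:
            raise ValueError("site/sample dimensions inconsistent with call arrays")
        for arr in (self.ad_ref, self.ad_alt, self.dp, self.gq):
            if arr.shape != (m, n):
                raise ValueError("call arrays must share one shape")

    @property
    def n_variants(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def variant_keys(self) -> np.ndarray:
        s = self.sites
        return (
            s["chrom"].astype(str)
            + ":"
            + s["pos"].astype(str)
            + ":"
            + s["ref"]
            + ":"
            + s["alt"]
        ).to_numpy()

    def site(self, i: int) -> VariantSite:
        row = self.sites.iloc[i]
        return VariantSite(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            vqslod=float(row["vqslod"]),
            gt=self.gt[i],
            ad_ref=self.ad_ref[i],
            ad_alt=self.ad_alt[i],
            dp=self.dp[i],
            gq=self.gq[i],
        )

    def iter_sites(self):
        for i in range(self.n_variants):
            yield self.site(i)

    def subset_variants(self, idx) -> "CallMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CallMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            gt=self.gt[idx],
            ad_ref=self.ad_ref[idx],
            ad_alt=self.ad_alt[idx],
            dp=self.dp[idx],
            gq=self.gq[idx],
        )

    def subset_samples(self, mask) -> "CallMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return CallMatrix(
            sites=self.sites.copy(),
            samples=[self.samples[j] for j in cols],
            gt=self.gt[:, cols],
            ad_ref=self.ad_ref[:, cols],
            ad_alt=self.ad_alt[:, cols],
            dp=self.dp[:, cols],
            gq=self.gq[:, cols],
        )

    def dosage(self, mean_impute: bool = False) -> np.ndarray:
        """Alt-allele dosage as float, NaN (or per-variant mean) where missing."""
        d = self.gt.astype(float)
        d[self.gt == MISSING] = np.nan
        if mean_impute:
            means = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=1)
            means = np.where(np.isnan(means), 0.0, means)
            rows, cols = np.nonzero(np.isnan(d))
            d[rows, cols] = means[rows]
        return d


def from_sites(sites: list[VariantSite], samples: list[str]) -> CallMatrix:
    """Stack single-site records into a CallMatrix (order preserved)."""
    if not sites:
        empty = np.zeros((0, len(samples)), dtype=np.int32)
        return CallMatrix(
            sites=pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "vqslod"]),
            samples=list(samples),
            gt=empty.astype(np.int8),
            ad_ref=empty,
            ad_alt=empty,
            dp=empty,
            gq=empty.astype(np.int16),
        )
    tab = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "vqslod": [s.vqslod for s in sites],
        }
    )
    return CallMatrix(
        sites=tab,
        samples=list(samples),
        gt=np.vstack([s.gt for s in sites]).astype(np.int8),
        ad_ref=np.vstack([s.ad_ref for s in sites]).astype(np.int32),
        ad_alt=np.vstack([s.ad_alt for s in sites]).astype(np.int32),
        dp=np.vstack([s.dp for s in sites]).astype(np.int32),
        gq=np.vstack([s.gq for s in sites]).astype(np.int16),
    )


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and normalise column dtypes."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    bad_center = sorted(set(samples["center"]) - set(CENTERS))
    if bad_center:
        raise ValueError(f"unknown center labels: {bad_center}")
    bad_kit = sorted(set(samples["kit"]) - set(KITS))
    if bad_kit:
        raise ValueError(f"unknown kit labels: {bad_kit}")
    expected = samples["center"].map(KIT_OF_CENTER)
    mismatched = samples.loc[expected != samples["kit"], "sample_id"].tolist()
    if mismatched:
        raise ValueError(f"kit inconsistent with center for samples: {mismatched}")
    bad_pheno = sorted(set(samples["phenotype"]) - {"case", "control"})
    if bad_pheno:
        raise ValueError(f"unknown phenotype labels: {bad_pheno}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    return samples.reset_index(drop=True)


def phenotype_vector(samples: pd.DataFrame) -> np.ndarray:
    return (samples["phenotype"].to_numpy() == "case").astype(float)
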