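"""Readers and writers for the pipeline's external formats.

Supported inputs are a multi-sample VCF 4.2 restricted to biallelic SNPs with
FORMAT ``GT:AD:DP:GQ`` and a site-level ``VQSLOD`` INFO float, a sample
metadata TSV, and a two-column reference minor-allele-frequency table.  VCF
access goes through pysam, so plain and bgzipped files both work.  Records
that are not biallelic SNPs are rejected at parse time with a logged count;
write/read round-trips are identities on the supported subset.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import MISSING, CallMatrix, validate_samples

log = logging.getLogger(__name__)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=VQSLOD,Number=1,Type=Float,Description="Recalibrated variant quality log-odds">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(calls: CallMatrix, path: str | Path) -> None:
    """Write a CallMatrix as VCF 4.2 with FORMAT GT:AD:DP:GQ."""
    path = Path(path)
    lines = [_VCF_HEADER]
    for ch in pd.unique(calls.sites["chrom"].astype(str)):
        lines.append(f"##contig=<ID={ch}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(calls.samples)
        + "\n"
    )
    for site in calls.iter_sites():
        fields = [
            str(site.chrom),
            str(site.pos),
            ".",
            site.ref,
            site.alt,
            ".",
            "PASS",
            f"VQSLOD={site.vqslod:g}",
            "GT:AD:DP:GQ",
        ]
        cells = []
        for j in range(len(site.gt)):
            g = int(site.gt[j])
            gq = "." if g == MISSING else str(int(site.gq[j]))
            cells.append(
                f"{_GT_STRINGS[g]}:{int(site.ad_ref[j])},{int(site.ad_alt[j])}:"
                f"{int(site.dp[j])}:{gq}"
            )
        lines.append("\t".join(fields + cells) + "\n")
    path.write_text("".join(lines))


def read_vcf(path: str | Path) -> CallMatrix:
    """Parse a VCF into a CallMatrix; non-biallelic-SNP records are skipped.

    Raises ``ValueError`` with the record position for malformed entries.
    """
    path = str(path)
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    rows = {"chrom": [], "pos": [], "ref": [], "alt": [], "vqslod": []}
    gts, refs, alts, dps, gqs = [], [], [], [], []
    n_rejected = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_rejected += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or alt == "*":
            n_rejected += 1
            continue
        try:
            vq = float(rec.info.get("VQSLOD", np.nan))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed VQSLOD at {rec.chrom}:{rec.pos}") from exc
        gt_row = np.full(len(samples), MISSING, dtype=np.int8)
        ad_ref_row = np.zeros(len(samples), dtype=np.int32)
        ad_alt_row = np.zeros(len(samples), dtype=np.int32)
        dp_row = np.zeros(len(samples), dtype=np.int32)
        gq_row = np.full(len(samples), MISSING, dtype=np.int16)
        for j, name in enumerate(samples):
            call = rec.samples[name]
            alleles = call.get("GT")
            ad = call.get("AD")
            if ad is not None and len(ad) == 2 and ad[0] is not None:
                ad_ref_row[j], ad_alt_row[j] = int(ad[0]), int(ad[1])
            dp = call.get("DP")
            dp_row[j] = int(dp) if dp is not None else ad_ref_row[j] + ad_alt_row[j]
            if alleles is None or any(a is None for a in alleles):
                continue  # missing call; AD of "." handled above
            gt_row[j] = int(sum(alleles))
            gq = call.get("GQ")
            gq_row[j] = int(gq) if gq is not None else MISSING
        rows["chrom"].append(str(rec.chrom))
        rows["pos"].append(int(rec.pos))
        rows["ref"].append(ref)
        rows["alt"].append(alt)
        rows["vqslod"].append(vq)
        gts.append(gt_row)
        refs.append(ad_ref_row)
        alts.append(ad_alt_row)
        dps.append(dp_row)
        gqs.append(gq_row)
    if n_rejected:
        log.info("read_vcf: rejected %d non-biallelic-SNP records", n_rejected)
    m = len(rows["chrom"])
    shape = (m, len(samples))
    return CallMatrix(
        sites=pd.DataFrame(rows),
        samples=samples,
        gt=np.vstack(gts) if m else np.zeros(shape, np.int8),
        ad_ref=np.vstack(refs) if m else np.zeros(shape, np.int32),
        ad_alt=np.vstack(alts) if m else np.zeros(shape, np.int32),
        dp=np.vstack(dps) if m else np.zeros(shape, np.int32),
        gq=np.vstack(gqs) if m else np.zeros(shape, np.int16),
    )


def write_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata TSV (gzip-transparent)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_samples(df)


def check_sample_match(calls: CallMatrix, samples: pd.DataFrame) -> None:
    """Hard error listing offending ids when VCF and metadata disagree."""
    vcf_ids = set(calls.samples)
    meta_ids = set(samples["sample_id"])
    only_vcf = sorted(vcf_ids - meta_ids)
    only_meta = sorted(meta_ids - vcf_ids)
    if only_vcf or only_meta:
        raise ValueError(
            f"sample sets disagree; VCF-only={only_vcf[:10]} metadata-only={only_meta[:10]}"
        )


def read_ref_maf(path: str | Path) -> dict[str, float]:
    """Reference MAF table: TSV with columns variant_key, maf.

    Frequencies are folded to the minor allele on read.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    out: dict[str, float] = {}
    with opener(path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("variant_key"):
            raise ValueError("reference MAF table must have a variant_key/maf header")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed reference MAF line {ln}")
            f = float(parts[1])
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency out of range at line {ln}")
            out[parts[0]] = min(f, 1.0 - f)
    return out


def write_ref_maf(table: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_key\tmaf\n")
        for key, f in table.items():
            fh.write(f"{key}\t{f:.6g}\n")
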