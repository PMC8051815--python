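"""End-to-end orchestration: simulate/load -> QC -> PCA -> association ->
batch diagnostics, with eagerly written stage outputs and a run manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as vio
from .assoc import (
    ModelSpec,
    bonferroni_threshold,
    flag_batch_exclusive,
    run_association,
)
from .batchdiag import (
    estimate_capture_efficiency,
    fit_aaf_bimodality,
    maf_concordance,
    partition_tails,
    per_kit_control_maf,
    per_variant_batch_metrics,
    subset_pca_separation,
)
from .core import KITS, CallMatrix
from .qc import QCThresholds, build_pruned_set, sample_qc, variant_filters
from .simdata import SimConfig, TruthTable, emit_dataset, simulate_dataset
from .structure import genotype_pca, retain_pcs

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults reproduce the study's thresholds."""

    sim: SimConfig | None = None
    vcf_path: str | None = None
    metadata_path: str | None = None
    ref_maf_path: str | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    models: list[str] = field(default_factory=lambda: ["M1", "M2"])
    alpha: float = 0.05
    null_floor: float = 0.05
    tail_frac: float = 0.05
    aaf_mode: str = "carriers"
    max_pcs: int = 10
    recompute_stratum_pcs: bool = True
    write_dataset: bool = False  # re-emit the simulated VCF/metadata/truth bundle
    seed: int = 0
    outdir: str = "varbatch_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        th = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if sim is not None:
            if "n_per_center" in sim:
                sim["n_per_center"] = tuple(sim["n_per_center"])
            cfg.sim = SimConfig(**sim)
        if th is not None:
            cfg.thresholds = QCThresholds(**th)
        return cfg


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        truth, samples, calls = simulate_dataset(sim)
        ref = {
            k: float(f)
            for k, f in zip(calls.variant_keys(), truth.population_maf())
        }
        return truth, samples, calls, ref
    if config.vcf_path is None or config.metadata_path is None:
        raise ValueError("config needs either a sim block or vcf+metadata paths")
    calls = vio.read_vcf(config.vcf_path)
    samples = vio.read_metadata(config.metadata_path)
    vio.check_sample_match(calls, samples)
    order = {s: i for i, s in enumerate(calls.samples)}
    samples = samples.iloc[samples["sample_id"].map(order).argsort()].reset_index(drop=True)
    ref = vio.read_ref_maf(config.ref_maf_path) if config.ref_maf_path else None
    return None, samples, calls, ref


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report bundle and writes stage outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    def _stage(name):
        log.info("pipeline stage: %s", name)

    try:
        _stage("input")
        truth, samples, calls, ref = _load_inputs(config)
        if config.sim is not None and config.write_dataset:
            emit_dataset(calls, samples, truth, outdir / "dataset")

        _stage("sample_qc")
        sq = sample_qc(calls, config.thresholds)
        keep = sq["pass"].to_numpy()
        calls = calls.subset_samples(keep)
        samples = samples.loc[keep].reset_index(drop=True)
        sq.to_csv(outdir / "sample_qc.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

        _stage("variant_filters")
        controls = (samples["phenotype"] == "control").to_numpy()
        retained, excl_counts = variant_filters(calls, controls, config.thresholds)
        analysis = calls.subset_variants(retained)

        _stage("pruned_set")
        pruned = build_pruned_set(calls, controls, config.thresholds)
        n_tests = analysis.n_variants
        threshold = bonferroni_threshold(n_tests, config.alpha) if n_tests else np.nan

        _stage("pca")
        pca = genotype_pca(calls.subset_variants(pruned), n_components=config.max_pcs)
        n_pcs = min(retain_pcs(pca), config.max_pcs)
        if n_pcs == 0:
            log.warning("no eigenvalues above 1; using 0 PC covariates")
        pcs = pca.eigenvectors[:, :n_pcs]
        pd.DataFrame(
            pca.coords,
            index=samples["sample_id"],
            columns=[f"PC{i+1}" for i in range(pca.coords.shape[1])],
        ).to_csv(outdir / "pca_coords.tsv", sep="\t", float_format=_FLOAT_FMT)

        _stage("association")
        strata = ["full", *sorted(samples["center"].unique()), *KITS]
        assoc_frames = []
        results_by = {}
        for model_id in config.models:
            model = ModelSpec(model_id)
            for stratum in strata:
                if stratum == "full" or not config.recompute_stratum_pcs:
                    use_pcs = pcs
                else:
                    mask = (
                        (samples["center"] == stratum)
                        if stratum in set(samples["center"])
                        else (samples["kit"] == stratum)
                    ).to_numpy()
                    sub_pca = genotype_pca(
                        calls.subset_variants(pruned).subset_samples(mask),
                        n_components=config.max_pcs,
                    )
                    k = min(retain_pcs(sub_pca), config.max_pcs)
                    stratum_pcs = np.zeros((len(samples), k))
                    stratum_pcs[mask] = sub_pca.eigenvectors[:, :k]
                    use_pcs = stratum_pcs
                res = run_association(analysis, samples, model, stratum, pcs=use_pcs)
                assoc_frames.append(res)
                results_by[(model_id, stratum)] = res
        assoc_df = pd.concat(assoc_frames, ignore_index=True)

        _stage("flags")
        flag_model = config.models[0]
        flags = flag_batch_exclusive(
            results_by[(flag_model, "full")],
            {k: results_by[(flag_model, k)] for k in KITS},
            threshold=threshold,
            null_floor=config.null_floor,
        )

        _stage("batch_diagnostics")
        metrics = per_variant_batch_metrics(analysis, samples, aaf_mode=config.aaf_mode)
        tails = partition_tails(metrics, tail_frac=config.tail_frac)
        tail_idx = np.flatnonzero(tails["tail_any"].to_numpy())
        mid_idx = np.flatnonzero(~tails["tail_any"].to_numpy())
        separations = {}
        for name, idx in (("tail", tail_idx), ("middle", mid_idx)):
            if len(idx) >= 2:
                separations[name] = subset_pca_separation(analysis, samples, idx)
        bimodality = {}
        for k in KITS:
            vals = np.log2(metrics[f"mean_aaf_{k}"].to_numpy())
            if np.isfinite(vals).sum() >= 50:
                fit = fit_aaf_bimodality(vals)
                bimodality[k] = {
                    "bimodal": fit.bimodal,
                    "means": fit.means.tolist(),
                    "weights": fit.weights.tolist(),
                    "separation": fit.separation,
                }
        kit_mafs = per_kit_control_maf(analysis, samples)
        concordance_df, concordance = (pd.DataFrame(), None)
        if ref:
            concordance_df, concordance = maf_concordance(kit_mafs, ref)
        biased_kit = config.sim.biased_kit if config.sim is not None else KITS[1]
        c_hat = estimate_capture_efficiency(analysis, samples, biased_kit)

        _stage("write")
        assoc_df = assoc_df.merge(
            flags.rename(columns={"p": "p_full", "flag": "batch_flag"})[
                ["variant_key", "batch_flag"]
            ],
            on="variant_key",
            how="left",
        )
        assoc_df.to_csv(outdir / "association.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        metrics.to_csv(outdir / "batch_metrics.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        tails.to_csv(outdir / "tails.tsv", sep="\t", index=False)
        flags.to_csv(outdir / "flags.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        c_hat.to_csv(outdir / "capture_efficiency.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        if len(concordance_df):
            concordance_df.to_csv(
                outdir / "maf_concordance.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )

        diagnostics = {
            "n_samples_input": int(len(sq)),
            "n_samples_pass": int(keep.sum()),
            "n_variants_input": int(len(keep) and calls.n_variants),
            "n_variants_retained": int(n_tests),
            "exclusion_counts": excl_counts,
            "n_pruned": int(len(pruned)),
            "eigenvalues": [round(float(v), 6) for v in pca.eigenvalues],
            "n_pcs_retained": int(n_pcs),
            "bonferroni_threshold": float(threshold),
            "flag_counts": flags["flag"].value_counts().to_dict(),
            "pca_separation": {k: round(v, 6) for k, v in separations.items()},
            "aaf_bimodality": bimodality,
            "maf_concordance": concordance,
        }
        (outdir / "diagnostics.json").write_text(
            json.dumps(diagnostics, sort_keys=True, indent=2, default=float)
        )
        manifest = {
            "varbatch_version": __version__,
            "seed": int(config.seed),
            "alpha": config.alpha,
            "null_floor": config.null_floor,
            "tail_frac": config.tail_frac,
            "aaf_mode": config.aaf_mode,
            "models": list(config.models),
            "thresholds": dataclasses.asdict(config.thresholds),
            "sim": dataclasses.asdict(config.sim) if config.sim else None,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))

        report.update(
            {
                "samples": samples,
                "sample_qc": sq,
                "association": assoc_df,
                "flags": flags,
                "metrics": metrics,
                "tails": tails,
                "capture_efficiency": c_hat,
                "concordance": concordance_df,
                "diagnostics": diagnostics,
                "manifest": manifest,
                "truth": truth,
            }
        )
        return report
    except Exception as exc:  # noqa: BLE001 - annotate stage context
        raise RuntimeError(f"pipeline failed: {exc}") from exc


def summarize(report: dict, top_n: int = 20) -> str:
    """Human-readable run summary with a top-variant table."""
    d = report["diagnostics"]
    lines = [
        "varbatch run summary",
        f"samples: {d['n_samples_pass']}/{d['n_samples_input']} passed sample QC",
        f"variants tested: {d['n_variants_retained']}"
        + (
            f" (excluded: {d['exclusion_counts']})"
            if d["n_variants_retained"] or d["exclusion_counts"]
            else ""
        ),
        f"pruned PCA set: {d['n_pruned']} variants; retained PCs: {d['n_pcs_retained']}",
        f"Bonferroni threshold: {d['bonferroni_threshold']:.3g}",
        f"batch flags: {d['flag_counts']}",
        f"tail/middle kit-separation silhouettes: {d['pca_separation']}",
    ]
    assoc = report["association"]
    full = assoc[(assoc["stratum"] == "full")].dropna(subset=["p"])
    if len(full) == 0:
        lines.append("0 variants tested")
    else:
        top = full.sort_values("p").head(top_n)
        lines.append(f"top {len(top)} variants by full-cohort p:")
        lines.append(
            top[["variant_key", "model", "beta", "p", "maf_case", "maf_ctrl"]].to_string(
                index=False, float_format=lambda v: f"{v:.3g}"
            )
        )
    return "\n".join(lines)
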