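"""Per-variant additive logistic association, stratified and flagged.

Each variant is tested with a logistic regression of case status on alt
dosage plus model covariates (M1: center + retained PCs; M2: M1 + sex +
major-locus genotype; M3: M2 + age).  Fits use iteratively reweighted least
squares with a log-likelihood tolerance of 1e-8 and at most 50 iterations;
the per-allele Wald p-value comes from beta/SE against the standard normal.
Samples with a missing genotype at a variant are dropped from that variant's
fit.  Exome-wide significance uses the Bonferroni threshold alpha / #tests.

"Batch-exclusive" formalises the visual notion of a signal carried by one
capture kit: a full-cohort-significant variant is exclusive to a kit when
that kit's stratum reaches the per-stratum threshold while the other kit
shows no evidence at all (p above a null floor, default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .core import MISSING, CallMatrix, phenotype_vector

log = logging.getLogger(__name__)

MODELS = ("M1", "M2", "M3")


@dataclass
class ModelSpec:
    """Covariate model. center dummies are dropped in single-center strata."""

    model_id: str = "M1"
    use_lrt: bool = False  # likelihood-ratio p instead of Wald

    def covariate_columns(self) -> list[str]:
        if self.model_id == "M1":
            return []
        if self.model_id == "M2":
            return ["sex", "apoe_cov"]
        if self.model_id == "M3":
            return ["sex", "apoe_cov", "age"]
        raise ValueError(f"unknown model id {self.model_id!r}")


@dataclass
class LogisticFit:
    beta: float
    se: float
    p: float
    converged: bool
    flag: str = ""
    loglik: float = np.nan
    loglik_null: float = np.nan


def _irls(
    x: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """IRLS for logistic regression; returns (beta, cov, loglik, converged)."""
    n, p = x.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    cov = np.full((p, p), np.nan)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        xt_w = x.T * w
        info = xt_w @ x
        score = x.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return beta, cov, ll_old, False
        beta = beta + step
        eta = np.clip(x @ beta, -30.0, 30.0)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    try:
        eta = np.clip(x @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        cov = np.linalg.inv((x.T * w) @ x)
    except np.linalg.LinAlgError:
        converged = False
    return beta, cov, ll_old, converged


def fit_logistic(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    use_lrt: bool = False,
) -> LogisticFit:
    """Additive logistic fit of y on dosage, adjusting for covariates.

    The design is [intercept, dosage, covariates]; the reported beta/SE/p are
    for the dosage term.  Constant dosage yields a flagged NA result; fits
    that do not converge or land at |beta| > 10 (near-separation) are flagged
    non-converged.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if np.ptp(dosage) == 0:
        return LogisticFit(np.nan, np.nan, np.nan, False, flag="constant_dosage")
    cols = [np.ones_like(y), dosage]
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        cols.extend(cov.T)
    x = np.column_stack(cols)
    if len(y) < x.shape[1] + 1:
        return LogisticFit(np.nan, np.nan, np.nan, False, flag="too_few_samples")

    beta, cov_m, ll, converged = _irls(x, y, tol=tol, max_iter=max_iter)
    b = float(beta[1])
    se = float(np.sqrt(cov_m[1, 1])) if np.isfinite(cov_m[1, 1]) else np.nan
    flag = ""
    if not converged or abs(b) > 10.0 or not np.isfinite(se):
        converged = False
        flag = "non_converged"
    if use_lrt:
        x0 = np.delete(x, 1, axis=1)
        _, _, ll0, conv0 = _irls(x0, y, tol=tol, max_iter=max_iter)
        stat = max(2.0 * (ll - ll0), 0.0)
        p = float(chi2.sf(stat, 1)) if conv0 else np.nan
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = float(2.0 * norm.sf(abs(b / se))) if se and np.isfinite(se) else np.nan
    if p == 0.0:
        p = np.nextafter(0.0, 1.0)  # p in (0, 1]
    return LogisticFit(b, se, p, converged, flag=flag, loglik=ll)


def case_control_maf(gt: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Folded per-variant MAF in cases and controls from called genotypes.

    Folding uses the cohort-wide minor allele so case and control
    frequencies refer to the same allele.
    """
    called = gt != MISSING
    alt_all = np.where(called, gt, 0).sum(axis=1)
    n_all = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_all = alt_all / (2.0 * n_all)
    flip = f_all > 0.5
    out = []
    for mask in (y == 1, y == 0):
        alt = np.where(called[:, mask], gt[:, mask], 0).sum(axis=1)
        n = called[:, mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = alt / (2.0 * n)
        f = np.where(n > 0, f, np.nan)
        out.append(np.where(flip, 1.0 - f, f))
    return out[0], out[1]


def _stratum_mask(samples: pd.DataFrame, stratum: str) -> np.ndarray:
    if stratum == "full":
        return np.ones(len(samples), dtype=bool)
    if stratum in set(samples["center"]):
        return (samples["center"] == stratum).to_numpy()
    if stratum in set(samples["kit"]):
        return (samples["kit"] == stratum).to_numpy()
    raise ValueError(f"unknown stratum {stratum!r}")


def build_design(
    samples: pd.DataFrame,
    model: ModelSpec,
    pcs: np.ndarray | None,
) -> np.ndarray:
    """Covariate matrix (no intercept, no dosage) for one analysis cohort.

    Center indicator columns are included only when more than one center is
    present (within-center strata drop them automatically).
    """
    cols: list[np.ndarray] = []
    centers = pd.unique(samples["center"])
    if len(centers) > 1:
        for c in sorted(centers)[1:]:
            cols.append((samples["center"] == c).to_numpy(dtype=float))
    for name in model.covariate_columns():
        if name == "sex":
            cols.append((samples["sex"] == "M").to_numpy(dtype=float))
        else:
            if name not in samples.columns:
                raise ValueError(f"model {model.model_id} needs sample column {name!r}")
            cols.append(samples[name].to_numpy(dtype=float))
    if pcs is not None and pcs.size:
        cols.extend(np.asarray(pcs, dtype=float).T)
    return np.column_stack(cols) if cols else np.zeros((len(samples), 0))


def run_association(
    calls: CallMatrix,
    samples: pd.DataFrame,
    model: ModelSpec,
    stratum: str = "full",
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """One association result per variant for a model and stratum.

    ``pcs`` are the retained PC coordinates for the full sample table; they
    are subset to the stratum here.  Variants are assumed pre-filtered.
    """
    mask = _stratum_mask(samples, stratum)
    sub = samples.loc[mask].reset_index(drop=True)
    y = phenotype_vector(sub)
    if len(np.unique(y)) < 2:
        raise ValueError(f"stratum {stratum!r} has fewer than two phenotype classes")
    covs = build_design(sub, model, pcs[mask] if pcs is not None else None)
    gt = calls.gt[:, mask]
    maf_case, maf_ctrl = case_control_maf(gt, y)

    rows = []
    keys = calls.variant_keys()
    for i in range(calls.n_variants):
        called = gt[i] != MISSING
        fit = fit_logistic(y[called], gt[i][called].astype(float), covs[called])
        rows.append(
            {
                "variant_key": keys[i],
                "stratum": stratum,
                "model": model.model_id,
                "beta": fit.beta,
                "se": fit.se,
                "p": fit.p,
                "maf_case": maf_case[i],
                "maf_ctrl": maf_ctrl[i],
                "converged": fit.converged,
                "flag": fit.flag,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def lambda_gc(p_values: np.ndarray) -> float:
    """Genomic inflation: median Wald chi-square over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    stats = chi2.isf(p, 1)
    return float(np.median(stats) / chi2.ppf(0.5, 1))


def flag_batch_exclusive(
    results_full: pd.DataFrame,
    results_by_kit: dict[str, pd.DataFrame],
    threshold: float,
    null_floor: float = 0.05,
    stratum_threshold: float | None = None,
) -> pd.DataFrame:
    """Adjudicate full-cohort-significant variants between capture kits.

    A variant significant in the full cohort is ``exclusive_<kit>`` when that
    kit's stratum p is below the per-stratum threshold (defaults to the
    full-cohort threshold) while the other kit's p exceeds the null floor;
    otherwise it is ``concordant``.  Missing or unusable stratum results give
    ``indeterminate``.
    """
    st_thr = threshold if stratum_threshold is None else stratum_threshold
    kits = sorted(results_by_kit)
    if len(kits) != 2:
        raise ValueError("flagging needs exactly two kit strata")
    by_kit = {k: df.set_index("variant_key") for k, df in results_by_kit.items()}
    flags = []
    for _, row in results_full.iterrows():
        key, p_full = row["variant_key"], row["p"]
        if not np.isfinite(p_full) or p_full >= threshold:
            flags.append("not_significant")
            continue
        ps = {}
        ok = True
        for k in kits:
            if key not in by_kit[k].index:
                log.info("flag_batch_exclusive: missing %s result for %s", k, key)
                ok = False
                continue
            rec = by_kit[k].loc[key]
            if np.isfinite(rec["p"]):
                ps[k] = float(rec["p"])
            elif rec.get("flag") == "constant_dosage":
                # no alt calls at all in this kit: total dropout, no evidence
                ps[k] = 1.0
            else:
                log.info("flag_batch_exclusive: unusable %s result for %s", k, key)
                ok = False
        if not ok:
            flags.append("indeterminate")
            continue
        a, b = kits
        if ps[a] < st_thr and ps[b] > null_floor:
            flags.append(f"exclusive_{a}")
        elif ps[b] < st_thr and ps[a] > null_floor:
            flags.append(f"exclusive_{b}")
        else:
            flags.append("concordant")
    out = results_full[["variant_key", "p"]].copy()
    out["flag"] = flags
    return out
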