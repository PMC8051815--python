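"""Genotype PCA, PC retention, and a PC-space subpopulation clustering.

PCA follows the standard genotype scaling: alt dosages are mean-imputed per
variant, centred by twice the sample allele frequency and divided by
sqrt(2 p (1-p)), so every variant contributes unit variance under
Hardy-Weinberg.  Eigenvalues are those of the realised relationship matrix
X X^T / m.  PC retention applies the eigenvalue-above-1 rule; subpopulation
labels come from k-means over the retained PCs with the number of clusters
chosen by mean silhouette (a surrogate for model-based admixture
estimation, used only for labelling, never as a covariate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.utils.extmath import randomized_svd

from .core import CallMatrix

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    coords: np.ndarray  # (n_samples, k) eigenvector coordinates scaled by sqrt(eigenvalue)
    eigenvectors: np.ndarray  # (n_samples, k), orthonormal
    eigenvalues: np.ndarray  # nonincreasing, >= 0
    loadings: np.ndarray  # (k, n_variants_used)
    variant_index: np.ndarray  # indices of variants actually used


def standardized_dosage(calls: CallMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(samples x variants) standardized dosage matrix and used-variant index.

    Zero-variance variants after imputation are dropped with a log entry.
    """
    dos = calls.dosage(mean_impute=True)  # (m, n)
    p_hat = dos.mean(axis=1) / 2.0
    denom = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    usable = denom > 0
    # imputation can leave a column constant even at 0 < p < 1
    usable &= dos.std(axis=1) > 0
    if (~usable).any():
        log.info("genotype_pca: dropped %d zero-variance variants", int((~usable).sum()))
    x = (dos[usable] - 2.0 * p_hat[usable, None]) / denom[usable, None]
    return x.T.astype(np.float64), np.flatnonzero(usable)


def genotype_pca(
    calls: CallMatrix,
    n_components: int = 10,
    random_state: int = 0,
) -> PCAResult:
    """PCA of standardized genotypes via truncated randomized SVD."""
    if calls.n_samples < 2 or calls.n_variants < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variants")
    x, used = standardized_dosage(calls)
    m = x.shape[1]
    if m < 1:
        raise ValueError("no usable variants for PCA")
    k = int(min(n_components, calls.n_samples - 1, m))
    if x.size <= 4_000_000:
        # exact SVD: deterministic and permutation-equivariant to precision
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    else:
        u, s, vt = randomized_svd(x, n_components=k, random_state=random_state)
    # sign convention: largest-|loading| entry of each component is positive
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    eigenvalues = s**2 / m
    return PCAResult(
        coords=u * s,
        eigenvectors=u,
        eigenvalues=eigenvalues,
        loadings=vt,
        variant_index=used,
    )


def retain_pcs(pca: PCAResult) -> int:
    """Number of leading components with eigenvalue above 1."""
    return int((pca.eigenvalues > 1.0).sum())


def cluster_subpops(
    pca: PCAResult,
    k_range,
    n_pcs: int | None = None,
    random_state: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, int]:
    """K-means over retained PCs; k chosen by maximum mean silhouette.

    Degenerate inputs (all points identical, or no k >= 2 feasible) collapse
    to a single cluster.
    """
    n = pca.coords.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 1 or k_range[-1] > n:
        raise ValueError("k_range must lie within [1, n_samples]")
    use = n_pcs if n_pcs is not None else max(retain_pcs(pca), 1)
    coords = pca.coords[:, : max(use, 1)]
    if np.allclose(coords, coords[0]):
        return np.zeros(n, dtype=int), 1

    best_labels, best_k, best_score = np.zeros(n, dtype=int), 1, -np.inf
    for k in k_range:
        if k < 2 or k >= n:
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=random_state)
        labels = km.fit_predict(coords)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(coords, labels)
        if score > best_score:
            best_labels, best_k, best_score = labels, k, score
    return best_labels, best_k
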