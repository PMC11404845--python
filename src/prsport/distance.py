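"""Training-set PCA, projection, and individual-level genetic distance.

The genetic distance (GD) of a target individual is the Euclidean norm
of its projection onto the principal-component space of the training
genotypes: d_i = sqrt(sum_j pc_ij^2). Training scores are centered at
the origin by construction, so the "center of the training data" needs
no explicit vector and GD is invariant under orthogonal rotation of the
PC basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix

__all__ = ["PCModel", "fit_pca", "project", "genetic_distance"]


@dataclass
class PCModel:
    """Per-SNP loadings plus the training dosage means/SDs needed to
    standardize a target cohort identically to the training set."""

    loadings: np.ndarray  # variants x n_pc
    means: np.ndarray
    sds: np.ndarray
    variant_ids: list[str]
    explained_variance_ratio: np.ndarray
    n_pc: int


def fit_pca(gm: GenotypeMatrix, n_pc: int = 20) -> PCModel:
    """Exact PCA of the standardized training dosage matrix.

    Dosages are standardized per SNP as (g - mean)/SD (missing calls
    imputed to the mean first); monomorphic variants are an error —
    upstream LD pruning should have removed them. The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    if gm.m < n_pc:
        raise ValueError("fewer pruned variants than requested components")
    G = gm.dosages.copy()
    mean = np.nanmean(G, axis=0)
    nan = np.isnan(G)
    if nan.any():
        G[nan] = np.take(mean, np.nonzero(nan)[1])
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    if np.any(sd == 0):
        bad = gm.variants["id"][sd == 0].tolist()
        raise ValueError(f"monomorphic variants reached PCA: {bad[:5]}")
    X = (G - mu) / sd
    # economy SVD: columns of V are the SNP loadings
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt[:n_pc].T
    # deterministic sign: largest |loading| per component is positive
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(n_pc)])
    flip[flip == 0] = 1.0
    V = V * flip
    var = S**2
    return PCModel(
        loadings=V,
        means=mu,
        sds=sd,
        variant_ids=gm.variants["id"].tolist(),
        explained_variance_ratio=var[:n_pc] / var.sum(),
        n_pc=n_pc,
    )


def project(model: PCModel, gm: GenotypeMatrix) -> np.ndarray:
    """PC scores of target samples in the training PC space.

    Target dosages are matched to the model's variant list by ID,
    standardized with the TRAINING means/SDs (missing calls and absent
    variants fall back to the training mean, i.e. contribute zero) and
    multiplied by the loadings.
    """
    col = {vid: j for j, vid in enumerate(gm.variants["id"])}
    n = gm.n
    X = np.zeros((n, len(model.variant_ids)))
    for k, vid in enumerate(model.variant_ids):
        j = col.get(vid)
        if j is None:
            continue  # absent variant: standardized value 0
        g = gm.dosages[:, j]
        g = np.where(np.isnan(g), model.means[k], g)
        X[:, k] = (g - model.means[k]) / model.sds[k]
    return X @ model.loadings


def genetic_distance(scores: np.ndarray) -> np.ndarray:
    """d_i = sqrt(sum_j pc_ij^2) per sample."""
    return np.sqrt(np.sum(np.asarray(scores, dtype=float) ** 2, axis=1))
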