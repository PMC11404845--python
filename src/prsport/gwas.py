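"""Covariate-adjusted per-variant association testing.

Each variant is tested with the fixed-effect linear model
``phenotype ~ dosage + covariates`` (intercept included). The
implementation residualizes the phenotype and all dosages on the
covariates once (Frisch-Waugh-Lovell), which reproduces the full-model
dosage coefficient, its standard error and t test exactly while staying
vectorized over variants. Two-sided p-values come from the t
distribution with n - k - 1 degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeMatrix

__all__ = ["build_covariate_matrix", "run_gwas"]


def build_covariate_matrix(
    cohort: pd.DataFrame,
    columns: tuple[str, ...] = ("age", "age2", "sex", "height", "weight"),
    pcs: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the association covariate matrix (no intercept column;
    the intercept is added inside run_gwas). ``pcs`` appends leading
    genetic principal-component scores."""
    cols = [cohort[c].to_numpy(dtype=float) for c in columns if c in cohort.columns]
    X = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    if pcs is not None:
        X = np.column_stack([X, np.asarray(pcs, dtype=float)])
    return X


def run_gwas(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant beta, SE, t and two-sided p for a quantitative trait.

    Missing dosages are mean-imputed per variant. Variants monomorphic
    after imputation are flagged (``monomorphic`` column) and carry NaN
    statistics. Returns a frame with the summary-statistics schema
    (CHR POS ID A1 A2 BETA SE STAT P N MAF) plus the flag column.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    if gm.n != n:
        raise ValueError("phenotype length must match sample count")
    if covariates is None:
        covariates = np.empty((n, 0))
    C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    k = C.shape[1]  # includes intercept
    if n <= k + 2:
        raise ValueError("too few samples for the covariate set")
    if np.linalg.matrix_rank(C) < k:
        raise np.linalg.LinAlgError("rank-deficient covariate matrix")

    # residualize y and all dosages on the covariates via one QR
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)

    G = gm.dosages.copy()
    mean_dos = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    if nan_mask.any():
        G[nan_mask] = np.take(mean_dos, np.nonzero(nan_mask)[1])
    mono = G.std(axis=0) == 0

    G_r = G - Q @ (Q.T @ G)
    sxx = np.einsum("ij,ij->j", G_r, G_r)
    sxy = G_r.T @ y_r
    df = n - k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        sse = y_r @ y_r - beta * sxy
        se = np.sqrt(np.maximum(sse, 0.0) / df / sxx)
        tstat = beta / se
    pval = 2.0 * sps.t.sf(np.abs(tstat), df)
    beta[mono] = np.nan
    se[mono] = np.nan
    tstat[mono] = np.nan
    pval = np.where(mono, np.nan, pval)

    v = gm.variants
    n_obs = (~nan_mask).sum(axis=0)
    out = pd.DataFrame(
        {
            "CHR": v["chrom"].astype(str).to_numpy(),
            "POS": v["pos"].to_numpy(),
            "ID": v["id"].to_numpy(),
            "A1": v["alt"].to_numpy(),
            "A2": v["ref"].to_numpy(),
            "BETA": beta,
            "SE": se,
            "STAT": tstat,
            "P": pval,
            "N": n_obs,
            "MAF": gm.maf(),
            "monomorphic": mono,
        }
    )
    return out


def genomic_control_lambda(pvalues: np.ndarray) -> float:
    """lambda_GC: median association chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = sps.chi2.isf(p, df=1)
    return float(np.median(chi2) / sps.chi2.ppf(0.5, df=1))
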