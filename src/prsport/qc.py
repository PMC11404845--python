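"""Sample- and variant-level quality control.

Filters: extreme-BMD trimming, KING-robust kinship with greedy
relatedness pruning, the Hardy-Weinberg exact test, the four-step
variant filter (imputation INFO, MAF, missingness, HWE) and median
imputation of missing clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "exclude_bmd_outliers",
    "estimate_kinship",
    "kinship_matrix",
    "prune_related",
    "hwe_exact_test",
    "variant_qc",
    "impute_clinical_median",
]


@dataclass(frozen=True)
class QCThresholds:
    """Variant/sample filter thresholds.

    Defaults follow common post-imputation practice for biobank-scale
    data: INFO > 0.3, MAF > 0.001, missing rate < 0.1, HWE exact
    p > 1e-6; BMD trimmed at the 0.1th/99.9th percentiles; kinship cut
    at 0.0442 (third-degree relatives under the KING scale).
    """

    maf_min: float = 0.001
    miss_max: float = 0.1
    hwe_p_min: float = 1e-6
    info_min: float = 0.3
    bmd_outlier_pct: float = 0.1
    kinship_threshold: float = 0.0442


def exclude_bmd_outliers(
    cohort: pd.DataFrame,
    pct: float = 0.1,
    bmd_columns: tuple[str, ...] = ("bmd_fnk", "bmd_spn"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples with BMD below the pct-th or above the (100-pct)-th
    percentile at either site (union over sites).

    Percentile boundaries use the nearest-rank (inverted CDF) convention;
    a sample is removed when strictly outside [lower, upper]. Returns the
    filtered cohort and a removal log (sample index, site, reason).
    """
    if not (0.0 < pct < 50.0):
        raise ValueError("pct must lie in (0, 50)")
    removed = []
    drop = np.zeros(len(cohort), dtype=bool)
    for col in bmd_columns:
        if col not in cohort.columns:
            continue
        x = cohort[col].to_numpy(dtype=float)
        lo = np.quantile(x, pct / 100.0, method="inverted_cdf")
        hi = np.quantile(x, 1.0 - pct / 100.0, method="inverted_cdf")
        out = (x < lo) | (x > hi)
        for i in np.flatnonzero(out):
            removed.append((cohort.index[i], col,
                            "low" if x[i] < lo else "high"))
        drop |= out
    log = pd.DataFrame(removed, columns=["sample", "site", "reason"])
    return cohort.loc[~drop], log


def estimate_kinship(g_i: np.ndarray, g_j: np.ndarray,
                     min_overlap: int = 1000) -> float:
    """KING-robust between-family kinship coefficient.

    phi = (N_{Aa,Aa} - 2 N_{AA,aa}) / (N_Aa(i) + N_Aa(j)) over variants
    non-missing in both samples, where N_{Aa,Aa} counts doubly
    heterozygous variants, N_{AA,aa} opposite homozygotes and N_Aa(.)
    per-sample heterozygote counts. A duplicate (or self) gives 0.5,
    unrelated samples ~0.
    """
    gi = np.asarray(g_i, dtype=float)
    gj = np.asarray(g_j, dtype=float)
    ok = ~(np.isnan(gi) | np.isnan(gj))
    if ok.sum() < min_overlap:
        raise ValueError(
            f"insufficient overlapping variants ({int(ok.sum())} < {min_overlap})"
        )
    gi, gj = gi[ok], gj[ok]
    het_i = gi == 1
    het_j = gj == 1
    n_hh = int(np.sum(het_i & het_j))
    n_opp = int(np.sum(np.abs(gi - gj) == 2))
    denom = int(het_i.sum()) + int(het_j.sum())
    if denom == 0:
        return 0.0
    return (n_hh - 2 * n_opp) / denom


def kinship_matrix(gm: GenotypeMatrix, min_overlap: int = 1000) -> np.ndarray:
    """All-pairs KING-robust kinship (dense; intended for desk-scale n)."""
    n = gm.n
    phi = np.zeros((n, n))
    np.fill_diagonal(phi, 0.5)
    for i in range(n):
        for j in range(i + 1, n):
            phi[i, j] = phi[j, i] = estimate_kinship(
                gm.dosages[i], gm.dosages[j], min_overlap=min_overlap
            )
    return phi


def prune_related(phi: np.ndarray, threshold: float = 0.0442,
                  seed: int = 0) -> np.ndarray:
    """Indices of samples to keep so that no retained pair has
    kinship >= threshold.

    Greedy: repeatedly remove the sample with the most remaining
    relationships, breaking ties with a seeded random draw (which member
    of an isolated related pair goes is arbitrary by design).
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape[0] != phi.shape[1] or not np.allclose(phi, phi.T, equal_nan=True):
        raise ValueError("kinship matrix must be symmetric")
    n = phi.shape[0]
    adj = phi >= threshold
    np.fill_diagonal(adj, False)
    rng = np.random.default_rng(seed)
    alive = np.ones(n, dtype=bool)
    deg = adj.sum(axis=1).astype(float)
    while True:
        active = alive & (deg > 0)
        if not active.any():
            break
        dmax = deg[active].max()
        cand = np.flatnonzero(active & (deg == dmax))
        drop = int(rng.choice(cand))
        alive[drop] = False
        deg[adj[drop] & alive] -= 1
        deg[drop] = 0
    return np.flatnonzero(alive)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities
    of every admissible heterozygote count whose probability does not
    exceed that of the observed configuration. Monomorphic sites return
    1. Probabilities are computed by the standard recurrence on the
    heterozygote count (numerically stable, no factorials).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one sample required")
    n_a = 2 * n_aa + n_Aa  # rarer allele enforced below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    # admissible heterozygote counts share the parity of the rare allele
    # count; anchor the recurrence at the distribution's mode and move
    # outwards so the unnormalized terms only decay (no overflow):
    #   P(h-2)/P(h) = h(h-1) / (4 (hom_rare+1)(hom_common+1))
    #   P(h+2)/P(h) = 4 hom_rare hom_common / ((h+1)(h+2))
    probs = np.zeros(rare + 1)
    common = 2 * n - rare
    mode = int(round(rare * common / (2.0 * n)))
    if (mode % 2) != (rare % 2):
        mode += 1
    mode = min(mode, rare)
    probs[mode] = 1.0
    cur = mode
    while cur >= 2:
        hom_r = (rare - cur) // 2
        hom_c = n - cur - hom_r
        probs[cur - 2] = probs[cur] * cur * (cur - 1) / (
            4.0 * (hom_r + 1) * (hom_c + 1)
        )
        cur -= 2
    cur = mode
    while cur <= rare - 2:
        hom_r = (rare - cur) // 2
        hom_c = n - cur - hom_r
        probs[cur + 2] = probs[cur] * 4.0 * hom_r * hom_c / (
            (cur + 1) * (cur + 2)
        )
        cur += 2
    probs /= probs.sum()
    p_obs = probs[n_Aa]
    # sum of probabilities <= observed probability (small tolerance for
    # floating-point ties)
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def variant_qc(
    gm: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[np.ndarray, dict[str, int]]:
    """Keep variants passing ALL filters: INFO > info_min (when an
    info_score column is present), MAF > maf_min, missing rate <
    miss_max, HWE exact p > hwe_p_min.

    Returns (kept variant indices, per-filter removal tally). A variant
    failing several filters is attributed to the first in the order
    info -> maf -> missing -> hwe.
    """
    t = thresholds
    m = gm.m
    keep = np.ones(m, dtype=bool)
    tally = {"info": 0, "maf": 0, "missing": 0, "hwe": 0}

    if "info_score" in gm.variants.columns:
        info = gm.variants["info_score"].to_numpy(dtype=float)
        fail_info = ~(info > t.info_min)
    else:
        fail_info = np.zeros(m, dtype=bool)
    maf = gm.maf()
    fail_maf = ~(maf > t.maf_min)
    miss = gm.missing_rate()
    fail_miss = ~(miss < t.miss_max)
    fail_hwe = np.zeros(m, dtype=bool)
    for j in range(m):
        col = gm.dosages[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            fail_hwe[j] = True
            continue
        n_aa = int(np.sum(col == 0))
        n_het = int(np.sum(col == 1))
        n_AA = int(np.sum(col == 2))
        fail_hwe[j] = not (hwe_exact_test(n_AA, n_het, n_aa) > t.hwe_p_min)

    for j in range(m):
        if fail_info[j]:
            tally["info"] += 1
            keep[j] = False
        elif fail_maf[j]:
            tally["maf"] += 1
            keep[j] = False
        elif fail_miss[j]:
            tally["missing"] += 1
            keep[j] = False
        elif fail_hwe[j]:
            tally["hwe"] += 1
            keep[j] = False
    return np.flatnonzero(keep), tally


CONTINUOUS_COVARIATES = ("age", "age2", "height", "weight")
CATEGORICAL_COVARIATES = ("smoking", "drinking", "exercise")


def impute_clinical_median(
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] = CONTINUOUS_COVARIATES,
    categorical: tuple[str, ...] = CATEGORICAL_COVARIATES,
) -> pd.DataFrame:
    """Within-cohort median (continuous) / mode (categorical) imputation
    of missing clinical covariates.

    Samples missing sex or age are excluded rather than imputed; a
    covariate that is entirely missing raises.
    """
    out = cohort.copy()
    must_have = [c for c in ("sex", "age") if c in out.columns]
    if must_have:
        out = out.dropna(subset=must_have)
    for col in continuous:
        if col not in out.columns:
            continue
        if out[col].isna().all():
            raise ValueError(f"covariate {col!r} entirely missing")
        out[col] = out[col].fillna(out[col].median())
    for col in categorical:
        if col not in out.columns:
            continue
        if out[col].isna().all():
            raise ValueError(f"covariate {col!r} entirely missing")
        out[col] = out[col].fillna(out[col].mode().iloc[0])
    return out
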