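"""Linkage-disequilibrium tools: pairwise r², greedy clumping, sliding
window pruning and long-range-LD region exclusion.

r² is the squared Pearson correlation of alternate-allele dosages over
samples non-missing at both variants; it is symmetric and invariant to
allele-coding flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "ClumpConfig",
    "PruneConfig",
    "ld_r2",
    "clump",
    "prune_pairwise",
    "exclude_long_range_ld",
    "LONG_RANGE_LD_GRCH37",
]


@dataclass(frozen=True)
class ClumpConfig:
    r2_threshold: float = 0.05
    window_kb: float = 250.0
    p_threshold: float = 5e-4

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must lie in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass(frozen=True)
class PruneConfig:
    window_variants: int = 1000
    step: int = 50
    r2: float = 0.05

    def __post_init__(self) -> None:
        if self.step > self.window_variants:
            raise ValueError("step must not exceed window_variants")
        if self.step < 1 or self.window_variants < 1:
            raise ValueError("window and step must be >= 1")


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared dosage correlation on the jointly non-missing subset.

    Returns NaN when fewer than two complete pairs exist or either
    variant is monomorphic on the overlap (undefined LD).
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _filled_standardized(G: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages and z-score columns (0 for constant)."""
    X = G.copy()
    mean = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.take(mean, np.nonzero(nan)[1])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf
    return (X - mu) / sd


def clump(
    sumstats: pd.DataFrame,
    gm: GenotypeMatrix,
    cfg: ClumpConfig = ClumpConfig(),
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Greedy LD clumping of GWAS results.

    Candidates are variants with P < p_threshold, visited by ascending P
    (ties broken toward the lower genomic position). An unassigned
    candidate becomes an index; every unassigned variant on the same
    chromosome within window_kb whose r² with the index exceeds
    r2_threshold joins its clump. Returns the index-variant rows of
    ``sumstats`` sorted by P and the clump membership map.
    """
    ids = gm.variants["id"].tolist()
    id_to_col = {vid: j for j, vid in enumerate(ids)}
    ss = sumstats.dropna(subset=["P"])
    missing = set(ss["ID"]) - set(id_to_col)
    if missing:
        raise KeyError(f"sumstats variants absent from genotypes: {sorted(missing)[:5]}")
    cand = ss[ss["P"] < cfg.p_threshold]
    if cand.empty:
        warnings.warn("no variants pass the clump p-value threshold")
        return ss.iloc[0:0], {}
    order = cand.sort_values(["P", "CHR", "POS"], kind="mergesort").index
    X = _filled_standardized(gm.dosages)
    n = X.shape[0]

    assigned: set[str] = set()
    clumps: dict[str, list[str]] = {}
    index_rows = []
    pos_all = sumstats.set_index("ID")["POS"]
    chr_all = sumstats.set_index("ID")["CHR"].astype(str)
    # candidate pool for membership is every tested variant (assigned
    # ones drop out as clumps form)
    pool = ss
    for row_idx in order:
        vid = cand.loc[row_idx, "ID"]
        if vid in assigned:
            continue
        assigned.add(vid)
        index_rows.append(row_idx)
        vchr = str(cand.loc[row_idx, "CHR"])
        vpos = cand.loc[row_idx, "POS"]
        near = pool[
            (chr_all.loc[pool["ID"]].to_numpy() == vchr)
            & (np.abs(pos_all.loc[pool["ID"]].to_numpy() - vpos)
               <= cfg.window_kb * 1000)
            & (~pool["ID"].isin(assigned))
        ]
        members = []
        if not near.empty:
            xi = X[:, id_to_col[vid]]
            cols = [id_to_col[v] for v in near["ID"]]
            r = (X[:, cols].T @ xi) / n
            hit = r * r > cfg.r2_threshold
            members = [v for v, h in zip(near["ID"], hit) if h]
            assigned.update(members)
        clumps[vid] = members
    out = cand.loc[index_rows].sort_values(
        ["P", "CHR", "POS"], kind="mergesort"
    ).reset_index(drop=True)
    return out, clumps


def prune_pairwise(
    gm: GenotypeMatrix, cfg: PruneConfig = PruneConfig()
) -> np.ndarray:
    """Sliding-window LD pruning (kept variant indices).

    Windows of ``window_variants`` advance by ``step`` along the variant
    order; within a window, while any surviving pair has r² > cfg.r2 the
    worst pair's lower-MAF member is removed (ties: the later variant).
    Deterministic by construction.
    """
    m = gm.m
    if m == 0:
        raise ValueError("at least one variant required")
    X = _filled_standardized(gm.dosages)
    n = X.shape[0]
    maf = gm.maf()
    alive = np.ones(m, dtype=bool)
    start = 0
    while True:
        stop = min(start + cfg.window_variants, m)
        idx = np.flatnonzero(alive[start:stop]) + start
        if idx.size > 1:
            Xw = X[:, idx]
            r2 = (Xw.T @ Xw / n) ** 2
            np.fill_diagonal(r2, 0.0)
            local_alive = np.ones(idx.size, dtype=bool)
            while True:
                sub = r2[np.ix_(local_alive, local_alive)]
                if sub.size == 0 or sub.max() <= cfg.r2:
                    break
                li = np.flatnonzero(local_alive)
                a, b = np.unravel_index(np.argmax(sub), sub.shape)
                ia, ib = li[a], li[b]
                va, vb = idx[ia], idx[ib]
                # drop the lower-MAF member; tie -> the later position
                if (maf[va], -va) < (maf[vb], -vb):
                    local_alive[ia] = False
                else:
                    local_alive[ib] = False
            alive[idx[~local_alive]] = False
        if stop == m:
            break
        start += cfg.step
    return np.flatnonzero(alive)


# Catalogue of long-range LD / high-inversion regions on GRCh37
# (chromosome, start, end in 1-based inclusive Mb-scale coordinates),
# including the MHC and the 8p23 and 17q21 inversions.
LONG_RANGE_LD_GRCH37: tuple[tuple[str, int, int], ...] = (
    ("1", 48_000_000, 52_000_000),
    ("2", 86_000_000, 100_500_000),
    ("2", 134_500_000, 138_000_000),
    ("2", 183_000_000, 190_000_000),
    ("3", 47_500_000, 50_000_000),
    ("3", 83_500_000, 87_000_000),
    ("3", 89_000_000, 97_500_000),
    ("5", 44_500_000, 50_500_000),
    ("5", 98_000_000, 100_500_000),
    ("5", 129_000_000, 132_000_000),
    ("5", 135_500_000, 138_500_000),
    ("6", 25_500_000, 33_500_000),
    ("6", 57_000_000, 64_000_000),
    ("6", 140_000_000, 142_500_000),
    ("7", 55_000_000, 66_000_000),
    ("8", 8_000_000, 12_000_000),
    ("8", 43_000_000, 50_000_000),
    ("8", 112_000_000, 115_000_000),
    ("10", 37_000_000, 43_000_000),
    ("11", 46_000_000, 57_000_000),
    ("11", 87_500_000, 90_500_000),
    ("12", 33_000_000, 40_000_000),
    ("12", 109_500_000, 112_000_000),
    ("17", 40_000_000, 45_000_000),
    ("20", 32_000_000, 34_500_000),
)


def exclude_long_range_ld(
    variants: pd.DataFrame,
    region_table: tuple[tuple[str, int, int], ...] = LONG_RANGE_LD_GRCH37,
) -> np.ndarray:
    """Indices of variants falling outside every region.

    Regions are given as 1-based inclusive (chrom, start, end) and
    applied as half-open [start, end): a variant exactly at ``start`` is
    excluded, one at ``end`` is kept.
    """
    chrom = variants["chrom"].astype(str).to_numpy()
    pos = variants["pos"].to_numpy()
    bad = np.zeros(len(variants), dtype=bool)
    for c, start, end in region_table:
        bad |= (chrom == str(c)) & (pos >= start) & (pos < end)
    return np.flatnonzero(~bad)
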