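"""End-to-end orchestration of the four study phases on a simulated
multi-ancestry cohort: simulate -> QC -> split -> GWAS -> clump ->
train the threshold grid -> select -> evaluate with genetic distance ->
fracture-risk survival analysis.

Every stochastic stage receives a sub-seed derived by stable hashing of
(master seed, stage name), so a rerun with the same config reproduces
all numeric outputs bitwise.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import distance, evaluate, fracture, gwas, ld, models, qc, simulate
from .io import GenotypeMatrix, save_model, write_summary_stats

__all__ = ["PipelineConfig", "stage_seed", "split_cohort", "run_pipeline"]


def stage_seed(master: int, stage: str) -> int:
    """Stable sub-seed below 2^31 for a named pipeline stage."""
    return zlib.crc32(f"{master}:{stage}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    """Single document driving a full simulated-study run.

    Population 0 is the training population (split 60/20/20 by
    default); the remaining populations become external test cohorts at
    their configured Fst from the shared ancestral pool. A disjoint
    fracture case-control cohort is simulated from population 0.
    """

    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    m_variants: int = 2000
    n_training_pop: int = 3000
    fst_targets: tuple[float, ...] = (0.1, 0.2)
    n_per_target: int = 500
    cline_within_sd: float = 0.05
    ld_block: simulate.LDBlockSpec = field(
        default_factory=lambda: simulate.LDBlockSpec(block_length=10,
                                                     within_block_rho=0.9)
    )
    trait: simulate.TraitArchitecture = field(
        default_factory=lambda: simulate.TraitArchitecture(
            n_causal=40, h2_snp=0.4, clinical_frac=0.25
        )
    )
    causal_typed: bool = False  # when False, causal SNPs are absent from
    # the assay panel and models must rely on LD tags (the realistic case
    # that produces cross-population performance decay)
    hazard: simulate.HazardSpec = field(default_factory=simulate.HazardSpec)
    n_case_control: int = 4000
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    grid: models.ThresholdGrid = field(default_factory=models.ThresholdGrid)
    training: models.TrainingConfig = field(default_factory=models.TrainingConfig)
    families: tuple[str, ...] = ("prs", "lasso")
    n_pc_gwas: int = 20
    n_pc_model: int = 10
    clump: ld.ClumpConfig = field(default_factory=ld.ClumpConfig)
    prune: ld.PruneConfig = field(
        default_factory=lambda: ld.PruneConfig(window_variants=200, step=50)
    )
    site: str = "fnk"

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(f <= 0 for f in self.split_fractions):
            raise ValueError("split fractions must be positive")


def split_cohort(n: int, fractions=(0.6, 0.2, 0.2), seed: int = 0) -> np.ndarray:
    """Random disjoint exhaustive split labels (0=train, 1=selection,
    2=test). Sizes are floor allocations; remainder samples go to
    training."""
    fractions = tuple(fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    sizes = [int(np.floor(f * n)) for f in fractions]
    sizes[0] += n - sum(sizes)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    start = 0
    for lab, sz in enumerate(sizes):
        labels[perm[start:start + sz]] = lab
        start += sz
    return labels


def _wrap(geno: np.ndarray, variants: pd.DataFrame, prefix: str) -> GenotypeMatrix:
    samples = [f"{prefix}{i}" for i in range(geno.shape[0])]
    return GenotypeMatrix(geno, samples, variants[["chrom", "pos", "id", "ref", "alt"]])


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full study; write artifacts under ``outdir``; return a
    summary dict with the evaluation table and fracture statistics."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    cfg = config
    # ---- Phase 0: simulation -------------------------------------------
    # target cohorts sit on a shared ancestry cline at offset sqrt(2*Fst)
    # from the training population (Hudson Fst ~ offset^2 / 2)
    n_pops = 1 + len(cfg.fst_targets)
    pop_spec = simulate.PopulationSpec(
        fst=(0.0,) * n_pops,
        sample_sizes=(cfg.n_training_pop,)
        + (cfg.n_per_target,) * len(cfg.fst_targets),
    )
    cline = simulate.ClineSpec(
        pop_offset=(0.0,) + tuple(np.sqrt(2 * f) for f in cfg.fst_targets),
        within_pop_sd=(cfg.cline_within_sd,) * n_pops,
    )
    freqs = simulate.simulate_population_frequencies(
        pop_spec, cfg.m_variants, stage_seed(cfg.seed, "freqs"),
        block_length=cfg.ld_block.block_length,
    )
    geno, pops, variants = simulate.simulate_genotypes(
        freqs, pop_spec.sample_sizes, cfg.ld_block,
        stage_seed(cfg.seed, "genotypes"), cline=cline,
    )
    # causal variants: one per distinct LD block (block centre)
    rng_causal = np.random.default_rng(stage_seed(cfg.seed, "causal"))
    L = cfg.ld_block.block_length
    causal_blocks = rng_causal.choice(cfg.m_variants // L, cfg.trait.n_causal,
                                      replace=False)
    causal_idx = np.sort(causal_blocks * L + L // 2)
    cohort, truth = simulate.simulate_phenotypes(
        geno, variants, cfg.trait, stage_seed(cfg.seed, "phenotypes"),
        causal_idx=causal_idx,
    )
    cohort["population"] = pops
    panel = (np.arange(cfg.m_variants) if cfg.causal_typed
             else np.setdiff1d(np.arange(cfg.m_variants), causal_idx))
    gm_all = _wrap(geno, variants, "S").subset_variants(panel)
    note(f"simulated {gm_all.n} samples x {cfg.m_variants} variants "
         f"({gm_all.m} on the assay panel)")

    # ---- Phase 0b: QC ---------------------------------------------------
    kept, tally = qc.variant_qc(gm_all, cfg.qc_thresholds)
    gm_all = gm_all.subset_variants(kept)
    note(f"variant QC kept {len(kept)} variants; removals {tally}")
    cohort, removal_log = qc.exclude_bmd_outliers(
        cohort, cfg.qc_thresholds.bmd_outlier_pct
    )
    keep_idx = cohort.index.to_numpy()
    gm_all = gm_all.subset_samples(keep_idx)
    pops = pops[keep_idx]
    cohort = cohort.reset_index(drop=True)
    note(f"BMD outlier exclusion removed {len(removal_log)} samples")

    # ---- split ----------------------------------------------------------
    is_pop0 = pops == 0
    idx0 = np.flatnonzero(is_pop0)
    labels = split_cohort(idx0.size, cfg.split_fractions,
                          stage_seed(cfg.seed, "split"))
    split_idx = {name: idx0[labels == i]
                 for i, name in enumerate(("train", "selection", "test"))}
    ext_cohorts = {
        f"pop{k}_fst{cfg.fst_targets[k - 1]:g}": np.flatnonzero(pops == k)
        for k in range(1, n_pops)
    }

    y_col = f"bmd_{cfg.site}"
    gm = {name: gm_all.subset_samples(ix) for name, ix in split_idx.items()}
    co = {name: cohort.iloc[ix].reset_index(drop=True)
          for name, ix in split_idx.items()}
    for name, ix in ext_cohorts.items():
        gm[name] = gm_all.subset_samples(ix)
        co[name] = cohort.iloc[ix].reset_index(drop=True)

    # ---- PCA / genetic distance ----------------------------------------
    # variants can be monomorphic within the training split even after
    # pooled QC; PCA standardization requires polymorphism
    with np.errstate(invalid="ignore"):
        train_poly = np.flatnonzero(np.nanstd(gm["train"].dosages, axis=0) > 0)
    pruned = ld.prune_pairwise(gm["train"].subset_variants(train_poly),
                               cfg.prune)
    pruned = train_poly[pruned]
    lr_keep = ld.exclude_long_range_ld(
        gm["train"].variants.iloc[pruned].reset_index(drop=True))
    pruned = pruned[lr_keep]
    n_pc = min(cfg.n_pc_gwas, max(2, pruned.size - 1))
    pca = distance.fit_pca(gm["train"].subset_variants(pruned), n_pc=n_pc)
    note(f"PCA on {pruned.size} pruned variants, {n_pc} components")
    pcs, gd = {}, {}
    for name in gm:
        sc = distance.project(pca, gm[name])
        pcs[name] = sc
        gd[name] = distance.genetic_distance(sc)
        kmod = min(cfg.n_pc_model, n_pc)
        for j in range(kmod):
            co[name][f"pc{j + 1}"] = sc[:, j]

    # ---- GWAS + clumping ------------------------------------------------
    cov = gwas.build_covariate_matrix(co["train"],
                                      pcs=pcs["train"][:, :n_pc])
    sumstats = gwas.run_gwas(gm["train"], co["train"][y_col].to_numpy(), cov)
    write_summary_stats(sumstats.drop(columns=["monomorphic"]),
                        out / "sumstats.tsv")
    clump_cfg = ld.ClumpConfig(
        r2_threshold=cfg.clump.r2_threshold,
        window_kb=cfg.clump.window_kb,
        p_threshold=max(cfg.grid.thresholds),
    )
    index_stats, clumps = ld.clump(sumstats, gm["train"], clump_cfg)
    clumped_ids = index_stats["ID"].tolist()
    note(f"clumping: {len(clumped_ids)} index variants")

    # ---- model fitting over the threshold grid --------------------------
    y_train = co["train"][y_col].to_numpy()
    y_sel = co["selection"][y_col].to_numpy()
    clinical = models.fit_clinical_model(co["train"], y_train)
    candidates: list = []
    for family in cfg.families:
        candidates += models.fit_threshold_grid(
            family, cfg.grid, co["train"], gm["train"], y_train,
            sumstats, clumped_ids,
            selection=(co["selection"], gm["selection"], y_sel),
            cfg=cfg.training,
        )
    sel_r2 = [evaluate.r_squared(y_sel, mod.predict(co["selection"], gm["selection"]))
              for mod in candidates]
    best = evaluate.select_best_model(candidates, sel_r2)
    clin_sel_r2 = evaluate.r_squared(y_sel, clinical.predict(co["selection"]))
    note(
        f"selected {best.family} model, threshold {best.threshold:g}, "
        f"{best.n_snps} SNPs, selection R2 {max(sel_r2):.4f} "
        f"(clinical-only {clin_sel_r2:.4f})"
    )
    mdir = out / "models"
    mdir.mkdir(exist_ok=True)
    save_model(clinical, mdir / "clinical.json")
    save_model(best, mdir / "best.json")

    # ---- evaluation table ----------------------------------------------
    rows = []
    for name in ["test", *ext_cohorts]:
        yv = co[name][y_col].to_numpy()
        yhat = best.predict(co[name], gm[name])
        rows.append(
            {
                "cohort": name,
                "n": len(yv),
                "avg_gd": float(gd[name].mean()),
                "r2": evaluate.r_squared(yv, yhat),
                "pcc": evaluate.pcc(yv, yhat),
                "r2_clinical": evaluate.r_squared(
                    yv, clinical.predict(co[name])),
            }
        )
    eval_table = pd.DataFrame(rows)
    eval_table.to_csv(out / "eval_table.tsv", sep="\t", index=False)

    # ---- fracture case-control phase ------------------------------------
    cc_sizes = tuple(
        cfg.n_case_control if k == 0 else 0 for k in range(n_pops)
    )
    cc_geno, _, cc_variants = simulate.simulate_genotypes(
        freqs, cc_sizes, cfg.ld_block, stage_seed(cfg.seed, "casecontrol"),
        cline=cline,
    )
    cc_gm_full = _wrap(cc_geno, cc_variants, "CC")
    cc_gm = cc_gm_full.subset_variants(
        np.flatnonzero(cc_variants["id"].isin(gm_all.variants["id"]).to_numpy())
    )
    # same phenotype stage seed => identical causal set and effect sizes
    # as the DXA cohorts, so the trained model is applicable
    cc_cohort, _ = simulate.simulate_phenotypes(
        cc_geno, cc_variants, cfg.trait, stage_seed(cfg.seed, "phenotypes"),
        causal_idx=truth["causal_idx"],
    )
    cc_cohort = simulate.simulate_fracture_outcomes(
        cc_cohort, cfg.hazard, stage_seed(cfg.seed, "outcomes"),
        bmd_column=y_col,
    )
    sc = distance.project(pca, cc_gm)
    for j in range(min(cfg.n_pc_model, n_pc)):
        cc_cohort[f"pc{j + 1}"] = sc[:, j]
    pred = best.predict(cc_cohort, cc_gm)
    cc_cohort["pred_bmd_sd"] = (pred - pred.mean()) / pred.std()

    strata = fracture.stratify_and_incidence(
        cc_cohort["pred_bmd_sd"].to_numpy(), cc_cohort["event"].to_numpy()
    )
    cases = cc_cohort.loc[cc_cohort["event"] == 1, "pred_bmd_sd"]
    ctrls = cc_cohort.loc[cc_cohort["event"] == 0, "pred_bmd_sd"]
    t_stat, t_df, t_p = fracture.welch_t_test(ctrls, cases)
    lr_chi2, lr_p = fracture.log_rank(
        cc_cohort["time"], cc_cohort["event"], strata.group_index
    )
    cox_covs = ["pred_bmd_sd", "age", "sex", "height", "weight",
                "smoking", "drinking", "exercise"]
    cox_full = fracture.fit_cox(cc_cohort, cox_covs)
    cox_clin = fracture.fit_cox(cc_cohort, cox_covs[1:])
    hr = float(np.exp(cox_full.params_["pred_bmd_sd"]))
    hr_ci = tuple(
        np.exp(cox_full.confidence_intervals_.loc["pred_bmd_sd"]).tolist()
    )
    lrt_chi2, lrt_df, lrt_p = fracture.likelihood_ratio_test(cox_full, cox_clin)
    risk_diff = fracture.absolute_risk_10y(cox_full, cc_cohort, "pred_bmd_sd")
    lo = fracture.logistic_or(
        cc_cohort["event"].to_numpy(), cc_cohort["pred_bmd_sd"].to_numpy(),
        cc_cohort[cox_covs[1:]],
    )
    km_points = pd.concat(
        [
            fracture.km_estimate(
                cc_cohort.loc[strata.group_index == g, "time"],
                cc_cohort.loc[strata.group_index == g, "event"],
            ).assign(group=strata.labels[g])
            for g in range(len(strata.labels))
            if (strata.group_index == g).any()
        ]
    )
    km_points.to_csv(out / "km_curves.tsv", sep="\t", index=False)

    fracture_summary = {
        "welch_t": {"t": t_stat, "df": t_df, "p": t_p},
        "strata": {
            "labels": strata.labels,
            "n": strata.n.tolist(),
            "events": strata.events.tolist(),
            "incidence_pct": (100 * strata.incidence).round(2).tolist(),
        },
        "log_rank": {"chi2": lr_chi2, "p": lr_p},
        "cox": {
            "hr_per_sd": hr,
            "hr_ci": hr_ci,
            "c_index": float(cox_full.concordance_index_),
            "percent_risk_decrease": fracture.percent_risk_change(hr),
            "abs_risk_diff_10y_pct": 100 * risk_diff,
            "lrt": {"chi2": lrt_chi2, "df": lrt_df, "p": lrt_p},
        },
        "logistic": {"or_per_sd": lo["or"], "ci": lo["ci"], "p": lo["p"]},
    }

    summary = {
        "config_seed": cfg.seed,
        "selection": {
            "family": best.family,
            "threshold": best.threshold,
            "n_snps": best.n_snps,
            "selection_r2": float(max(sel_r2)),
            "clinical_selection_r2": float(clin_sel_r2),
        },
        "eval_table": eval_table.to_dict(orient="records"),
        "fracture": fracture_summary,
        "log": log,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary
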