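"""Synthetic multi-ancestry cohorts for genomic-prediction experiments.

Generates the statistical structure the downstream pipeline assumes:

* K populations differentiated by a per-population drift parameter
  (Balding–Nichols allele-frequency model),
* LD-blocked diploid genotypes (rank-copy copula haplotype chains),
* a polygenic quantitative trait ("BMD") at two skeletal sites with
  clinical covariate effects (age, age², sex, height, weight, smoking,
  drinking, exercise),
* fragility-fracture survival times whose hazard depends on the true
  trait value.

All operations take an explicit integer seed; there is no global
random state, and identical seeds give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "LDBlockSpec",
    "ClineSpec",
    "TraitArchitecture",
    "HazardSpec",
    "AlleleFrequencyTable",
    "simulate_population_frequencies",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotypes",
    "simulate_fracture_outcomes",
    "hudson_fst",
]

SITES = ("FNK", "SPN")

# population means/SDs used for the trait scale (g/cm^2), chosen to match
# typical DXA reference ranges at the two sites
SITE_MEAN = {"FNK": 0.94, "SPN": 1.10}
SITE_SD = {"FNK": 0.14, "SPN": 0.18}


@dataclass(frozen=True)
class PopulationSpec:
    """Ancestry structure: K populations drifted from a shared ancestral pool.

    ``fst`` is the per-population Balding–Nichols drift parameter F_k in
    [0, 1); F_k = 0 reproduces the ancestral frequency exactly.
    """

    fst: tuple[float, ...]
    sample_sizes: tuple[int, ...]
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if len(self.fst) != len(self.sample_sizes):
            raise ValueError("fst and sample_sizes must have equal length")
        if len(self.fst) == 0:
            raise ValueError("at least one population required")
        for f in self.fst:
            if not (0.0 <= f < 1.0):
                raise ValueError(f"Fst must lie in [0, 1), got {f}")
        for n in self.sample_sizes:
            if n < 1:
                raise ValueError("sample sizes must be >= 1")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must be within (0, 0.5]")

    @property
    def n_populations(self) -> int:
        return len(self.fst)


@dataclass(frozen=True)
class LDBlockSpec:
    """Block structure for linkage disequilibrium.

    Within a block adjacent variants have haplotype correlation ~
    ``within_block_rho``; distinct blocks are independent.
    """

    block_length: int = 10
    within_block_rho: float = 0.8

    def __post_init__(self) -> None:
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must lie in [0, 1)")


@dataclass(frozen=True)
class TraitArchitecture:
    """Polygenic architecture of the simulated BMD trait.

    ``h2_snp`` and ``clinical_frac`` are target variance fractions of the
    total trait variance attributable to the causal SNPs and to the
    clinical covariates; the remainder is i.i.d. Gaussian residual.
    The two sites share the causal SNP set with effect correlation
    ``site_effect_corr``.
    """

    n_causal: int = 30
    h2_snp: float = 0.25
    clinical_frac: float = 0.25
    site_effect_corr: float = 0.6
    clinical_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age": -0.3,
            "age2": -0.1,
            "sex": 0.5,
            "height": 0.2,
            "weight": 0.6,
            "smoking": -0.15,
            "drinking": 0.05,
            "exercise": 0.1,
        }
    )

    def __post_init__(self) -> None:
        if self.n_causal < 0:
            raise ValueError("n_causal must be >= 0")
        if not (0.0 <= self.h2_snp <= 1.0):
            raise ValueError("h2_snp must lie in [0, 1]")
        if not (0.0 <= self.clinical_frac <= 1.0):
            raise ValueError("clinical_frac must lie in [0, 1]")
        if self.h2_snp + self.clinical_frac > 1.0 + 1e-12:
            raise ValueError(
                "h2_snp + clinical variance fraction exceeds 1 "
                f"({self.h2_snp} + {self.clinical_frac})"
            )
        if not (-1.0 <= self.site_effect_corr <= 1.0):
            raise ValueError("site_effect_corr must lie in [-1, 1]")


@dataclass(frozen=True)
class HazardSpec:
    """Exponential fracture hazard modified by true BMD and covariates.

    ``gamma_bmd`` is the log hazard ratio per SD of true BMD (negative =
    higher BMD protects). Follow-up is administratively censored at
    ``censor_horizon`` years.
    """

    baseline_rate: float = 0.006
    gamma_bmd: float = float(np.log(0.7))
    covariate_log_hazards: dict[str, float] = field(
        default_factory=lambda: {"age": 0.3, "sex": 0.2}
    )
    censor_horizon: float = 10.0

    def __post_init__(self) -> None:
        if not self.baseline_rate > 0:
            raise ValueError("baseline_rate must be positive")
        if not self.censor_horizon > 0:
            raise ValueError("censor_horizon must be positive")


@dataclass(frozen=True)
class ClineSpec:
    """Ancestry-continuum structure layered on the population model.

    Human diversity follows a genetic ancestry continuum rather than
    discrete clusters; this spec realizes it as a single shared drift
    direction field eta_j over loci. Each individual i carries an
    ancestry coefficient a_i ~ N(pop_offset_k, within_pop_sd_k^2) and
    samples its alleles at frequency
    p_ij = clip(p_kj + a_i * eta_j * sqrt(p_kj (1-p_kj))).
    A population with offset A sits at Hudson Fst ~ A^2 from one at
    offset 0, and a training set with within_pop_sd > 0 exposes the
    cline direction to its own PCA — which is what makes projection-
    based genetic distance informative for more-drifted cohorts.
    """

    pop_offset: tuple[float, ...]
    within_pop_sd: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.pop_offset) != len(self.within_pop_sd):
            raise ValueError("pop_offset and within_pop_sd length mismatch")
        if any(s < 0 for s in self.within_pop_sd):
            raise ValueError("within_pop_sd must be >= 0")


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Ancestral and per-population alternate-allele frequencies.

    ``pop_freqs`` has shape (n_populations, m); variants are grouped in
    LD blocks of ``block_length`` loci sharing one ancestral frequency.
    """

    ancestral: np.ndarray
    pop_freqs: np.ndarray
    block_length: int = 1

    @property
    def m(self) -> int:
        return self.ancestral.shape[0]


def simulate_population_frequencies(
    spec: PopulationSpec, m: int, seed: int, block_length: int = 1
) -> AlleleFrequencyTable:
    """Draw ancestral and drifted per-population allele frequencies.

    Ancestral frequency p ~ Uniform(ancestral_maf_range), shared by all
    loci of an LD block (so that block-wise haplotype correlation is
    attainable downstream); the frequency of population k is drawn per
    locus from Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k), the Balding–Nichols
    model, or equals p exactly when F_k = 0.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = spec.ancestral_maf_range
    n_blocks = -(-m // block_length)
    p_block = rng.uniform(lo, hi, size=n_blocks)
    ancestral = np.repeat(p_block, block_length)[:m]

    pop_freqs = np.empty((spec.n_populations, m))
    for k, f in enumerate(spec.fst):
        if f == 0.0:
            pop_freqs[k] = ancestral
        else:
            scale = (1.0 - f) / f
            a = ancestral * scale
            b = (1.0 - ancestral) * scale
            pop_freqs[k] = rng.beta(a, b)
    # keep loci strictly polymorphic for downstream numerics
    np.clip(pop_freqs, 1e-12, 1.0 - 1e-12, out=pop_freqs)
    return AlleleFrequencyTable(ancestral=ancestral, pop_freqs=pop_freqs,
                                block_length=block_length)


def _haplotypes(freqs: np.ndarray, rho: float, block_length: int,
                n_hap: int, rng: np.random.Generator) -> np.ndarray:
    """Rank-copy copula chain: uniform rank u_j is copied from u_{j-1}
    with probability rho (within a block) or drawn fresh; the allele is
    the indicator u_j < p_j. Marginals are exact Bernoulli(p_j); the
    adjacent-allele correlation equals rho when adjacent frequencies are
    equal and is attenuated otherwise.

    ``freqs`` may be (m,) for a shared population frequency or
    (n_hap, m) for per-individual frequencies (ancestry cline).
    """
    m = freqs.shape[-1]
    u = rng.random((n_hap, m))
    if rho > 0.0 and block_length > 1:
        copy = rng.random((n_hap, m)) < rho
        block_starts = np.arange(0, m, block_length)
        copy[:, block_starts] = False  # chains restart at block boundaries
        for j in range(1, m):
            cj = copy[:, j]
            if cj.any():
                u[cj, j] = u[cj, j - 1]
    p = freqs[None, :] if freqs.ndim == 1 else freqs
    return (u < p).astype(np.int8)


def simulate_genotypes(
    freqs: AlleleFrequencyTable,
    sample_sizes: tuple[int, ...],
    spec: LDBlockSpec,
    seed: int,
    missing_rate: float = 0.0,
    cline: ClineSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Diploid dosages for all populations of an AlleleFrequencyTable.

    Returns ``(genotypes, pop_labels, variants)``: genotypes is an
    (n_total, m) float array of {0,1,2} dosages (NaN for missing calls),
    pop_labels the per-sample population index, and variants a metadata
    frame (chrom, pos, id, ref, alt, block). Genotype = sum of two
    independent haplotypes from the rank-copy copula chain. An optional
    :class:`ClineSpec` shifts each individual's sampling frequencies
    along a shared ancestry-continuum direction.
    """
    if freqs.pop_freqs.shape[0] != len(sample_sizes):
        raise ValueError("sample_sizes must match the table's populations")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    if cline is not None and len(cline.pop_offset) != len(sample_sizes):
        raise ValueError("cline spec must cover every population")
    rng = np.random.default_rng(seed)
    m = freqs.m
    blocks = spec.block_length
    eta = rng.standard_normal(m) if cline is not None else None
    parts, labels = [], []
    for k, n in enumerate(sample_sizes):
        pk = freqs.pop_freqs[k]
        if cline is not None:
            a = cline.pop_offset[k] + cline.within_pop_sd[k] * rng.standard_normal(n)
            pk = np.clip(
                pk[None, :] + a[:, None] * eta[None, :]
                * np.sqrt(pk * (1.0 - pk))[None, :],
                1e-6, 1.0 - 1e-6,
            )
        h1 = _haplotypes(pk, spec.within_block_rho, blocks, n, rng)
        h2 = _haplotypes(pk, spec.within_block_rho, blocks, n, rng)
        g = (h1 + h2).astype(np.float64)
        parts.append(g)
        labels.append(np.full(n, k))
    geno = np.vstack(parts)
    pops = np.concatenate(labels)
    if missing_rate > 0.0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = np.nan
    variants = variant_frame(m, blocks)
    return geno, pops, variants


def variant_frame(m: int, block_length: int) -> pd.DataFrame:
    """Synthetic variant metadata: one chromosome, 5 kb spacing."""
    pos = 1 + 5000 * np.arange(m)
    return pd.DataFrame(
        {
            "chrom": np.repeat("1", m),
            "pos": pos.astype(np.int64),
            "id": [f"snp{i}" for i in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "block": np.arange(m) // block_length,
        }
    )


def simulate_covariates(n: int, seed: int,
                        age_range: tuple[float, float] = (40.0, 70.0)
                        ) -> pd.DataFrame:
    """Clinical covariates with sex-dependent height/weight means.

    Mimics a middle-aged biobank imaging cohort: age uniform over
    ``age_range``; sex balanced; height/weight Gaussian with male and
    female means; smoking/drinking/exercise Bernoulli lifestyle flags.
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(*age_range, size=n)
    sex = rng.integers(0, 2, size=n)  # 1 = male
    height = np.where(sex == 1, rng.normal(175.0, 7.0, n), rng.normal(162.0, 6.0, n))
    weight = np.where(sex == 1, rng.normal(82.0, 13.0, n), rng.normal(70.0, 13.0, n))
    smoking = (rng.random(n) < 0.38).astype(int)
    drinking = (rng.random(n) < 0.90).astype(int)
    exercise = (rng.random(n) < 0.85).astype(int)
    return pd.DataFrame(
        {
            "age": age,
            "age2": age**2,
            "sex": sex,
            "height": height,
            "weight": weight,
            "smoking": smoking,
            "drinking": drinking,
            "exercise": exercise,
        }
    )


def simulate_phenotypes(
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    arch: TraitArchitecture,
    seed: int,
    covariates: pd.DataFrame | None = None,
    causal_idx: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Two-site BMD phenotypes from genotypes + clinical covariates.

    BMD_site = site_mean + site_sd * (sqrt(clin_frac)*C + g + e) where C
    is the standardized clinical predictor, g the causal-SNP score scaled
    so its realized variance fraction equals ``h2_snp``, and e Gaussian
    residual filling the remaining fraction.

    Returns the cohort table and a truth dict (causal indices, per-site
    standardized effects, true genetic scores) for oracle checks.
    """
    n, m = genotypes.shape
    if arch.n_causal > m:
        raise ValueError("n_causal exceeds variant count")
    # independent child streams so that e.g. supplying causal_idx leaves
    # the effect-size draws unchanged
    ss = np.random.SeedSequence(seed).spawn(4)
    rng_cov, rng_causal, rng_eff, rng_res = map(np.random.default_rng, ss)
    if covariates is None:
        covariates = simulate_covariates(n, seed=int(rng_cov.integers(2**31)))
    cov = covariates.reset_index(drop=True)

    # clinical predictor: named effects on z-scored covariates, rescaled
    # to the target variance fraction
    cvals = np.zeros(n)
    for name, beta in arch.clinical_effects.items():
        x = cov[name].to_numpy(dtype=float)
        sd = x.std()
        if sd > 0:
            cvals += beta * (x - x.mean()) / sd
    csd = cvals.std()
    cpred = cvals / csd if csd > 0 else np.zeros(n)

    if causal_idx is None:
        causal_idx = np.sort(rng_causal.choice(m, size=arch.n_causal,
                                               replace=False))
    else:
        causal_idx = np.asarray(causal_idx)

    # shared causal set, correlated per-site effects
    base = rng_eff.standard_normal(arch.n_causal)
    rho = arch.site_effect_corr
    eff = {
        "FNK": base,
        "SPN": rho * base + np.sqrt(max(0.0, 1 - rho**2))
        * rng_eff.standard_normal(arch.n_causal),
    }

    g_causal = np.nan_to_num(genotypes[:, causal_idx])
    gsd = g_causal.std(axis=0)
    gsd[gsd == 0] = 1.0
    gz = (g_causal - g_causal.mean(axis=0)) / gsd

    out = cov.copy()
    truth: dict = {"causal_idx": causal_idx, "effects": {}, "gscore": {}}
    for site in SITES:
        if arch.n_causal > 0 and arch.h2_snp > 0:
            graw = gz @ eff[site]
            s = graw.std()
            gscore = np.sqrt(arch.h2_snp) * (graw - graw.mean()) / (s if s > 0 else 1.0)
        else:
            gscore = np.zeros(n)
        resid_frac = max(0.0, 1.0 - arch.h2_snp - arch.clinical_frac)
        latent = (
            np.sqrt(arch.clinical_frac) * cpred
            + gscore
            + np.sqrt(resid_frac) * rng_res.standard_normal(n)
        )
        out[f"bmd_{site.lower()}"] = SITE_MEAN[site] + SITE_SD[site] * latent
        truth["effects"][site] = eff[site]
        truth["gscore"][site] = gscore
    return out, truth


def simulate_fracture_outcomes(
    cohort: pd.DataFrame, hz: HazardSpec, seed: int,
    bmd_column: str = "bmd_fnk",
) -> pd.DataFrame:
    """Exponential fracture times given true BMD and covariates.

    The event rate for individual i is
    baseline_rate * exp(gamma_bmd * z_i + sum_c gamma_c * z_ic) with z
    the within-cohort SD-standardization; observed time is min(event,
    censor_horizon) with the matching event indicator.
    """
    rng = np.random.default_rng(seed)
    bmd = cohort[bmd_column].to_numpy(dtype=float)
    z = (bmd - bmd.mean()) / bmd.std()
    lp = hz.gamma_bmd * z
    for name, gamma in hz.covariate_log_hazards.items():
        x = cohort[name].to_numpy(dtype=float)
        sd = x.std()
        if sd > 0:
            lp = lp + gamma * (x - x.mean()) / sd
    rate = hz.baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    time = np.minimum(t_event, hz.censor_horizon)
    event = (t_event <= hz.censor_horizon).astype(int)
    out = cohort.copy()
    out["time"] = time
    out["event"] = event
    out["bmd_z"] = z
    return out


def hudson_fst(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Hudson's Fst estimator from dosage matrices of two populations.

    Uses the ratio-of-averages form: mean over loci of
    (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) divided by the mean of
    p1(1-p2) + p2(1-p1), with p the sample alternate-allele frequency.
    """
    n1 = 2 * np.sum(~np.isnan(g_a), axis=0)
    n2 = 2 * np.sum(~np.isnan(g_b), axis=0)
    p1 = np.nansum(g_a, axis=0) / n1
    p2 = np.nansum(g_b, axis=0) / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return float(np.sum(num[ok]) / np.sum(den[ok]))
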