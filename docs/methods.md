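# Methods

This note documents the models and procedures the package implements,
the parameters that matter, the design choices made where the design
was genuinely open, and what the synthetic-data experiments do and do
not demonstrate.

## The study design

The pipeline reproduces a four-phase genomic-prediction study for
DXA-BMD at two skeletal sites (femoral neck, FNK; lumbar spine, SPN):

1. train a family of prediction models combining clinical factors and
   GWAS-selected SNPs on one population's training split;
2. pick the winner by coefficient of determination (R²) on a
   model-selection split;
3. test it on a holdout of the training population and on cohorts at
   increasing genetic distance from it;
4. use the predicted BMD as a risk factor for fragility fracture in a
   large case-control cohort followed for 10 years.

Real biobank cohorts of this kind are access-restricted, so the package
ships a simulator that generates data with the statistical structure
the analysis assumes; every pipeline stage is exercised and tested
against it.

## Synthetic cohorts

**Allele frequencies.** Ancestral frequencies are Uniform on a
configurable MAF range (default 0.05–0.5). Population *k* drifts by the
Balding–Nichols model: p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), so
Var(p_k) = F_k·p(1−p) and two populations each drifted at F sit at
pairwise Hudson Fst ≈ F. One ancestral frequency is drawn per LD block
and shared by the block's loci: with binary alleles the attainable
correlation between two loci is capped by their frequency difference
(the Fréchet bound), and a shared block frequency is what lets the
haplotype chain hit high within-block r².

**LD.** Haplotypes follow a rank-copy copula chain: the uniform rank at
locus j is copied from locus j−1 with probability ρ (within a block)
or drawn fresh; the allele is the indicator u_j < p_j. Marginals are
exactly Bernoulli(p_j); at equal adjacent frequencies the adjacent
allele correlation equals ρ (so adjacent r² ≈ ρ², e.g. ρ = 0.9 gives
median adjacent r² ≈ 0.81), decaying geometrically with distance, and
blocks are independent. Genotype = sum of two independent haplotypes.

**Ancestry continuum.** Pure Balding–Nichols populations are internally
exchangeable, so a PCA fitted on one of them has no ancestry axis to
find, and projection-based genetic distance retains only a weak
fraction of the drift signal. Real cohorts are not like that: diversity
runs along a continuum, and a training set's own PCs align with the
axes along which other cohorts are displaced. The simulator models this
with an optional `ClineSpec`: one shared drift-direction field η_j over
loci; individual i carries an ancestry coefficient a_i ~
N(offset_k, s_k²) and samples alleles at p + a_i·η_j·√(p(1−p)). A
population at offset A sits at Hudson Fst ≈ A²/2 from one at offset 0
(the pipeline uses offset √(2F) to target Fst ≈ F), and a training set
with s > 0 (default 0.05) exposes the cline to its own PCA. The
default pipeline and the portability experiments use the cline; the
Fst-recovery and frequency-moment checks use pure Balding–Nichols.

**Trait.** BMD_site = μ_site + σ_site·(√c·C̃ + G + √(1−h²−c)·ε), with
C̃ the standardized clinical predictor (effects on age, age², sex,
height, weight, smoking, drinking, exercise; sex-specific height and
weight means), G the causal-SNP score empirically scaled so its
variance fraction equals h², and ε standard normal. h² (SNP
heritability) and c (clinical fraction) are explicit targets; h² + c
≤ 1 is enforced. The two sites share the causal set with effect
correlation 0.6 by default (the true cross-site genetic correlation of
the real cohorts is unreported, so this is configurable, not
calibrated). Scale parameters μ, σ (0.94/0.14 FNK, 1.10/0.18 SPN
g/cm²) match typical DXA reference values.

**Fracture.** Event times are exponential with rate
λ₀·exp(γ·BMD_z + Σ γ_c·z_c), administratively censored at 10 years.
Defaults: λ₀ = 0.006/person-year (≈6% 10-year cumulative incidence,
matching a mid-life biobank), γ = log 0.7 per SD of true BMD (within
the range reported for BMD and major osteoporotic fracture), age and
sex as additional log-hazards. A constant baseline keeps closed-form
oracles available (10-year risk = 1 − exp(−10λ)); only 10-year
cumulative quantities are analyzed, for which the constant-hazard
choice is immaterial.

## Quality control

Variant filters, applied jointly and attributed in a fixed order for
reproducible logs (INFO → MAF → missingness → HWE): imputation INFO >
0.3 (when present), MAF > 0.001, missing rate < 0.1, Hardy–Weinberg
exact p > 1e-6. All comparisons are strict, so a variant exactly at a
boundary is removed. The HWE test is the exact conditional test: the
probability of every admissible heterozygote count given the allele
counts, computed by the standard two-sided recurrence anchored at the
distribution's mode (numerically stable to n in the thousands; no
mid-p correction), summing outcomes no more probable than the observed.

BMD trimming removes samples outside the 0.1th–99.9th percentile of
either site (nearest-rank percentiles; two-sided, since extreme values
on both ends indicate measurement artifacts). Kinship uses the
KING-robust between-family estimator; relatives at φ ≥ 0.0442 (the
standard third-degree cutoff) are pruned greedily by descending number
of remaining relationships with a seeded random tie-break — which
member of an isolated pair is kept is arbitrary by design. Missing
clinical covariates are imputed with the within-cohort median
(continuous) or mode (categorical); samples without confirmed sex or
age are excluded instead.

## Association testing

Each variant is tested in the fixed-effect linear model BMD ~ dosage +
covariates (age, age², sex, height, weight, leading PCs). The
implementation residualizes the phenotype and all dosages on the
covariates once and fits the per-variant simple regressions in one
vectorized pass; with the degrees of freedom n − k − 1 this reproduces
the joint-fit coefficient, SE and two-sided t-test exactly
(Frisch–Waugh–Lovell), which the tests verify against statsmodels to
1e-8. A mixed model brings nothing at this scale: samples are
simulated unrelated and relatives are removed upstream, so the
fixed-effect model with PC adjustment is the appropriate reduction.
Missing dosages are mean-imputed per variant; monomorphic variants are
flagged and skipped. GWAS adjusts for 20 PCs and the prediction models
use 10, both configurable.

## SNP selection

Greedy clumping by ascending p-value among variants below the
candidate threshold: an unassigned variant becomes an index, and every
unassigned variant on the same chromosome within 250 kb with r² > 0.05
joins its clump. p-ties break toward the lower genomic position. The
250 kb window is the convention of the standard clumping tools;
clumping is restricted to within-chromosome windows.
Pairwise pruning for PCA slides a 1000-variant window by 50, repeatedly
removing the lower-MAF member of the worst pair above r² = 0.05 —
deterministic by construction. Long-range LD regions (MHC, common
inversions; GRCh37 catalogue, overridable) are excluded before PCA,
with 1-based inclusive input applied as half-open [start, end).

## Prediction models

Eighteen clinical features: age, age², height, weight and 10 PCs
z-scored with training means/SDs; sex, smoking, drinking, exercise
one-hot against training levels (binary → one column). SNP genotypes
are one-hot over dosage {0, 1, 2}; a missing dosage is imputed to the
training mean and assigned to the nearest category. All encoding
parameters live in the model file, so a saved model reproduces its
predictions bitwise.

Model families over the threshold grid {5e-8, 5e-7, 5e-6, 5e-5, 5e-4}:

- *clinical*: least squares on the clinical block;
- *C+T PRS*: additive dosage-weighted score over clumped index SNPs
  below the threshold (classic C+T scoring stays additive even though
  joint models one-hot their SNP inputs), entered as one feature next
  to the clinical block;
- *joint linear*: unpenalized least squares on clinical + one-hot SNPs
  (minimum-norm solution, as one-hot blocks are collinear with the
  intercept);
- *LASSO*: ½n‖y − β₀ − Xβ‖² + λ‖β_SNP‖₁ with the intercept and
  clinical coefficients unpenalized — the point of the penalty is SNP
  selection, and shrinking 18 established risk factors would
  contradict the clinical-baseline framing.

LASSO is fit by cyclic coordinate descent in partialled-out form: the
penalized columns and the outcome are residualized on the unpenalized
block once, descent runs over penalized coordinates only, and the
unpenalized coefficients are recovered exactly afterwards (equivalent
to joint descent because the unpenalized block is unrestricted, and
immune to the slow drift that intercept/one-hot collinearity causes in
naive cyclic descent). Convergence: max coefficient change < 1e-6 or
1000 sweeps. λ is chosen per threshold by selection-set R² over 20
log-spaced values in [1e-4·λ_max, λ_max], walked descending with warm
starts. A seeded mini-batch Adam optimizer (batch 32, learning rate
1e-4, epoch cap 200, early stopping on selection MSE with patience 10)
is provided as the stochastic alternative; the tests verify the two
optimizers agree on predictions at matched λ. Models train on raw BMD
with an intercept (no outcome centering).

At prediction time model SNPs are matched by (chrom, pos): identical
alleles score directly, swapped alleles reverse the dosage (2 − g),
non-palindromic strand flips are complemented and resolved, and
palindromic A/T / C/G mismatches — where swap and strand flip are
indistinguishable — are dropped with a warning and scored at the
training-mean dosage. A variant absent from the target cohort is an
explicit error naming it.

## Genetic distance

PCA (exact SVD; no randomized approximation needed at these scales) on
the standardized, LD-pruned, long-range-excluded training genotypes;
component signs fixed so each component's largest-magnitude loading is
positive. Targets are standardized with the *training* means/SDs and
multiplied by the loadings; GD is the Euclidean norm of the resulting
20-component score vector. Training scores are centered by
construction, so the "center of the training data" is the origin and
needs no explicit vector. Two practical caveats the tests encode:
pruning before PCA is load-bearing (on unpruned data the top PCs track
LD-block variance, which frequency drift attenuates, and the GD
ordering can invert), and training-set self-scores are
eigenvalue-inflated relative to projections of held-out samples, so GD
is only compared across held-out cohorts.

## Evaluation

R² is 1 − SS_res/SS_tot, *not* a squared correlation: a model
transferred to a shifted cohort can predict worse than the cohort mean
and R² then goes negative, which is itself a finding. Bootstrap
uncertainty resamples the training set 50 times with replacement,
retrains, evaluates on the fixed test set, and reports the mean and
percentile 2.5/97.5% interval (the percentile CI is the package's
choice; degenerate resamples are redrawn and logged). Model selection
is argmax selection-set R², ties toward fewer SNPs then the smaller
threshold. The residual–GD correlation uses |y − ŷ|/sd(y) — the
*magnitude* of the standardized residual — because a merely unbiased
model has signed residuals uncorrelated with everything; signed
residuals are available by composing `pcc` directly if preferred. Backward stepwise regression drops the
largest-p covariate until all p < 0.05 (configurable to AIC).

## Fracture risk

Welch's unequal-variance t compares predicted BMD between cases and
controls. Quantile strata at percentiles (5, 20, 40, 60, 80, 95) give
seven groups with per-group 10-year incidence. Survival machinery —
Kaplan–Meier, log-rank, Cox with Efron tie handling (the default of
the R `survival` package) — is delegated to lifelines; the package owns
the statistics built on top: HR per evaluation-cohort SD of predicted
BMD with Wald CIs, Harrell's C, the likelihood-ratio test of the
predicted-BMD term over the clinical-only Cox model, the logistic OR
per SD (offered both crude and covariate-adjusted, since practice
varies), percent risk change 100·(1 − ratio), and
the 10-year absolute-risk difference: with Breslow baseline Ĥ₀,
risk(x) = 1 − exp(−Ĥ₀(10)·e^{lp(x)}), reported as the cohort mean of
risk(observed) − risk(BMD + 1 SD).

## The pipeline and its experiment sizes

`run_pipeline` wires the stages together from one config; every
stochastic stage gets a sub-seed derived by stable hashing of (master
seed, stage name), so reruns are bitwise identical. Splits are
60/20/20 with floor allocation and the remainder to training; the
fracture case-control cohort is simulated disjointly from all splits
with the same causal architecture. By default the causal variants are
*excluded from the assay panel*: models must work through LD tags, the
realistic regime in which frequency drift degrades tag–causal
correlation and produces the cross-population performance decay. With
`causal_typed=True` the causal variants are genotyped and portability
is correspondingly better — useful for parameter-recovery checks.

Experiment sizes are chosen to make each effect measurable in seconds
to minutes on a single core: parameter recovery at n_train = 6,000 over
m = 5,000 variants (30 causal, h² = 0.25, clinical fraction 0.25);
portability over 20 replicates with a 2,200-strong training population
split 60/20/20, target cohorts of 800 at Fst 0.1 and 0.2 (cline
offsets √(2F)), 40 causal blocks at h² = 0.4 — within the 50–85%
heritability reported for BMD and large enough that tag-decay, not
sampling noise, dominates the cohort contrasts; Fst recovery at
m = 20,000 and n = 1,000 per population; fracture-risk statistics on
20,000 simulated case-control samples.

## What the synthetic experiments show — and what they do not

Passing tests demonstrate that the machinery is correct (oracle
equivalences to enumeration, closed forms and independent fits), that
the estimators are calibrated under the null (uniform GWAS p-values,
χ²-distributed log-rank and LR statistics), that known effect sizes
are recovered (h², Fst, hazard ratios with nominal CI coverage), and
that the study's qualitative phenomena — genetics adding over clinical
factors, threshold overfitting at small n, R² decay with genetic
distance, positive residual–GD correlation, BMD-stratified fracture
incidence — emerge under the stated generative assumptions. They do
not show that real cohorts satisfy those assumptions: the simulator
has no genotyping batch effects, no imputation error structure, no
gene–environment interaction, no population-specific causal variants,
covariate distributions identical across cohorts, and an idealized
one-dimensional ancestry continuum. Absolute numbers from the
simulation (R² levels, HR attenuation) characterize the simulated
regime, not any real population.

## Known limitations

- The rank-copy LD chain produces geometric within-block decay only;
  no realistic human LD map, recombination hotspots or sex chromosomes.
- KING-robust kinship is computed densely over all pairs — fine at desk
  scale, quadratic in n.
- The Cox layer reports Efron ties only (Breslow would require going
  around lifelines); time-varying covariates and competing risks are
  out of scope.
- Logistic and Cox per-SD effects standardize by the evaluation
  cohort's own SD, so effects are not directly comparable across
  cohorts with very different score spreads.
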