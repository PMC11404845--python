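"""Feature encoding and the BMD prediction-model family.

Four model families over a shared clinical baseline:

* ``clinical`` — least squares on the 18 clinical features alone,
* ``prs``      — a clumping+thresholding polygenic score (additive
                 dosage-weighted sum of GWAS effects) entered as one
                 extra feature next to the clinical block,
* ``lr``       — joint least squares on clinical features plus one-hot
                 encoded genotypes of the selected SNPs,
* ``lasso``    — the same design with an L1 penalty on the SNP block
                 (clinical coefficients and intercept unpenalized),
                 fit either by deterministic coordinate descent or by
                 seeded mini-batch gradient descent with Adam.

Continuous covariates are z-scored with training means/SDs; categorical
covariates and SNP genotypes are one-hot encoded; all encoding
parameters come from the training split only and travel inside the
model file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MissingVariantError

__all__ = [
    "EncodingSpec",
    "ThresholdGrid",
    "TrainingConfig",
    "TrainedModel",
    "encode_features",
    "fit_clinical_model",
    "compute_prs",
    "fit_ct_prs_model",
    "fit_lasso",
    "fit_threshold_grid",
    "lasso_lambda_max",
    "align_dosages",
]

CONTINUOUS_DEFAULT = ("age", "age2", "height", "weight")
CATEGORICAL_DEFAULT = ("sex", "smoking", "drinking", "exercise")

DEFAULT_THRESHOLDS = (5e-8, 5e-7, 5e-6, 5e-5, 5e-4)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ThresholdGrid:
    """GWAS p-value inclusion cutoffs for SNP selection."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS


@dataclass
class TrainingConfig:
    """Optimizer settings for penalized model fitting.

    The mini-batch defaults (batch 32, learning rate 1e-4, Adam)
    mirror a stochastic-gradient training regime; coordinate descent is
    the deterministic reference optimizer.
    """

    optimizer: str = "coordinate_descent"  # or "mbgd_adam"
    batch_size: int = 32
    learning_rate: float = 1e-4
    epochs: int = 200
    patience: int = 10
    tol: float = 1e-6
    n_lambda: int = 20
    lambda_min_ratio: float = 1e-4
    seed: int = 0


@dataclass
class EncodingSpec:
    """Training-split feature encoding parameters.

    continuous: column -> (mean, sd); categorical: column -> ordered
    levels (first level is the dropped reference); pc_columns are
    treated as continuous. SNPs are one-hot over dosage {0,1,2} with a
    stored training mean dosage for imputation.
    """

    continuous: dict[str, tuple[float, float]] = field(default_factory=dict)
    categorical: dict[str, list] = field(default_factory=dict)
    snps: list[dict] = field(default_factory=list)  # id, chrom, pos, a1, a2, mean_dosage
    feature_names: list[str] = field(default_factory=list)

    @classmethod
    def fit(
        cls,
        cohort: pd.DataFrame,
        gm: GenotypeMatrix | None = None,
        snp_ids: list[str] | None = None,
        continuous: tuple[str, ...] | None = None,
        categorical: tuple[str, ...] = CATEGORICAL_DEFAULT,
    ) -> "EncodingSpec":
        if continuous is None:
            pcs = tuple(c for c in cohort.columns if c.startswith("pc"))
            continuous = tuple(c for c in CONTINUOUS_DEFAULT if c in cohort.columns) + pcs
        spec = cls()
        for c in continuous:
            x = cohort[c].to_numpy(dtype=float)
            spec.continuous[c] = (float(x.mean()), float(x.std()))
        for c in categorical:
            if c in cohort.columns:
                spec.categorical[c] = sorted(pd.unique(cohort[c]).tolist())
        if snp_ids:
            assert gm is not None
            v = gm.variants.set_index("id")
            cols = {vid: j for j, vid in enumerate(gm.variants["id"])}
            for vid in snp_ids:
                j = cols[vid]
                spec.snps.append(
                    {
                        "id": vid,
                        "chrom": str(v.loc[vid, "chrom"]),
                        "pos": int(v.loc[vid, "pos"]),
                        "a1": str(v.loc[vid, "alt"]),
                        "a2": str(v.loc[vid, "ref"]),
                        "mean_dosage": float(np.nanmean(gm.dosages[:, j])),
                    }
                )
        spec.feature_names = spec._names()
        return spec

    def _names(self) -> list[str]:
        names = list(self.continuous)
        for c, levels in self.categorical.items():
            names += [f"{c}={lv}" for lv in levels[1:]]
        for s in self.snps:
            names += [f"{s['id']}:{d}" for d in (0, 1, 2)]
        return names

    @property
    def n_clinical(self) -> int:
        return len(self.continuous) + sum(
            len(lv) - 1 for lv in self.categorical.values()
        )

    def snp_feature_mask(self) -> np.ndarray:
        """Boolean mask over feature columns marking the SNP block."""
        k = self.n_clinical
        mask = np.zeros(k + 3 * len(self.snps), dtype=bool)
        mask[k:] = True
        return mask


def align_dosages(snps: list[dict], gm: GenotypeMatrix) -> np.ndarray:
    """Dosages of model SNPs in a target cohort, allele-harmonized.

    Variants are matched by (chrom, pos). Swapped alleles reverse the
    dosage (2 - g); non-palindromic strand flips are resolved by
    complementing; palindromic A/T / C/G flips are ambiguous and are
    dropped with a warning (the column falls back to the training mean
    dosage). Variants absent from the target raise MissingVariantError
    naming them. Missing calls are imputed to the training mean dosage.
    """
    key = {
        (str(c), int(p)): j
        for j, (c, p) in enumerate(zip(gm.variants["chrom"], gm.variants["pos"]))
    }
    tv = gm.variants
    n = gm.n
    out = np.empty((n, len(snps)))
    absent, dropped = [], []
    for k, s in enumerate(snps):
        j = key.get((str(s["chrom"]), int(s["pos"])))
        if j is None:
            absent.append(s["id"])
            continue
        r, a = str(tv["ref"][j]), str(tv["alt"][j])
        A1, A2 = s["a1"], s["a2"]  # a1 = effect/alt allele, a2 = other/ref
        palindromic = _COMPLEMENT.get(A1) == A2
        g = gm.dosages[:, j]
        if (a, r) == (A1, A2):
            col = g
        elif palindromic:
            # swap and strand flip are indistinguishable for A/T and C/G
            dropped.append(s["id"])
            out[:, k] = s["mean_dosage"]
            continue
        elif (a, r) == (A2, A1):
            col = 2.0 - g
        elif (
            _COMPLEMENT.get(a), _COMPLEMENT.get(r)) == (A1, A2):
            col = g
        elif (_COMPLEMENT.get(a), _COMPLEMENT.get(r)) == (A2, A1):
            col = 2.0 - g
        else:
            dropped.append(s["id"])
            out[:, k] = s["mean_dosage"]
            continue
        col = np.where(np.isnan(col), s["mean_dosage"], col)
        out[:, k] = col
    if absent:
        raise MissingVariantError(
            f"target cohort lacks model variants: {absent}"
        )
    if dropped:
        warnings.warn(
            "ambiguous or unmatched alleles; scored with training mean "
            f"dosage: {dropped}"
        )
    return out


def encode_features(
    cohort: pd.DataFrame,
    gm: GenotypeMatrix | None,
    spec: EncodingSpec,
) -> np.ndarray:
    """Design matrix under a fitted encoding (no intercept column).

    Continuous columns are z-scored with the training mean/SD (a
    constant training column maps to zeros, SD guard 1e-12); categorical
    columns are one-hot against the training levels with the first level
    as reference — an unseen level yields an all-zero block with a
    warning; SNP dosages are aligned, mean-imputed, rounded to the
    nearest integer category and one-hot encoded over {0,1,2}.
    """
    n = len(cohort)
    blocks = []
    for c, (mu, sd) in spec.continuous.items():
        x = cohort[c].to_numpy(dtype=float)
        blocks.append(((x - mu) / sd if sd > 1e-12 else np.zeros(n))[:, None])
    for c, levels in spec.categorical.items():
        x = cohort[c].to_numpy()
        unseen = set(pd.unique(x)) - set(levels)
        if unseen:
            warnings.warn(f"unseen level(s) {unseen} for {c!r}; encoded as zeros")
        blocks.append(
            np.column_stack([(x == lv).astype(float) for lv in levels[1:]])
            if len(levels) > 1 else np.empty((n, 0))
        )
    if spec.snps:
        if gm is None:
            raise ValueError("genotypes required: the encoding includes SNPs")
        D = align_dosages(spec.snps, gm)
        D = np.clip(np.rint(D), 0, 2)
        snp_block = np.zeros((n, 3 * len(spec.snps)))
        for k in range(len(spec.snps)):
            for d in (0, 1, 2):
                snp_block[:, 3 * k + d] = D[:, k] == d
        blocks.append(snp_block)
    X = np.hstack(blocks) if blocks else np.empty((n, 0))
    return X


@dataclass
class TrainedModel:
    """A fitted BMD prediction model with its full scoring recipe."""

    family: str
    encoding: EncodingSpec
    weights: np.ndarray  # [intercept, features...]
    threshold: float | None = None
    lam: float | None = None
    prs_recipe: list[dict] | None = None  # id/chrom/pos/a1/a2/beta/mean_dosage
    seed: int | None = None
    optimizer: str | None = None
    n_snps: int = 0

    def predict(self, cohort: pd.DataFrame,
                gm: GenotypeMatrix | None = None) -> np.ndarray:
        X = self.design(cohort, gm)
        return self.weights[0] + X @ self.weights[1:]

    def predict_from_prs(self, prs: np.ndarray,
                         cohort: pd.DataFrame) -> np.ndarray:
        """Predict with an externally supplied polygenic score (useful
        when the score was already computed for the cohort)."""
        if self.family != "prs":
            raise ValueError("only PRS-family models accept external scores")
        Xc = encode_features(cohort, None, self.encoding)
        X = np.column_stack([np.asarray(prs, dtype=float), Xc])
        return self.weights[0] + X @ self.weights[1:]

    def design(self, cohort: pd.DataFrame,
               gm: GenotypeMatrix | None = None) -> np.ndarray:
        X = encode_features(cohort, gm, self.encoding)
        if self.family == "prs":
            if gm is None:
                raise ValueError("genotypes required for a PRS model")
            prs = _score_prs(self.prs_recipe, gm)
            X = np.column_stack([prs, X])
        return X

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "encoding": {
                "continuous": {k: list(v) for k, v in self.encoding.continuous.items()},
                "categorical": {k: list(v) for k, v in self.encoding.categorical.items()},
                "snps": self.encoding.snps,
                "feature_names": self.encoding.feature_names,
            },
            "weights": np.asarray(self.weights).tolist(),
            "threshold": self.threshold,
            "lambda": self.lam,
            "prs_recipe": self.prs_recipe,
            "seed": self.seed,
            "optimizer": self.optimizer,
            "n_snps": self.n_snps,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "TrainedModel":
        enc = EncodingSpec(
            continuous={k: tuple(v) for k, v in doc["encoding"]["continuous"].items()},
            categorical={k: list(v) for k, v in doc["encoding"]["categorical"].items()},
            snps=doc["encoding"]["snps"],
            feature_names=doc["encoding"]["feature_names"],
        )
        return cls(
            family=doc["family"],
            encoding=enc,
            weights=np.asarray(doc["weights"], dtype=float),
            threshold=doc["threshold"],
            lam=doc["lambda"],
            prs_recipe=doc["prs_recipe"],
            seed=doc["seed"],
            optimizer=doc["optimizer"],
            n_snps=doc.get("n_snps", 0),
        )


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design (duplicate features?)")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


def fit_clinical_model(
    cohort: pd.DataFrame, y: np.ndarray,
    encoding: EncodingSpec | None = None,
) -> TrainedModel:
    """Least-squares model on the clinical feature block only."""
    if encoding is None:
        encoding = EncodingSpec.fit(cohort)
    X = encode_features(cohort, None, encoding)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more samples than features")
    coef = _ols(X, np.asarray(y, dtype=float))
    return TrainedModel(family="clinical", encoding=encoding, weights=coef)


def _score_prs(recipe: list[dict], gm: GenotypeMatrix) -> np.ndarray:
    D = align_dosages(recipe, gm)
    beta = np.array([s["beta"] for s in recipe])
    return D @ beta


def compute_prs(
    sumstats: pd.DataFrame,
    gm: GenotypeMatrix,
    threshold: float,
    clumped_ids: list[str],
) -> tuple[np.ndarray, list[dict], int]:
    """Additive C+T polygenic score.

    Score_i = sum_k beta_k * dosage_ik over clumped index variants with
    P < threshold; missing dosages fall back to the cohort mean dosage
    of the variant. Returns (scores, scoring recipe, SNP count).
    """
    sel = sumstats[(sumstats["ID"].isin(clumped_ids))
                   & (sumstats["P"] < threshold)]
    if sel.empty:
        warnings.warn("no SNPs pass the PRS threshold; scores are all zero")
        return np.zeros(gm.n), [], 0
    cols = {vid: j for j, vid in enumerate(gm.variants["id"])}
    recipe = []
    for _, row in sel.iterrows():
        j = cols[row["ID"]]
        recipe.append(
            {
                "id": row["ID"],
                "chrom": str(row["CHR"]),
                "pos": int(row["POS"]),
                "a1": str(row["A1"]),
                "a2": str(row["A2"]),
                "beta": float(row["BETA"]),
                "mean_dosage": float(np.nanmean(gm.dosages[:, j])),
            }
        )
    return _score_prs(recipe, gm), recipe, len(recipe)


def fit_ct_prs_model(
    prs_scores: np.ndarray,
    cohort: pd.DataFrame,
    y: np.ndarray,
    encoding: EncodingSpec | None = None,
    prs_recipe: list[dict] | None = None,
    threshold: float | None = None,
) -> TrainedModel:
    """Least squares on [PRS, clinical features]; the scoring recipe is
    stored inside the model so it can be re-derived on new cohorts."""
    if encoding is None:
        encoding = EncodingSpec.fit(cohort)
    Xc = encode_features(cohort, None, encoding)
    X = np.column_stack([np.asarray(prs_scores, dtype=float), Xc])
    prs_sd = np.asarray(prs_scores, float).std()
    if prs_sd < 1e-12:
        # constant PRS carries no information; fit clinical-only shape
        coef_c = _ols(Xc, np.asarray(y, dtype=float))
        coef = np.concatenate([[coef_c[0], 0.0], coef_c[1:]])
    else:
        coef = _ols(X, np.asarray(y, dtype=float))
    return TrainedModel(
        family="prs", encoding=encoding, weights=coef,
        prs_recipe=prs_recipe or [], threshold=threshold,
        n_snps=len(prs_recipe or []),
    )


def lasso_lambda_max(X: np.ndarray, y: np.ndarray,
                     penalized: np.ndarray) -> float:
    """Smallest lambda that zeroes every penalized coefficient.

    Computed as max_j |x_j' r| / n with r the residual of y on the
    unpenalized block (plus intercept).
    """
    n = X.shape[0]
    U = np.column_stack([np.ones(n), X[:, ~penalized]])
    Q, _ = np.linalg.qr(U)
    r = y - Q @ (Q.T @ y)
    return float(np.max(np.abs(X[:, penalized].T @ r)) / n)


def _soft(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


def _lasso_cd(X, y, lam, penalized, tol, max_sweeps=1000, b_init=None):
    """Cyclic coordinate descent for (1/2n)||y - b0 - Xb||^2 + lam * sum
    of |b_j| over the penalized block. Deterministic; returns
    (intercept, coefs, converged).

    The unpenalized block (intercept + clinical features) is handled in
    partialled-out form: penalized columns and the outcome are
    residualized on it once, coordinate descent runs over the penalized
    coordinates only, and the unpenalized coefficients are recovered by
    exact least squares afterwards. This is equivalent to joint descent
    (the unpenalized block is unrestricted, so Frisch-Waugh applies) and
    sidesteps the slow drift that exact collinearity between one-hot SNP
    blocks and the intercept would otherwise cause.
    """
    n, p = X.shape
    pen_idx = np.flatnonzero(penalized)
    U = np.column_stack([np.ones(n), X[:, ~penalized]])
    Q, _ = np.linalg.qr(U)
    y_r = y - Q @ (Q.T @ y)
    Xp = X[:, pen_idx]
    Xp_r = Xp - Q @ (Q.T @ Xp)

    bp = (np.zeros(pen_idx.size) if b_init is None
          else np.asarray(b_init, float)[pen_idx].copy())
    r = y_r - Xp_r @ bp if bp.any() else y_r.copy()
    col_ss = np.einsum("ij,ij->j", Xp_r, Xp_r) / n
    active = col_ss > 1e-14
    converged = False
    for _ in range(max_sweeps):
        delta = 0.0
        for k in range(pen_idx.size):
            if not active[k]:
                continue
            xk = Xp_r[:, k]
            rho = (xk @ r) / n + col_ss[k] * bp[k]
            new = _soft(rho, lam) / col_ss[k]
            if new != bp[k]:
                r -= (new - bp[k]) * xk
                delta = max(delta, abs(new - bp[k]))
                bp[k] = new
        if delta < tol:
            converged = True
            break
    # exact unpenalized coefficients given the penalized fit
    coef_u, *_ = np.linalg.lstsq(U, y - Xp @ bp, rcond=None)
    b = np.zeros(p)
    b[pen_idx] = bp
    b[~penalized] = coef_u[1:]
    return float(coef_u[0]), b, converged


def _lasso_adam(X, y, lam, penalized, cfg: TrainingConfig,
                X_val=None, y_val=None):
    """Mini-batch Adam on the L1-penalized MSE objective.

    Seeded shuffling; optional early stopping on validation MSE with the
    configured patience. The L1 term uses the subgradient at the current
    iterate, so coefficients approach but rarely hit exact zero.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = X.shape
    w = np.concatenate([[y.mean()], 0.001 * rng.standard_normal(p)])
    m1 = np.zeros_like(w)
    m2 = np.zeros_like(w)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    pen = np.concatenate([[False], penalized])
    best_val, best_w, stale = np.inf, w.copy(), 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            Xb, yb = X[idx], y[idx]
            pred = w[0] + Xb @ w[1:]
            err = pred - yb
            grad = np.concatenate(
                [[err.mean()], Xb.T @ err / len(idx)]
            )
            grad[pen] += lam * np.sign(w[pen])
            t += 1
            m1 = beta1 * m1 + (1 - beta1) * grad
            m2 = beta2 * m2 + (1 - beta2) * grad**2
            mhat = m1 / (1 - beta1**t)
            vhat = m2 / (1 - beta2**t)
            w -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        if X_val is not None:
            val = float(np.mean((w[0] + X_val @ w[1:] - y_val) ** 2))
            if val < best_val - 1e-10:
                best_val, best_w, stale = val, w.copy(), 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if X_val is not None:
        w = best_w
    return w[0], w[1:]


def fit_lasso(
    cohort: pd.DataFrame,
    gm: GenotypeMatrix | None,
    y: np.ndarray,
    lam: float,
    encoding: EncodingSpec,
    cfg: TrainingConfig = TrainingConfig(),
    validation: tuple[pd.DataFrame, GenotypeMatrix | None, np.ndarray] | None = None,
) -> TrainedModel:
    """L1-penalized least squares on [clinical, one-hot SNP] features.

    The SNP block is penalized; the intercept and clinical coefficients
    are not. ``cfg.optimizer`` selects deterministic coordinate descent
    (reference) or seeded mini-batch Adam.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = np.asarray(y, dtype=float)
    X = encode_features(cohort, gm, encoding)
    penalized = encoding.snp_feature_mask()
    if cfg.optimizer == "coordinate_descent":
        b0, b, converged = _lasso_cd(X, y, lam, penalized, cfg.tol)
        if not converged:
            warnings.warn("coordinate descent hit the sweep cap before tol")
    elif cfg.optimizer == "mbgd_adam":
        if validation is not None:
            Xv = encode_features(validation[0], validation[1], encoding)
            yv = np.asarray(validation[2], dtype=float)
        else:
            Xv = yv = None
        b0, b = _lasso_adam(X, y, lam, penalized, cfg, Xv, yv)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    return TrainedModel(
        family="lasso", encoding=encoding,
        weights=np.concatenate([[b0], b]), lam=lam,
        seed=cfg.seed, optimizer=cfg.optimizer, n_snps=len(encoding.snps),
    )


def fit_lr_model(
    cohort: pd.DataFrame,
    gm: GenotypeMatrix | None,
    y: np.ndarray,
    encoding: EncodingSpec,
) -> TrainedModel:
    """Unpenalized joint regression on clinical + one-hot SNP features.

    One-hot SNP blocks are collinear with the intercept, so the
    minimum-norm least-squares solution is used.
    """
    X = encode_features(cohort, gm, encoding)
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(A, np.asarray(y, float), rcond=None)
    return TrainedModel(family="lr", encoding=encoding, weights=coef,
                        n_snps=len(encoding.snps))


def fit_threshold_grid(
    family: str,
    grid: ThresholdGrid,
    train_cohort: pd.DataFrame,
    train_gm: GenotypeMatrix,
    y_train: np.ndarray,
    sumstats: pd.DataFrame,
    clumped_ids: list[str],
    selection: tuple[pd.DataFrame, GenotypeMatrix, np.ndarray] | None = None,
    cfg: TrainingConfig = TrainingConfig(),
) -> list[TrainedModel]:
    """One fitted model per p-value threshold for a family.

    SNP sets are the clumped index variants passing each threshold (so a
    looser threshold never selects fewer SNPs). For LASSO the lambda is
    chosen per threshold by selection-set R² over a log-spaced grid of
    ``cfg.n_lambda`` values in [lambda_min_ratio * lambda_max,
    lambda_max]; without a selection set, the smallest lambda is used.
    """
    from .evaluate import r_squared

    idx_stats = sumstats[sumstats["ID"].isin(clumped_ids)]
    models = []
    for thr in grid.thresholds:
        snp_ids = idx_stats.loc[idx_stats["P"] < thr, "ID"].tolist()
        if family == "prs":
            scores, recipe, _ = compute_prs(sumstats, train_gm, thr, clumped_ids)
            enc = EncodingSpec.fit(train_cohort)
            model = fit_ct_prs_model(scores, train_cohort, y_train,
                                     encoding=enc, prs_recipe=recipe,
                                     threshold=thr)
        elif family == "lr":
            enc = EncodingSpec.fit(train_cohort, train_gm, snp_ids)
            model = fit_lr_model(train_cohort, train_gm, y_train, enc)
            model.threshold = thr
        elif family == "lasso":
            enc = EncodingSpec.fit(train_cohort, train_gm, snp_ids)
            X = encode_features(train_cohort, train_gm, enc)
            pen = enc.snp_feature_mask()
            if pen.any():
                lmax = lasso_lambda_max(X, np.asarray(y_train, float), pen)
            else:
                lmax = 0.0
            if lmax > 0:
                lams = np.geomspace(cfg.lambda_min_ratio * lmax, lmax,
                                    cfg.n_lambda)[::-1]
            else:
                lams = np.array([0.0])
            if selection is not None:
                Xs = encode_features(selection[0], selection[1], enc)
                ys = np.asarray(selection[2], dtype=float)
            yt = np.asarray(y_train, dtype=float)
            best, best_r2 = None, -np.inf
            b_init = None
            for lam in lams:  # descending: warm starts along the path
                b0, b, _ = _lasso_cd(X, yt, float(lam), pen, cfg.tol,
                                     b_init=b_init)
                b_init = b.copy()
                cand = TrainedModel(
                    family="lasso", encoding=enc,
                    weights=np.concatenate([[b0], b]), lam=float(lam),
                    threshold=thr, seed=cfg.seed,
                    optimizer="coordinate_descent", n_snps=len(enc.snps),
                )
                if selection is not None:
                    r2 = r_squared(ys, b0 + Xs @ b)
                else:
                    r2 = -lam  # no selection data: prefer least shrinkage
                if r2 > best_r2:
                    best, best_r2 = cand, r2
            model = best
        else:
            raise ValueError(f"unknown family {family!r}")
        models.append(model)
    return models
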