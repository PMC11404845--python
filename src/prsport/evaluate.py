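"""Model evaluation: R², Pearson correlation, bootstrap uncertainty,
model selection, residual-vs-genetic-distance correlation and backward
stepwise covariate regression.

R² here is the coefficient of determination 1 - SS_res/SS_tot — NOT the
squared correlation — so it can go negative when a model transferred to
a shifted cohort predicts worse than the cohort mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "EvalResult",
    "r_squared",
    "pcc",
    "bootstrap_performance",
    "select_best_model",
    "residual_gd_correlation",
    "backward_stepwise",
]


@dataclass
class EvalResult:
    """Cohort-level performance of one model (a Table-2-shaped row)."""

    cohort: str
    model: str
    r2: float
    pcc: float
    n: int
    avg_gd: float | None = None
    r2_ci: tuple[float, float] | None = None
    pcc_ci: tuple[float, float] | None = None


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """1 - sum((y - yhat)^2) / sum((y - mean(y))^2); may be negative."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant outcome: R² undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def pcc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation between observed and predicted values."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.std() == 0 or yhat.std() == 0:
        raise ValueError("constant input: correlation undefined")
    return float(sps.pearsonr(y, yhat).statistic)


def bootstrap_performance(
    train_fn,
    metric_fn,
    train_data,
    test_data,
    B: int = 50,
    seed: int = 0,
    max_redraws: int = 100,
) -> dict:
    """Bootstrap mean and percentile 95% CI of a train/test metric.

    Draws B resamples (with replacement, size n) of the training set via
    ``train_data.iloc``-style integer indexing (train_fn receives the
    index array), retrains, evaluates ``metric_fn(model)`` on the fixed
    test set, and reports the mean and the [2.5%, 97.5%] percentile
    interval. A degenerate resample (train_fn raises ValueError) is
    redrawn and logged.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(train_data)
    vals = []
    redraws = 0
    while len(vals) < B:
        idx = rng.integers(0, n, size=n)
        try:
            model = train_fn(idx)
        except ValueError:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            warnings.warn("degenerate bootstrap resample redrawn")
            continue
        vals.append(metric_fn(model, test_data))
    vals = np.asarray(vals, dtype=float)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return {"mean": float(vals.mean()), "ci": (float(lo), float(hi)),
            "values": vals, "redraws": redraws}


def select_best_model(models: list, r2_values: list[float]) -> object:
    """Argmax of selection-set R²; ties break toward fewer SNPs, then
    the smaller p-value threshold."""
    if not models:
        raise ValueError("no candidate models")
    order = sorted(
        range(len(models)),
        key=lambda i: (
            -r2_values[i],
            getattr(models[i], "n_snps", 0),
            getattr(models[i], "threshold", 0.0) or 0.0,
        ),
    )
    return models[order[0]]


def residual_gd_correlation(
    y: np.ndarray, yhat: np.ndarray, gd: np.ndarray,
    sd_y: float | None = None,
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between |y - yhat| / sd(y)
    and the individual genetic distance.

    The residual magnitude is used: under an unbiased model the signed
    residual would correlate ~0 with any covariate by construction,
    while its magnitude grows when the model transfers poorly.
    Constant GD -> (nan, nan), reported rather than raised.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    gd = np.asarray(gd, dtype=float)
    if sd_y is None:
        sd_y = float(y.std())
    if np.std(gd) == 0:
        warnings.warn("constant genetic distance: correlation undefined")
        return (float("nan"), float("nan"))
    res = np.abs(y - yhat) / sd_y
    out = sps.pearsonr(res, gd)
    return float(out.statistic), float(out.pvalue)


def backward_stepwise(
    cohort: pd.DataFrame,
    covariates: list[str],
    y: np.ndarray,
    p_remove: float = 0.05,
    criterion: str = "pvalue",
) -> pd.DataFrame:
    """Backward stepwise OLS covariate selection.

    Starts from the full model and repeatedly drops the covariate with
    the largest p-value until every remaining one has p < p_remove
    (criterion="pvalue") or until AIC stops improving
    (criterion="aic"). Returns a frame of retained covariates with
    coefficients and p-values (possibly empty).
    """
    y = np.asarray(y, dtype=float)
    if len(cohort) <= len(covariates) + 2:
        raise ValueError("too few samples for the candidate covariate set")
    kept = list(covariates)
    while kept:
        X = sm.add_constant(cohort[kept].to_numpy(dtype=float))
        fit = sm.OLS(y, X).fit()
        pvals = fit.pvalues[1:]  # skip intercept
        if criterion == "pvalue":
            worst = int(np.argmax(pvals))
            if pvals[worst] < p_remove:
                break
            kept.pop(worst)
        elif criterion == "aic":
            best_aic, best_drop = fit.aic, None
            for i in range(len(kept)):
                sub = kept[:i] + kept[i + 1:]
                Xs = sm.add_constant(cohort[sub].to_numpy(dtype=float)) \
                    if sub else np.ones((len(y), 1))
                a = sm.OLS(y, Xs).fit().aic
                if a < best_aic:
                    best_aic, best_drop = a, i
            if best_drop is None:
                break
            kept.pop(best_drop)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    if not kept:
        return pd.DataFrame(columns=["covariate", "coef", "p"])
    X = sm.add_constant(cohort[kept].to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {"covariate": kept, "coef": fit.params[1:], "p": fit.pvalues[1:]}
    )
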