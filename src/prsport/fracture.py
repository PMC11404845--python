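"""Predicted BMD as a fragility-fracture risk factor.

Group comparison (Welch t), quantile-stratum incidences, Kaplan-Meier /
log-rank survival contrasts, Cox proportional-hazards modelling with
per-SD hazard ratios, 10-year absolute-risk differences, likelihood
ratio tests of nested Cox models, and per-cohort logistic odds ratios.

Survival machinery is delegated to lifelines (Efron tie handling, the
default of the R ``survival`` package) and logistic fits to
statsmodels; this module owns the study-specific statistics built on
top of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "QuantileStrata",
    "welch_t_test",
    "stratify_and_incidence",
    "km_estimate",
    "log_rank",
    "fit_cox",
    "absolute_risk_10y",
    "percent_risk_change",
    "likelihood_ratio_test",
    "logistic_or",
]

DEFAULT_STRATA_PCT = (5.0, 20.0, 40.0, 60.0, 80.0, 95.0)


@dataclass
class QuantileStrata:
    """Quantile groups of a score with per-group event incidence."""

    boundaries_pct: tuple[float, ...]
    labels: list[str]
    group_index: np.ndarray  # per-sample group id, 0 = lowest scores
    n: np.ndarray
    events: np.ndarray
    incidence: np.ndarray  # events / n, in [0, 1]


def welch_t_test(group_a: np.ndarray, group_b: np.ndarray
                 ) -> tuple[float, float, float]:
    """Welch unequal-variance t test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def stratify_and_incidence(
    scores: np.ndarray,
    events: np.ndarray,
    boundaries_pct: tuple[float, ...] = DEFAULT_STRATA_PCT,
) -> QuantileStrata:
    """Partition a cohort by score percentiles and tally event incidence.

    The default boundaries (5, 20, 40, 60, 80, 95) yield seven groups:
    <=5%, 5-20%, 20-40%, 40-60%, 60-80%, 80-95%, >95%. Boundaries use
    the nearest-rank percentile convention; a sample equal to a boundary
    value falls in the lower group.
    """
    s = np.asarray(scores, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.isnan(s).any():
        raise ValueError("scores must be non-missing")
    cuts = np.quantile(s, np.asarray(boundaries_pct) / 100.0,
                       method="inverted_cdf")
    # side="left": a score equal to a boundary lands in the lower group
    group = np.searchsorted(cuts, s, side="left")
    k = len(boundaries_pct) + 1
    n = np.bincount(group, minlength=k)
    ev = np.bincount(group, weights=e, minlength=k).astype(int)
    with np.errstate(invalid="ignore"):
        inc = np.where(n > 0, ev / np.maximum(n, 1), 0.0)
    edges = ["<=%g%%" % boundaries_pct[0]] + [
        "%g%%-%g%%" % (boundaries_pct[i], boundaries_pct[i + 1])
        for i in range(len(boundaries_pct) - 1)
    ] + [">%g%%" % boundaries_pct[-1]]
    return QuantileStrata(
        boundaries_pct=tuple(boundaries_pct), labels=edges,
        group_index=group, n=n, events=ev, incidence=inc,
    )


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival curve: columns ``time`` and ``survival``."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, int))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float),
         "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
    )


def log_rank(times: np.ndarray, events: np.ndarray,
             groups: np.ndarray) -> tuple[float, float]:
    """Log-rank test across groups: (chi², p) with (groups - 1) df."""
    res = multivariate_logrank_test(
        np.asarray(times, float), np.asarray(groups), np.asarray(events, int)
    )
    return float(res.test_statistic), float(res.p_value)


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "efron",
) -> CoxPHFitter:
    """Cox proportional-hazards fit (Efron partial likelihood).

    Returns the fitted lifelines model; hazard ratios are
    ``np.exp(fit.params_)`` with Wald CIs in ``fit.summary``; Harrell's
    C is ``fit.concordance_index_``. Monotone likelihood (separation) is
    surfaced as a ConvergenceError / warning by lifelines.
    """
    if records[event_col].sum() < 1:
        raise ValueError("at least one event required")
    if ties != "efron":
        raise NotImplementedError("only Efron tie handling is exposed")
    cph = CoxPHFitter()
    cph.fit(records[covariates + [time_col, event_col]],
            duration_col=time_col, event_col=event_col)
    return cph


def absolute_risk_10y(
    cph: CoxPHFitter,
    records: pd.DataFrame,
    bmd_col: str,
    delta_sd: float = 1.0,
    horizon: float = 10.0,
) -> float:
    """Cohort-average 10-year absolute-risk difference per BMD shift.

    risk(x) = 1 - exp(-H0(10) * exp(lp(x))) with H0 the Breslow baseline
    cumulative hazard; the reported value is mean[risk(observed)] -
    mean[risk(BMD + delta_sd * SD)], i.e. how much 10-year risk drops
    when everyone's predicted BMD is one SD higher.
    """
    X = records[cph.params_.index.tolist()]
    ch_obs = cph.predict_cumulative_hazard(X, times=[horizon]).iloc[0].to_numpy()
    shifted = X.copy()
    shifted[bmd_col] = shifted[bmd_col] + delta_sd * records[bmd_col].std()
    ch_shift = cph.predict_cumulative_hazard(
        shifted, times=[horizon]).iloc[0].to_numpy()
    risk_obs = 1.0 - np.exp(-ch_obs)
    risk_shift = 1.0 - np.exp(-ch_shift)
    return float(risk_obs.mean() - risk_shift.mean())


def percent_risk_change(ratio: float) -> float:
    """Percent risk decrease implied by a hazard/odds ratio:
    100 * (1 - ratio). HR 0.83 -> 17%; ratio 1 -> 0%."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return 100.0 * (1.0 - ratio)


def likelihood_ratio_test(full: CoxPHFitter, reduced: CoxPHFitter
                          ) -> tuple[float, int, float]:
    """2·Δ log partial likelihood of nested Cox fits: (chi², df, p)."""
    stat = 2.0 * (full.log_likelihood_ - reduced.log_likelihood_)
    df = len(full.params_) - len(reduced.params_)
    if df < 0:
        raise ValueError("models are not nested (df < 0)")
    stat = max(stat, 0.0)
    if df == 0:  # identical parameterizations: no evidence either way
        return float(stat), 0, 1.0
    return float(stat), int(df), float(sps.chi2.sf(stat, df))


def logistic_or(
    outcome: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    per_sd: bool = True,
) -> dict:
    """Logistic regression odds ratio per SD of the predictor.

    Returns {"or", "ci", "p", "beta"}; the OR is exp(beta) for a one-SD
    increase when ``per_sd`` (standardized with the evaluation cohort's
    own SD). Complete separation is reported as an error.
    """
    yb = np.asarray(outcome, dtype=int)
    if yb.min() == yb.max():
        raise ValueError("outcome must include both classes")
    x = np.asarray(predictor, dtype=float)
    if per_sd:
        x = (x - x.mean()) / x.std()
    cols = [x]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    X = sm.add_constant(np.column_stack(cols))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(yb, X).fit(disp=0)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        raise ValueError(f"complete separation in logistic fit: {exc}") from exc
    beta = fit.params[1]
    se = fit.bse[1]
    z = sps.norm.ppf(0.975)
    return {
        "or": float(np.exp(beta)),
        "ci": (float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
        "p": float(fit.pvalues[1]),
        "beta": float(beta),
    }
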