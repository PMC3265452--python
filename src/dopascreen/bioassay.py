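"""Larval dose-mortality analysis: single-dose t-tests and LC50/LC90 fitting.

Mortality at 24 h is modeled as binomial per well.  The dose-mortality fit is
a binomial regression of deaths on log10 dose with a logistic link (probit
available via ``link="probit"``).  With a logit link the model is the
log-logistic tolerance distribution, which gives the closed-form relation

    log10(LC90) - log10(LC50) = log10(9) / slope_base10

where ``slope_base10`` is the fitted slope in base-10 logits per log10 dose.
Confidence intervals are percentile bootstrap over wells (technical
replicates share a plate and day, so the well is the resampling unit).
Control wells are excluded from the regression; Abbott's correction for
nonzero control mortality is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import ValidationError

__all__ = ["SingleDoseResult", "LCFit", "single_dose_test", "fit_lc", "abbott_correct"]

_LN9 = math.log(9.0)


@dataclass(frozen=True)
class SingleDoseResult:
    mean_mortality: float  # percent
    t_statistic: float
    p_value: float
    df: int
    n_replicates: int
    zero_variance: bool = False


def single_dose_test(
    treated_pct: Sequence[float], control_mean_pct: float = 0.0
) -> SingleDoseResult:
    """One-sample two-tailed t-test of replicate mortalities against the control mean.

    ``treated_pct`` holds per-biological-replicate percent mortalities; the
    control enters as its (typically 0%) observed mean.  Zero replicate
    variance with a nonzero difference is flagged and the p-value reported at
    the machine floor rather than exactly zero.
    """
    vals = np.asarray(treated_pct, dtype=float)
    if vals.size < 2:
        raise ValidationError("need >= 2 biological replicates for the t-test")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    df = int(vals.size - 1)
    if sd == 0:
        if mean == control_mean_pct:
            return SingleDoseResult(mean, 0.0, 1.0, df, int(vals.size), True)
        return SingleDoseResult(
            mean, math.inf if mean > control_mean_pct else -math.inf,
            float(np.finfo(float).tiny), df, int(vals.size), True,
        )
    t, p = stats.ttest_1samp(vals, popmean=control_mean_pct)
    return SingleDoseResult(mean, float(t), float(p), df, int(vals.size))


@dataclass(frozen=True)
class LCFit:
    lc50: float  # uM
    lc90: float  # uM
    slope: float  # natural logits (or probits) per log10 dose
    slope_base10: float  # base-10 logits per log10 dose (logit link only)
    intercept: float
    lc50_ci: tuple[float, float]
    lc90_ci: tuple[float, float]
    deviance: float
    pearson_chi2: float
    df_resid: int
    link: str
    n_wells: int


def _lc_from_params(intercept: float, slope: float, link: str) -> tuple[float, float]:
    if link == "logit":
        q50, q90 = 0.0, _LN9
    else:  # probit
        q50, q90 = 0.0, float(stats.norm.ppf(0.9))
    lc50 = 10.0 ** ((q50 - intercept) / slope)
    lc90 = 10.0 ** ((q90 - intercept) / slope)
    return lc50, lc90


def _fit_glm(logd: np.ndarray, dead: np.ndarray, alive: np.ndarray, link: str):
    fam_link = sm.families.links.Logit() if link == "logit" else sm.families.links.Probit()
    endog = np.column_stack([dead, alive])
    exog = sm.add_constant(logd)
    model = sm.GLM(endog, exog, family=sm.families.Binomial(link=fam_link))
    return model.fit()


def abbott_correct(dead: np.ndarray, n: np.ndarray, control_mortality: float) -> np.ndarray:
    """Abbott's correction: rescale treated kills for background control mortality."""
    if not 0 <= control_mortality < 1:
        raise ValidationError("control mortality must be in [0, 1)")
    p = dead / n
    p_adj = np.clip((p - control_mortality) / (1.0 - control_mortality), 0.0, 1.0)
    return p_adj * n


def fit_lc(
    records: pd.DataFrame,
    link: str = "logit",
    n_boot: int = 500,
    seed: int = 0,
    ci_level: float = 0.95,
    abbott: bool = False,
) -> LCFit:
    """Fit the dose-mortality model and derive LC50/LC90 with bootstrap CIs.

    ``records`` is the tidy bioassay table (``dose_uM, n_larvae, n_dead`` per
    well; dose 0 marks water controls, which are excluded from the
    regression).  Requires >= 3 distinct nonzero doses and partial-kill
    information: all-or-nothing mortality at every dose is complete
    separation, reported as an explicit failure.
    """
    if link not in ("logit", "probit"):
        raise ValidationError("link must be 'logit' or 'probit'")
    treated = records[records["dose_uM"] > 0].reset_index(drop=True)
    controls = records[records["dose_uM"] == 0]
    if treated["dose_uM"].nunique() < 3:
        raise ValidationError("need >= 3 distinct nonzero doses")
    per_dose = treated.groupby("dose_uM").agg(dead=("n_dead", "sum"), n=("n_larvae", "sum"))
    if ((per_dose["dead"] == 0) | (per_dose["dead"] == per_dose["n"])).all():
        raise ValidationError(
            "complete separation: every dose shows all-or-nothing mortality"
        )

    dead = treated["n_dead"].to_numpy(float)
    n = treated["n_larvae"].to_numpy(float)
    if abbott and len(controls):
        pc = float(controls["n_dead"].sum() / controls["n_larvae"].sum())
        if pc > 0:
            dead = abbott_correct(dead, n, pc)
    alive = n - dead
    logd = np.log10(treated["dose_uM"].to_numpy(float))

    fit = _fit_glm(logd, dead, alive, link)
    intercept, slope = (float(v) for v in fit.params)
    lc50, lc90 = _lc_from_params(intercept, slope, link)

    rng = np.random.default_rng(seed)
    idx = np.arange(len(treated))
    boots50, boots90 = [], []
    for _ in range(n_boot):
        take = rng.choice(idx, size=idx.size, replace=True)
        if len(np.unique(logd[take])) < 2:
            continue
        try:
            bf = _fit_glm(logd[take], dead[take], alive[take], link)
        except Exception:
            continue
        a, b = (float(v) for v in bf.params)
        if b <= 0:
            continue
        l50, l90 = _lc_from_params(a, b, link)
        boots50.append(l50)
        boots90.append(l90)
    alpha = (1.0 - ci_level) / 2.0
    if boots50:
        ci50 = tuple(np.quantile(boots50, [alpha, 1 - alpha]))
        ci90 = tuple(np.quantile(boots90, [alpha, 1 - alpha]))
    else:
        ci50 = ci90 = (math.nan, math.nan)

    return LCFit(
        lc50=lc50,
        lc90=lc90,
        slope=slope,
        slope_base10=slope / math.log(10.0) if link == "logit" else math.nan,
        intercept=intercept,
        lc50_ci=(float(ci50[0]), float(ci50[1])),
        lc90_ci=(float(ci90[0]), float(ci90[1])),
        deviance=float(fit.deviance),
        pearson_chi2=float(fit.pearson_chi2),
        df_resid=int(fit.df_resid),
        link=link,
        n_wells=int(len(treated)),
    )
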