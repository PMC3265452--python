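"""Four-parameter logistic potency estimation (EC50 / IC50).

The response model, in log10-concentration space, is

    y = bottom + (top - bottom) / (1 + 10**(hill * (log10 potency - log10 c)))

with a free Hill slope.  Agonist curves rise (hill > 0 after orientation
normalization), antagonist curves fall (negative slope in the same
parameterization); potency is the midpoint either way.

Fitting is per independent experiment by bounded nonlinear least squares with
multi-start initialization (hill in {+1, -1}, midpoint candidates from the
half-range crossing and the center of the tested range), with box bounds one
decade beyond the tested concentration range on the midpoint.  Experiment
potencies are then aggregated as a geometric mean, with the SEM computed on
the log scale and reported on the linear scale by the delta method.  Potencies
at or beyond the censoring limit (default 10 uM) are reported as
right-censored: such compounds are considered to lack intrinsic activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import ValidationError
from .simulate import four_pl

__all__ = ["Fit4PL", "PotencyEstimate", "fit_4pl", "fit_experiments", "summarize_experiments", "estimate_potency"]

RECEPTORS = ("AaDOP1", "AaDOP2", "hD1")


@dataclass(frozen=True)
class Fit4PL:
    """One experiment's 4PL fit."""

    top: float
    bottom: float
    log10_potency: float
    hill: float
    sse: float
    converged: bool
    flat: bool = False  # monotone-flat data, potency not identifiable

    @property
    def potency(self) -> float:
        return 10.0 ** self.log10_potency


@dataclass(frozen=True)
class PotencyEstimate:
    """Aggregated potency over replicate experiments."""

    compound_id: str
    receptor: str
    mode: str  # agonist | antagonist
    potency: float  # molar; geometric mean over experiments
    sem: float  # molar (delta-method from log-scale SEM)
    hill: float
    top: float
    bottom: float
    n_experiments: int
    censored: bool
    censor_limit: float = 1e-5

    def render_potency(self) -> str:
        if self.censored:
            return f">={self.censor_limit * 1e6:g} uM"
        return f"{self.potency:.3g} M"


def _fit_once(logc, y, x0, bounds):
    def resid(p):
        top, bottom, logp, hill = p
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logp - logc))) - y

    return least_squares(resid, x0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12)


def fit_4pl(
    concentrations: Sequence[float],
    responses: Sequence[float],
    mode: str = "agonist",
    flat_sigma: float = 3.0,
) -> Fit4PL:
    """Fit one experiment's 4PL by multi-start bounded least squares.

    A curve whose fitted span |top-bottom| is below ``flat_sigma`` residual
    standard deviations is declared flat: the potency is not identifiable and
    the caller censors the compound at the activity limit.
    """
    conc = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if conc.size != y.size or conc.size < 4:
        raise ValidationError("need >= 4 (concentration, response) points")
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be strictly positive")
    if len(np.unique(conc)) < 4:
        raise ValidationError("need >= 4 distinct concentrations")
    logc = np.log10(conc)
    lo, hi = logc.min() - 1.0, logc.max() + 1.0
    ymin, ymax = float(y.min()), float(y.max())
    spread = ymax - ymin if ymax > ymin else 1.0

    # midpoint starts: half-range crossing plus the center of the range
    half = (ymin + ymax) / 2.0
    crossing = logc[np.argmin(np.abs(y - half))]
    mid = (logc.min() + logc.max()) / 2.0
    starts = []
    for logp0 in {float(crossing), float(mid)}:
        for hill0 in (1.0, -1.0):
            starts.append((ymax, ymin, logp0, hill0))

    bounds = (
        [ymin - 2 * spread, ymin - 2 * spread, lo, -10.0],
        [ymax + 2 * spread, ymax + 2 * spread, hi, 10.0],
    )
    best = None
    converged = False
    for x0 in starts:
        try:
            res = _fit_once(logc, y, np.asarray(x0), bounds)
        except Exception:
            continue
        sse = float(2 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res)
            converged = bool(res.success)
    if best is None:
        return Fit4PL(ymax, ymin, math.nan, math.nan, math.inf, False, flat=True)
    sse, res = best
    top, bottom, logp, hill = (float(v) for v in res.x)
    dof = max(y.size - 4, 1)
    resid_sd = math.sqrt(sse / dof)
    flat = abs(top - bottom) < max(flat_sigma * resid_sd, 1e-8 * spread)
    # orientation normalization: report an ascending curve for agonist mode
    # and its mirror convention for antagonists; the (top, bottom, hill) triple
    # (t, b, h) is equivalent to (b, t, -h).
    if mode == "agonist" and hill < 0:
        top, bottom, hill = bottom, top, -hill
    if mode == "antagonist" and hill > 0:
        top, bottom, hill = bottom, top, -hill
    return Fit4PL(top, bottom, logp, hill, sse, converged, flat=flat)


def fit_experiments(curve: pd.DataFrame, mode: str = "agonist") -> list[Fit4PL]:
    """Fit each experiment of a tidy (concentration_M, response, experiment_id) frame."""
    fits = []
    for _, sub in curve.groupby("experiment_id", sort=True):
        fits.append(fit_4pl(sub["concentration_M"], sub["response"], mode=mode))
    return fits


def summarize_experiments(
    fits: Sequence[Fit4PL],
    compound_id: str = "",
    receptor: str = "AaDOP2",
    mode: str = "agonist",
    censor_limit: float = 1e-5,
) -> PotencyEstimate:
    """Aggregate per-experiment fits into one :class:`PotencyEstimate`.

    Potency is the geometric mean of per-experiment potencies; the SEM is the
    standard error of the per-experiment log10 potencies mapped to the linear
    scale as ``potency * ln(10) * sem_log10``.  Censoring (at the limit) is
    applied after aggregation; flat or failed experiments count as censored
    evidence, and if no experiment succeeded the estimate is censored with a
    failure marker (NaN parameters).
    """
    ok = [f for f in fits if f.converged and not f.flat and math.isfinite(f.log10_potency)]
    if not ok:
        return PotencyEstimate(compound_id, receptor, mode, censor_limit, math.nan,
                               math.nan, math.nan, math.nan, 0, True, censor_limit)
    logp = np.array([f.log10_potency for f in ok])
    potency = float(10.0 ** logp.mean())
    sem_log = float(logp.std(ddof=1) / math.sqrt(logp.size)) if logp.size > 1 else 0.0
    sem = potency * math.log(10.0) * sem_log
    censored = potency >= censor_limit or len(ok) < len(fits)
    # flat experiments imply no measurable activity below the limit; only the
    # aggregated potency position decides censoring when all fits succeeded
    if len(ok) == len(fits):
        censored = potency >= censor_limit
    return PotencyEstimate(
        compound_id, receptor, mode, potency, sem,
        float(np.mean([f.hill for f in ok])),
        float(np.mean([f.top for f in ok])),
        float(np.mean([f.bottom for f in ok])),
        len(ok), censored, censor_limit,
    )


def estimate_potency(
    curve: pd.DataFrame,
    compound_id: str = "",
    receptor: str = "AaDOP2",
    mode: str = "agonist",
    censor_limit: float = 1e-5,
) -> PotencyEstimate:
    """Convenience: per-experiment 4PL fits followed by aggregation."""
    fits = fit_experiments(curve, mode=mode)
    return summarize_experiments(fits, compound_id, receptor, mode, censor_limit)


def potency_table(estimates: Sequence[PotencyEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "compound_id": e.compound_id,
                "receptor": e.receptor,
                "mode": e.mode,
                "potency_M": e.potency,
                "sem_M": e.sem,
                "hill": e.hill,
                "top": e.top,
                "bottom": e.bottom,
                "n_experiments": e.n_experiments,
                "censored": e.censored,
                "potency_report": e.render_potency(),
            }
        )
    return pd.DataFrame(rows)
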