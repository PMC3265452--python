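"""Cross-receptor selectivity: fold ratios and rank-order potency correlation.

Fold selectivity for the target receptor over the reference is the ratio of
the reference IC50 to the target IC50 (``> 1`` means more potent at the
target, here the mosquito receptor).  Agreement of potency rank orders across
receptors is summarized by a tie-aware Spearman correlation (Pearson on
mid-ranks) squared, with a permutation p-value: exhaustive over one margin's
permutations when feasible, Monte Carlo otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import ValidationError, round_sig

__all__ = ["SelectivityRecord", "compute_fold_selectivity", "rank_order_correlation", "RankCorrelation"]

_EXHAUSTIVE_MAX_N = 8  # 8! = 40320 permutations


@dataclass(frozen=True)
class SelectivityRecord:
    compound_id: str
    ic50_target: float  # molar
    ic50_reference: float  # molar
    fold_selectivity: float  # ic50_reference / ic50_target
    computable: bool = True


def compute_fold_selectivity(
    pairs: pd.DataFrame,
    target_col: str = "ic50_aadop2",
    reference_col: str = "ic50_hd1",
    censored_cols: tuple[str, str] = ("censored_aadop2", "censored_hd1"),
) -> pd.DataFrame:
    """Fold selectivity per compound from paired potencies.

    ``pairs`` needs ``compound_id`` plus the two potency columns (molar, any
    common unit works: the ratio is unit-free).  Rows with a censored potency
    (flag columns optional) are retained but flagged not-computable.
    """
    out = pairs.copy()
    cens = np.zeros(len(out), dtype=bool)
    for col in censored_cols:
        if col in out.columns:
            cens |= out[col].fillna(False).astype(bool).to_numpy()
    cens |= out[target_col].isna().to_numpy() | out[reference_col].isna().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = out[reference_col].to_numpy(float) / out[target_col].to_numpy(float)
    fold = np.where(cens, np.nan, fold)
    out["fold_selectivity"] = fold
    out["fold_selectivity_report"] = [
        round_sig(f, 2) if np.isfinite(f) else np.nan for f in fold
    ]
    out["computable"] = ~cens
    return out


@dataclass(frozen=True)
class RankCorrelation:
    rho: float
    r_squared: float
    p_value: float
    n: int
    method: str  # "exhaustive" | "monte_carlo"
    n_permutations: int


def _midrank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return math.nan
    return float((rx @ ry) / denom)


def rank_order_correlation(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 20000,
    seed: Optional[int] = 0,
) -> RankCorrelation:
    """Tie-aware Spearman correlation squared, with a permutation p-value.

    The statistic is Pearson's correlation on mid-ranks; ties share the
    average of the ranks they span.  The two-sided p-value permutes one margin
    -- exhaustively for n <= 8, by seeded Monte Carlo above that (the observed
    ordering is included in the Monte Carlo null, the standard +1 correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired potencies required")
    if x.size < 4:
        raise ValidationError("need >= 4 compound pairs for a rank correlation")
    rho = _midrank_pearson(x, y)
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc @ rxc) * (ryc @ ryc))
    if x.size <= _EXHAUSTIVE_MAX_N:
        perms = np.array(list(permutations(ry)))
        rhos = (perms - ry.mean()) @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return RankCorrelation(rho, rho * rho, p, int(x.size),
                               "exhaustive", int(perms.shape[0]))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(ry) for _ in range(n_permutations)])
    rhos = (perms - ry.mean()) @ rxc / denom
    count = 1 + int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))  # +1: observed ordering
    return RankCorrelation(rho, rho * rho, count / (n_permutations + 1), int(x.size),
                           "monte_carlo", n_permutations)
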