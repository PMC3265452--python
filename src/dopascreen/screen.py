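"""Primary-screen processing: normalization, scoring, threshold, hit calling.

The chain mirrors a standard reporter-assay antagonist screen:

1.  The mean background luminescence (cells without agonist or compound) is
    subtracted from every well, per plate.
2.  Maximum-stimulation wells (agonist alone) are averaged within each plate
    to set the 100% stimulation level; percent inhibition of a well is
    ``100 * (1 - net / plate max-stimulation net mean)``.  Normalization is
    strictly per plate so that multiplicative plate effects cancel.
3.  Replicate test wells of a compound (quadruplicate, split over two plates)
    are averaged, unweighted, after normalization.
4.  The hit threshold is derived from the antagonist-control wells, pooled
    over all plates of the run: ``threshold = mean - k_sd * SD`` of their
    percent inhibition.  With the default control behaviour (mean 93%,
    SD 4%), k=3 puts the cut at 81% inhibition and k=6 at 69%.
5.  A compound is a hit when its mean percent inhibition is at least the
    threshold (closed bound); hits are partitioned into mode-of-action
    classes taken from the compound annotation table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import CompoundRecord, HIT_CLASSES, ScreenDataset, ValidationError

__all__ = [
    "ThresholdResult",
    "normalize",
    "control_inhibitions",
    "aggregate_replicates",
    "derive_threshold",
    "call_hits",
    "score_against_truth",
]


def normalize(dataset: ScreenDataset) -> pd.DataFrame:
    """Background-subtract and normalize every well, per plate.

    Returns a frame with columns ``plate_id, well, role, compound_id,
    net_cps, pct_stimulation, pct_inhibition``.  Every plate must carry at
    least two background and two maximum-stimulation wells.
    """
    df = dataset.to_frame()
    out = []
    for plate, sub in df.groupby("plate_id", sort=False):
        for role in ("background", "max_stim"):
            if (sub["role"] == role).sum() < 2:
                raise ValidationError(
                    f"plate {plate}: needs >= 2 wells of role {role!r} for normalization"
                )
        bg = sub.loc[sub["role"] == "background", "luminescence_cps"].mean()
        net = sub["luminescence_cps"] - bg
        max_net = net[sub["role"] == "max_stim"].mean()
        if max_net == 0:
            raise ValidationError(f"plate {plate}: zero stimulation window")
        pct_stim = 100.0 * net / max_net
        sub = sub.assign(
            net_cps=net, pct_stimulation=pct_stim, pct_inhibition=100.0 - pct_stim
        )
        out.append(sub)
    cols = ["plate_id", "well", "role", "compound_id",
            "net_cps", "pct_stimulation", "pct_inhibition"]
    return pd.concat(out, ignore_index=True)[cols]


def control_inhibitions(normalized: pd.DataFrame) -> np.ndarray:
    """Percent-inhibition values of all antagonist-control wells, pooled."""
    mask = normalized["role"] == "antagonist_control"
    return normalized.loc[mask, "pct_inhibition"].to_numpy()


def aggregate_replicates(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-compound unweighted mean and SD of percent inhibition over replicates.

    SD uses the n-1 denominator and is NaN-flagged for single replicates.
    """
    tests = normalized[normalized["role"] == "test"]
    if tests.empty:
        raise ValidationError("no test wells to aggregate")
    agg = (
        tests.groupby("compound_id", sort=True)["pct_inhibition"]
        .agg(mean_pct_inhibition="mean",
             sd_pct_inhibition=lambda v: v.std(ddof=1),
             n_replicates="size")
        .reset_index()
    )
    agg["n_replicates"] = agg["n_replicates"].astype(int)
    return agg


@dataclass(frozen=True)
class ThresholdResult:
    """Hit threshold derived from the antagonist-control distribution."""

    threshold_pct_inhibition: float
    control_mean: float
    control_sd: float
    k_sd: float
    n_control_wells: int


def derive_threshold(control_pct_inhibition: Sequence[float], k_sd: float = 3.0) -> ThresholdResult:
    """``threshold = mean - k_sd * SD`` of the control percent inhibitions.

    Larger ``k_sd`` widens the acceptance band below the control mean, i.e.
    lowers the threshold and admits more compounds.
    """
    vals = np.asarray(control_pct_inhibition, dtype=float)
    if vals.size < 2:
        raise ValidationError("need >= 2 antagonist-control wells to derive a threshold")
    if k_sd < 0:
        raise ValidationError("k_sd must be >= 0")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return ThresholdResult(mean - k_sd * sd, mean, sd, float(k_sd), int(vals.size))


def call_hits(
    aggregated: pd.DataFrame,
    threshold: ThresholdResult,
    compounds: Sequence[CompoundRecord] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag hits and partition them by annotation class.

    Returns ``(hit_table, class_counts)``.  The hit table carries
    ``compound_id, mean_pct_inhibition, sd_pct_inhibition, n_replicates,
    pct_of_control_effect, threshold_pct_inhibition, k_sd, is_hit,
    hit_class``; ``pct_of_control_effect`` is the compound's mean inhibition
    as a percentage of the control mean inhibition.  The hit bound is closed:
    a compound exactly at the threshold is a hit.
    """
    classes = {c.compound_id: c.hit_class for c in compounds}
    bad = [c.hit_class for c in compounds if c.hit_class not in HIT_CLASSES]
    if bad:  # CompoundRecord already validates; guard raw inputs routed here
        raise ValidationError(f"unknown hit_class labels: {sorted(set(bad))}")
    out = aggregated.copy()
    out["pct_of_control_effect"] = (
        100.0 * out["mean_pct_inhibition"] / threshold.control_mean
    )
    out["threshold_pct_inhibition"] = threshold.threshold_pct_inhibition
    out["k_sd"] = threshold.k_sd
    out["is_hit"] = out["mean_pct_inhibition"] >= threshold.threshold_pct_inhibition
    out["hit_class"] = [classes.get(cid, "unknown") for cid in out["compound_id"]]
    counts = (
        out[out["is_hit"]]
        .groupby("hit_class", sort=True)
        .size()
        .reindex(HIT_CLASSES, fill_value=0)
        .rename("n_hits")
        .reset_index()
    )
    return out, counts


def score_against_truth(hit_table: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Sensitivity/specificity of hit calls against a planted-truth table.

    A planted positive is any compound whose mechanism suppresses the reporter
    signal past the threshold (true antagonists and off-target reporter
    inhibitors alike reduce luminescence; sensitivity for receptor-specific
    discovery is reported separately as ``sensitivity_antagonist``).
    """
    merged = hit_table.merge(truth, on="compound_id", validate="one_to_one")
    thr = merged["threshold_pct_inhibition"].iloc[0]
    pos = merged["true_effect_at_10uM"] * 100.0 >= thr
    hit = merged["is_hit"].to_numpy()
    res: dict[str, float] = {}
    res["n_compounds"] = float(len(merged))
    res["n_hits"] = float(hit.sum())
    res["sensitivity"] = float(hit[pos].mean()) if pos.any() else math.nan
    res["specificity"] = float((~hit[~pos]).mean()) if (~pos).any() else math.nan
    ant = pos & (merged["mechanism"] == "true_antagonist")
    res["sensitivity_antagonist"] = float(hit[ant].mean()) if ant.any() else math.nan
    return res
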