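"""Assay quality control: checkerboard analysis and Z-factor computation.

Two variants are reported side by side.  The classical screening-window
statistic of Zhang et al. is

    Z = 1 - 3 (sigma_pos + sigma_neg) / |mu_pos - mu_neg|

and the replicate-adjusted form (the NIH assay-guidance plate-uniformity
variant) shrinks both condition SDs by the square root of the number of
replicates planned per compound in the production screen:

    Z_n = 1 - 3 (sigma_pos / sqrt(n) + sigma_neg / sqrt(n)) / |mu_pos - mu_neg|

Sample SDs use the n-1 denominator throughout (control-well counts are small).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ScreenDataset, ValidationError

__all__ = ["QCReport", "compute_z", "checkerboard_qc"]


@dataclass(frozen=True)
class QCReport:
    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float
    n_pos: int
    n_neg: int
    n_replicates_planned: int
    z_standard: float
    z_replicate_adjusted: float
    undefined: bool = False  # flagged when mu_pos == mu_neg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def compute_z(
    pos: Sequence[float], neg: Sequence[float], n_replicates_planned: int = 4
) -> QCReport:
    """Z-factor of a positive/negative control separation.

    ``pos`` and ``neg`` are raw signals of the maximum- and minimum-stimulation
    conditions (each needs at least two values).  A zero control separation
    yields a flagged-undefined report rather than an exception.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("need >= 2 wells per condition to compute Z")
    if n_replicates_planned < 1:
        raise ValidationError("n_replicates_planned must be >= 1")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    sd_p = float(pos.std(ddof=1))
    sd_n = float(neg.std(ddof=1))
    sep = abs(mu_p - mu_n)
    if sep == 0:
        return QCReport(mu_p, sd_p, mu_n, sd_n, pos.size, neg.size,
                        n_replicates_planned, math.nan, math.nan, undefined=True)
    z_std = 1.0 - 3.0 * (sd_p + sd_n) / sep
    root_n = math.sqrt(n_replicates_planned)
    z_adj = 1.0 - 3.0 * (sd_p / root_n + sd_n / root_n) / sep
    return QCReport(mu_p, sd_p, mu_n, sd_n, int(pos.size), int(neg.size),
                    n_replicates_planned, z_std, z_adj)


def checkerboard_qc(dataset: ScreenDataset, n_replicates_planned: int = 4) -> pd.DataFrame:
    """Per-plate QC reports for a checkerboard dataset.

    Maximum-stimulation wells are the positive condition; antagonist-control
    (minimum) wells are the negative condition.
    """
    rows = []
    for plate in dataset.plate_ids:
        pos = [w.luminescence for w in dataset.wells
               if w.plate_id == plate and w.role == "max_stim"]
        neg = [w.luminescence for w in dataset.wells
               if w.plate_id == plate and w.role == "antagonist_control"]
        rep = compute_z(pos, neg, n_replicates_planned)
        rows.append({"plate_id": plate, **rep.__dict__})
    return pd.DataFrame(rows)
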