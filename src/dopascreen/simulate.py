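"""Synthetic screening campaigns with known ground truth.

The generator emulates the design of a 384-well luciferase-reporter antagonist
screen against the mosquito dopamine receptor AaDOP2: plates carry background
wells (cells without agonist), maximum-stimulation wells (300 nM dopamine),
antagonist-control wells (10 uM SCH23390 + 300 nM dopamine), a dopamine
response curve (14 nM - 30 uM), and test wells with library compounds at
10 uM.  Each compound is placed in quadruplicate -- duplicate wells on each of
two plates, in different quadrants -- to control for plate and automation
effects.

Noise model: luminescence is positive and heteroscedastic, so well noise is a
multiplicative lognormal with a given coefficient of variation, and each plate
carries a multiplicative lognormal plate effect.  Antagonist-control wells are
generated directly on the percent-inhibition scale so that their inhibition
distribution has a configurable mean and SD; the defaults (93%, 4%) are the
unique pair that places a mean-minus-3-SD threshold at 81% inhibition and a
mean-minus-6-SD threshold at 69%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import (
    CompoundRecord,
    ScreenDataset,
    ScreenDesign,
    ValidationError,
    WellMeasurement,
    ROW_LETTERS,
    N_COLS,
)

__all__ = [
    "AssayNoiseModel",
    "SyntheticTruth",
    "CHECKERBOARD_NOISE",
    "make_screen",
    "make_checkerboard",
    "make_dose_response",
    "make_bioassay",
    "four_pl",
    "loglogistic_mortality",
]

MECHANISMS = ("true_antagonist", "inactive", "off_target_reporter_inhibitor")

#: Screening concentration of every library compound (molar).
SCREEN_CONC = 1e-5
#: Maximum-stimulation dopamine concentration (molar).
MAX_STIM_DOPAMINE = 3e-7


@dataclass(frozen=True)
class AssayNoiseModel:
    """Mean/noise model of the luminescence assay.

    The ~10x separation between maximum stimulation and background follows the
    reported dopamine response window of the AaDOP2 reporter line.
    """

    background_mean: float = 1000.0  # cps
    max_net_signal: float = 9000.0  # cps above background at full stimulation
    well_noise_cv: float = 0.10
    plate_effect_sd: float = 0.10  # sd of the multiplicative lognormal plate effect

    def __post_init__(self) -> None:
        if self.background_mean <= 0 or self.max_net_signal <= 0:
            raise ValidationError("signal means must be positive")
        if not 0 <= self.well_noise_cv < 1:
            raise ValidationError("well_noise_cv must be a fraction < 1")
        if self.plate_effect_sd < 0:
            raise ValidationError("plate_effect_sd must be >= 0")


#: Checkerboard default noise, chosen so that the replicate-adjusted Z-factor
#: (n=4) of a simulated plate sits near 0.5, the qualification value of the
#: original assay.
CHECKERBOARD_NOISE = AssayNoiseModel(well_noise_cv=0.24)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted mechanism and potency for one simulated compound."""

    compound_id: str
    mechanism: str
    true_ic50: Optional[float] = None  # molar, antagonists only
    true_effect_at_10uM: float = 0.0  # fraction inhibition in [0, 1]

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValidationError(f"unknown mechanism {self.mechanism!r}")
        if (self.true_ic50 is not None) != (self.mechanism == "true_antagonist"):
            raise ValidationError("true_ic50 present iff mechanism is true_antagonist")
        if not 0 <= self.true_effect_at_10uM <= 1:
            raise ValidationError("true_effect_at_10uM must be in [0, 1]")


def _lognormal_multipliers(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def inhibition_at_screen_conc(ic50: float, conc: float = SCREEN_CONC, hill: float = 1.0) -> float:
    """Fractional inhibition of a simple competitive antagonist at ``conc``.

    Single-site occupancy with unit Hill slope unless overridden.
    """
    return 1.0 / (1.0 + (ic50 / conc) ** hill)


# ---------------------------------------------------------------------------
# Primary screen
# ---------------------------------------------------------------------------

# Control block: columns 1-2.  Test block: columns 3-24 (22 columns x 16 rows
# = 352 wells -> 176 compounds per plate pair at 2 wells per plate).
_TEST_COLS = list(range(3, N_COLS + 1))
_PAIR_CAPACITY = (len(_TEST_COLS) * len(ROW_LETTERS)) // 2
_DOPAMINE_CURVE = np.geomspace(14e-9, 30e-6, 8)  # 14 nM - 30 uM, ~half-log


def make_truth_table(
    n_compounds: int,
    rng: np.random.Generator,
    frac_antagonist: float = 0.04,
    frac_off_target: float = 0.01,
    ic50_range: tuple[float, float] = (1e-9, 1e-6),
    off_target_effect_range: tuple[float, float] = (0.8, 1.0),
) -> list[SyntheticTruth]:
    """Draw per-compound mechanisms and potencies.

    The 4% antagonist fraction mirrors the hit rate of the original 1,280
    compound pilot screen; antagonist IC50s are log-uniform over a range whose
    10 uM occupancy keeps planted hits mostly above the screening threshold.
    A small fraction of reporter-system inhibitors is planted as well: they
    suppress the luminescence signal without touching the receptor.
    """
    truths: list[SyntheticTruth] = []
    width = max(len(str(n_compounds)), 4)
    for i in range(n_compounds):
        cid = f"C{i + 1:0{width}d}"
        u = rng.uniform()
        if u < frac_antagonist:
            ic50 = 10 ** rng.uniform(*np.log10(ic50_range))
            truths.append(
                SyntheticTruth(
                    cid, "true_antagonist", float(ic50),
                    inhibition_at_screen_conc(float(ic50)),
                )
            )
        elif u < frac_antagonist + frac_off_target:
            truths.append(
                SyntheticTruth(
                    cid, "off_target_reporter_inhibitor", None,
                    float(rng.uniform(*off_target_effect_range)),
                )
            )
        else:
            truths.append(SyntheticTruth(cid, "inactive", None, 0.0))
    return truths


def truth_frame(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [t.compound_id for t in truths],
            "mechanism": [t.mechanism for t in truths],
            "true_ic50_M": [t.true_ic50 for t in truths],
            "true_effect_at_10uM": [t.true_effect_at_10uM for t in truths],
        }
    )


def make_screen(
    n_compounds: int = 1280,
    truths: Optional[Sequence[SyntheticTruth]] = None,
    noise: AssayNoiseModel = AssayNoiseModel(),
    seed: int = 0,
    control_inhibition_mean: float = 93.0,
    control_inhibition_sd: float = 4.0,
    frac_antagonist: float = 0.04,
    frac_off_target: float = 0.01,
) -> tuple[ScreenDataset, pd.DataFrame]:
    """Simulate a full primary screen and return (dataset, truth table).

    Each plate pair carries up to 176 compounds; a compound occupies two wells
    on each plate of its pair, the two wells of a plate in different quadrants
    and the second plate shifted one column so all four quadrants are covered.
    """
    if n_compounds < 1:
        raise ValidationError("n_compounds must be >= 1")
    rng = np.random.default_rng(seed)
    if truths is None:
        truths = make_truth_table(
            n_compounds, rng, frac_antagonist=frac_antagonist, frac_off_target=frac_off_target
        )
    if len(truths) != n_compounds:
        raise ValidationError("truth table size does not match n_compounds")

    wells: list[WellMeasurement] = []
    n_pairs = math.ceil(n_compounds / _PAIR_CAPACITY)
    bg, net_max = noise.background_mean, noise.max_net_signal

    for pair in range(n_pairs):
        plate_ids = (f"P{2 * pair + 1:03d}", f"P{2 * pair + 2:03d}")
        effects = _lognormal_multipliers(rng, noise.plate_effect_sd, 2)
        chunk = truths[pair * _PAIR_CAPACITY : (pair + 1) * _PAIR_CAPACITY]
        for plate_id, pe, col_shift in zip(plate_ids, effects, (0, 1)):
            # control block
            for r in ROW_LETTERS[:8]:
                m = _lognormal_multipliers(rng, noise.well_noise_cv, None)
                wells.append(WellMeasurement(plate_id, r, 1, "background", luminescence=bg * pe * m))
            for r in ROW_LETTERS[8:]:
                m = _lognormal_multipliers(rng, noise.well_noise_cv, None)
                wells.append(
                    WellMeasurement(
                        plate_id, r, 1, "max_stim", concentration=MAX_STIM_DOPAMINE,
                        luminescence=(bg + net_max) * pe * m,
                    )
                )
            for r in ROW_LETTERS[:8]:
                inh = rng.normal(control_inhibition_mean, control_inhibition_sd) / 100.0
                cps = (bg + net_max * max(0.0, 1.0 - inh)) * pe
                wells.append(
                    WellMeasurement(
                        plate_id, r, 2, "antagonist_control", compound_id="SCH23390",
                        concentration=1e-5, luminescence=cps,
                    )
                )
            for r, conc in zip(ROW_LETTERS[8:], _DOPAMINE_CURVE):
                frac = conc / (conc + 2.4e-7)  # dopamine EC50 of the screened receptor
                m = _lognormal_multipliers(rng, noise.well_noise_cv, None)
                wells.append(
                    WellMeasurement(
                        plate_id, r, 2, "dopamine_curve", concentration=float(conc),
                        luminescence=(bg + net_max * frac) * pe * m,
                    )
                )
            # test block: slot s -> rows (2j, 2j+1), column 3 + ((s//8 + shift) % 22)
            for s, truth in enumerate(chunk):
                j = s % 8
                c = _TEST_COLS[(s // 8 + col_shift) % len(_TEST_COLS)]
                for r in (ROW_LETTERS[2 * j], ROW_LETTERS[2 * j + 1]):
                    m = _lognormal_multipliers(rng, noise.well_noise_cv, None)
                    cps = (bg + net_max * (1.0 - truth.true_effect_at_10uM)) * pe * m
                    wells.append(
                        WellMeasurement(
                            plate_id, r, c, "test", compound_id=truth.compound_id,
                            concentration=SCREEN_CONC, luminescence=cps,
                        )
                    )

    compounds = [CompoundRecord(t.compound_id) for t in truths]
    dataset = ScreenDataset(wells=wells, compounds=compounds, design=ScreenDesign()).validate(
        check_design=True
    )
    return dataset, truth_frame(truths)


# ---------------------------------------------------------------------------
# Checkerboard (assay qualification)
# ---------------------------------------------------------------------------

def make_checkerboard(
    noise: AssayNoiseModel = CHECKERBOARD_NOISE,
    n_plates: int = 3,
    seed: int = 0,
    control_inhibition_mean: float = 93.0,
) -> ScreenDataset:
    """Alternate minimum and maximum stimulatory conditions over full plates.

    The maximum condition is 300 nM dopamine alone; the minimum adds 10 uM
    SCH23390, leaving the residual signal implied by the control inhibition
    mean.  Wells alternate by (row+column) parity across the 16x24 grid.
    """
    if n_plates < 1:
        raise ValidationError("n_plates must be >= 1")
    rng = np.random.default_rng(seed)
    bg, net_max = noise.background_mean, noise.max_net_signal
    min_mean = bg + net_max * (1.0 - control_inhibition_mean / 100.0)
    max_mean = bg + net_max
    wells: list[WellMeasurement] = []
    for p in range(n_plates):
        plate_id = f"CB{p + 1:02d}"
        pe = _lognormal_multipliers(rng, noise.plate_effect_sd, None)
        for i, r in enumerate(ROW_LETTERS):
            for c in range(1, N_COLS + 1):
                is_max = (i + c) % 2 == 0
                m = _lognormal_multipliers(rng, noise.well_noise_cv, None)
                if is_max:
                    wells.append(
                        WellMeasurement(
                            plate_id, r, c, "max_stim", concentration=MAX_STIM_DOPAMINE,
                            luminescence=max_mean * pe * m,
                        )
                    )
                else:
                    wells.append(
                        WellMeasurement(
                            plate_id, r, c, "antagonist_control", compound_id="SCH23390",
                            concentration=1e-5, luminescence=min_mean * pe * m,
                        )
                    )
    return ScreenDataset(wells=wells).validate()


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

def four_pl(conc: np.ndarray, top: float, bottom: float, log10_potency: float, hill: float) -> np.ndarray:
    """Four-parameter logistic response at molar concentrations ``conc``.

    response = bottom + (top - bottom) / (1 + 10**(hill * (log10_potency - log10 c))).
    Positive ``hill`` rises with concentration; negative falls.
    """
    logc = np.log10(np.asarray(conc, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log10_potency - logc)))


def make_dose_response(
    potency: float,
    concentrations: Sequence[float],
    n_experiments: int = 3,
    noise_cv: float = 0.10,
    seed: int = 0,
    top: float = 100.0,
    bottom: float = 0.0,
    hill: float = 1.0,
    n_replicates_per_point: int = 3,
) -> pd.DataFrame:
    """Simulate replicate dose-response experiments from a 4PL mean model.

    The default design follows the characterization assays: a minimum of
    three independent experiments with each sample measured in triplicate.
    Returns a tidy frame with columns ``concentration_M, response,
    experiment_id``.  Responses are the 4PL mean times a mean-1 lognormal
    multiplier with coefficient of variation ``noise_cv`` (luminescence and
    cAMP reads are positive with roughly proportional error).
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be strictly positive")
    if n_replicates_per_point < 1:
        raise ValidationError("n_replicates_per_point must be >= 1")
    rng = np.random.default_rng(seed)
    conc_rep = np.repeat(conc, n_replicates_per_point)
    frames = []
    for e in range(1, n_experiments + 1):
        mean = four_pl(conc_rep, top, bottom, math.log10(potency), hill)
        mult = _lognormal_multipliers(rng, noise_cv, conc_rep.size)
        frames.append(
            pd.DataFrame(
                {
                    "concentration_M": conc_rep,
                    "response": mean * mult,
                    "experiment_id": e,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Larval bioassay
# ---------------------------------------------------------------------------

def loglogistic_mortality(dose_uM: np.ndarray, lc50: float, lc90: float) -> np.ndarray:
    """Mortality probability of the log-logistic implied by an (LC50, LC90) pair."""
    if not lc90 > lc50 > 0:
        raise ValidationError("need lc90 > lc50 > 0")
    slope = math.log(9.0) / (math.log10(lc90) - math.log10(lc50))  # logits / log10 dose
    eta = slope * (np.log10(np.asarray(dose_uM, dtype=float)) - math.log10(lc50))
    return 1.0 / (1.0 + np.exp(-eta))


def make_bioassay(
    truth_lc50: float,
    truth_lc90: float,
    doses: Sequence[float] = (400.0, 200.0, 100.0, 50.0, 25.0),
    n_per_well: int = 10,
    wells_per_dose: int = 5,
    n_assays: int = 3,
    seed: int = 0,
    compound_id: str = "amitriptyline",
) -> pd.DataFrame:
    """Simulate a larval dose-mortality assay at the standard design.

    Defaults follow the campaign design: five doses (400, 200, 100, 50, 25 uM),
    five technical replicates of 10 larvae per dose, repeated in three assays.
    Deaths per well are binomial with the log-logistic mortality implied by
    the (LC50, LC90) truth pair.  Doses are micromolar.
    """
    rng = np.random.default_rng(seed)
    p = loglogistic_mortality(np.asarray(doses, dtype=float), truth_lc50, truth_lc90)
    rows = []
    for a in range(1, n_assays + 1):
        for d, pd_ in zip(doses, p):
            for w in range(1, wells_per_dose + 1):
                dead = int(rng.binomial(n_per_well, pd_))
                rows.append(
                    {
                        "compound_id": compound_id,
                        "dose_uM": float(d),
                        "n_larvae": n_per_well,
                        "n_dead": dead,
                        "technical_replicate": w,
                        "assay_replicate": a,
                    }
                )
        for w in range(1, wells_per_dose + 1):  # water controls, zero mortality model
            rows.append(
                {
                    "compound_id": "water",
                    "dose_uM": 0.0,
                    "n_larvae": n_per_well,
                    "n_dead": 0,
                    "technical_replicate": w,
                    "assay_replicate": a,
                }
            )
    return pd.DataFrame(rows)
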