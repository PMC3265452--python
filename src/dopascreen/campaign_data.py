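"""Reported values from the original AaDOP2 antagonist discovery campaign.

These printed results serve as fixed inputs: the hit summary of the primary
LOPAC1280 screen (51 hits with their percent of the SCH23390 antagonist-
control effect and mode-of-action class) and the confirmation-assay IC50
table comparing AaDOP2 with the human D1 receptor, including the derived
fold-selectivity column.  Potencies are nanomolar; percent-effect values are
percentages.  Campaign-level anchors (control behaviour, thresholds, potency
ground truths, larval design) are collected at the bottom.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "HIT_SUMMARY",
    "CONFIRMATION_IC50_NM",
    "hit_summary_frame",
    "confirmation_frame",
    "CONTROL_INHIBITION_MEAN",
    "CONTROL_INHIBITION_SD",
    "THRESHOLD_K3",
    "THRESHOLD_K6",
    "N_HITS",
    "EC50_DOPAMINE_NM",
    "LARVAL_LC50_UM",
    "LARVAL_LC90_UM",
    "LARVAL_DOSES_UM",
    "SINGLE_DOSE_MORTALITY_PCT",
]

# (compound, hit class, % of the SCH23390 effect) for the 51 primary-screen hits.
HIT_SUMMARY: list[tuple[str, str, float]] = [
    ("R(+)-SCH-23390 hydrochloride", "dopamine_receptor_antagonist", 83),
    ("(+/-)-Butaclamol hydrochloride", "dopamine_receptor_antagonist", 81),
    ("(+)-Butaclamol hydrochloride", "dopamine_receptor_antagonist", 87),
    ("Chlorprothixene hydrochloride", "dopamine_receptor_antagonist", 94),
    ("Clozapine", "dopamine_receptor_antagonist", 81),
    ("Fluphenazine dihydrochloride", "dopamine_receptor_antagonist", 82),
    ("cis-(Z)-Flupenthixol dihydrochloride", "dopamine_receptor_antagonist", 88),
    ("JL-18", "dopamine_receptor_antagonist", 98),
    ("LE 300", "dopamine_receptor_antagonist", 99),
    ("Loxapine succinate", "dopamine_receptor_antagonist", 97),
    ("(+/-)-Octoclothepin maleate", "dopamine_receptor_antagonist", 97),
    ("Perphenazine", "dopamine_receptor_antagonist", 95),
    ("Prochlorperazine dimaleate", "dopamine_receptor_antagonist", 83),
    ("Promazine hydrochloride", "dopamine_receptor_antagonist", 88),
    ("Propionylpromazine hydrochloride", "dopamine_receptor_antagonist", 85),
    ("Risperidone", "dopamine_receptor_antagonist", 83),
    ("Triflupromazine hydrochloride", "dopamine_receptor_antagonist", 88),
    ("Trifluoperazine dihydrochloride", "dopamine_receptor_antagonist", 81),
    ("Thiothixene hydrochloride", "dopamine_receptor_antagonist", 86),
    ("Thioridazine hydrochloride", "dopamine_receptor_antagonist", 86),
    ("Amperozide hydrochloride", "serotonin_receptor_ligand", 83),
    ("LY-310,762 hydrochloride", "serotonin_receptor_ligand", 81),
    ("Mianserin hydrochloride", "serotonin_receptor_ligand", 95),
    ("Methiothepin mesylate", "serotonin_receptor_ligand", 99),
    ("Pirenperone", "serotonin_receptor_ligand", 90),
    ("Ritanserin", "serotonin_receptor_ligand", 83),
    ("Ketotifen fumarate", "histamine_receptor_ligand", 96),
    ("Promethazine hydrochloride", "histamine_receptor_ligand", 95),
    ("Benztropine mesylate", "machr_ligand", 89),
    ("Amitriptyline hydrochloride", "uptake_inhibitor", 90),
    ("Amoxapine", "uptake_inhibitor", 90),
    ("4'-Chloro-3-alpha-(diphenylmethoxy)tropane hydrochloride", "uptake_inhibitor", 85),
    ("Doxepin hydrochloride", "uptake_inhibitor", 90),
    ("Imipramine hydrochloride", "uptake_inhibitor", 96),
    ("Maprotiline hydrochloride", "uptake_inhibitor", 82),
    ("Nortriptyline hydrochloride", "uptake_inhibitor", 96),
    ("Protriptyline hydrochloride", "uptake_inhibitor", 82),
    ("Trimipramine maleate", "uptake_inhibitor", 87),
    ("Diacylglycerol kinase inhibitor I", "kinase_modulator", 90),
    ("Kenpaullone", "kinase_modulator", 83),
    ("NSC 95397", "kinase_modulator", 83),
    ("Piceatannol", "kinase_modulator", 98),
    ("Phorbol 12-myristate 13-acetate", "kinase_modulator", 88),
    ("Purvalanol A", "kinase_modulator", 93),
    ("beta-Lapachone", "miscellaneous", 86),
    ("(S)-(+)-Camptothecin", "miscellaneous", 93),
    ("Emetine dihydrochloride hydrate", "miscellaneous", 86),
    ("Idarubicin", "miscellaneous", 83),
    ("Mitoxantrone", "miscellaneous", 83),
    ("Niclosamide", "miscellaneous", 95),
    ("Resveratrol", "miscellaneous", 89),
]

# Confirmation assays: compound -> (AaDOP2 IC50 nM, hD1 IC50 nM, fold selectivity
# for AaDOP2 over hD1).  None marks a censored (>= 10 uM) or untested entry.
CONFIRMATION_IC50_NM: dict[str, tuple[float | None, float | None, float | None]] = {
    "Amitriptyline": (14.0, 470.0, 36.0),
    "(+)-Butaclamol": (480.0, 3.7, 0.008),
    "cis-(Z)-Flupenthixol": (20.0, 11.0, 0.55),
    "Clozapine": (31.0, 300.0, 9.7),
    "Doxepin": (31.0, 960.0, 31.0),
    "Methiothepin": (14.0, 80.0, 5.7),
    "Mianserin": (120.0, 1200.0, 10.0),
    "Niclosamide": (None, None, None),
    "Piceatannol": (None, None, None),
    "Resveratrol": (None, None, None),
    "SCH23390": (1600.0, 0.47, 0.0003),
}


def hit_summary_frame() -> pd.DataFrame:
    return pd.DataFrame(HIT_SUMMARY, columns=["compound", "hit_class", "pct_of_control_effect"])


def confirmation_frame(drop_censored: bool = True) -> pd.DataFrame:
    rows = [
        {"compound_id": k, "ic50_aadop2": a, "ic50_hd1": h, "fold_reported": f}
        for k, (a, h, f) in CONFIRMATION_IC50_NM.items()
    ]
    df = pd.DataFrame(rows)
    if drop_censored:
        df = df.dropna(subset=["ic50_aadop2", "ic50_hd1"]).reset_index(drop=True)
    return df


# Campaign anchors -----------------------------------------------------------

#: Antagonist-control percent-inhibition behaviour implied jointly by the two
#: published cutoffs (mean - 3*SD = 81, mean - 6*SD = 69).
CONTROL_INHIBITION_MEAN = 93.0
CONTROL_INHIBITION_SD = 4.0
THRESHOLD_K3 = 81.0
THRESHOLD_K6 = 69.0
N_HITS = 51

#: Dopamine EC50s (nM) at the two mosquito receptors.
EC50_DOPAMINE_NM = {"AaDOP1": 3.1, "AaDOP2": 240.0}

#: Amitriptyline larval toxicity estimates (micromolar) and assay design.
LARVAL_LC50_UM = 78.0
LARVAL_LC90_UM = 185.0
LARVAL_DOSES_UM = (400.0, 200.0, 100.0, 50.0, 25.0)

#: Single-dose (400 uM) observed mean mortalities, percent.
SINGLE_DOSE_MORTALITY_PCT = {"amitriptyline": 93.0, "doxepin": 72.0}
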