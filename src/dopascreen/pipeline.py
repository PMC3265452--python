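"""End-to-end campaign orchestration: simulate -> qc -> hits -> potency -> selectivity -> bioassay.

The campaign runs each analysis stage in order on synthetic inputs generated
from one seed, writes per-stage TSV artifacts, and renders a Markdown report
whose body is a pure function of (config, seed) -- rerunning with the same
inputs reproduces it byte for byte (timings go to the log, never the report).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import campaign_data as ref
from .bioassay import LCFit, fit_lc, single_dose_test
from .data import RunConfig, ScreenDataset, ValidationError, write_table
from .doseresponse import estimate_potency, potency_table
from .qc import checkerboard_qc
from .screen import aggregate_replicates, call_hits, control_inhibitions, derive_threshold, normalize, score_against_truth
from .selectivity import compute_fold_selectivity, rank_order_correlation
from .simulate import (
    AssayNoiseModel,
    CHECKERBOARD_NOISE,
    make_bioassay,
    make_checkerboard,
    make_dose_response,
    make_screen,
)

logger = logging.getLogger("dopascreen")

__all__ = ["CampaignReport", "run_campaign"]


@dataclass
class CampaignReport:
    config: dict
    config_hash: str
    seed: int
    qc: pd.DataFrame
    threshold: dict
    hit_counts: pd.DataFrame
    truth_scores: dict
    potencies: pd.DataFrame
    selectivity: pd.DataFrame
    rank_correlation: dict
    lc_fit: dict
    single_dose: dict

    def to_markdown(self) -> str:
        lines = ["# Screening campaign report", ""]
        lines += [f"- config sha256: `{self.config_hash}`", f"- seed: {self.seed}", ""]
        lines += ["## Assay QC (checkerboard)", "",
                  self.qc.round(4).to_string(index=False), ""]
        lines += ["## Primary screen", "",
                  f"- hit threshold: {self.threshold['threshold_pct_inhibition']:.2f}% inhibition "
                  f"(control mean {self.threshold['control_mean']:.2f}%, SD "
                  f"{self.threshold['control_sd']:.2f}%, k={self.threshold['k_sd']:g})",
                  f"- hits: {int(self.hit_counts['n_hits'].sum())}", "",
                  self.hit_counts.to_string(index=False), "",
                  "Planted-truth recovery: "
                  + ", ".join(f"{k}={v:.3f}" for k, v in self.truth_scores.items()), ""]
        lines += ["## Confirmation potencies", "",
                  self.potencies.to_string(index=False, float_format=lambda v: f"{v:.4g}"), ""]
        lines += ["## Selectivity", "",
                  self.selectivity.round(4).to_string(index=False), "",
                  f"Rank-order correlation R^2 = {self.rank_correlation['r_squared']:.4f} "
                  f"(p = {self.rank_correlation['p_value']:.4f})", ""]
        lines += ["## Larval toxicity", "",
                  f"- LC50 = {self.lc_fit['lc50']:.2f} uM "
                  f"(95% CI {self.lc_fit['lc50_ci'][0]:.2f}-{self.lc_fit['lc50_ci'][1]:.2f})",
                  f"- LC90 = {self.lc_fit['lc90']:.2f} uM "
                  f"(95% CI {self.lc_fit['lc90_ci'][0]:.2f}-{self.lc_fit['lc90_ci'][1]:.2f})",
                  f"- single-dose (400 uM): mean mortality "
                  f"{self.single_dose['mean_mortality']:.1f}%, "
                  f"t = {self.single_dose['t_statistic']:.2f}, "
                  f"p = {self.single_dose['p_value']:.2e}", ""]
        return "\n".join(lines)


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2fs", name, dt)
            else:
                logger.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def run_campaign(
    config: Optional[RunConfig] = None,
    outdir: str | Path = "campaign_out",
    n_compounds: int = 1280,
    n_boot: int = 200,
) -> CampaignReport:
    """Run the full synthetic campaign and write all stage artifacts.

    Stage failures propagate (halting downstream stages) after being logged.
    """
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(cfg)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    seed = cfg.rng_seed
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]

    noise = AssayNoiseModel(well_noise_cv=cfg.noise_cv, plate_effect_sd=cfg.plate_effect_sd)

    with _stage("qc"):
        cb = make_checkerboard(CHECKERBOARD_NOISE, n_plates=3, seed=seeds[0])
        qc = checkerboard_qc(cb, n_replicates_planned=4)
        write_table(qc, outdir / "qc.tsv")

    with _stage("screen"):
        dataset, truth = make_screen(n_compounds=n_compounds, noise=noise, seed=seeds[1])
        norm = normalize(dataset)
        agg = aggregate_replicates(norm)
        thr = derive_threshold(control_inhibitions(norm), k_sd=cfg.k_sd)
        hits, counts = call_hits(agg, thr, dataset.compounds)
        scores = score_against_truth(hits, truth)
        write_table(truth, outdir / "truth.tsv")
        write_table(hits, outdir / "hits.tsv")
        write_table(counts, outdir / "hit_class_counts.tsv")

    with _stage("dose_response"):
        spans = {"AaDOP1": (1e-12, 1e-6), "AaDOP2": (1e-11, 1e-4)}
        estimates = []
        for receptor, ec50_nm in ref.EC50_DOPAMINE_NM.items():
            conc = np.geomspace(*spans[receptor], 10)
            curve = make_dose_response(ec50_nm * 1e-9, conc, n_experiments=3,
                                       noise_cv=cfg.noise_cv, seed=seeds[2])
            estimates.append(
                estimate_potency(curve, "dopamine", receptor, mode="agonist",
                                 censor_limit=cfg.censor_limit)
            )
        pot = potency_table(estimates)
        write_table(pot, outdir / "potencies.tsv")

    with _stage("selectivity"):
        pairs = ref.confirmation_frame()
        sel = compute_fold_selectivity(pairs)
        rank = rank_order_correlation(pairs["ic50_aadop2"], pairs["ic50_hd1"],
                                      seed=seeds[3])
        write_table(sel, outdir / "selectivity.tsv")

    with _stage("bioassay"):
        records = make_bioassay(ref.LARVAL_LC50_UM, ref.LARVAL_LC90_UM, seed=seeds[4])
        lc = fit_lc(records, n_boot=n_boot, seed=seeds[4])
        top_dose = records[records["dose_uM"] == records["dose_uM"].max()]
        per_assay = (
            top_dose.groupby("assay_replicate")
            .apply(lambda g: 100.0 * g["n_dead"].sum() / g["n_larvae"].sum(),
                   include_groups=False)
        )
        sd = single_dose_test(per_assay.to_numpy(), control_mean_pct=0.0)
        write_table(records, outdir / "bioassay.tsv")

    report = CampaignReport(
        config=cfg_dict,
        config_hash=cfg_hash,
        seed=seed,
        qc=qc[["plate_id", "z_standard", "z_replicate_adjusted"]],
        threshold=asdict(thr),
        hit_counts=counts,
        truth_scores=scores,
        potencies=pot,
        selectivity=sel[["compound_id", "fold_selectivity", "fold_selectivity_report"]],
        rank_correlation={"r_squared": rank.r_squared, "p_value": rank.p_value,
                          "rho": rank.rho, "n": rank.n},
        lc_fit={"lc50": lc.lc50, "lc90": lc.lc90, "slope": lc.slope,
                "lc50_ci": lc.lc50_ci, "lc90_ci": lc.lc90_ci},
        single_dose=asdict(sd),
    )
    (outdir / "report.md").write_text(report.to_markdown())
    return report
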