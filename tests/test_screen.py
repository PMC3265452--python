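"""Normalization, replicate aggregation, threshold derivation, hit calling."""

import numpy as np
import pandas as pd
import pytest

from dopascreen import (
    AssayNoiseModel,
    CompoundRecord,
    ScreenDataset,
    SyntheticTruth,
    ValidationError,
    WellMeasurement,
    aggregate_replicates,
    call_hits,
    control_inhibitions,
    derive_threshold,
    make_screen,
    normalize,
    score_against_truth,
)
from dopascreen.screen import ThresholdResult


def _plate(bg=100.0, maxstim=1100.0, test=600.0):
    wells = [
        WellMeasurement("P1", "A", 1, "background", luminescence=bg),
        WellMeasurement("P1", "B", 1, "background", luminescence=bg),
        WellMeasurement("P1", "C", 1, "max_stim", concentration=3e-7, luminescence=maxstim),
        WellMeasurement("P1", "D", 1, "max_stim", concentration=3e-7, luminescence=maxstim),
        WellMeasurement("P1", "E", 3, "test", compound_id="C1", concentration=1e-5,
                        luminescence=test),
    ]
    return ScreenDataset(wells=wells).validate()


def test_normalize_direct_arithmetic():
    """bg 100, max 1100, test 600 -> net 500, 50% stimulation, 50% inhibition."""
    norm = normalize(_plate())
    row = norm[norm["role"] == "test"].iloc[0]
    assert row["net_cps"] == pytest.approx(500.0)
    assert row["pct_stimulation"] == pytest.approx(50.0)
    assert row["pct_inhibition"] == pytest.approx(50.0)


def test_normalize_boundary_wells():
    norm = normalize(_plate(test=1100.0))
    assert norm[norm["role"] == "test"]["pct_inhibition"].iloc[0] == pytest.approx(0.0)
    norm = normalize(_plate(test=100.0))
    assert norm[norm["role"] == "test"]["pct_inhibition"].iloc[0] == pytest.approx(100.0)
    # max_stim wells average exactly 100% stimulation per plate
    norm = normalize(_plate())
    assert norm[norm["role"] == "max_stim"]["pct_stimulation"].mean() == pytest.approx(100.0)


def test_missing_control_role_names_plate_and_role():
    ds = ScreenDataset(
        wells=[
            WellMeasurement("P9", "A", 1, "background", luminescence=100),
            WellMeasurement("P9", "B", 1, "background", luminescence=100),
            WellMeasurement("P9", "E", 3, "test", compound_id="C1",
                            concentration=1e-5, luminescence=600),
        ]
    )
    with pytest.raises(ValidationError, match="P9.*max_stim"):
        normalize(ds)


def test_aggregate_replicates_mean_and_sd():
    norm = pd.DataFrame(
        {
            "plate_id": ["P1"] * 4,
            "well": ["E3", "F3", "E4", "F4"],
            "role": ["test"] * 4,
            "compound_id": ["C1"] * 4,
            "net_cps": [0.0] * 4,
            "pct_stimulation": [20.0, 18.0, 16.0, 22.0],
            "pct_inhibition": [80.0, 82.0, 84.0, 78.0],
        }
    )
    agg = aggregate_replicates(norm)
    assert agg["mean_pct_inhibition"].iloc[0] == pytest.approx(81.0)
    assert agg["sd_pct_inhibition"].iloc[0] == pytest.approx(2.581988897)
    assert agg["n_replicates"].iloc[0] == 4
    # permutation symmetry
    agg2 = aggregate_replicates(norm.iloc[::-1].reset_index(drop=True))
    pd.testing.assert_frame_equal(agg, agg2)


def test_single_replicate_sd_flagged_absent():
    norm = pd.DataFrame(
        {
            "plate_id": ["P1"], "well": ["E3"], "role": ["test"],
            "compound_id": ["C1"], "net_cps": [1.0],
            "pct_stimulation": [20.0], "pct_inhibition": [80.0],
        }
    )
    agg = aggregate_replicates(norm)
    assert agg["mean_pct_inhibition"].iloc[0] == 80.0
    assert np.isnan(agg["sd_pct_inhibition"].iloc[0])


def test_threshold_from_published_control_behaviour():
    """Control mean 93%, SD 4% puts the cut at 81% (k=3) and 69% (k=6)."""
    rng = np.random.default_rng(0)
    # large control sample whose realized moments are then used exactly
    vals = rng.normal(93, 4, size=200000)
    m, s = vals.mean(), vals.std(ddof=1)
    t3 = derive_threshold(vals, k_sd=3)
    t6 = derive_threshold(vals, k_sd=6)
    assert t3.threshold_pct_inhibition == pytest.approx(m - 3 * s)
    assert t6.threshold_pct_inhibition == pytest.approx(m - 6 * s)
    assert t3.threshold_pct_inhibition == pytest.approx(81.0, abs=0.15)
    assert t6.threshold_pct_inhibition == pytest.approx(69.0, abs=0.25)


def test_threshold_k0_equals_control_mean():
    t = derive_threshold([90.0, 94.0, 92.0], k_sd=0)
    assert t.threshold_pct_inhibition == pytest.approx(92.0)


def test_threshold_requires_two_controls():
    with pytest.raises(ValidationError):
        derive_threshold([93.0], k_sd=3)


def _agg(values):
    return pd.DataFrame(
        {
            "compound_id": [f"C{i}" for i in range(len(values))],
            "mean_pct_inhibition": values,
            "sd_pct_inhibition": [1.0] * len(values),
            "n_replicates": [4] * len(values),
        }
    )


def test_exactly_at_threshold_is_a_hit():
    thr = ThresholdResult(81.0, 93.0, 4.0, 3.0, 16)
    hits, _ = call_hits(_agg([81.0, 80.999]), thr)
    assert hits["is_hit"].tolist() == [True, False]


def test_pct_of_control_effect_is_100_at_control_mean():
    thr = ThresholdResult(81.0, 93.0, 4.0, 3.0, 16)
    hits, _ = call_hits(_agg([93.0]), thr)
    assert hits["pct_of_control_effect"].iloc[0] == pytest.approx(100.0)


def test_hits_monotone_in_k_sd():
    """hits(k=3) is a subset of hits(k=6) on any synthetic screen."""
    for seed in range(3):
        dataset, _ = make_screen(n_compounds=96, seed=seed)
        norm = normalize(dataset)
        agg = aggregate_replicates(norm)
        ctrl = control_inhibitions(norm)
        h3, _ = call_hits(agg, derive_threshold(ctrl, 3))
        h6, _ = call_hits(agg, derive_threshold(ctrl, 6))
        set3 = set(h3.loc[h3["is_hit"], "compound_id"])
        set6 = set(h6.loc[h6["is_hit"], "compound_id"])
        assert set3 <= set6


def test_plate_effect_invariance_on_noiseless_compounds():
    """Per-plate normalization cancels multiplicative plate effects exactly."""
    truths = [
        SyntheticTruth(f"C{i+1:04d}", "off_target_reporter_inhibitor", None, e)
        for i, e in enumerate(np.linspace(0.0, 1.0, 20))
    ]
    base = AssayNoiseModel(well_noise_cv=0.0, plate_effect_sd=0.0)
    bumped = AssayNoiseModel(well_noise_cv=0.0, plate_effect_sd=0.2)
    out = {}
    for name, noise in [("flat", base), ("plate", bumped)]:
        ds, _ = make_screen(n_compounds=20, truths=truths, noise=noise, seed=3,
                            control_inhibition_sd=0.0)
        agg = aggregate_replicates(normalize(ds))
        out[name] = agg.set_index("compound_id")["mean_pct_inhibition"]
    pd.testing.assert_series_equal(out["flat"], out["plate"], atol=1e-9, rtol=0)


def test_class_partition_and_unknown_annotation():
    thr = ThresholdResult(81.0, 93.0, 4.0, 3.0, 16)
    annos = [
        CompoundRecord("C0", hit_class="dopamine_receptor_antagonist"),
        CompoundRecord("C1", hit_class="uptake_inhibitor"),
    ]
    hits, counts = call_hits(_agg([90.0, 85.0, 82.0]), thr, annos)
    assert hits["hit_class"].tolist() == [
        "dopamine_receptor_antagonist", "uptake_inhibitor", "unknown"
    ]
    n = counts.set_index("hit_class")["n_hits"]
    assert n["dopamine_receptor_antagonist"] == 1 and n["unknown"] == 1
    assert n.sum() == 3


def test_planted_truth_recovery_scores(small_screen):
    dataset, truth = small_screen
    norm = normalize(dataset)
    agg = aggregate_replicates(norm)
    thr = derive_threshold(control_inhibitions(norm), 3)
    hits, _ = call_hits(agg, thr, dataset.compounds)
    scores = score_against_truth(hits, truth)
    assert scores["n_compounds"] == 64
    assert 0 <= scores["specificity"] <= 1
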