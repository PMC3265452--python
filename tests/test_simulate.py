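"""Ground-truth generators: design invariants, no-noise identities, mean models."""

import numpy as np
import pandas as pd
import pytest

from dopascreen import (
    AssayNoiseModel,
    SyntheticTruth,
    ValidationError,
    four_pl,
    loglogistic_mortality,
    make_bioassay,
    make_checkerboard,
    make_dose_response,
    make_screen,
)
from dopascreen.simulate import inhibition_at_screen_conc, make_truth_table


def test_seed_fixes_every_generated_byte():
    a, ta = make_screen(n_compounds=40, seed=7)
    b, tb = make_screen(n_compounds=40, seed=7)
    pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
    pd.testing.assert_frame_equal(ta, tb)
    c, _ = make_screen(n_compounds=40, seed=8)
    assert not a.to_frame().equals(c.to_frame())


def test_replication_design_holds(small_screen):
    dataset, _ = small_screen
    # validated at construction; re-check one compound explicitly
    wells = [w for w in dataset.wells if w.compound_id == "C0001" and w.role == "test"]
    assert len(wells) == 4
    assert len({w.plate_id for w in wells}) == 2
    for plate in {w.plate_id for w in wells}:
        quads = [w.quadrant for w in wells if w.plate_id == plate]
        assert len(set(quads)) == len(quads)


def test_no_noise_inactive_equals_max_stim(noiseless_screen):
    dataset, truth = noiseless_screen
    df = dataset.to_frame()
    inactive = truth.loc[truth["mechanism"] == "inactive", "compound_id"]
    for plate in dataset.plate_ids:
        sub = df[df["plate_id"] == plate]
        max_cps = sub.loc[sub["role"] == "max_stim", "luminescence_cps"].unique()
        test_cps = sub.loc[
            (sub["role"] == "test") & sub["compound_id"].isin(inactive),
            "luminescence_cps",
        ]
        assert np.allclose(test_cps, max_cps[0])


def test_full_blocker_equals_background_no_noise():
    noise = AssayNoiseModel(well_noise_cv=0.0, plate_effect_sd=0.0)
    truths = [SyntheticTruth("C0001", "off_target_reporter_inhibitor", None, 1.0)]
    dataset, _ = make_screen(n_compounds=1, truths=truths, noise=noise, seed=0)
    df = dataset.to_frame()
    bg = df.loc[df["role"] == "background", "luminescence_cps"].iloc[0]
    assert np.allclose(df.loc[df["role"] == "test", "luminescence_cps"], bg)


def test_all_luminescence_nonnegative(small_screen):
    dataset, _ = small_screen
    assert all(w.luminescence >= 0 for w in dataset.wells)


def test_screen_mean_model_monte_carlo():
    """Generated well means match the stated mean model within 3 standard errors."""
    noise = AssayNoiseModel(well_noise_cv=0.2, plate_effect_sd=0.0)
    truths = [SyntheticTruth(f"C{i+1:04d}", "off_target_reporter_inhibitor", None, 0.4)
              for i in range(170)]
    dataset, _ = make_screen(n_compounds=170, truths=truths, noise=noise, seed=3)
    df = dataset.to_frame()
    vals = df.loc[df["role"] == "test", "luminescence_cps"]
    expected = noise.background_mean + noise.max_net_signal * 0.6
    se = expected * 0.2 / np.sqrt(len(vals))
    assert abs(vals.mean() - expected) < 3 * se


def test_truth_table_invariants():
    rng = np.random.default_rng(0)
    truths = make_truth_table(500, rng)
    for t in truths:
        assert (t.true_ic50 is not None) == (t.mechanism == "true_antagonist")
        assert 0 <= t.true_effect_at_10uM <= 1
    assert SyntheticTruth("x", "inactive").true_effect_at_10uM == 0
    with pytest.raises(ValidationError):
        SyntheticTruth("x", "inactive", true_ic50=1e-7)


def test_occupancy_inhibition_at_screen_concentration():
    # single-site occupancy with unit Hill slope: IC50 == screen conc -> 50%
    assert inhibition_at_screen_conc(1e-5) == pytest.approx(0.5)
    assert inhibition_at_screen_conc(1e-7) == pytest.approx(1 / 1.01)


def test_checkerboard_alternates_and_covers_plate():
    ds = make_checkerboard(n_plates=1, seed=0)
    assert len(ds.wells) == 384
    roles = {w.role for w in ds.wells}
    assert roles == {"max_stim", "antagonist_control"}
    n_max = sum(w.role == "max_stim" for w in ds.wells)
    assert n_max == 192


def test_doubling_noise_decreases_expected_z():
    from dopascreen.qc import checkerboard_qc

    def mean_z(cv, seeds=range(5)):
        zs = []
        for s in seeds:
            ds = make_checkerboard(AssayNoiseModel(well_noise_cv=cv), n_plates=1, seed=s)
            zs.append(checkerboard_qc(ds)["z_replicate_adjusted"].mean())
        return np.mean(zs)

    assert mean_z(0.2) > mean_z(0.4)


def test_dose_response_no_noise_on_curve():
    conc = np.geomspace(1e-10, 1e-5, 8)
    df = make_dose_response(1e-7, conc, n_experiments=2, noise_cv=0.0, seed=0)
    expected = four_pl(df["concentration_M"].to_numpy(), 100.0, 0.0, -7.0, 1.0)
    assert np.allclose(df["response"], expected)


def test_dose_response_scale_equivariance():
    conc = np.geomspace(1e-10, 1e-5, 8)
    a = make_dose_response(1e-7, conc, 2, 0.1, seed=9)
    b = make_dose_response(1e-6, conc * 10, 2, 0.1, seed=9)
    assert np.allclose(a["response"], b["response"])


def test_dose_response_rejects_nonpositive_concentration():
    with pytest.raises(ValidationError):
        make_dose_response(1e-7, [0.0, 1e-8], 1, 0.1, seed=0)


def test_bioassay_mortality_at_lc50_and_lc90():
    p = loglogistic_mortality(np.array([78.0, 185.0]), 78.0, 185.0)
    assert p[0] == pytest.approx(0.5)
    assert p[1] == pytest.approx(0.9)


def test_bioassay_counts_bounded_and_design_sized():
    rec = make_bioassay(78, 185, seed=1)
    treated = rec[rec["dose_uM"] > 0]
    assert len(treated) == 5 * 5 * 3
    assert ((rec["n_dead"] >= 0) & (rec["n_dead"] <= rec["n_larvae"])).all()


def test_bioassay_rejects_inconsistent_lc_pair():
    with pytest.raises(ValidationError):
        make_bioassay(185, 78, seed=0)


def test_bioassay_mean_mortality_matches_model():
    rec = make_bioassay(78, 185, doses=(78.0,), wells_per_dose=50, n_assays=10, seed=2)
    treated = rec[rec["dose_uM"] > 0]
    frac = treated["n_dead"].sum() / treated["n_larvae"].sum()
    se = np.sqrt(0.25 / treated["n_larvae"].sum())
    assert abs(frac - 0.5) < 3 * se


def test_capacity_error_when_layout_overflows():
    # 176 compounds fit a plate pair; the generator rolls extra pairs instead
    ds, _ = make_screen(n_compounds=200, seed=0)
    assert len(ds.plate_ids) == 4
    with pytest.raises(ValidationError):
        make_screen(n_compounds=0, seed=0)
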