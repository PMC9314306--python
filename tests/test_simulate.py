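import io

import numpy as np
import pytest

from promirt import grm
from promirt.data import compute_total_scores, derive_baselines
from promirt.simulate import (TrialDesign, baseline_theta_moments, calibrate_baseline,
                              default_item_params, expected_total_under, generate_trial,
                              synthetic_item_layout)
from promirt.references import reference_trial_params


def _csv(ds):
    buf = io.StringIO()
    ds.write_csv(buf)
    return buf.getvalue()


def test_same_seed_gives_identical_csv():
    design = TrialDesign(n_per_arm=(25, 25), schedule="weekly")
    a = _csv(generate_trial(design, seed=11))
    b = _csv(generate_trial(design, seed=11))
    assert a == b
    c = _csv(generate_trial(design, seed=12))
    assert a != c


def test_no_missingness_yields_full_diaries():
    design = TrialDesign(n_per_arm=(8, 8), completer_fraction=1.0, missing_median=0)
    ds = generate_trial(design, seed=0)
    days = ds.responses.groupby("subject_id")["study_day"].nunique()
    assert (days == 182).all()  # 14 run-in + 168 treatment days


def test_completer_fraction_matches_design():
    design = TrialDesign(n_per_arm=(300, 300), missing_median=0)
    frac = []
    for seed in (1, 2):
        ds = generate_trial(design, seed=seed)
        last = ds.responses.groupby("subject_id")["study_day"].max()
        frac.append((last == 168).mean())
    assert abs(np.mean(frac) - 0.91) < 0.02


def test_missing_days_median_near_design():
    design = TrialDesign(n_per_arm=(150, 150))
    ds = generate_trial(design, seed=5)
    tot = compute_total_scores(ds)
    last = tot.groupby("subject_id")["study_day"].max()
    completers = last[last == 168].index
    ndays = tot[tot.subject_id.isin(completers)].groupby("subject_id")["study_day"].count()
    missing = 182 - ndays
    assert 3 <= missing.median() <= 7


def test_forced_baseline_gap_flagged():
    design = TrialDesign(n_per_arm=(10, 10), schedule="weekly", force_baseline_gap_subjects=2)
    ds = generate_trial(design, seed=9)
    _, excluded = derive_baselines(compute_total_scores(ds))
    assert len(excluded) == 2


def test_generated_data_pass_validators():
    # from_frame runs the validators internally; also check score ranges
    design = TrialDesign(n_per_arm=(12, 12), schedule="weekly")
    ds = generate_trial(design, seed=2)
    maxes = ds.responses["item_id"].map(ds.instrument.max_scores())
    assert (ds.responses["score"] <= maxes).all()
    assert (ds.responses["score"] >= 0).all()


def test_calibration_hits_target_mean():
    ref = reference_trial_params()
    mean, sd = baseline_theta_moments(ref, "FF/UMEC/VI")
    items = default_item_params()
    assert expected_total_under(items, mean, sd) == pytest.approx(12.2, abs=1e-6)
    # simulated draw lands in the published neighbourhood
    rng = np.random.default_rng(0)
    th = rng.normal(mean, sd, 20_000)
    sim_mean = grm.simulate_item_responses(th, items, rng).sum(axis=1).mean()
    assert 11.7 <= sim_mean <= 12.7


def test_calibration_other_target_and_boundary():
    items20 = calibrate_baseline(synthetic_item_layout(), target_mean=20.0)
    rng = np.random.default_rng(1)
    th = rng.normal(0.0, 1.1, 20_000)
    sim = grm.simulate_item_responses(th, items20, rng).sum(axis=1).mean()
    assert abs(sim - 20.0) < 0.5
    with pytest.raises(ValueError):
        calibrate_baseline(synthetic_item_layout(), target_mean=0.0)


def test_baseline_totals_near_published_summaries():
    design = TrialDesign(n_per_arm=(250, 250), schedule="weekly")
    ds = generate_trial(design, seed=4)
    base, _ = derive_baselines(compute_total_scores(ds))
    by_arm = base.groupby("arm")["baseline"].mean()
    assert by_arm["FF/UMEC/VI"] == pytest.approx(12.2, abs=0.8)
    assert by_arm["BUD/FOR"] == pytest.approx(12.9, abs=1.2)
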