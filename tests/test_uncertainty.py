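import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promirt.longitudinal import ArmFixedEffects, CovariateEffects, trajectory
from promirt.references import reference_trial_params
from promirt.uncertainty import (ArmParams, CovariateDesign, ParamUncertainty, SimConfig,
                                 TrialParams, cfb_by_interval, compute_cfb, derive_iw_df,
                                 point_params, run_uncertainty, sample_parameters,
                                 summarize_replicates)
from promirt import grm


def test_derive_iw_df_formula_and_sentinel():
    assert derive_iw_df(1.0, 0.1, dim=1) == pytest.approx(202.0)
    assert derive_iw_df(1.0, 0.1, dim=3) == pytest.approx(204.0)
    assert math.isinf(derive_iw_df(0.5, 0.0))
    with pytest.raises(ValueError):
        derive_iw_df(-1.0, 0.1)


def test_iw_sampled_cv_matches_relative_se():
    omega2, rel = 0.8, 0.2
    df = derive_iw_df(omega2, rel * omega2, dim=1)
    draws = stats.invwishart.rvs(df=df, scale=omega2 * (df - 2), size=100_000,
                                 random_state=np.random.default_rng(0))
    cv = draws.std() / draws.mean()
    assert cv == pytest.approx(rel, rel=0.10)


def _tiny_point():
    ref = reference_trial_params()
    return ref


def test_sample_parameters_point_and_reproducible():
    point = _tiny_point()
    unc = ParamUncertainty.zero(point)
    rng = np.random.default_rng(0)
    draw = sample_parameters(point, unc, rng)
    for arm in point.arms:
        assert draw.arms[arm].fixed == point.arms[arm].fixed
        assert np.allclose(draw.arms[arm].omega, point.arms[arm].omega)
    assert draw.sigma2 == point.sigma2
    # with uncertainty: identical seeds give identical draws
    from promirt.longitudinal import DEFAULT_CORR_PAIRS
    rse = {"FF/UMEC/VI|r_max": 0.11, "FF/UMEC/VI|omega2_theta0": 0.03, "sigma2": 0.02}
    unc2 = ParamUncertainty.from_rse(point, rse, DEFAULT_CORR_PAIRS)
    d1 = sample_parameters(point, unc2, np.random.default_rng(5))
    d2 = sample_parameters(point, unc2, np.random.default_rng(5))
    assert d1.arms["FF/UMEC/VI"].fixed == d2.arms["FF/UMEC/VI"].fixed
    assert d1.sigma2 == d2.sigma2


def test_sampled_fixed_effect_mean_is_unbiased():
    point = _tiny_point()
    rse = {"FF/UMEC/VI|r_max": 0.11}
    unc = ParamUncertainty.from_rse(point, rse, {})
    rng = np.random.default_rng(1)
    draws = np.array([sample_parameters(point, unc, rng).arms["FF/UMEC/VI"].fixed.r_max
                      for _ in range(10_000)])
    se = abs(-0.31) * 0.11
    assert draws.mean() == pytest.approx(-0.31, abs=3 * se / np.sqrt(10_000))


def test_cfb_by_interval_hand_example():
    days = np.array([-14, -7, -1, 14, 56, 100, 150])
    totals = np.tile([12.0, 12, 12, 10, 9, 8, 7], (3, 1))
    cfb = cfb_by_interval(totals, days)
    assert cfb[0] == pytest.approx(-2.0)   # interval 1 only holds day 14
    assert cfb[1] == pytest.approx(-3.0)   # day 56
    assert cfb[3] == pytest.approx(-4.0)   # day 100
    assert cfb[5] == pytest.approx(-5.0)   # day 150
    assert np.isnan(cfb[2]) and np.isnan(cfb[4])  # intervals without observed days
    const = np.tile([12.0] * 7, (3, 1))
    out = cfb_by_interval(const, days)
    assert np.allclose(out[~np.isnan(out)], 0.0)


def test_compute_cfb_excludes_baseline_free_subjects():
    rows = [("A", "X", d, 12) for d in range(-14, 0)] + [("A", "X", 10, 10)]
    rows += [("B", "X", 12, 9)]  # no baseline
    df = pd.DataFrame(rows, columns=["subject_id", "arm", "study_day", "rs_total"])
    out = compute_cfb(df)
    assert out.attrs["n_excluded"] == 1
    assert out["mean_cfb"].iloc[0] == pytest.approx(-2.0)


def test_summarize_replicates_percentiles():
    rows = [{"replicate": r, "arm": "A", "interval": "1-4", "mean_cfb": float(r + 1)}
            for r in range(100)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = summarize_replicates(pd.DataFrame(rows))
    assert s["mean"].iloc[0] == pytest.approx(50.5)
    assert s["lo"].iloc[0] == pytest.approx(3.475)
    assert s["hi"].iloc[0] == pytest.approx(97.525)
    degenerate = pd.DataFrame([{"replicate": r, "arm": "A", "interval": "1-4", "mean_cfb": 1.5}
                               for r in range(150)])
    s2 = summarize_replicates(degenerate)
    assert s2["hi"].iloc[0] - s2["lo"].iloc[0] == 0
    with pytest.raises(ValueError):
        summarize_replicates(pd.DataFrame(rows[:1]))


def _null_point():
    fx = ArmFixedEffects(theta0=0.3, t_prog=0.08, r_max=0.0, gamma=5.0, offset=0.0)
    omega = np.diag([0.5, 0.2, 1e-8, 1e-8])
    return TrialParams(arms={"A": ArmParams(fixed=fx, omega=omega)},
                       cov_effects=CovariateEffects(), sigma2=0.2)


def test_null_model_gives_zero_cfb(ers_items):
    cfg = SimConfig(n_replicates=3, n_subjects_per_arm=4000, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dist = run_uncertainty(_null_point(), None, ers_items, cfg)
    assert np.abs(dist["mean_cfb"]).max() < 0.25


def test_more_negative_offset_gives_more_negative_early_cfb(ers_items):
    out = {}
    for off in (-0.05, -0.5):
        fx = ArmFixedEffects(theta0=0.3, t_prog=0.08, r_max=-0.1, gamma=5.0, offset=off)
        point = TrialParams(arms={"A": ArmParams(fixed=fx, omega=np.diag([0.5, 0.2, 0.2, 0.1]))},
                            cov_effects=CovariateEffects(), sigma2=0.2)
        cfg = SimConfig(n_replicates=2, n_subjects_per_arm=3000, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dist = run_uncertainty(point, None, ers_items, cfg)
        out[off] = dist[dist["interval"] == "1-4"]["mean_cfb"].mean()
    assert out[-0.5] < out[-0.05] - 0.5


def test_typical_subject_latent_path_matches_trajectory(ers_items):
    from promirt.uncertainty import simulate_latent, _obs_days
    fx = ArmFixedEffects(theta0=0.3, t_prog=0.08, r_max=-0.3, gamma=6.0, offset=-0.2)
    point = TrialParams(arms={"A": ArmParams(fixed=fx, omega=np.zeros((4, 4)))},
                        cov_effects=CovariateEffects(), sigma2=0.0)
    cfg = SimConfig(n_replicates=1, n_subjects_per_arm=3)
    days = _obs_days(cfg)
    design = CovariateDesign(0.0, {2: 1.0})
    theta = simulate_latent(point, "A", 3, days, design, np.random.default_rng(0))
    t = np.where(days < 1, 0.0, days / 365.25)
    expect = trajectory(t, 0.3, 0.08, -0.3, 6.0, -0.2)
    assert np.allclose(theta, expect[None, :], atol=1e-4)  # PD jitter is 1e-12


def test_run_uncertainty_reproducible_and_bounded(ers_items):
    point = _tiny_point()
    cfg = SimConfig(n_replicates=4, n_subjects_per_arm=300, seed=21)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d1 = run_uncertainty(point, None, ers_items, cfg)
        d2 = run_uncertainty(point, None, ers_items, cfg)
    pd.testing.assert_frame_equal(d1, d2)
    assert d1["mean_cfb"].between(-40, 40).all()
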