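import warnings

import numpy as np
import pandas as pd
import pytest

from promirt import grm
from promirt.data import ItemDataset
from promirt.diagnostics import gof_summary, icf_fit_check, vpc
from promirt.ebe import map_theta
from promirt.icf import GradedResponseIRT
from promirt.longitudinal import LatentTrajectoryNLME, trajectory
from promirt.occasions import build_independent_occasions
from promirt.references import reference_trial_params
from promirt.uncertainty import point_params


@pytest.fixture(scope="module")
def truth_point(icf_fit_small, theta_small):
    # trajectory parameters actually fitted to the small trial, so VPC
    # self-simulation is from (approximately) the data-generating process
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = LatentTrajectoryNLME(compute_se=False, max_iter=250).fit(theta_small)
    return point_params(fit)


def test_vpc_degenerate_single_simulation(small_trial, icf_fit_small, truth_point):
    res = vpc(small_trial, icf_fit_small.item_params_, truth_point, n_sim=1, seed=0)
    assert (res.table["hi"] - res.table["lo"]).abs().max() < 1e-9


def test_vpc_flags_systematic_shift(small_trial, icf_fit_small, truth_point):
    shifted = ItemDataset(
        responses=small_trial.responses.assign(
            score=lambda d: np.minimum(d["score"] + 2,
                                       d["item_id"].map(small_trial.instrument.max_scores()))),
        covariates=small_trial.covariates,
        instrument=small_trial.instrument,
    )
    res = vpc(shifted, icf_fit_small.item_params_, truth_point, n_sim=60, seed=1)
    med = res.table[res.table["stat"] == 50.0]
    assert med["outside"].mean() > 0.9


def test_icf_check_self_consistency(ers_items):
    rng = np.random.default_rng(0)
    th = rng.normal(0, 1.1, 10_000)
    scores = grm.simulate_item_responses(th, ers_items, rng)
    th_hat, _ = map_theta(scores, ers_items)
    from promirt.occasions import OccasionData
    meta = pd.DataFrame({"pseudo_id": np.arange(len(th)), "subject_id": np.arange(len(th)),
                         "arm": "A", "study_day": 1, "smoking": 0, "region": 2,
                         "is_baseline": False, "interval": 1})
    occ = OccasionData(scores=scores, meta=meta,
                       item_ids=tuple(it.item_id for it in ers_items),
                       max_scores=tuple(it.max_score for it in ers_items))
    from promirt.icf import PopulationDist
    _, max_dev = icf_fit_check(occ, ers_items, theta_hat=th_hat,
                               pop=PopulationDist(0.0, 1.1 ** 2))
    assert max(max_dev.values()) < 0.05


def test_icf_check_detects_flipped_discrimination(ers_items):
    rng = np.random.default_rng(1)
    th = rng.normal(0, 1.1, 4000)
    scores = grm.simulate_item_responses(th, ers_items, rng)
    th_hat, _ = map_theta(scores, ers_items)
    # score the check against a corrupted parameter set: mirrored thresholds
    broken = list(ers_items)
    it = broken[3]
    broken[3] = grm.ItemParams(it.item_id, it.a, np.sort(-it.b))
    from promirt.occasions import OccasionData
    meta = pd.DataFrame({"pseudo_id": np.arange(len(th)), "subject_id": np.arange(len(th)),
                         "arm": "A", "study_day": 1, "smoking": 0, "region": 2,
                         "is_baseline": False, "interval": 1})
    occ = OccasionData(scores=scores, meta=meta,
                       item_ids=tuple(i.item_id for i in ers_items),
                       max_scores=tuple(i.max_score for i in ers_items))
    from promirt.icf import PopulationDist
    _, max_dev = icf_fit_check(occ, broken, theta_hat=th_hat,
                               pop=PopulationDist(0.0, 1.1 ** 2))
    assert max_dev[broken[3].item_id] > 0.3


def test_icf_check_single_bin(ers_items):
    rng = np.random.default_rng(2)
    th = rng.normal(0, 1, 200)
    scores = grm.simulate_item_responses(th, ers_items, rng)
    from promirt.occasions import OccasionData
    meta = pd.DataFrame({"pseudo_id": np.arange(200), "subject_id": np.arange(200),
                         "arm": "A", "study_day": 1, "smoking": 0, "region": 2,
                         "is_baseline": False, "interval": 1})
    occ = OccasionData(scores=scores, meta=meta,
                       item_ids=tuple(i.item_id for i in ers_items),
                       max_scores=tuple(i.max_score for i in ers_items))
    curves, _ = icf_fit_check(occ, ers_items, n_bins=1)
    assert curves.groupby(["item_id", "threshold"])["bin"].nunique().eq(1).all()


def _direct_obs(rng, n=60, sigma2=0.3):
    days = np.array([-7, -1, 7, 28, 56, 84, 126, 168])
    t = np.where(days < 1, 0.0, days / 365.25)
    rows = []
    for i in range(n):
        eta = rng.normal(0, [0.6, 0.4, 0.4, 0.3])
        f = trajectory(t, 0.3 + eta[0], 0.08 * np.exp(eta[1]), -0.3 + eta[2], 5.0, -0.2 + eta[3])
        y = f + rng.normal(0, np.sqrt(sigma2), t.size)
        rows.append(pd.DataFrame({"subject_id": f"S{i}", "arm": "A", "study_day": days,
                                  "theta_hat": y, "se_theta": 0.0}))
    return pd.concat(rows, ignore_index=True)


def test_gof_residuals_calibrated_under_true_model():
    rng = np.random.default_rng(3)
    obs = _direct_obs(rng, n=120)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = LatentTrajectoryNLME(corr_pairs={}, use_ebe_se=False, compute_se=False,
                                   max_iter=300).fit(obs)
    g = gof_summary(obs, fit)
    assert abs(g["iwres_mean"]) < 0.08
    assert 0.85 < g["iwres_sd"] < 1.1
    assert abs(g["pwres_mean"]) < 0.15
    assert 0.8 < g["pwres_sd"] < 1.2


def test_gof_zero_noise_residuals_vanish():
    rng = np.random.default_rng(4)
    days = np.array([-1, 7, 56, 168])
    rows = []
    for i in range(10):
        t = np.where(days < 1, 0.0, days / 365.25)
        y = trajectory(t, 0.3, 0.08, -0.3, 5.0, -0.2)
        rows.append(pd.DataFrame({"subject_id": f"S{i}", "arm": "A", "study_day": days,
                                  "theta_hat": y, "se_theta": 0.0}))
    obs = pd.concat(rows, ignore_index=True)
    fix = {"*|log_sd_theta0": np.log(1e-3), "*|log_sd_t_prog": np.log(1e-3),
           "*|log_sd_r_max": np.log(1e-3), "*|log_sd_offset": np.log(1e-3),
           "log_sd_resid": np.log(1e-2)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = LatentTrajectoryNLME(corr_pairs={}, fix=fix, use_ebe_se=False,
                                   compute_se=False, covariates=(), max_iter=400).fit(obs)
    g = gof_summary(obs, fit)
    assert np.abs(g["table"]["iwres"]).max() < 0.2


def test_gof_halved_sigma_inflates_iwres_by_sqrt2():
    # with the random effects pinned (tiny fixed IIV) the individual
    # predictions do not react to sigma, so the normalization scales exactly
    rng = np.random.default_rng(5)
    obs = _direct_obs(rng, n=60)
    fix = {"*|log_sd_theta0": np.log(1e-3), "*|log_sd_t_prog": np.log(1e-3),
           "*|log_sd_r_max": np.log(1e-3), "*|log_sd_offset": np.log(1e-3)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = LatentTrajectoryNLME(corr_pairs={}, fix=fix, use_ebe_se=False,
                                   compute_se=False, covariates=(), max_iter=300).fit(obs)
    base = gof_summary(obs, fit)["iwres_sd"]
    fit.sigma2_ = fit.sigma2_ / 2.0
    inflated = gof_summary(obs, fit)["iwres_sd"]
    assert inflated / base == pytest.approx(np.sqrt(2.0), rel=0.02)
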