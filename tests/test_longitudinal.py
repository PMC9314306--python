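import warnings

import numpy as np
import pandas as pd
import pytest

from promirt.longitudinal import (ETA_NAMES, ArmFixedEffects, CovariateEffects,
                                  LatentTrajectoryNLME, _f_and_jac, _inner_gn,
                                  individual_params, rse_summary, trajectory)
from promirt.references import load_longitudinal_reference, reference_rse_entries


def test_trajectory_baseline_and_halfway():
    assert trajectory(0.0, 0.4, 0.1, -0.3, 2.0, -0.2) == pytest.approx(0.4)
    # gamma = 1, t = T_prog: exp(-ln2) = 1/2
    val = trajectory(0.1, 0.4, 0.1, -0.3, 1.0, -0.2)
    assert val == pytest.approx(0.4 - 0.15 - 0.2, abs=1e-12)
    with pytest.raises(ValueError):
        trajectory(-0.1, 0.4, 0.1, -0.3, 1.0, -0.2)


def test_trajectory_at_published_typical_values():
    # steep Weibull has saturated by week 24: theta0 + R_max + offset
    val = trajectory(24 * 7 / 365.25, 0.33, 0.08, -0.31, 9.27, -0.27)
    assert val == pytest.approx(-0.25, abs=1e-3)


def test_trajectory_monotone_when_improving():
    t = np.linspace(1e-6, 0.5, 400)
    th = trajectory(t, 0.33, 0.08, -0.31, 9.27, 0.0)
    assert np.all(np.diff(th) <= 1e-12)


def test_individual_params_covariates_and_exponential_iiv():
    fx = ArmFixedEffects(theta0=0.33, t_prog=0.08, r_max=-0.31, gamma=9.27, offset=-0.27)
    ce = CovariateEffects(smoking=0.13, region={1: -0.64, 6: -0.98})
    smoker_r2 = individual_params(fx, {"smoking": 1, "region": 2}, ce, np.zeros(4))
    assert smoker_r2["theta0"] == pytest.approx(0.33 + 0.13)
    ns_r6 = individual_params(fx, {"smoking": 0, "region": 6}, ce, np.zeros(4))
    assert ns_r6["theta0"] == pytest.approx(0.33 - 0.98)
    doubled = individual_params(fx, {"smoking": 0, "region": 2}, ce,
                                np.array([0.0, np.log(2), 0.0, 0.0]))
    assert doubled["t_prog"] == pytest.approx(0.16)


def test_rse_summary_on_published_table():
    entries = reference_rse_entries()
    assert len(entries) == 29
    s = rse_summary(entries)
    assert s["median"] == pytest.approx(0.13)
    assert (s["min"], s["max"]) == (0.02, 0.75)
    assert rse_summary([0.1, 0.1, 0.1])["median"] == pytest.approx(0.1)
    assert rse_summary([0.42])["median"] == pytest.approx(0.42)


def _simulate_direct(n_per_arm, rng, sigma=0.3, days=None):
    days = days if days is not None else np.array([-14, -7, -1, 7, 14, 21, 28, 42, 56, 84, 126, 168])
    spec = {"A": (0.3, 0.08, -0.3, 6.0, -0.2), "B": (0.2, 0.10, -0.15, 4.0, -0.1)}
    sds = np.array([0.6, 0.45, 0.4, 0.35])
    rows = []
    t = np.where(days < 1, 0.0, days / 365.25)
    for arm, (th0, tp, rm, gam, off) in spec.items():
        for i in range(n_per_arm):
            eta = rng.normal(0, sds)
            f = trajectory(t, th0 + eta[0], tp * np.exp(eta[1]), rm + eta[2], gam, off + eta[3])
            y = f + rng.normal(0, sigma, size=t.size)
            for d, yy in zip(days, y):
                rows.append((f"{arm}{i}", arm, int(d), yy))
    return pd.DataFrame(rows, columns=["subject_id", "arm", "study_day", "theta_hat"])


def test_zero_noise_fixed_effects_recovered_exactly():
    rng = np.random.default_rng(0)
    days = np.array([-7, -1, 7, 14, 21, 28, 42, 56, 84, 126, 168])
    t = np.where(days < 1, 0.0, days / 365.25)
    rows = []
    for arm, (th0, tp, rm, gam, off) in {"A": (0.3, 0.08, -0.3, 6.0, -0.2)}.items():
        for i in range(8):
            y = trajectory(t, th0, tp, rm, gam, off)
            rows.append(pd.DataFrame({"subject_id": f"{arm}{i}", "arm": arm,
                                      "study_day": days, "theta_hat": y}))
    obs = pd.concat(rows)
    fix = {"*|log_sd_theta0": np.log(1e-3), "*|log_sd_t_prog": np.log(1e-3),
           "*|log_sd_r_max": np.log(1e-3), "*|log_sd_offset": np.log(1e-3),
           "log_sd_resid": np.log(1e-3)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = LatentTrajectoryNLME(corr_pairs={}, fix=fix, compute_se=False,
                                   covariates=(), max_iter=600).fit(obs)
    fx = fit.fixed_effects_["A"]
    assert fx.theta0 == pytest.approx(0.3, abs=1e-3)
    assert fx.t_prog == pytest.approx(0.08, abs=1e-3)
    assert fx.r_max == pytest.approx(-0.3, abs=2e-3)
    assert fx.offset == pytest.approx(-0.2, abs=2e-3)


def test_marginal_likelihood_matches_bruteforce_marginalization():
    """Exactness check: the closed-form-plus-quadrature marginal likelihood
    agrees with brute-force Monte-Carlo integration of all four random
    effects on a 10-subject toy set (the single-mode Laplace alternative
    fails this check by several units)."""
    from scipy.special import logsumexp

    rng = np.random.default_rng(5)
    obs = _simulate_direct(5, rng)  # 5 per arm -> 10 subjects
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = LatentTrajectoryNLME(corr_pairs={}, compute_se=False, max_iter=5).fit(obs)
    x = est.packed_
    layout, data = est.layout_, est._data
    ours = est._objective(x, data, layout)
    sigma2 = layout.sigma2(x)
    total = 0.0
    for arm, d in data.items():
        fx = layout.fixed(x, arm)
        omega, _, _ = layout.omega(x, arm)
        L = np.linalg.cholesky(omega)
        m = int(d.mask[0].sum())
        for i in range(len(d.y)):
            g = np.random.default_rng(10_000 + i + (0 if arm == "A" else 500))
            lls = []
            for _ in range(8):
                etas = g.standard_normal((150_000, 4)) @ L.T
                f_i, _ = _f_and_jac(np.tile(d.t[i], (len(etas), 1)),
                                    np.tile(d.pos[i], (len(etas), 1)),
                                    np.zeros(len(etas)), etas, fx)
                r = np.where(d.mask[i], d.y[i] - f_i, 0.0)
                lls.append(logsumexp(-0.5 * (r * r / sigma2).sum(axis=1)))
            total += logsumexp(lls) - np.log(8 * 150_000) \
                - 0.5 * m * np.log(2 * np.pi * sigma2)
    assert ours == pytest.approx(-2 * total, abs=0.5)


def test_loglik_invariant_to_subject_relabeling():
    rng = np.random.default_rng(8)
    obs = _simulate_direct(15, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = LatentTrajectoryNLME(corr_pairs={}, compute_se=False, max_iter=5).fit(obs)
    relabeled = obs.copy()
    mapping = {s: f"Z{j}" for j, s in enumerate(obs["subject_id"].unique()[::-1])}
    relabeled["subject_id"] = relabeled["subject_id"].map(mapping)
    from promirt.longitudinal import _prepare
    data2 = _prepare(relabeled, est.arms_)
    v1 = est._objective(est.packed_, est._data, est.layout_)
    v2 = est._objective(est.packed_, data2, est.layout_)
    assert v1 == pytest.approx(v2, abs=1e-8)


def test_fit_produces_psd_covariance_and_rses(nlme_small):
    assert nlme_small.se_, "standard errors expected"
    cov = nlme_small.cov_natural_
    assert np.allclose(cov, cov.T, atol=1e-8)
    assert np.linalg.eigvalsh(0.5 * (cov + cov.T)).min() > -1e-8
    s = nlme_small.summarize_rse()
    assert s["n"] >= 25
    assert 0 < s["median"] < 5


def test_rejects_correlation_with_progression_time():
    obs = _simulate_direct(3, np.random.default_rng(0))
    with pytest.raises(ValueError, match="progression-time"):
        LatentTrajectoryNLME(corr_pairs={"A": (("t_prog", "offset"),)}).fit(obs)


def test_missing_required_columns_rejected():
    with pytest.raises(ValueError, match="missing column"):
        LatentTrajectoryNLME().fit(pd.DataFrame({"subject_id": [1], "arm": ["A"]}))
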