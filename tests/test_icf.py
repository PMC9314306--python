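import numpy as np
import pandas as pd
import pytest

from promirt import grm
from promirt.icf import GradedResponseIRT, PopulationDist, fit_icf, marginal_loglik
from promirt.occasions import OccasionData, build_independent_occasions
from sklearn.base import clone


def make_occ(scores, is_baseline, item_ids, max_scores):
    n = len(scores)
    meta = pd.DataFrame({
        "pseudo_id": np.arange(n),
        "subject_id": [f"S{i}" for i in range(n)],
        "arm": "A", "study_day": np.where(is_baseline, -3, 10),
        "smoking": 0, "region": 2,
        "is_baseline": np.asarray(is_baseline, dtype=bool),
        "interval": np.where(is_baseline, 0, 1),
    })
    return OccasionData(scores=np.asarray(scores, dtype=np.int64), meta=meta,
                        item_ids=tuple(item_ids), max_scores=tuple(max_scores))


def simulate_occasions(items, n_base, n_post, mu, sd, rng):
    th = np.concatenate([rng.normal(0, 1, n_base), rng.normal(mu, sd, n_post)])
    scores = grm.simulate_item_responses(th, items, rng)
    is_base = np.arange(n_base + n_post) < n_base
    return make_occ(scores, is_base, [it.item_id for it in items],
                    [it.max_score for it in items])


def test_build_occasions_counts_and_classes(small_trial):
    occ = build_independent_occasions(small_trial)
    days = small_trial.responses.groupby(["subject_id", "study_day"]).ngroups
    assert occ.n_occasions == days
    assert set(occ.meta.loc[occ.is_baseline, "study_day"]) <= set(range(-14, 0))
    # mapping inverts exactly: pseudo ids are unique and carry the original keys
    assert occ.meta["pseudo_id"].is_unique
    back = occ.meta.set_index("pseudo_id")[["subject_id", "study_day"]]
    assert len(back.drop_duplicates()) == occ.n_occasions


def test_two_subject_three_day_counting(small_trial):
    sub = small_trial.covariates["subject_id"].iloc[:2]
    resp = small_trial.responses
    resp = resp[resp["subject_id"].isin(sub)]
    days = resp.groupby("subject_id")["study_day"].unique().apply(lambda d: d[:3])
    keep = pd.concat([resp[(resp.subject_id == s) & (resp.study_day.isin(d))]
                      for s, d in days.items()])
    from promirt.data import ItemDataset
    ds = ItemDataset(responses=keep.reset_index(drop=True),
                     covariates=small_trial.covariates[small_trial.covariates.subject_id.isin(sub)],
                     instrument=small_trial.instrument)
    occ = build_independent_occasions(ds)
    assert occ.n_occasions == 6


def test_marginal_loglik_symmetric_binary_item():
    # one occasion, one 2-category item with a=1, b=0, theta ~ N(0,1):
    # P(y=1) = E[expit(theta)] = 1/2 by symmetry
    items = [grm.ItemParams(1, 1.0, np.array([0.0]))]
    occ = make_occ([[1]], [True], [1], [1])
    ll = marginal_loglik(items, PopulationDist(0.0, 1.0), occ)
    assert ll == pytest.approx(np.log(0.5), abs=1e-9)


def test_marginal_loglik_matches_trapezoid_oracle(toy_items):
    rng = np.random.default_rng(0)
    occ = simulate_occasions(toy_items, 6, 6, 0.35, 1.2, rng)
    pop = PopulationDist(0.35, 1.44)
    arrays = grm.pack_items(toy_items)
    th = np.arange(-10, 10.0005, 0.001)
    ll_bf = 0.0
    for i in range(occ.n_occasions):
        lp = grm.pattern_loglik(np.tile(occ.scores[i], (th.size, 1)), arrays, th)
        m, s = (0.0, 1.0) if occ.is_baseline[i] else (0.35, 1.2)
        dens = np.exp(lp - (th - m) ** 2 / (2 * s * s)) / np.sqrt(2 * np.pi * s * s)
        ll_bf += np.log(np.trapezoid(dens, th))
    ll = marginal_loglik(toy_items, pop, occ, scheme="agh", n_nodes=15)
    assert ll == pytest.approx(ll_bf, abs=1e-6)


def test_loglik_invariant_to_occasion_order(toy_items):
    rng = np.random.default_rng(1)
    occ = simulate_occasions(toy_items, 10, 10, -0.2, 1.1, rng)
    pop = PopulationDist(-0.2, 1.21)
    perm = rng.permutation(occ.n_occasions)
    occ2 = make_occ(occ.scores[perm], occ.is_baseline[perm], occ.item_ids, occ.max_scores)
    assert marginal_loglik(toy_items, pop, occ) == pytest.approx(
        marginal_loglik(toy_items, pop, occ2), abs=1e-9)


def test_noninformative_occasion_shifts_loglik_by_constant():
    # an item with near-zero discrimination is equiprobable at every theta,
    # so adding such an occasion adds a constant independent of the
    # population distribution
    items = [grm.ItemParams(1, 1e-6, np.array([0.0]))]
    occ1 = make_occ([[1]], [False], [1], [1])
    d1 = marginal_loglik(items, PopulationDist(0.0, 1.0), occ1)
    d2 = marginal_loglik(items, PopulationDist(1.5, 0.25), occ1)
    assert d1 == pytest.approx(np.log(0.5), abs=1e-5)
    assert d1 == pytest.approx(d2, abs=1e-5)


def test_quadrature_node_convergence(toy_items):
    rng = np.random.default_rng(2)
    occ = simulate_occasions(toy_items, 75, 75, -0.3, 1.2, rng)
    est = GradedResponseIRT(n_quadrature=15, compute_se=False, max_iter=300).fit(occ)
    lls = [marginal_loglik(est.item_params_, est.pop_, occ, scheme="agh", n_nodes=q)
           for q in (7, 15, 31)]
    assert abs(lls[1] - lls[2]) < 1e-4
    assert abs(lls[0] - lls[1]) < 0.05  # few-node counts are visibly coarser


def test_parameter_recovery_with_standard_errors():
    rng = np.random.default_rng(42)
    items = [
        grm.ItemParams(1, 0.9, np.array([-1.2, 0.0, 1.1])),
        grm.ItemParams(2, 1.4, np.array([-0.5, 0.6])),
        grm.ItemParams(3, 2.0, np.array([-0.8, 0.1, 0.9, 1.7])),
        grm.ItemParams(4, 1.1, np.array([0.2, 1.3])),
        grm.ItemParams(5, 1.7, np.array([-1.5, -0.4, 0.7])),
        grm.ItemParams(6, 1.3, np.array([-0.2, 0.9, 2.0])),
    ]
    occ = simulate_occasions(items, 2500, 2500, -0.4, 1.25, rng)
    res = fit_icf(occ, n_quadrature=15, compute_se=True, max_iter=400)
    assert res.converged
    hits = 0
    for it_true, it_fit in zip(items, res.item_params):
        se = res.se[f"a[{it_true.item_id}]"]
        hits += abs(it_fit.a - it_true.a) <= 2 * se
    assert hits >= round(0.9 * len(items)) - 1  # >= 90% of discriminations within 2 SE
    assert res.pop_dist.mu == pytest.approx(-0.4, abs=0.15)
    assert res.pop_dist.omega2 == pytest.approx(1.25 ** 2, rel=0.2)


def test_self_consistent_population_estimates(toy_items):
    # both classes truly N(0,1): the post-baseline class should recover it
    rng = np.random.default_rng(7)
    occ = simulate_occasions(toy_items, 1500, 1500, 0.0, 1.0, rng)
    est = GradedResponseIRT(n_quadrature=15, compute_se=False, max_iter=300).fit(occ)
    assert est.pop_mu_[0] == pytest.approx(0.0, abs=0.12)
    assert est.pop_omega2_[0] == pytest.approx(1.0, abs=0.25)


def test_degenerate_item_warns_at_boundary(toy_items):
    rng = np.random.default_rng(3)
    occ = simulate_occasions(toy_items, 150, 150, 0.0, 1.0, rng)
    sc = occ.scores.copy()
    sc[:, 1] = 0  # everyone gives the same answer on item 2
    occ2 = make_occ(sc, occ.is_baseline.copy(), occ.item_ids, occ.max_scores)
    with pytest.warns(UserWarning, match="degenerate"):
        GradedResponseIRT(n_quadrature=9, compute_se=False, max_iter=150).fit(occ2)


def test_sklearn_estimator_contract(icf_fit_small):
    params = icf_fit_small.get_params()
    assert params["n_quadrature"] == 15
    fresh = clone(icf_fit_small)
    assert not hasattr(fresh, "item_params_")
    fresh.set_params(n_quadrature=7)
    assert fresh.get_params()["n_quadrature"] == 7
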