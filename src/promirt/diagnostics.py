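"""Internal model evaluation: visual predictive checks, non-parametric
item-characteristic checks, and residual (goodness-of-fit) summaries.

All diagnostics emit tabular results; rendering is left to the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import grm
from .data import ItemDataset, compute_total_scores
from .ebe import map_theta
from .longitudinal import LatentTrajectoryNLME, _f_and_jac, _prepare
from .occasions import OccasionData, build_independent_occasions
from .uncertainty import TrialParams

PCTS = (2.5, 50.0, 97.5)


@dataclass
class VpcResult:
    """Observed percentiles per time bin with simulation-based 95% bands."""

    table: pd.DataFrame  # arm, bin, stat, observed, lo, hi, n_obs, outside
    n_sim: int

    @property
    def fraction_inside(self) -> float:
        return float(1.0 - self.table["outside"].mean())


def _week_bin(day):
    day = np.asarray(day)
    return np.where(day < 1, 0, (day + 6) // 7).astype(int)


def vpc(dataset: ItemDataset, item_params, traj_params: TrialParams,
        n_sim: int = 500, seed: int = 0, min_bin: int = 1) -> VpcResult:
    """Visual predictive check of the total score binned by study week.

    Simulates ``n_sim`` replicates of the observed design (same subjects,
    covariates and diary days) at the point estimates — no parameter
    uncertainty — and compares observed 2.5/50/97.5 percentiles per
    (arm, week) bin against the 95% interval of each percentile across
    simulations.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    totals = compute_total_scores(dataset)
    totals = totals.merge(dataset.covariates[["subject_id", "smoking", "region"]], on="subject_id")
    totals["bin"] = _week_bin(totals["study_day"])
    totals = totals.sort_values(["arm", "subject_id", "study_day"], kind="stable").reset_index(drop=True)

    rng = np.random.default_rng(seed)
    rows = []
    for arm, g in totals.groupby("arm", sort=True):
        if arm not in traj_params.arms:
            raise KeyError(f"no trajectory parameters for arm {arm!r}")
        ap = traj_params.arms[arm]
        subj, subj_idx = np.unique(g["subject_id"], return_inverse=True)
        n_subj = subj.size
        day = g["study_day"].to_numpy()
        t = np.where(day < 1, 0.0, day / 365.25)
        pos = t > 0
        first = pd.DataFrame({"subject_id": g["subject_id"], "smoking": g["smoking"],
                              "region": g["region"]}).drop_duplicates("subject_id")
        shift = traj_params.cov_effects.shift(first["smoking"].to_numpy(), first["region"].to_numpy())
        bins = g["bin"].to_numpy()
        ubins = np.unique(bins)
        bin_cols = {b: np.flatnonzero(bins == b) for b in ubins}
        obs_tot = g["rs_total"].to_numpy()
        obs_pct = {b: np.percentile(obs_tot[c], PCTS) for b, c in bin_cols.items() if c.size >= min_bin}
        dropped = [b for b, c in bin_cols.items() if c.size < min_bin]
        if dropped:
            warnings.warn(f"{arm}: dropping empty/thin bins {dropped}", stacklevel=2)

        L = np.linalg.cholesky(ap.omega + 1e-12 * np.eye(4))
        tt = np.where(pos, t, 1.0)
        sim_pct = np.empty((n_sim, len(obs_pct), len(PCTS)))
        keys = sorted(obs_pct)
        fx = np.array([ap.fixed.theta0, ap.fixed.t_prog, ap.fixed.r_max, ap.fixed.gamma,
                       ap.fixed.offset])
        for s in range(n_sim):
            eta = rng.standard_normal((n_subj, 4)) @ L.T
            th0 = fx[0] + shift + eta[:, 0]
            tp = fx[1] * np.exp(eta[:, 1])
            logu = fx[3] * (np.log(np.log(2.0) * tt) - np.log(tp)[subj_idx])
            S = np.where(pos, 1.0 - np.exp(-np.exp(np.minimum(logu, 30.0))), 0.0)
            theta = th0[subj_idx] + (fx[2] + eta[:, 2])[subj_idx] * S \
                + (fx[4] + eta[:, 3])[subj_idx] * pos
            theta = theta + rng.normal(0.0, np.sqrt(traj_params.sigma2), size=theta.shape)
            tot = grm.simulate_item_responses(theta, item_params, rng).sum(axis=1)
            for bi, b in enumerate(keys):
                sim_pct[s, bi] = np.percentile(tot[bin_cols[b]], PCTS)
        lo = np.percentile(sim_pct, 2.5, axis=0)
        hi = np.percentile(sim_pct, 97.5, axis=0)
        for bi, b in enumerate(keys):
            for pi, p in enumerate(PCTS):
                o = obs_pct[b][pi]
                rows.append({"arm": arm, "bin": int(b), "stat": p, "observed": o,
                             "lo": lo[bi, pi], "hi": hi[bi, pi],
                             "n_obs": int(bin_cols[b].size),
                             "outside": bool(o < lo[bi, pi] or o > hi[bi, pi])})
    return VpcResult(table=pd.DataFrame(rows), n_sim=n_sim)


def _binned_fractions(scores, theta_hat, item_params, n_bins, min_bin):
    order = np.argsort(theta_hat, kind="stable")
    n = theta_hat.size
    n_bins = max(1, min(n_bins, n // max(min_bin, 1)) or 1)
    edges = np.array_split(order, n_bins)
    merged = []
    for grp in edges:  # merge any undersized bin with its neighbour
        if merged and grp.size < min_bin:
            merged[-1] = np.concatenate([merged[-1], grp])
        else:
            merged.append(grp)
    out = {}
    mids = []
    for b, grp in enumerate(merged):
        mids.append(float(theta_hat[grp].mean()))
        for j, it in enumerate(item_params):
            y = scores[grp, j]
            for k in range(1, it.max_score + 1):
                out[(it.item_id, k, b)] = float((y >= k).mean())
    return out, mids, [g.size for g in merged]


def icf_fit_check(occasions, item_params, theta_hat=None, pop=None, n_bins: int = 10,
                  min_bin: int = 10, n_sim: int = 10, seed: int = 0):
    """Non-parametric item-characteristic check.

    Occasions are binned by their latent estimate (equal counts); per item
    and score threshold k the observed fraction scoring >= k in a bin is
    compared with two references: the model curve P(y >= k) at the bin-mean
    latent estimate, and a parametric-bootstrap expectation that simulates
    latent values from the fitted occasion-class distributions (``pop``,
    a :class:`~promirt.icf.PopulationDist` for the post-baseline class;
    baseline occasions use the N(0, 1) anchor), draws responses and pushes
    them through the same estimate-then-bin pipeline.  Binning on a noisy
    latent estimate flattens the curves at the extremes, so the bootstrap
    is the reference used for the deviation summary.
    Returns (curves frame, per-item max absolute deviation vs bootstrap).
    """
    occ = occasions if isinstance(occasions, OccasionData) else build_independent_occasions(occasions)
    if theta_hat is None:
        theta_hat, _ = map_theta(occ.scores, item_params)
    theta_hat = np.asarray(theta_hat, dtype=float)
    obs_frac, mids, sizes = _binned_fractions(occ.scores, theta_hat, item_params, n_bins, min_bin)

    rng = np.random.default_rng(seed)
    if pop is not None:
        mean = np.where(occ.is_baseline, 0.0, pop.mu)
        sd = np.where(occ.is_baseline, 1.0, np.sqrt(pop.omega2))
    else:
        # plug-in fallback: centre the bootstrap on the latent estimates
        mean, sd = theta_hat, 0.0
    boot = {key: 0.0 for key in obs_frac}
    for _ in range(n_sim):
        th_sim = mean + sd * rng.standard_normal(theta_hat.size)
        sim_scores = grm.simulate_item_responses(th_sim, item_params, rng)
        sim_hat, _ = map_theta(sim_scores, item_params)
        sim_frac, _, _ = _binned_fractions(sim_scores, sim_hat, item_params, n_bins, min_bin)
        for key in boot:
            boot[key] += sim_frac.get(key, np.nan) / n_sim

    rows = []
    max_dev = {}
    for it in item_params:
        dev = 0.0
        for k in range(1, it.max_score + 1):
            for b, mid in enumerate(mids):
                key = (it.item_id, k, b)
                if key not in obs_frac:
                    continue
                o = obs_frac[key]
                e = boot[key]
                dev = max(dev, abs(o - e))
                rows.append({"item_id": it.item_id, "threshold": k, "bin": b,
                             "theta_mid": mid, "n": sizes[b], "observed": o,
                             "expected": e,
                             "model": float(grm.prob_at_least(mid, it.a, it.b[k - 1]))})
        max_dev[it.item_id] = dev
    return pd.DataFrame(rows), max_dev


def gof_summary(theta_obs: pd.DataFrame, fit: LatentTrajectoryNLME) -> dict:
    """Population (PWRES) and individual (IWRES) normalized residuals.

    Under a correct model both have mean near 0; IWRES has SD near 1, and
    PWRES (normalized by the linearized marginal SD) close to 1.
    """
    data = _prepare(theta_obs, fit.arms_, thin_days=fit.thin_days)
    eb = fit.individual_effects(theta_obs)
    frames = []
    for arm, d in data.items():
        fx = np.array([fit.fixed_effects_[arm].theta0, fit.fixed_effects_[arm].t_prog,
                       fit.fixed_effects_[arm].r_max, fit.fixed_effects_[arm].gamma,
                       fit.fixed_effects_[arm].offset])
        omega = fit.iiv_[arm]["omega"]
        shift = fit.covariate_effects_.shift(d.smoke, d.region)
        v = fit.sigma2_ + (d.se2 if fit.use_ebe_se else 0.0)
        f0, J0 = _f_and_jac(d.t, d.pos, shift, np.zeros((len(d.y), 4)), fx)
        var_marg = np.einsum("nmp,pq,nmq->nm", J0, omega, J0) + v
        pwres = np.where(d.mask, (d.y - f0) / np.sqrt(var_marg), np.nan)
        eta = (eb[eb["arm"] == arm].set_index("subject_id")
               .loc[list(d.subjects), [f"eta_{e}" for e in ("theta0", "t_prog", "r_max", "offset")]]
               .to_numpy())
        fi, _ = _f_and_jac(d.t, d.pos, shift, eta, fx)
        iwres = np.where(d.mask, (d.y - fi) / np.sqrt(v), np.nan)
        for i, sid in enumerate(d.subjects):
            m = d.mask[i]
            frames.append(pd.DataFrame({
                "subject_id": sid, "arm": arm, "t_years": d.t[i, m],
                "pwres": pwres[i, m], "iwres": iwres[i, m],
            }))
    table = pd.concat(frames, ignore_index=True)
    return {
        "table": table,
        "pwres_mean": float(np.nanmean(table["pwres"])),
        "pwres_sd": float(np.nanstd(table["pwres"])),
        "iwres_mean": float(np.nanmean(table["iwres"])),
        "iwres_sd": float(np.nanstd(table["iwres"])),
    }
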