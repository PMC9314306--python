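"""Trial simulation with parameter uncertainty.

The precision of the change-from-baseline (CFB) endpoint is obtained by
replicated stochastic simulation: each replicate draws one realization of
the longitudinal parameters (fixed effects multivariate-normal on the
estimation scale, random-effect covariance blocks inverse-Wishart with
degrees of freedom matched to the reported standard errors), simulates a
large virtual trial on the latent scale, converts latent states to item
responses (or to expected totals), and records the arm-level mean CFB per
4-week interval.  The median and 2.5th/97.5th percentiles across
replicates represent the mean and 95% CI of the endpoint.  With many
virtual subjects the spread across replicates is dominated by parameter
uncertainty, which is the design intent.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import grm
from .data import BASELINE_WINDOW, assign_interval, INTERVAL_LABELS
from .longitudinal import (ETA_NAMES, ArmFixedEffects, CovariateEffects,
                           LatentTrajectoryNLME, trajectory)

logger = logging.getLogger(__name__)

#: Fixed-effect fields per arm and their estimation-scale transform.
_FIXED_FIELDS = (("theta0", "id"), ("t_prog", "log"), ("r_max", "id"),
                 ("gamma", "log"), ("offset", "id"))


@dataclass
class ArmParams:
    fixed: ArmFixedEffects
    omega: np.ndarray  # 4x4 covariance of (theta0, t_prog, r_max, offset) effects


@dataclass
class TrialParams:
    """One complete parameter set for trial simulation."""

    arms: dict
    cov_effects: CovariateEffects
    sigma2: float


def point_params(fit: LatentTrajectoryNLME) -> TrialParams:
    return TrialParams(
        arms={a: ArmParams(fixed=fit.fixed_effects_[a], omega=fit.iiv_[a]["omega"].copy())
              for a in fit.arms_},
        cov_effects=fit.covariate_effects_,
        sigma2=fit.sigma2_,
    )


@dataclass
class SimConfig:
    n_replicates: int = 200
    n_subjects_per_arm: int = 2000
    horizon_weeks: int = 24
    obs_interval_days: int = 7
    baseline_days: tuple = (-14, -7, -1)
    response: str = "items"      # or "expected" (latent -> expected-total mapping)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_replicates, self.n_subjects_per_arm, self.horizon_weeks) < 1:
            raise ValueError("simulation sizes must be positive")


@dataclass
class CovariateDesign:
    smoker_fraction: float = 0.44
    region_fractions: dict = field(default_factory=lambda: {1: 0.21, 2: 0.24, 3: 0.21, 4: 0.18, 5: 0.06, 6: 0.10})

    def sample(self, n, rng):
        smoking = (rng.random(n) < self.smoker_fraction).astype(int)
        keys = sorted(self.region_fractions)
        p = np.array([self.region_fractions[k] for k in keys], dtype=float)
        region = rng.choice(keys, size=n, p=p / p.sum())
        return smoking, region


def derive_iw_df(omega2_hat: float, se_omega2: float, dim: int = 1) -> float:
    """Inverse-Wishart degrees of freedom matched to a variance SE.

    Chosen so the relative spread of the sampled variance matches
    se/omega2: df = 2 (omega2/se)^2 + 1 + dim.  A zero SE yields an
    infinite-df sentinel (the variance is held fixed).
    """
    if omega2_hat <= 0:
        raise ValueError("omega2 must be positive")
    if se_omega2 < 0:
        raise ValueError("se must be non-negative")
    if se_omega2 == 0:
        return math.inf
    return 2.0 * (omega2_hat / se_omega2) ** 2 + 1.0 + dim


def _blocks_from_pairs(pairs) -> list:
    """Connected components of the correlation graph over the 4 effects."""
    parent = list(range(4))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for p, q in pairs:
        i, j = find(ETA_NAMES.index(p)), find(ETA_NAMES.index(q))
        parent[i] = j
    comp = {}
    for i in range(4):
        comp.setdefault(find(i), []).append(i)
    return sorted(comp.values())


@dataclass
class ParamUncertainty:
    """Sampling distribution of the estimates for simulation replicates."""

    fixed_names: list          # "{arm}|{field}" then covariate names
    fixed_mean: np.ndarray     # on the estimation scale (logs for t_prog, gamma)
    fixed_cov: np.ndarray
    blocks: list               # (arm, indices, omega_block_hat, df)
    sigma2_df: float

    @classmethod
    def zero(cls, point: TrialParams) -> "ParamUncertainty":
        names, mean = _fixed_vector(point)
        k = len(names)
        blocks = [(arm, [0, 1, 2, 3], point.arms[arm].omega.copy(), math.inf)
                  for arm in point.arms]
        return cls(fixed_names=names, fixed_mean=mean, fixed_cov=np.zeros((k, k)),
                   blocks=blocks, sigma2_df=math.inf)

    @classmethod
    def from_rse(cls, point: TrialParams, rse: dict, corr_pairs: dict) -> "ParamUncertainty":
        """Build from relative standard errors (variance rows on the SD scale).

        ``rse`` maps "{arm}|{field}", covariate names, "{arm}|omega2_{eff}"
        and "sigma2" to RSE values; unlisted entries get zero uncertainty.
        """
        names, mean = _fixed_vector(point)
        se = np.zeros(len(names))
        for i, (name, kind) in enumerate(zip(names, _fixed_kinds(point))):
            r = rse.get(name, 0.0) or 0.0
            if kind == "log":
                se[i] = r  # RSE of a log-normal quantity ~ SD of its log
            else:
                natural = mean[i]
                se[i] = abs(natural) * r
        blocks = []
        for arm, ap in point.arms.items():
            for idx in _blocks_from_pairs(corr_pairs.get(arm, ())):
                dfs = []
                for i in idx:
                    om2 = ap.omega[i, i]
                    r = rse.get(f"{arm}|omega2_{ETA_NAMES[i]}", 0.0) or 0.0
                    se_om2 = 2.0 * om2 * r  # SD-scale RSE -> variance-scale SE
                    dfs.append(derive_iw_df(om2, se_om2, dim=len(idx)))
                blocks.append((arm, idx, ap.omega[np.ix_(idx, idx)], min(dfs)))
        r_sig = rse.get("sigma2", 0.0) or 0.0
        sigma2_df = derive_iw_df(point.sigma2, 2.0 * point.sigma2 * r_sig, dim=1)
        return cls(fixed_names=names, fixed_mean=mean, fixed_cov=np.diag(se ** 2),
                   blocks=blocks, sigma2_df=sigma2_df)

    @classmethod
    def from_fit(cls, fit: LatentTrajectoryNLME) -> "ParamUncertainty":
        """Asymptotic uncertainty taken from a fitted longitudinal model."""
        if not getattr(fit, "se_", None):
            raise ValueError("fit carries no covariance matrix (compute_se=False?)")
        point = point_params(fit)
        names, mean = _fixed_vector(point)
        layout = fit.layout_
        packed_names = []
        for arm in fit.arms_:
            packed_names += [f"{arm}|theta0", f"{arm}|log_t_prog", f"{arm}|r_max",
                             f"{arm}|log_gamma", f"{arm}|offset"]
        if layout.use_smoking:
            packed_names.append("smoking")
        packed_names += [f"region[{k}]" for k in layout.regions]
        idx = [layout.index[n] for n in packed_names]
        cov = fit.cov_packed_[np.ix_(idx, idx)]
        blocks = []
        for arm in fit.arms_:
            ap = point.arms[arm]
            for bidx in _blocks_from_pairs(layout.corr_pairs[arm]):
                dfs = []
                for i in bidx:
                    om2 = ap.omega[i, i]
                    se_om2 = 2.0 * om2 * fit.rse_.get(f"{arm}|omega2_{ETA_NAMES[i]}", 0.0)
                    dfs.append(derive_iw_df(om2, se_om2, dim=len(bidx)))
                blocks.append((arm, bidx, ap.omega[np.ix_(bidx, bidx)], min(dfs)))
        sig_rse = fit.rse_.get("sigma2", 0.0)
        sigma2_df = derive_iw_df(fit.sigma2_, 2.0 * fit.sigma2_ * sig_rse, dim=1)
        return cls(fixed_names=names, fixed_mean=mean, fixed_cov=cov, blocks=blocks,
                   sigma2_df=sigma2_df)


def _fixed_kinds(point: TrialParams):
    kinds = []
    for _ in point.arms:
        kinds += [k for _, k in _FIXED_FIELDS]
    kinds += ["id"]  # smoking
    kinds += ["id"] * len(point.cov_effects.region)
    return kinds


def _fixed_vector(point: TrialParams):
    names, mean = [], []
    for arm, ap in point.arms.items():
        for f_, kind in _FIXED_FIELDS:
            v = getattr(ap.fixed, f_)
            names.append(f"{arm}|{f_}")
            mean.append(np.log(v) if kind == "log" else v)
    names.append("smoking")
    mean.append(point.cov_effects.smoking)
    for k in sorted(point.cov_effects.region):
        names.append(f"region[{k}]")
        mean.append(point.cov_effects.region[k])
    return names, np.asarray(mean, dtype=float)


def _unpack_fixed(point: TrialParams, values) -> tuple[dict, CovariateEffects]:
    arms = {}
    pos = 0
    for arm in point.arms:
        vals = {}
        for f_, kind in _FIXED_FIELDS:
            v = values[pos]
            vals[f_] = float(np.exp(v)) if kind == "log" else float(v)
            pos += 1
        arms[arm] = vals
    smoking = float(values[pos]); pos += 1
    region = {}
    for k in sorted(point.cov_effects.region):
        region[k] = float(values[pos]); pos += 1
    return arms, CovariateEffects(smoking=smoking, region=region)


def sample_parameters(point: TrialParams, unc: ParamUncertainty, rng: np.random.Generator,
                      max_tries: int = 100) -> TrialParams:
    """One joint draw of fixed effects, IIV covariance blocks and sigma2."""
    if np.any(unc.fixed_cov):
        z = rng.multivariate_normal(unc.fixed_mean, unc.fixed_cov, method="svd")
        arm_fixed, cov_eff = _unpack_fixed(point, z)
    else:
        arm_fixed = {arm: {f_: getattr(ap.fixed, f_) for f_, _ in _FIXED_FIELDS}
                     for arm, ap in point.arms.items()}
        cov_eff = point.cov_effects
    arms = {}
    for arm, ap in point.arms.items():
        omega = np.zeros((4, 4))
        for barm, idx, block, df in unc.blocks:
            if barm != arm:
                continue
            p = len(idx)
            if not math.isfinite(df):
                draw = block
            else:
                scale = block * (df - p - 1)
                for _ in range(max_tries):
                    draw = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
                    draw = np.atleast_2d(draw)
                    if np.linalg.eigvalsh(draw).min() > 0:
                        break
                else:  # pragma: no cover - IW draws are PD by construction
                    logger.warning("replicate IIV block stayed non-PD; using point estimate")
                    draw = block
            omega[np.ix_(idx, idx)] = draw
        arms[arm] = ArmParams(fixed=ArmFixedEffects(**arm_fixed[arm]), omega=omega)
    if math.isfinite(unc.sigma2_df):
        df = unc.sigma2_df
        sigma2 = float(stats.invwishart.rvs(df=df, scale=point.sigma2 * (df - 2), random_state=rng))
    else:
        sigma2 = point.sigma2
    return TrialParams(arms=arms, cov_effects=cov_eff, sigma2=sigma2)


# ---------------------------------------------------------------------------
# Virtual-trial simulation
# ---------------------------------------------------------------------------

def _obs_days(config: SimConfig) -> np.ndarray:
    treat = np.arange(config.obs_interval_days, config.horizon_weeks * 7 + 1,
                      config.obs_interval_days)
    return np.concatenate([np.asarray(config.baseline_days, dtype=int), treat])


def simulate_latent(params: TrialParams, arm: str, n: int, days: np.ndarray,
                    design: CovariateDesign, rng: np.random.Generator) -> np.ndarray:
    """Latent states (n, n_days) for one arm's virtual subjects."""
    ap = params.arms[arm]
    smoking, region = design.sample(n, rng)
    shift = params.cov_effects.shift(smoking, region)
    L = np.linalg.cholesky(ap.omega + 1e-12 * np.eye(4))
    eta = rng.standard_normal((n, 4)) @ L.T
    t = np.where(days < 1, 0.0, days / 365.25)
    th0 = ap.fixed.theta0 + shift + eta[:, 0]
    tp = ap.fixed.t_prog * np.exp(eta[:, 1])
    rm = ap.fixed.r_max + eta[:, 2]
    off = ap.fixed.offset + eta[:, 3]
    pos = t > 0
    tt = np.where(pos, t, 1.0)
    logu = ap.fixed.gamma * (np.log(np.log(2.0) * tt) - np.log(tp)[:, None])
    S = np.where(pos, 1.0 - np.exp(-np.exp(np.minimum(logu, 30.0))), 0.0)
    theta = th0[:, None] + rm[:, None] * S + off[:, None] * pos
    theta += rng.normal(0.0, np.sqrt(params.sigma2), size=theta.shape)
    return theta


def _totals_from_latent(theta: np.ndarray, item_params, response: str, rng,
                        score_map: grm.TotalScoreMap | None = None) -> np.ndarray:
    if response == "items":
        flat = theta.ravel()
        scores = grm.simulate_item_responses(flat, item_params, rng)
        return scores.sum(axis=1).reshape(theta.shape)
    if response == "expected":
        score_map = score_map or grm.TotalScoreMap(item_params)
        return score_map.theta_to_total(theta)
    raise ValueError(f"unknown response mode {response!r}")


def cfb_by_interval(totals: np.ndarray, days: np.ndarray) -> np.ndarray:
    """Arm-level mean CFB per 4-week interval from a totals matrix (n, n_days)."""
    base_cols = (days >= BASELINE_WINDOW[0]) & (days <= BASELINE_WINDOW[1])
    if not base_cols.any():
        raise ValueError("no baseline days in the observation grid")
    baseline = totals[:, base_cols].mean(axis=1)
    treat_cols = days >= 1
    iv = assign_interval(days[treat_cols])
    out = np.full(len(INTERVAL_LABELS), np.nan)
    tvals = totals[:, treat_cols]
    for i in range(len(INTERVAL_LABELS)):
        cols = iv == i + 1
        if cols.any():
            out[i] = (tvals[:, cols].mean(axis=1) - baseline).mean()
    return out


def compute_cfb(total_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean CFB per interval from a long totals frame.

    Subjects without any baseline day are excluded and counted in the
    ``n_excluded`` attribute of the result.
    """
    from .data import derive_baselines

    base, excluded = derive_baselines(total_scores)
    post = total_scores[total_scores["study_day"] >= 1].copy()
    post = post[post["subject_id"].isin(base["subject_id"])]
    post["interval"] = assign_interval(post["study_day"].to_numpy())
    merged = post.merge(base[["subject_id", "baseline"]], on="subject_id")
    per_subj = (merged.groupby(["arm", "subject_id", "interval"], sort=True)
                .apply(lambda g: g["rs_total"].mean() - g["baseline"].iloc[0],
                       include_groups=False)
                .rename("cfb").reset_index())
    out = per_subj.groupby(["arm", "interval"], sort=True)["cfb"].agg(["mean", "count"]).reset_index()
    out = out.rename(columns={"mean": "mean_cfb", "count": "n_subjects"})
    out["interval_label"] = [INTERVAL_LABELS[i - 1] for i in out["interval"]]
    out.attrs["n_excluded"] = len(excluded)
    return out


def run_uncertainty(point: TrialParams, unc: ParamUncertainty | None, item_params,
                    config: SimConfig, design: CovariateDesign | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Replicated virtual trials -> long frame (replicate, arm, interval, mean_cfb)."""
    design = design or CovariateDesign()
    days = _obs_days(config)
    score_map = grm.TotalScoreMap(item_params) if config.response == "expected" else None
    seeds = np.random.SeedSequence(config.seed if seed is None else seed).spawn(config.n_replicates)
    rows = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        params = sample_parameters(point, unc, rng) if unc is not None else point
        for arm in point.arms:
            theta = simulate_latent(params, arm, config.n_subjects_per_arm, days, design, rng)
            totals = _totals_from_latent(theta, item_params, config.response, rng, score_map)
            cfb = cfb_by_interval(totals, days)
            for i, label in enumerate(INTERVAL_LABELS):
                rows.append({"replicate": rep, "arm": arm, "interval": label, "mean_cfb": cfb[i]})
    return pd.DataFrame(rows)


def summarize_replicates(cfb_dist: pd.DataFrame) -> pd.DataFrame:
    """Median and 2.5/97.5 percentiles of mean CFB across replicates.

    Percentiles use linear interpolation (numpy default).  The median plays
    the role of the point estimate and the percentile pair the 95% CI.
    """
    n_rep = cfb_dist["replicate"].nunique()
    if n_rep < 2:
        raise ValueError("need at least two replicates to summarize")
    if n_rep < 100:
        warnings.warn(f"only {n_rep} replicates; percentile CI will be noisy", stacklevel=2)
    g = cfb_dist.groupby(["arm", "interval"], sort=False)["mean_cfb"]
    out = g.agg(
        mean=lambda s: float(np.percentile(s, 50)),
        lo=lambda s: float(np.percentile(s, 2.5)),
        hi=lambda s: float(np.percentile(s, 97.5)),
    ).reset_index()
    order = {lab: i for i, lab in enumerate(INTERVAL_LABELS)}
    return out.sort_values(["arm", "interval"], key=lambda s: s.map(order) if s.name == "interval" else s,
                           kind="stable").reset_index(drop=True)
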