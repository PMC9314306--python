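"""Nonlinear mixed-effects fit of the latent symptom trajectory.

The typical time course on the latent scale is a Weibull onset toward a
maximum response plus a rapid-onset additive drug effect ("offset"),

    theta(t) = theta0                                                   t = 0
    theta(t) = theta0 + R_max * (1 - exp(-((ln2 / T_prog) * t)^gamma)) + offset,  t > 0

with t in years; T_prog is the time to half of the Weibull response and
gamma its steepness.  theta0, T_prog, R_max and offset carry
inter-individual variability (T_prog log-normally via an exponential
model, the others additively) with an arm-specific sparse correlation
structure; smoking status and geographic region shift the typical
baseline.  Each arm has its own fixed effects; residual variance and
covariate effects are shared.  Observations are per-occasion latent
estimates, whose curvature SEs can be added to the residual variance.

Estimation exploits a structural property: conditional on the
progression-time effect, the model is *linear* in the remaining three
random effects, so they integrate out of the marginal likelihood in
closed form (standard linear-mixed-model algebra via the Woodbury
identity).  Only a one-dimensional integral over the progression-time
effect remains, evaluated on a dense quadrature grid expressed in units
of its prior SD.  The resulting marginal likelihood is exact up to that
1-D quadrature — no Laplace approximation — and all outer gradients are
analytic, which matters because sharp Weibull shapes make the per-subject
posterior multimodal in the progression-time effect and defeat
single-mode approximations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))
DAYS_PER_YEAR = 365.25

#: Random-effect order used throughout.
ETA_NAMES = ("theta0", "t_prog", "r_max", "offset")
#: Indices of the conditionally linear effects (everything but t_prog).
_LIN = (0, 2, 3)

#: Default arm-specific correlation sparsity between random effects.
DEFAULT_CORR_PAIRS = {
    "FF/UMEC/VI": (("r_max", "offset"), ("theta0", "offset")),
    "BUD/FOR": (("theta0", "offset"), ("r_max", "theta0")),
}


@dataclass(frozen=True)
class ArmFixedEffects:
    theta0: float
    t_prog: float
    r_max: float
    gamma: float
    offset: float

    def __post_init__(self):
        if not self.t_prog > 0:
            raise ValueError("t_prog must be positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class CovariateEffects:
    """Additive shifts on the typical baseline latent value (region 2 = reference)."""

    smoking: float = 0.0
    region: dict = field(default_factory=dict)

    def shift(self, smoking, region):
        smoking = np.asarray(smoking, dtype=float)
        region = np.asarray(region)
        reg = np.zeros(region.shape, dtype=float)
        for k, v in self.region.items():
            reg = np.where(region == k, v, reg)
        return self.smoking * smoking + reg


def trajectory(t_years, theta0, t_prog, r_max, gamma, offset):
    """Typical latent trajectory; t = 0 is baseline (no drug effect applied)."""
    t = np.asarray(t_years, dtype=float)
    if (t < 0).any():
        raise ValueError("time must be non-negative (baseline is t = 0)")
    pos = t > 0
    tt = np.where(pos, t, 1.0)
    logu = gamma * (np.log(LN2 * tt) - np.log(t_prog))
    u = np.exp(np.minimum(logu, 30.0))
    S = np.where(pos, 1.0 - np.exp(-u), 0.0)
    return theta0 + r_max * S + np.where(pos, offset, 0.0)


def individual_params(arm_fixed: ArmFixedEffects, covariates, cov_effects: CovariateEffects,
                      eta) -> dict:
    """Subject-level parameters from typical values, covariates and random effects.

    ``eta`` follows :data:`ETA_NAMES`; T_prog uses an exponential model,
    the rest are additive; covariate shifts enter the baseline.
    """
    eta = np.asarray(eta, dtype=float)
    shift = cov_effects.shift(covariates.get("smoking", 0), covariates.get("region", 2))
    return {
        "theta0": arm_fixed.theta0 + float(shift) + eta[0],
        "t_prog": arm_fixed.t_prog * np.exp(eta[1]),
        "r_max": arm_fixed.r_max + eta[2],
        "gamma": arm_fixed.gamma,
        "offset": arm_fixed.offset + eta[3],
    }


def rse_summary(entries) -> dict:
    """Median and range of a collection of relative standard errors."""
    vals = np.asarray([v for v in entries if v is not None and np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no RSE entries available (fit without standard errors?)")
    return {"median": float(np.median(vals)), "min": float(vals.min()),
            "max": float(vals.max()), "n": int(vals.size)}


# ---------------------------------------------------------------------------
# Batched model evaluation (used for simulation, EBEs and diagnostics)
# ---------------------------------------------------------------------------

def _f_and_jac(t, pos, shift, eta, fx: np.ndarray, extras: bool = False):
    """f(t; individual params) and its jacobian wrt eta, batched (n, m)."""
    th0, tp, rm, gam, off = fx
    th0_i = th0 + shift + eta[:, 0]
    tp_i = tp * np.exp(eta[:, 1])
    rm_i = rm + eta[:, 2]
    off_i = off + eta[:, 3]
    tt = np.where(pos, t, 1.0)
    logu = gam * (np.log(LN2 * tt) - np.log(tp_i)[:, None])
    logu = np.minimum(logu, 30.0)
    u = np.exp(logu)
    em = np.exp(-u)
    uem = u * em
    S = np.where(pos, 1.0 - em, 0.0)
    dS = np.where(pos, -gam * uem, 0.0)  # dS/d eta_tprog
    f = th0_i[:, None] + rm_i[:, None] * S + off_i[:, None] * pos
    J = np.empty(t.shape + (4,))
    J[..., 0] = 1.0
    J[..., 1] = rm_i[:, None] * dS
    J[..., 2] = S
    J[..., 3] = pos
    if not extras:
        return f, J
    S_g = np.where(pos, uem * logu, 0.0)          # dS/dlog gamma
    ex = {"S": S, "S_t": dS, "S_g": S_g, "rm_i": rm_i}
    return f, J, ex


def _inner_gn(y, t, pos, mask, w, shift, eta0, fx, omega_inv, max_iter=30, tol=1e-9,
              extra_starts=()):
    """Batched Gauss-Newton joint-posterior modes over eta (for EBEs/GOF).

    With sharp Weibull shapes the joint posterior can be multimodal in the
    progression-time effect; ``extra_starts`` re-runs the solve from
    shifted starts and keeps the per-subject best.
    """
    eta, f, J, q = _inner_gn_single(y, t, pos, mask, w, shift, eta0, fx, omega_inv,
                                    max_iter, tol)
    for s0 in extra_starts:
        e0 = eta0.copy()
        e0[:, 1] = s0
        e2, f2, J2, q2 = _inner_gn_single(y, t, pos, mask, w, shift, e0, fx, omega_inv,
                                          max_iter, tol)
        better = q2 < q - 1e-12
        if better.any():
            eta[better] = e2[better]
            f[better] = f2[better]
            J[better] = J2[better]
            q[better] = q2[better]
    return eta, f, J, q


def _inner_gn_single(y, t, pos, mask, w, shift, eta0, fx, omega_inv, max_iter=30, tol=1e-9):
    eta = eta0.copy()

    def q_of(eta, f):
        r = np.where(mask, y - f, 0.0)
        return (w * r * r).sum(axis=1) + np.einsum("np,pq,nq->n", eta, omega_inv, eta)

    f, J = _f_and_jac(t, pos, shift, eta, fx)
    q = q_of(eta, f)
    for _ in range(max_iter):
        r = np.where(mask, y - f, 0.0)
        Jm = J * w[..., None]
        A = np.einsum("nmp,nmq->npq", Jm, J) + omega_inv
        g = np.einsum("nmp,nm->np", Jm, r) - eta @ omega_inv
        step = np.linalg.solve(A, g[..., None])[..., 0]
        alpha = np.ones(len(eta))
        for _ in range(12):
            eta_new = eta + alpha[:, None] * step
            f_new, J_new = _f_and_jac(t, pos, shift, eta_new, fx)
            q_new = q_of(eta_new, f_new)
            worse = q_new > q + 1e-12
            if not worse.any():
                break
            alpha = np.where(worse, alpha * 0.5, alpha)
        if worse.any():  # strictly monotone: freeze subjects that cannot improve
            alpha = np.where(worse, 0.0, alpha)
            eta_new = eta + alpha[:, None] * step
            f_new, J_new = _f_and_jac(t, pos, shift, eta_new, fx)
            q_new = np.minimum(q_of(eta_new, f_new), q)
        moved = np.abs(alpha[:, None] * step).max()
        eta, f, J, q = eta_new, f_new, J_new, q_new
        if moved < tol:
            break
    return eta, f, J, q


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------

class _Layout:
    def __init__(self, arms, corr_pairs, regions, use_smoking):
        self.arms = list(arms)
        self.corr_pairs = {a: tuple(corr_pairs.get(a, ())) for a in self.arms}
        for a, pairs in self.corr_pairs.items():
            for p, q in pairs:
                if "t_prog" in (p, q):
                    raise ValueError("the progression-time effect must stay uncorrelated "
                                     "with the other random effects")
        self.regions = list(regions)          # non-reference regions with an effect
        self.use_smoking = use_smoking
        names = []
        for a in self.arms:
            names += [f"{a}|theta0", f"{a}|log_t_prog", f"{a}|r_max", f"{a}|log_gamma", f"{a}|offset"]
        for a in self.arms:
            names += [f"{a}|log_sd_{e}" for e in ETA_NAMES]
            names += [f"{a}|corr_{p}_{q}" for p, q in self.corr_pairs[a]]
        names.append("log_sd_resid")
        if use_smoking:
            names.append("smoking")
        names += [f"region[{k}]" for k in self.regions]
        self.names = names
        self.size = len(names)
        self.index = {n: i for i, n in enumerate(names)}

    def fixed(self, x, arm):
        i = self.index[f"{arm}|theta0"]
        th0, ltp, rm, lg, off = x[i:i + 5]
        return np.array([th0, np.exp(ltp), rm, np.exp(lg), off])

    def omega(self, x, arm):
        sd = np.array([np.exp(x[self.index[f"{arm}|log_sd_{e}"]]) for e in ETA_NAMES])
        C = np.eye(4)
        for p, q in self.corr_pairs[arm]:
            r = np.tanh(x[self.index[f"{arm}|corr_{p}_{q}"]])
            i, j = ETA_NAMES.index(p), ETA_NAMES.index(q)
            C[i, j] = C[j, i] = r
        return sd[:, None] * C * sd[None, :], sd, C

    def sigma2(self, x):
        return float(np.exp(2 * x[self.index["log_sd_resid"]]))

    def cov_effects(self, x):
        smoking = float(x[self.index["smoking"]]) if self.use_smoking else 0.0
        region = {k: float(x[self.index[f"region[{k}]"]]) for k in self.regions}
        return CovariateEffects(smoking=smoking, region=region)

    def natural(self, x):
        """Reporting-scale vector: fixed effects, covariates, variances,
        correlations, residual variance."""
        out, names = [], []
        for a in self.arms:
            fx = self.fixed(x, a)
            for n, v in zip(("theta0", "t_prog", "r_max", "gamma", "offset"), fx):
                out.append(v); names.append(f"{a}|{n}")
        if self.use_smoking:
            out.append(x[self.index["smoking"]]); names.append("smoking")
        for k in self.regions:
            out.append(x[self.index[f"region[{k}]"]]); names.append(f"region[{k}]")
        for a in self.arms:
            _, sd, C = self.omega(x, a)
            for e, s in zip(ETA_NAMES, sd):
                out.append(s ** 2); names.append(f"{a}|omega2_{e}")
            for p, q in self.corr_pairs[a]:
                out.append(C[ETA_NAMES.index(p), ETA_NAMES.index(q)]); names.append(f"{a}|corr_{p}_{q}")
        out.append(self.sigma2(x)); names.append("sigma2")
        return np.asarray(out), names


@dataclass
class _ArmData:
    y: np.ndarray      # (n, m) padded
    t: np.ndarray
    pos: np.ndarray
    mask: np.ndarray
    se2: np.ndarray
    smoke: np.ndarray  # (n,)
    region: np.ndarray
    subjects: np.ndarray


def _prepare(df: pd.DataFrame, arms, thin_days=None) -> dict:
    req = {"subject_id", "arm", "study_day", "theta_hat"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"theta observations missing column(s) {sorted(missing)}")
    df = df.copy()
    if thin_days:
        day = df["study_day"]
        keep = (day < 1) | (day % thin_days == 0)
        df = df[keep]
    if "se_theta" not in df.columns:
        df["se_theta"] = 0.0
    if "smoking" not in df.columns:
        df["smoking"] = 0
    if "region" not in df.columns:
        df["region"] = 2
    out = {}
    for arm in arms:
        sub = df[df["arm"] == arm].sort_values(["subject_id", "study_day"], kind="stable")
        groups = list(sub.groupby("subject_id", sort=True))
        n = len(groups)
        m = max(len(g) for _, g in groups)
        y = np.zeros((n, m)); t = np.zeros((n, m)); se2 = np.zeros((n, m))
        mask = np.zeros((n, m), dtype=bool)
        smoke = np.zeros(n); region = np.empty(n, dtype=object); subjects = np.empty(n, dtype=object)
        for i, (sid, g) in enumerate(groups):
            k = len(g)
            y[i, :k] = g["theta_hat"].to_numpy()
            day = g["study_day"].to_numpy()
            t[i, :k] = np.where(day < 1, 0.0, day / DAYS_PER_YEAR)
            se2[i, :k] = g["se_theta"].to_numpy() ** 2
            mask[i, :k] = True
            smoke[i] = g["smoking"].iloc[0]
            region[i] = g["region"].iloc[0]
            subjects[i] = sid
        out[arm] = _ArmData(y=y, t=t, pos=(t > 0) & mask, mask=mask, se2=se2,
                            smoke=smoke, region=region, subjects=subjects)
    return out


class LatentTrajectoryNLME(BaseEstimator):
    """Arm-specific Weibull-plus-offset latent trajectory model.

    ``fit`` expects a frame of per-occasion latent estimates (columns
    subject_id, arm, study_day, theta_hat, and optionally se_theta,
    smoking, region).  All arms are fit jointly with shared residual
    variance and covariate effects; the marginal likelihood marginalizes
    the three conditionally linear random effects exactly and the
    progression-time effect on a dense 1-D quadrature grid.

    Parameters
    ----------
    corr_pairs : mapping arm -> pairs of random-effect names allowed to
        correlate (the progression-time effect must stay independent);
        defaults to the built-in sparsity for the two known arm labels.
    use_ebe_se : add each observation's se_theta^2 to the residual
        variance (propagating latent-estimate uncertainty into stage 2).
    n_quad : number of quadrature points for the progression-time effect.
    fix : mapping of packed parameter names (see ``param_names_``; ``*``
        may stand for the arm prefix) to values on the packed
        (log / atanh) scale, removed from optimization.
    """

    def __init__(self, corr_pairs=None, use_ebe_se: bool = True,
                 covariates=("smoking", "region"), n_quad: int = 71,
                 quad_width: float = 5.5, max_iter: int = 500,
                 gtol: float = 1e-5, ftol: float = 1e-11, compute_se: bool = True,
                 fix: dict | None = None, thin_days: int | None = None):
        self.corr_pairs = corr_pairs
        self.use_ebe_se = use_ebe_se
        self.covariates = covariates
        self.n_quad = n_quad
        self.quad_width = quad_width
        self.max_iter = max_iter
        self.gtol = gtol
        self.ftol = ftol
        self.compute_se = compute_se
        self.fix = fix
        self.thin_days = thin_days

    # ------------------------------------------------------------------
    def _quad_grid(self):
        u = np.linspace(-self.quad_width, self.quad_width, self.n_quad)
        du = u[1] - u[0]
        logw = np.log(du) - 0.5 * np.log(2 * np.pi) - 0.5 * u ** 2
        return u, logw

    def _objective(self, x, data, layout, want_grad=False):
        """-2 x marginal log-likelihood (exact in the linear effects)."""
        sigma2 = layout.sigma2(x)
        cov_eff = layout.cov_effects(x)
        u, logw0 = self._quad_grid()
        total = 0.0
        penalty = 0.0
        grad = np.zeros(layout.size) if want_grad else None
        for arm, d in data.items():
            th0, tp, rm, gam, off = layout.fixed(x, arm)
            omega, sd, C = layout.omega(x, arm)
            Sb = omega[np.ix_(_LIN, _LIN)]
            lam = np.linalg.eigvalsh(Sb).min()
            if lam < 1e-10:
                penalty += 1e7 * (1e-10 - lam)
                shrink = 0.5
                C3 = Sb / np.sqrt(np.outer(np.diag(Sb), np.diag(Sb)))
                for _ in range(40):
                    C2 = np.eye(3) + shrink * (C3 - np.eye(3))
                    Sb = np.sqrt(np.outer(np.diag(omega)[list(_LIN)], np.diag(omega)[list(_LIN)])) * C2
                    if np.linalg.eigvalsh(Sb).min() > 1e-10:
                        break
                    shrink *= 0.5
                logger.info("non-positive-definite IIV at %s during search; correlations shrunk", arm)
            Sb_inv = np.linalg.inv(Sb)
            om_t = sd[1]                      # prior SD of the t_prog effect
            s_nodes = om_t * u                # (K,)

            v = sigma2 + (d.se2 if self.use_ebe_se else 0.0)
            v = np.where(d.mask, v, 1.0)
            w = np.where(d.mask, 1.0 / v, 0.0)
            shift = cov_eff.shift(d.smoke, d.region)
            n, m = d.y.shape
            K = u.size

            tt = np.where(d.pos, d.t, 1.0)
            LT = np.log(LN2 * tt) - np.log(tp)          # (n, m)
            logu_ = gam * (LT[:, None, :] - s_nodes[None, :, None])
            logu_ = np.minimum(logu_, 30.0)
            uu = np.exp(logu_)
            em = np.exp(-uu)
            posm = d.pos[:, None, :]
            S = np.where(posm, 1.0 - em, 0.0)            # (n, K, m)
            S_t = np.where(posm, -gam * uu * em, 0.0)    # dS/d eta_tprog
            S_g = np.where(posm, uu * em * logu_, 0.0)   # dS/dlog gamma

            base = (th0 + shift)[:, None, None] + off * posm
            r = np.where(d.mask[:, None, :], d.y[:, None, :] - base - rm * S, 0.0)
            wk = w[:, None, :]

            # Z = [1, S, pos]; accumulate h = Z'W r and A = Z'W Z
            h = np.empty((n, K, 3))
            h[..., 0] = np.einsum("nm,nkm->nk", w, r)
            h[..., 1] = np.einsum("nm,nkm,nkm->nk", w, S, r)
            h[..., 2] = np.einsum("nm,nm,nkm->nk", w, d.pos, r)
            A = np.empty((n, K, 3, 3))
            sw = w.sum(axis=1)
            swp = (w * d.pos).sum(axis=1)
            A[..., 0, 0] = sw[:, None]
            A[..., 0, 1] = A[..., 1, 0] = np.einsum("nm,nkm->nk", w, S)
            A[..., 0, 2] = A[..., 2, 0] = swp[:, None]
            A[..., 1, 1] = np.einsum("nm,nkm->nk", w, S * S)
            A[..., 1, 2] = A[..., 2, 1] = np.einsum("nm,nm,nkm->nk", w, d.pos, S)
            A[..., 2, 2] = swp[:, None]

            P = np.eye(3) + np.einsum("ab,nkbc->nkac", Sb, A)
            detP = np.linalg.det(P)
            G = np.linalg.inv(Sb_inv + A)                # (n, K, 3, 3)
            bhat = np.einsum("nkab,nkb->nka", G, h)
            rWr = np.einsum("nm,nkm,nkm->nk", w, r, r)
            Q = rWr - np.einsum("nka,nka->nk", h, bhat)
            ll_k = -0.5 * (Q + np.log(np.maximum(detP, 1e-300)))
            const = np.where(d.mask, np.log(2 * np.pi * v), 0.0).sum()
            Lw = logw0[None, :] + ll_k
            Li = logsumexp(Lw, axis=1)
            total += -2.0 * Li.sum() + const
            if not want_grad:
                continue

            p = np.exp(Lw - Li[:, None])                  # posterior node weights
            e = r - (bhat[..., 0:1] + bhat[..., 1:2] * S + bhat[..., 2:3] * d.pos[:, None, :])
            We = wk * e
            sumWe = We.sum(axis=2)                        # (n, K)
            M3 = np.einsum("nkab,bc->nkac", G, Sb_inv)    # (I + Sb A)^-1

            def acc(X):
                return float(np.einsum("nk,nk->", p, X))

            i0 = layout.index[f"{arm}|theta0"]
            grad[i0 + 0] += acc(-2.0 * sumWe)
            # d/d log t_prog and d/d log gamma share structure via dS
            for slot, dS in ((1, S_t), (3, S_g)):
                dQ = -2.0 * np.einsum("nkm,nkm->nk", We, dS) * rm \
                     - 2.0 * np.einsum("nkm,nkm,nk->nk", We, dS, bhat[..., 1])
                dA01 = np.einsum("nm,nkm->nk", w, dS)
                dA11 = 2.0 * np.einsum("nm,nkm,nkm->nk", w, S, dS)
                dA12 = np.einsum("nm,nm,nkm->nk", w, d.pos, dS)
                dLD = (2.0 * G[..., 0, 1] * dA01 + G[..., 1, 1] * dA11
                       + 2.0 * G[..., 1, 2] * dA12)
                grad[i0 + slot] += acc(dQ + dLD)
                if slot == 1:
                    # same chain scaled by the node value gives d/dlog sd_t_prog
                    grad[layout.index[f"{arm}|log_sd_t_prog"]] += \
                        acc((dQ + dLD) * s_nodes[None, :])
            grad[i0 + 2] += acc(-2.0 * np.einsum("nkm,nkm->nk", We, S))
            grad[i0 + 4] += acc(-2.0 * np.einsum("nkm,nm->nk", We, d.pos * 1.0))
            if layout.use_smoking:
                grad[layout.index["smoking"]] += acc(-2.0 * sumWe * d.smoke[:, None])
            for kreg in layout.regions:
                ind = (d.region == kreg).astype(float)
                grad[layout.index[f"region[{kreg}]"]] += acc(-2.0 * sumWe * ind[:, None])

            # residual variance (chain d sigma2/d log sd = 2 sigma2)
            w2 = w * w
            dQ = -np.einsum("nm,nkm,nkm->nk", w2, e, e)
            dA00 = np.broadcast_to(-w2.sum(axis=1)[:, None], (n, K))
            dA01 = -np.einsum("nm,nkm->nk", w2, S)
            dA02 = np.broadcast_to(-(w2 * d.pos).sum(axis=1)[:, None], (n, K))
            dA11 = -np.einsum("nm,nkm->nk", w2, S * S)
            dA12 = -np.einsum("nm,nm,nkm->nk", w2, d.pos, S)
            dA22 = dA02
            dLD = (G[..., 0, 0] * dA00 + 2 * G[..., 0, 1] * dA01 + 2 * G[..., 0, 2] * dA02
                   + G[..., 1, 1] * dA11 + 2 * G[..., 1, 2] * dA12 + G[..., 2, 2] * dA22)
            grad[layout.index["log_sd_resid"]] += (acc(dQ + dLD) + float(sw.sum())) * 2 * sigma2

            # Sigma_b parameters: explicit dOmega_b matrices
            ct = np.einsum("nka,ab->nkb", bhat, Sb_inv)

            def sb_grad(dSb):
                dQ = -np.einsum("nka,ab,nkb->nk", ct, dSb, ct)
                dLD = np.einsum("nkab,bc,nkca->nk", M3, dSb, A)  # tr(M3 dSb A)
                return acc(dQ + dLD)

            for kk, e_name in enumerate(ETA_NAMES):
                if e_name == "t_prog":
                    continue
                j = _LIN.index(ETA_NAMES.index(e_name))
                dSb = np.zeros((3, 3))
                dSb[j, :] += Sb[j, :]
                dSb[:, j] += Sb[:, j]
                grad[layout.index[f"{arm}|log_sd_{e_name}"]] += sb_grad(dSb)
            for p_, q_ in layout.corr_pairs[arm]:
                i_, j_ = _LIN.index(ETA_NAMES.index(p_)), _LIN.index(ETA_NAMES.index(q_))
                rho = Sb[i_, j_] / np.sqrt(Sb[i_, i_] * Sb[j_, j_])
                dSb = np.zeros((3, 3))
                dSb[i_, j_] = dSb[j_, i_] = np.sqrt(Sb[i_, i_] * Sb[j_, j_]) * (1.0 - rho ** 2)
                grad[layout.index[f"{arm}|corr_{p_}_{q_}"]] += sb_grad(dSb)
        if want_grad:
            return total + penalty, grad
        return total + penalty

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        arms = sorted(pd.unique(X["arm"]))
        corr = self.corr_pairs if self.corr_pairs is not None else DEFAULT_CORR_PAIRS
        use_smoking = "smoking" in self.covariates and "smoking" in X.columns
        regions = []
        if "region" in self.covariates and "region" in X.columns:
            regions = sorted(int(k) if isinstance(k, (int, np.integer)) else k
                             for k in pd.unique(X["region"]) if k != 2)
        layout = _Layout(arms, corr, regions, use_smoking)
        data = _prepare(X, arms, thin_days=self.thin_days)
        x0 = self._start_values(data, layout)

        free = np.ones(layout.size, dtype=bool)
        if self.fix:
            for key, val in self.fix.items():
                targets = [n for n in layout.names
                           if n == key or (key.startswith("*") and n.endswith(key[1:]))]
                if not targets:
                    raise KeyError(f"fix target {key!r} matches no parameter")
                for nme in targets:
                    x0[layout.index[nme]] = val
                    free[layout.index[nme]] = False
        x_template = x0.copy()

        def embed(z):
            xx = x_template.copy()
            xx[free] = z
            return xx

        def fun(z):
            f0, g = self._objective(embed(z), data, layout, want_grad=True)
            if not np.isfinite(f0):
                return 1e15, np.zeros(z.size)
            return f0, g[free]

        # box constraints keep the search in the interpretable range; the
        # gamma cap reflects that beyond ~60 the onset is a step at any
        # realistic sampling interval and the likelihood goes flat
        bounds = []
        for nme in layout.names:
            if "log_gamma" in nme:
                bounds.append((np.log(0.2), np.log(60.0)))
            elif "log_t_prog" in nme:
                bounds.append((np.log(0.002), np.log(5.0)))
            elif "log_sd" in nme:
                bounds.append((-6.0, 3.0))
            elif "corr" in nme:
                bounds.append((-3.0, 3.0))
            else:
                bounds.append((-15.0, 15.0))
        bounds = [b for b, fr in zip(bounds, free) if fr]
        x0c = x0.copy()
        for i, (lo_, hi_) in zip(np.flatnonzero(free), bounds):
            x0c[i] = np.clip(x0c[i], lo_, hi_)
        with np.errstate(over="ignore", invalid="ignore"):
            res = minimize(fun, x0c[free], jac=True, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": self.max_iter, "gtol": self.gtol,
                                    "ftol": self.ftol, "maxcor": 30})
        x = embed(res.x)
        self.layout_ = layout
        self.packed_ = x
        self.free_ = free
        active = np.zeros(layout.size, dtype=bool)
        for i, (lo_, hi_) in zip(np.flatnonzero(free), bounds):
            if x[i] - lo_ < 1e-9 or hi_ - x[i] < 1e-9:
                active[i] = True
        self.active_bounds_ = [layout.names[i] for i in np.flatnonzero(active)]
        self._se_free = free & ~active
        self.arms_ = arms
        self.param_names_ = layout.names
        self.fixed_effects_ = {}
        self.iiv_ = {}
        for arm in arms:
            fx = layout.fixed(x, arm)
            self.fixed_effects_[arm] = ArmFixedEffects(*fx)
            omega, sd, C = layout.omega(x, arm)
            self.iiv_[arm] = {"omega": omega, "sd": sd, "corr": C,
                              "pairs": layout.corr_pairs[arm]}
        self.covariate_effects_ = layout.cov_effects(x)
        self.sigma2_ = layout.sigma2(x)
        self.loglik_ = -0.5 * float(res.fun)
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.message_ = str(res.message)
        self._data = data
        if not self.converged_:
            warnings.warn(f"longitudinal fit did not flag convergence: {self.message_}", stacklevel=2)
        self.se_ = {}
        self.rse_ = {}
        if self.compute_se:
            self._compute_se(data, layout)
        return self

    # ------------------------------------------------------------------
    def _start_values(self, data, layout):
        x = np.zeros(layout.size)
        sig_parts = []
        for arm, d in data.items():
            base_mask = d.mask & ~d.pos
            nb = base_mask.sum(axis=1)
            has_base = nb > 0
            base_mean = np.where(has_base, np.where(base_mask, d.y, 0.0).sum(axis=1) / np.maximum(nb, 1), 0.0)
            th0 = float(base_mean[has_base].mean()) if has_base.any() else float(d.y[d.mask].mean())
            late = d.mask & (d.t > 100.0 / DAYS_PER_YEAR)
            plateau = float(d.y[late].mean()) if late.any() else th0 - 0.1
            drop = min(plateau - th0, -0.02)
            i = layout.index[f"{arm}|theta0"]
            x[i:i + 5] = [th0, np.log(0.1), 0.6 * drop, np.log(5.0), 0.4 * drop]
            v0 = float(np.var(base_mean[has_base])) if has_base.any() else 1.0
            x[layout.index[f"{arm}|log_sd_theta0"]] = 0.5 * np.log(max(v0, 0.05))
            x[layout.index[f"{arm}|log_sd_t_prog"]] = 0.5 * np.log(0.3)
            x[layout.index[f"{arm}|log_sd_r_max"]] = 0.5 * np.log(0.3)
            x[layout.index[f"{arm}|log_sd_offset"]] = 0.5 * np.log(0.3)
            dev = np.where(base_mask, d.y - base_mean[:, None], 0.0)
            denom = max(int(base_mask.sum() - has_base.sum()), 1)
            wvar = float((dev ** 2).sum() / denom)
            se_adj = float(d.se2[base_mask].mean()) if (self.use_ebe_se and base_mask.any()) else 0.0
            sig_parts.append(max(wvar - se_adj, 0.02))
        x[layout.index["log_sd_resid"]] = 0.5 * np.log(float(np.mean(sig_parts)))
        return x

    def _compute_se(self, data, layout):
        """Asymptotic covariance from the observed information (FD of the
        analytic gradient).  Parameters pinned at an active box bound are
        conditioned on (no SE reported for them)."""
        if self.active_bounds_:
            warnings.warn(f"parameters at bounds excluded from SEs: {self.active_bounds_}",
                          stacklevel=2)
        x = self.packed_
        idx = np.flatnonzero(self._se_free)
        k = idx.size
        h = 1e-4 * (1 + np.abs(x[idx]))
        H = np.zeros((k, k))
        for a in range(k):
            xp = x.copy(); xp[idx[a]] += h[a]
            xm = x.copy(); xm[idx[a]] -= h[a]
            _, gp = self._objective(xp, data, layout, want_grad=True)
            _, gm = self._objective(xm, data, layout, want_grad=True)
            H[:, a] = (gp[idx] - gm[idx]) / (2 * h[a])
        H = 0.25 * (H + H.T)  # objective is -2 loglik; information = H/2
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            warnings.warn("observed information singular; no standard errors", stacklevel=2)
            return
        if np.any(np.diag(cov) <= 0):
            warnings.warn("observed information not positive definite; no standard errors",
                          stacklevel=2)
            return
        self.cov_packed_ = np.zeros((layout.size, layout.size))
        self.cov_packed_[np.ix_(idx, idx)] = cov
        nat0, nat_names = layout.natural(x)
        Jc = np.zeros((nat0.size, layout.size))
        for a in range(k):
            xp = x.copy(); xp[idx[a]] += h[a]
            xm = x.copy(); xm[idx[a]] -= h[a]
            Jc[:, idx[a]] = (layout.natural(xp)[0] - layout.natural(xm)[0]) / (2 * h[a])
        cov_nat = Jc @ self.cov_packed_ @ Jc.T
        var_nat = np.maximum(np.diag(cov_nat), 0.0)
        self.cov_natural_ = cov_nat
        self.natural_names_ = nat_names
        self.natural_values_ = nat0
        se = np.sqrt(var_nat)
        self.se_ = dict(zip(nat_names, se))
        rse = {}
        for n, v, s in zip(nat_names, nat0, se):
            if "omega2" in n or n == "sigma2":
                rse[n] = 0.5 * s / v if v > 0 else np.nan  # approximate SD scale
            else:
                rse[n] = s / abs(v) if v != 0 else np.nan
        self.rse_ = rse

    # ------------------------------------------------------------------
    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Typical (eta = 0) latent value for rows of (arm, study_day [, covariates])."""
        if not hasattr(self, "fixed_effects_"):
            raise AttributeError("estimator is not fitted")
        day = np.asarray(X["study_day"], dtype=int)
        t = np.where(day < 1, 0.0, day / DAYS_PER_YEAR)
        shift = self.covariate_effects_.shift(
            X["smoking"] if "smoking" in X.columns else np.zeros(len(X)),
            X["region"] if "region" in X.columns else np.full(len(X), 2),
        )
        out = np.empty(len(X))
        for arm in self.arms_:
            fx = self.fixed_effects_[arm]
            sel = (X["arm"] == arm).to_numpy()
            out[sel] = trajectory(t[sel], fx.theta0 + shift[sel], fx.t_prog, fx.r_max,
                                  fx.gamma, fx.offset)
        return out

    def individual_effects(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Empirical-Bayes random effects per subject at the fitted parameters."""
        if not hasattr(self, "fixed_effects_"):
            raise AttributeError("estimator is not fitted")
        data = self._data if X is None else _prepare(X, self.arms_, thin_days=self.thin_days)
        rows = []
        for arm, d in data.items():
            fe = self.fixed_effects_[arm]
            fx = np.array([fe.theta0, fe.t_prog, fe.r_max, fe.gamma, fe.offset])
            omega_inv = np.linalg.inv(self.iiv_[arm]["omega"])
            sd_t = self.iiv_[arm]["sd"][1]
            v = self.sigma2_ + (d.se2 if self.use_ebe_se else 0.0)
            w = np.where(d.mask, 1.0 / np.where(d.mask, v, 1.0), 0.0)
            shift = self.covariate_effects_.shift(d.smoke, d.region)
            eta, f, _, _ = _inner_gn(d.y, d.t, d.pos, d.mask, w, shift,
                                     np.zeros((len(d.y), 4)), fx, omega_inv,
                                     extra_starts=(-2 * sd_t, -sd_t, sd_t, 2 * sd_t))
            for i, sid in enumerate(d.subjects):
                rows.append({"subject_id": sid, "arm": arm,
                             **{f"eta_{e}": eta[i, j] for j, e in enumerate(ETA_NAMES)}})
        return pd.DataFrame(rows)

    def summarize_rse(self) -> dict:
        return rse_summary(self.rse_.values())


def fit_longitudinal(theta_obs: pd.DataFrame, **options) -> LatentTrajectoryNLME:
    """Functional wrapper over :class:`LatentTrajectoryNLME`."""
    return LatentTrajectoryNLME(**options).fit(theta_obs)
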