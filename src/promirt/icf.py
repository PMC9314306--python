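"""Item-characteristic-function estimation by marginal maximum likelihood.

Occasions are independent pseudo-subjects (see :mod:`promirt.occasions`).
The latent variable is integrated out of each occasion's likelihood with
Gauss-Hermite quadrature, either centred on the occasion-class prior
(``scheme="gh"``) or adaptively on each occasion's posterior mode
(``scheme="agh"``, the default; one node reduces to a Laplace
approximation).  The baseline occasion class is fixed at N(0, 1) — this is
the identifiability anchor — while each post-baseline class contributes an
estimated mean and variance.

Gradients are analytic given the node positions; for the adaptive scheme
the node positions are frozen within each evaluation, which perturbs the
gradient only at the (negligible) level of the quadrature error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator, TransformerMixin

from . import grm
from .data import ItemDataset, InstrumentSpec
from .ebe import estimate_thetas, posterior_mode
from .occasions import OccasionData, build_independent_occasions

__all__ = ["PopulationDist", "IcfFitResult", "GradedResponseIRT", "fit_icf", "marginal_loglik",
           "build_independent_occasions"]

_LOG_SQRT_PI = 0.5 * np.log(np.pi)


@dataclass(frozen=True)
class PopulationDist:
    """Latent-variable distribution of one post-baseline occasion class."""

    mu: float
    omega2: float

    def __post_init__(self):
        if not self.omega2 > 0:
            raise ValueError("omega2 must be positive")


@dataclass
class IcfFitResult:
    item_params: list
    pop: list               # PopulationDist per post-baseline class
    loglik: float
    se: dict = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    message: str = ""
    n_occasions: int = 0

    @property
    def pop_dist(self) -> PopulationDist:
        return self.pop[0]


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------

class _Layout:
    """Maps the flat unconstrained vector to item and class parameters."""

    def __init__(self, n_thresholds, n_classes):
        self.K = np.asarray(n_thresholds, dtype=int)
        self.n_classes = n_classes  # post-baseline classes with free (mu, log sd)
        self.item_slices = []
        pos = 0
        for K in self.K:
            self.item_slices.append(slice(pos, pos + 1 + K))
            pos += 1 + K
        self.n_item_params = pos
        self.size = pos + 2 * n_classes

    def pack(self, items, pops):
        x = np.empty(self.size)
        for sl, it in zip(self.item_slices, items):
            d = np.diff(it.b)
            x[sl] = np.concatenate([[np.log(it.a), it.b[0]], np.log(d)])
        for c, p in enumerate(pops):
            x[self.n_item_params + 2 * c] = p.mu
            x[self.n_item_params + 2 * c + 1] = 0.5 * np.log(p.omega2)
        return x

    def unpack(self, x):
        J = len(self.K)
        kmax = int(self.K.max())
        a = np.empty(J)
        b = np.full((J, kmax), np.inf)
        for j, sl in enumerate(self.item_slices):
            v = x[sl]
            a[j] = np.exp(v[0])
            b[j, : self.K[j]] = v[1] + np.concatenate([[0.0], np.cumsum(np.exp(v[2:]))])
        mu = x[self.n_item_params::2].copy()
        log_sd = x[self.n_item_params + 1::2].copy()
        return a, b, mu, log_sd

    def natural(self, x):
        """Flat vector of (a_j, b_jk..., mu_c, omega2_c) for delta-method SEs."""
        a, b, mu, log_sd = self.unpack(x)
        parts = []
        for j in range(len(self.K)):
            parts.append([a[j]])
            parts.append(b[j, : self.K[j]])
        parts.append(mu)
        parts.append(np.exp(2 * log_sd))
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    def natural_names(self, item_ids):
        names = []
        for j, iid in enumerate(item_ids):
            names.append(f"a[{iid}]")
            names += [f"b[{iid},{k + 1}]" for k in range(self.K[j])]
        names += [f"mu[{c + 1}]" for c in range(self.n_classes)]
        names += [f"omega2[{c + 1}]" for c in range(self.n_classes)]
        return names


# ---------------------------------------------------------------------------
# Likelihood core
# ---------------------------------------------------------------------------

def _class_index(occ: OccasionData, post_grouping: str) -> tuple[np.ndarray, int]:
    """0 = baseline; 1..C = post-baseline classes."""
    if post_grouping == "pooled":
        cls = (~occ.is_baseline).astype(int)
        return cls, 1
    if post_grouping == "interval":
        iv = occ.meta["interval"].to_numpy()
        n = int(iv.max())
        return iv.astype(int), n
    raise ValueError(f"unknown post_grouping {post_grouping!r}")


def _nodes(scores, arrays, cls, mu_all, sd_all, scheme, n_nodes, mode_cache=None):
    """Node positions (N, Q) and log-weights for the latent integral."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    m = mu_all[cls]
    s = sd_all[cls]
    if scheme == "gh":
        theta = m[:, None] + np.sqrt(2.0) * s[:, None] * x
        logw = np.broadcast_to(np.log(w) - _LOG_SQRT_PI, theta.shape)
        return theta, logw
    if scheme == "agh":
        start = None
        if mode_cache is not None and mode_cache.get("mode") is not None:
            start = mode_cache["mode"]
        mode, sd_n, _ = posterior_mode(scores, arrays, prior_mean=m, prior_var=s ** 2, start=start,
                                       tol=1e-9, max_iter=40)
        if mode_cache is not None:
            mode_cache["mode"] = mode
        theta = mode[:, None] + np.sqrt(2.0) * sd_n[:, None] * x
        dev = theta - m[:, None]
        log_prior = -0.5 * np.log(2 * np.pi * s[:, None] ** 2) - dev ** 2 / (2 * s[:, None] ** 2)
        logw = (np.log(w) + x ** 2) + 0.5 * np.log(2.0) + np.log(sd_n)[:, None] + log_prior
        return theta, logw
    raise ValueError(f"unknown quadrature scheme {scheme!r}")


def _mll(x, layout, scores, cls, scheme, n_nodes, item_ids, want_grad, mode_cache=None):
    """Marginal log-likelihood (and gradient on the packed scale)."""
    a, b, mu_post, log_sd_post = layout.unpack(x)
    arrays = grm.ItemArrays(tuple(item_ids), a, b, layout.K)
    mu_all = np.concatenate([[0.0], mu_post])
    sd_all = np.concatenate([[1.0], np.exp(log_sd_post)])
    theta, logw = _nodes(scores, arrays, cls, mu_all, sd_all, scheme, n_nodes, mode_cache)

    sc = scores[:, None, :]
    z_lo, z_hi = grm._edges(sc, arrays, theta)
    with np.errstate(invalid="ignore"):
        gap = z_hi - z_lo
    gap = np.where(np.isinf(z_hi) | np.isinf(z_lo), -np.inf, gap)
    lp = grm._log_sigmoid(z_lo) + grm._log_sigmoid(-z_hi) + grm._log1mexp(gap)  # (N, Q, J)
    S = lp.sum(axis=-1)
    L = logsumexp(logw + S, axis=1)
    ll = float(L.sum())
    if not want_grad:
        return ll, None

    p = np.exp(logw + S - L[:, None])  # posterior node weights, rows sum to 1
    with np.errstate(over="ignore"):
        E = 1.0 / np.expm1(-gap)       # 0 at gap = -inf
    s_lo = expit(-z_lo)
    s_hi = expit(z_hi)
    f_lo = s_lo + E                    # d logP / d z_lo
    f_hi = -(s_hi + E)                 # d logP / d z_hi
    lo_fin = np.isfinite(z_lo)
    hi_fin = np.isfinite(z_hi)
    g_loga = (f_lo * np.where(lo_fin, z_lo, 0.0) + f_hi * np.where(hi_fin, z_hi, 0.0))
    g_th = arrays.a * (s_lo - s_hi)

    grad = np.zeros(layout.size)
    # discrimination (log scale): z depends on log a as dz/dloga = z
    ga = np.einsum("nq,nqj->j", p, g_loga)
    # difficulty thresholds: reduce the node axis, then scatter by observed category
    Blo = np.einsum("nq,nqj->nj", p, np.where(lo_fin, f_lo, 0.0) * (-arrays.a))
    Bhi = np.einsum("nq,nqj->nj", p, np.where(hi_fin, f_hi, 0.0) * (-arrays.a))
    J = arrays.n_items
    kmax = arrays.kmax
    gb = np.zeros((J, kmax))
    jj = np.broadcast_to(np.arange(J), scores.shape)
    lo_thr = scores - 1
    ok = lo_thr >= 0
    np.add.at(gb, (jj[ok], lo_thr[ok]), Blo[ok])
    ok = scores < layout.K
    np.add.at(gb, (jj[ok], scores[ok]), Bhi[ok])
    for j, sl in enumerate(layout.item_slices):
        K = layout.K[j]
        gbj = gb[j, :K]
        grad[sl.start] = ga[j]
        # b_k = b_1 + sum_{i<=k} delta_i: accumulate tail sums
        tail = np.cumsum(gbj[::-1])[::-1]
        grad[sl.start + 1] = tail[0]
        if K > 1:
            deltas = np.exp(x[sl.start + 2: sl.start + 1 + K])
            grad[sl.start + 2: sl.start + 1 + K] = deltas * tail[1:]
    # class parameters
    for c in range(layout.n_classes):
        sel = cls == c + 1
        if not sel.any():
            continue
        pc = p[sel]
        if scheme == "gh":
            D = g_th[sel].sum(axis=-1)
            dev = theta[sel] - mu_all[c + 1]
            gmu = np.sum(pc * D)
            gls = np.sum(pc * D * dev)
        else:
            s2 = sd_all[c + 1] ** 2
            dev = theta[sel] - mu_all[c + 1]
            gmu = np.sum(pc * dev / s2)
            gls = np.sum(pc * (dev ** 2 / s2 - 1.0))
        grad[layout.n_item_params + 2 * c] = gmu
        grad[layout.n_item_params + 2 * c + 1] = gls
    return ll, grad


def marginal_loglik(item_params, pop, occasions, scheme: str = "agh", n_nodes: int = 15,
                    post_grouping: str = "pooled") -> float:
    """Marginal log-likelihood of an occasion set under given parameters.

    ``pop`` is a :class:`PopulationDist` (pooled) or a sequence of them (one
    per post-baseline class).
    """
    occ = occasions if isinstance(occasions, OccasionData) else build_independent_occasions(occasions)
    pops = [pop] if isinstance(pop, PopulationDist) else list(pop)
    cls, n_classes = _class_index(occ, post_grouping)
    if len(pops) != n_classes:
        raise ValueError(f"need {n_classes} population distribution(s), got {len(pops)}")
    layout = _Layout([it.max_score for it in item_params], n_classes)
    x = layout.pack(item_params, pops)
    ll, _ = _mll(x, layout, occ.scores, cls, scheme, n_nodes, [it.item_id for it in item_params],
                 want_grad=False)
    if not np.isfinite(ll):
        raise FloatingPointError(f"non-finite marginal likelihood at parameters {x!r}")
    return ll


def _start_values(scores, K, item_ids=None):
    """a = 1, difficulties at empirical logit quantiles of cumulative frequencies."""
    items = []
    item_ids = item_ids or list(range(1, len(K) + 1))
    for j, Kj in enumerate(K):
        y = scores[:, j]
        p = np.array([(y >= k).mean() for k in range(1, Kj + 1)])
        p = np.clip(p, 0.005, 0.995)
        b = np.log((1 - p) / p)
        b = np.maximum.accumulate(b + 1e-6 * np.arange(Kj))
        b += 0.05 * np.arange(Kj)  # enforce strict increase
        items.append(grm.ItemParams(item_id=item_ids[j], a=1.0, b=b))
    return items


class GradedResponseIRT(TransformerMixin, BaseEstimator):
    """Graded-response-model estimator under the independent-occasion design.

    ``fit`` expects an :class:`ItemDataset` (or :class:`OccasionData`) and
    maximizes the quadrature-approximated marginal likelihood over all item
    discriminations/difficulties plus the post-baseline latent mean(s) and
    variance(s); the baseline class is fixed at N(0, 1).  ``transform``
    returns per-occasion empirical-Bayes latent estimates under a diffuse
    prior (variance ``prior_var``), reconciled to subject time courses.

    Parameters
    ----------
    n_quadrature : number of Gauss-Hermite nodes (1 with ``scheme="agh"``
        is a Laplace approximation).
    scheme : "agh" (adaptive, default) or "gh" (prior-centred).
    post_grouping : "pooled" shares one N(mu, omega^2) across all
        post-baseline occasions; "interval" estimates one per 4-week
        interval.
    """

    def __init__(self, n_quadrature: int = 15, scheme: str = "agh", post_grouping: str = "pooled",
                 max_iter: int = 500, gtol: float = 1e-5, ftol: float = 1e-9,
                 compute_se: bool = True, prior_var: float = 100.0, start_items=None):
        self.n_quadrature = n_quadrature
        self.scheme = scheme
        self.post_grouping = post_grouping
        self.max_iter = max_iter
        self.gtol = gtol
        self.ftol = ftol
        self.compute_se = compute_se
        self.prior_var = prior_var
        self.start_items = start_items

    # -- sklearn plumbing ---------------------------------------------------
    def _as_occasions(self, X) -> OccasionData:
        if isinstance(X, OccasionData):
            return X
        if isinstance(X, ItemDataset):
            return build_independent_occasions(X)
        raise TypeError("X must be an ItemDataset or OccasionData")

    def fit(self, X, y=None):
        occ = self._as_occasions(X)
        cls, n_classes = _class_index(occ, self.post_grouping)
        if len(np.unique(cls)) < 2:
            raise ValueError("need occasions from at least two occasion classes")
        item_ids = list(occ.item_ids)
        if occ.max_scores:
            K = list(occ.max_scores)
        else:
            K = [int(occ.scores[:, j].max(initial=1)) for j in range(occ.scores.shape[1])]
        for j, (iid, Kj) in enumerate(zip(item_ids, K)):
            counts = np.bincount(occ.scores[:, j], minlength=Kj + 1)
            if (counts == 0).any() or (counts > 0).sum() < 2:
                warnings.warn(
                    f"item {iid}: categories {np.flatnonzero(counts == 0).tolist()} never "
                    "observed; the item is degenerate and its parameters will drift to a "
                    "boundary", stacklevel=2)
        start = self.start_items or _start_values(occ.scores, K, item_ids)
        layout = _Layout([it.max_score for it in start], n_classes)
        x0 = layout.pack(start, [PopulationDist(0.0, 1.0)] * n_classes)
        cache = {"mode": None}

        def fun(x):
            ll, g = _mll(x, layout, occ.scores, cls, self.scheme, self.n_quadrature,
                         item_ids, want_grad=True, mode_cache=cache)
            if not np.isfinite(ll):
                return 1e15, np.zeros_like(x)
            return -ll, -g

        res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iter, "gtol": self.gtol, "ftol": self.ftol,
                                "maxcor": 20})
        a, b, mu, log_sd = layout.unpack(res.x)
        self.item_params_ = [
            grm.ItemParams(item_id=iid, a=a[j], b=b[j, : layout.K[j]].copy())
            for j, iid in enumerate(item_ids)
        ]
        self.pop_ = [PopulationDist(mu[c], float(np.exp(2 * log_sd[c]))) for c in range(n_classes)]
        self.pop_mu_ = np.array([p.mu for p in self.pop_])
        self.pop_omega2_ = np.array([p.omega2 for p in self.pop_])
        self.loglik_ = float(-res.fun)
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.message_ = str(res.message)
        self.layout_ = layout
        self.packed_ = res.x
        self.n_occasions_ = occ.n_occasions
        for it in self.item_params_:
            if not (0.05 < it.a < 30):
                warnings.warn(f"item {it.item_id}: discrimination {it.a:.3g} at boundary "
                              "(degenerate or non-discriminating item)", stacklevel=2)
        self.se_ = {}
        if self.compute_se and self.converged_:
            self._compute_se(occ, cls, item_ids, cache)
        return self

    def _compute_se(self, occ, cls, item_ids, cache):
        x = self.packed_
        layout = self.layout_
        h = 1e-4 * (1 + np.abs(x))
        n = x.size
        H = np.zeros((n, n))
        for i in range(n):
            xp = x.copy(); xp[i] += h[i]
            xm = x.copy(); xm[i] -= h[i]
            _, gp = _mll(xp, layout, occ.scores, cls, self.scheme, self.n_quadrature,
                         item_ids, want_grad=True, mode_cache=cache)
            _, gm = _mll(xm, layout, occ.scores, cls, self.scheme, self.n_quadrature,
                         item_ids, want_grad=True, mode_cache=cache)
            H[:, i] = (gm - gp) / (2 * h[i])  # Hessian of -loglik
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            self.se_ = {}
            self.message_ += "; information matrix singular, no SEs"
            return
        if np.any(np.diag(cov) <= 0):
            self.se_ = {}
            self.message_ += "; information matrix not positive definite, no SEs"
            return
        # delta method to the natural scale via the numerical jacobian of unpack
        nat0 = layout.natural(x)
        Jac = np.empty((nat0.size, n))
        for i in range(n):
            xp = x.copy(); xp[i] += h[i]
            xm = x.copy(); xm[i] -= h[i]
            Jac[:, i] = (layout.natural(xp) - layout.natural(xm)) / (2 * h[i])
        var_nat = np.einsum("pi,ij,pj->p", Jac, cov, Jac)
        names = layout.natural_names([it.item_id for it in self.item_params_])
        self.cov_packed_ = cov
        self.se_ = dict(zip(names, np.sqrt(np.maximum(var_nat, 0.0))))

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "item_params_"):
            raise AttributeError("estimator is not fitted")
        occ = self._as_occasions(X)
        return estimate_thetas(occ, self.item_params_, prior_var=self.prior_var)

    def score(self, X, y=None) -> float:
        occ = self._as_occasions(X)
        return marginal_loglik(self.item_params_, self.pop_, occ, scheme=self.scheme,
                               n_nodes=self.n_quadrature, post_grouping=self.post_grouping) / occ.n_occasions

    def result(self) -> IcfFitResult:
        return IcfFitResult(item_params=self.item_params_, pop=self.pop_, loglik=self.loglik_,
                            se=self.se_, converged=self.converged_, n_iter=self.n_iter_,
                            message=self.message_, n_occasions=self.n_occasions_)


def fit_icf(occasions, instrument: InstrumentSpec | None = None, **options) -> IcfFitResult:
    """Functional wrapper around :class:`GradedResponseIRT`."""
    est = GradedResponseIRT(**options)
    est.fit(occasions)
    return est.result()
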