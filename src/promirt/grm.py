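"""Graded response model mathematics.

An item *j* with ordered categories 0..K_j is described by a discrimination
``a_j > 0`` and strictly increasing difficulties ``b_j1 < ... < b_jK``.  The
cumulative model is logistic,

    P(y_j >= k | theta) = expit(a_j * (theta - b_jk)),

and category probabilities follow by differencing.  ``theta`` is the latent
disease status (higher = worse symptoms).  All evaluators here are
vectorized over theta and numerically stable for |a(theta-b)| up to the
floating-point overflow range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "ItemParams",
    "prob_at_least",
    "prob_exact",
    "expected_item_score",
    "expected_total_score",
    "simulate_item_responses",
    "TotalScoreMap",
    "item_params_to_json",
    "item_params_from_json",
]


@dataclass(frozen=True)
class ItemParams:
    """Discrimination and ordered difficulty parameters for one item."""

    item_id: int
    a: float
    b: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "b", b)
        if not self.a > 0:
            raise ValueError(f"item {self.item_id}: discrimination must be positive, got {self.a}")
        if b.ndim != 1 or b.size < 1:
            raise ValueError(f"item {self.item_id}: need a 1-D difficulty vector")
        if not np.all(np.diff(b) > 0):
            raise ValueError(f"item {self.item_id}: difficulties must be strictly increasing")

    @property
    def max_score(self) -> int:
        return self.b.size

    @property
    def n_categories(self) -> int:
        return self.b.size + 1


def item_params_to_json(items: list[ItemParams], path=None) -> str:
    payload = [{"item_id": it.item_id, "a": float(it.a), "b": [float(x) for x in it.b]} for it in items]
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def item_params_from_json(source) -> list[ItemParams]:
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("["):
            payload = json.loads(text)
        else:
            with open(text) as fh:
                payload = json.load(fh)
    return [ItemParams(item_id=d["item_id"], a=d["a"], b=np.asarray(d["b"], dtype=float)) for d in payload]


def _log_sigmoid(x):
    return -np.logaddexp(0.0, -x)


def _log1mexp(x):
    """log(1 - exp(x)) for x <= 0, stable near both ends."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < -0.6931471805599453
    with np.errstate(divide="ignore"):
        out[small] = np.log1p(-np.exp(x[small]))
        out[~small] = np.log(-np.expm1(x[~small]))
    return out


def prob_at_least(theta, a: float, b_k: float):
    """P(y >= k) for one threshold: the two-parameter logistic curve."""
    if not a > 0:
        raise ValueError("discrimination must be positive")
    return expit(a * (np.asarray(theta, dtype=float) - b_k))


def prob_exact(theta, item: ItemParams, k: int | None = None):
    """Category probabilities P(y = k | theta).

    With ``k=None`` returns an array with a trailing axis over all
    ``item.n_categories`` categories; otherwise that single category.
    """
    theta = np.asarray(theta, dtype=float)
    cum = expit(item.a * (theta[..., None] - item.b))  # (..., K)
    upper = np.concatenate([np.ones_like(theta)[..., None], cum], axis=-1)
    lower = np.concatenate([cum, np.zeros_like(theta)[..., None]], axis=-1)
    p = upper - lower
    if k is None:
        return p
    if not 0 <= k <= item.max_score:
        raise ValueError(f"category {k} outside 0..{item.max_score}")
    return p[..., k]


def expected_item_score(theta, item: ItemParams):
    """E[y | theta] = sum_k P(y >= k); strictly increasing in theta."""
    theta = np.asarray(theta, dtype=float)
    return expit(item.a * (theta[..., None] - item.b)).sum(axis=-1)


def expected_total_score(theta, items: list[ItemParams]):
    theta = np.asarray(theta, dtype=float)
    out = np.zeros(theta.shape, dtype=float)
    for it in items:
        out += expected_item_score(theta, it)
    return out


def simulate_item_responses(theta, items: list[ItemParams], rng: np.random.Generator):
    """Draw one ordinal response per item at each theta.

    theta has shape (n,); the result is an (n, n_items) integer array.  A
    single uniform per (subject, item) is compared against the decreasing
    cumulative curve, so the draw follows the exact category distribution.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    n = theta.size
    out = np.empty((n, len(items)), dtype=np.int64)
    for j, it in enumerate(items):
        cum = expit(it.a * (theta[:, None] - it.b))  # P(y>=k), decreasing in k
        u = rng.random((n, 1))
        out[:, j] = (u < cum).sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# Padded-array utilities shared by the likelihood code (icf / ebe modules).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemArrays:
    """Items packed into padded arrays: b is (J, Kmax) with +inf padding."""

    item_ids: tuple
    a: np.ndarray          # (J,)
    b: np.ndarray          # (J, Kmax), +inf beyond K_j
    n_thresholds: np.ndarray  # (J,)

    @property
    def n_items(self) -> int:
        return self.a.size

    @property
    def kmax(self) -> int:
        return self.b.shape[1]


def pack_items(items: list[ItemParams]) -> ItemArrays:
    kmax = max(it.max_score for it in items)
    b = np.full((len(items), kmax), np.inf)
    a = np.empty(len(items))
    K = np.empty(len(items), dtype=int)
    for j, it in enumerate(items):
        a[j] = it.a
        K[j] = it.max_score
        b[j, : it.max_score] = it.b
    return ItemArrays(tuple(it.item_id for it in items), a, b, K)


def _edges(scores, arrays: ItemArrays, theta):
    """z at the two thresholds bracketing each observed category.

    scores: (..., J) ints; theta broadcastable against scores[..., 0].
    Returns (z_lo, z_hi) with +inf / -inf at the open ends.
    """
    scores = np.asarray(scores)
    th = np.asarray(theta, dtype=float)[..., None]
    J = arrays.n_items
    jj = np.arange(J)
    b_ext = np.concatenate([np.full((J, 1), -np.inf), arrays.b], axis=1)  # b_ext[:, k] = b_k, b_0=-inf
    b_lo = b_ext[jj, scores]                       # b_{k}; -inf when k==0
    hi_idx = np.minimum(scores + 1, arrays.n_thresholds)
    b_hi = b_ext[jj, hi_idx]
    b_hi = np.where(scores >= arrays.n_thresholds, np.inf, b_hi)  # +inf when k==K
    with np.errstate(invalid="ignore"):
        z_lo = arrays.a * (th - b_lo)
        z_hi = arrays.a * (th - b_hi)
    z_lo = np.where(np.isinf(b_lo), np.inf, z_lo)
    z_hi = np.where(np.isinf(b_hi), -np.inf, z_hi)
    return z_lo, z_hi


def pattern_loglik(scores, arrays: ItemArrays, theta, order: int = 0):
    """Sum over items of log P(y_j | theta), optionally with theta-derivatives.

    scores: (N, J); theta: (N,) or (N, Q) (a node axis is appended before J).
    Returns ll, or (ll, d1), or (ll, d1, d2) summed over items; the category
    log-probability is evaluated in a cancellation-free three-term form.
    """
    scores = np.asarray(scores)
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == scores.ndim:  # (N, Q): broadcast items after node axis
        sc = scores[:, None, :]
    else:
        sc = scores
    z_lo, z_hi = _edges(sc, arrays, theta)
    with np.errstate(invalid="ignore"):
        gap = z_hi - z_lo
    gap = np.where(np.isinf(z_hi) | np.isinf(z_lo), -np.inf, gap)
    ll = (_log_sigmoid(z_lo) + _log_sigmoid(-z_hi) + _log1mexp(gap)).sum(axis=-1)
    if order == 0:
        return ll
    s_lo = expit(-z_lo)            # sigma(-z_lo); 0 at +inf
    s_hi = expit(z_hi)             # sigma(z_hi); 0 at -inf
    d1 = (arrays.a * (s_lo - s_hi)).sum(axis=-1)
    if order == 1:
        return ll, d1
    d2 = (-(arrays.a ** 2) * (s_lo * (1 - s_lo) + s_hi * (1 - s_hi))).sum(axis=-1)
    return ll, d1, d2


def affine_scale_alignment(items, reference_items):
    """Affine map between two latent-scale conventions of the same instrument.

    The latent scale is identified only up to an affine transform fixed by
    the anchoring convention, so two parameter sets for the same items are
    comparable only after alignment.  Regressing fitted difficulties on
    reference difficulties (b' ~ (b - m)/s) returns (s, m) such that
    theta_reference = s * theta_fitted + m.
    """
    b_ref = np.concatenate([it.b for it in reference_items])
    b_fit = np.concatenate([it.b for it in items])
    if b_ref.size != b_fit.size:
        raise ValueError("item sets have different threshold counts")
    slope, intercept = np.polyfit(b_ref, b_fit, 1)
    s = 1.0 / slope
    return float(s), float(-intercept * s)


class TotalScoreMap:
    """Tabulated bijection between theta and the expected total score.

    The forward map is the strictly increasing expected-total curve; the
    inverse is a monotone interpolation lookup on a dense theta grid.
    """

    def __init__(self, items: list[ItemParams], theta_lo=-6.0, theta_hi=6.0, step=0.01):
        self.grid = np.arange(theta_lo, theta_hi + step / 2, step)
        self.totals = expected_total_score(self.grid, items)
        self.max_total = float(sum(it.max_score for it in items))

    def theta_to_total(self, theta):
        return np.interp(np.asarray(theta, dtype=float), self.grid, self.totals)

    def total_to_theta(self, total):
        return np.interp(np.asarray(total, dtype=float), self.totals, self.grid)
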