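"""Samejima's graded response model: calibration and EAP trait scoring.

The graded response model (GRM) describes an ordered polytomous item by a
discrimination ``a`` and strictly increasing category thresholds
``b_1 < ... < b_{K-1}``; the cumulative probability of responding in
category ``k`` or higher is a two-parameter logistic curve,

    P(Y >= k | theta) = 1 / (1 + exp(-a * (theta - b_k))),

with ``P(Y >= 0) = 1`` and ``P(Y >= K) = 0``; category probabilities are
differences of adjacent cumulative curves.

Calibration is marginal maximum likelihood via EM over a fixed quadrature
grid (default 49 equally spaced points on [-4, 4] with standard-normal
weights), identifying the latent trait as N(0, 1).  During iterative DIF
purification, items already flagged with DIF receive separate parameters
per group while the remaining (anchor) items keep shared parameters, so the
trait metric is anchored by the DIF-free items.  Trait estimates are
expected a posteriori (EAP) scores — defined for every response pattern,
including perfect and empty-category ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from ._exceptions import ConvergenceError, DataError

__all__ = [
    "GRMItemParams",
    "GRMCalibration",
    "grm_cumulative_prob",
    "grm_category_probs",
    "fit_grm",
    "eap_score",
    "collapse_sparse_categories",
    "make_quadrature",
]


@dataclass(frozen=True)
class GRMItemParams:
    """Discrimination and ordered thresholds of one GRM item.

    ``group`` is set when the item is calibrated separately per group
    (purification of a DIF-flagged item); ``None`` for shared parameters.
    """

    item_id: str
    a: float
    b: tuple
    group: object = None

    def __post_init__(self):
        if not self.a > 0:
            raise DataError(f"item {self.item_id!r}: discrimination must be positive")
        b = np.asarray(self.b, dtype=float)
        if b.ndim != 1 or b.size < 1 or np.any(np.diff(b) <= 0):
            raise DataError(f"item {self.item_id!r}: thresholds must strictly increase")

    @property
    def n_categories(self):
        return len(self.b) + 1


def grm_cumulative_prob(theta, params: GRMItemParams, k: int):
    """P(Y >= k | theta) for category index ``k`` (1 <= k <= K-1)."""
    if not 1 <= k <= len(params.b):
        raise DataError(f"category index {k} out of range 1..{len(params.b)}")
    return expit(params.a * (np.asarray(theta, dtype=float) - params.b[k - 1]))


def grm_category_probs(theta, a, b):
    """Category probability matrix P(Y = k | theta), shape (len(theta), K).

    Rows sum to 1 by the telescoping construction P(Y=k) = P(Y>=k) - P(Y>=k+1).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(b, dtype=float)
    cum = expit(a * (theta[:, None] - b[None, :]))          # (Q, K-1)
    ones = np.ones((theta.size, 1))
    zeros = np.zeros((theta.size, 1))
    full = np.hstack([ones, cum, zeros])                     # (Q, K+1)
    return full[:, :-1] - full[:, 1:]


def make_quadrature(n_points: int = 49, half_range: float = 4.0):
    """Equally spaced quadrature grid with standard-normal weights.

    Weights are normal densities at the nodes, normalized to sum to one —
    the fixed-grid scheme common to GRM software.
    """
    nodes = np.linspace(-half_range, half_range, n_points)
    w = np.exp(-0.5 * nodes**2)
    return nodes, w / w.sum()


# --------------------------------------------------------------------------
# sparse-category handling


def collapse_sparse_categories(y, group01=None, min_count: int = 5):
    """Merge sparse response categories with a neighbor before fitting.

    Any observed category with fewer than ``min_count`` responses in either
    group is merged with its less extreme neighbor (ties toward the lower
    neighbor), repeatedly, until all remaining categories clear the minimum
    in both groups.  Unobserved categories are dropped by compaction.

    Returns
    -------
    (y_new, mapping)
        ``y_new`` — responses recoded to ``0..K'-1`` (NaN preserved);
        ``mapping`` — dict raw value -> collapsed index, for the log.
    """
    y = np.asarray(y, dtype=float)
    obs = y[~np.isnan(y)]
    if obs.size == 0:
        raise DataError("item has no observed responses")
    levels = [int(v) for v in np.unique(obs)]
    groups = (np.zeros(y.size, dtype=int) if group01 is None
              else np.asarray(group01, dtype=int))
    # each entry of `blocks` is the list of raw levels merged together
    blocks = [[lv] for lv in levels]

    def block_min_count(block):
        mask = np.isin(y, block)
        return min(int(np.sum(mask & (groups == g) & ~np.isnan(y)))
                   for g in np.unique(groups))

    while len(blocks) > 1:
        counts = [block_min_count(bl) for bl in blocks]
        short = [i for i, c in enumerate(counts) if c < min_count]
        if not short:
            break
        i = short[0]
        j = i - 1 if i > 0 else i + 1
        lo, hi = sorted((i, j))
        blocks[lo] = blocks[lo] + blocks[hi]
        del blocks[hi]
    if len(blocks) < 2:
        raise DataError("fewer than 2 categories remain after collapsing")
    mapping = {}
    for new, bl in enumerate(blocks):
        for lv in bl:
            mapping[lv] = new
    y_new = y.copy()
    mask = ~np.isnan(y)
    y_new[mask] = [mapping[int(v)] for v in y[mask]]
    return y_new, mapping


# --------------------------------------------------------------------------
# calibration


@dataclass
class GRMCalibration:
    """Result of a GRM marginal-maximum-likelihood fit.

    ``params[item_id]`` is a :class:`GRMItemParams` for anchor items or a
    dict ``{group_label: GRMItemParams}`` for items calibrated per group.
    """

    item_ids: list
    params: dict
    loglik_trajectory: list
    converged: bool
    n_iter: int
    quad_nodes: np.ndarray
    quad_weights: np.ndarray
    category_maps: dict = field(default_factory=dict)

    @property
    def loglik(self):
        return self.loglik_trajectory[-1]

    def item_probs(self, item_id, group=None):
        """(Q, K) category probabilities on the quadrature grid."""
        p = self.params[item_id]
        if isinstance(p, dict):
            p = p[group]
        return grm_category_probs(self.quad_nodes, p.a, p.b)

    def to_frame(self):
        import pandas as pd

        rows = []
        for iid in self.item_ids:
            p = self.params[iid]
            entries = p.values() if isinstance(p, dict) else [p]
            for e in entries:
                rows.append({"item_id": iid, "group": e.group, "a": e.a,
                             **{f"b_{k + 1}": v for k, v in enumerate(e.b)}})
        return pd.DataFrame(rows)


def _item_loglik_tables(y, probs_by_group, groups, group_levels):
    """(n, Q) total log-likelihood matrix across items."""
    n, Q = y.shape[0], probs_by_group[group_levels[0]][0].shape[0]
    logL = np.zeros((n, Q))
    for gi, g in enumerate(group_levels):
        rows = np.flatnonzero(groups == g)
        if rows.size == 0:
            continue
        acc = np.zeros((rows.size, Q))
        for j, logp in enumerate(probs_by_group[g]):
            yj = y[rows, j]
            ok = ~np.isnan(yj)
            acc[ok] += logp[:, yj[ok].astype(int)].T
        logL[rows] = acc
    return logL


def _neg_q_and_grad(x, theta, r):
    """Negative expected complete-data log-likelihood for one item + gradient.

    ``x`` = [log a, b_1, log(b_2-b_1), ...]; ``r`` is the (Q, K) expected
    count table from the E-step.
    """
    K = r.shape[1]
    a = np.exp(x[0])
    b = np.empty(K - 1)
    b[0] = x[1]
    if K > 2:
        b[1:] = x[1] + np.cumsum(np.exp(x[2:]))
    cum = expit(a * (theta[:, None] - b[None, :]))            # (Q, K-1)
    dcum = cum * (1 - cum)
    p = np.hstack([np.ones((theta.size, 1)), cum]) - np.hstack([cum, np.zeros((theta.size, 1))])
    p = np.clip(p, 1e-12, None)
    f = -np.sum(r * np.log(p))
    w = r / p                                                  # (Q, K)
    # dP_k/dc_j: +1 for k=j, -1 for k=j-1  (c_j = cum[:, j-1])
    dc = w[:, 1:] - w[:, :-1]                                  # coeff of dcum_j
    grad_a = -np.sum(dc * dcum * (theta[:, None] - b[None, :])) * a
    grad_b = np.sum(dc * dcum, axis=0) * a                     # (K-1,)
    grad = np.empty_like(x)
    grad[0] = grad_a
    grad[1] = grad_b.sum()
    if K > 2:
        grad[2:] = np.exp(x[2:]) * np.cumsum(grad_b[::-1])[::-1][1:]
    return f, grad


def _pack(a, b):
    b = np.asarray(b, dtype=float)
    x = np.empty(1 + b.size)
    x[0] = np.log(a)
    x[1] = b[0]
    if b.size > 1:
        x[2:] = np.log(np.diff(b))
    return x


def _unpack(x):
    a = float(np.exp(x[0]))
    b = np.empty(x.size - 1)
    b[0] = x[1]
    if b.size > 1:
        b[1:] = x[1] + np.cumsum(np.exp(x[2:]))
    return a, b


def _start_values(yj, K):
    """a=1, thresholds at the normal quantiles of cumulative frequencies."""
    from scipy.stats import norm

    obs = yj[~np.isnan(yj)].astype(int)
    freq = np.bincount(obs, minlength=K) + 0.5
    cumfrac = np.cumsum(freq)[:-1] / freq.sum()
    b = norm.ppf(cumfrac)
    b = np.maximum.accumulate(b + 1e-6 * np.arange(K - 1))
    return 1.0, b


def fit_grm(y, item_ids, groups=None, dif_items=(), *, n_quad: int = 49,
            quad_range: float = 4.0, tol: float = 1e-4, max_iter: int = 500,
            min_category_count: int = 5):
    """Calibrate the GRM by EM marginal maximum likelihood.

    Parameters
    ----------
    y : ndarray (n, J)
        Item responses, NaN = missing.  Sparse categories are collapsed per
        item (fewer than ``min_category_count`` responses in either group)
        before fitting; the mapping is recorded on the calibration.
    item_ids : sequence of str
    groups : array-like or None
        Group label per respondent; required when ``dif_items`` is nonempty.
    dif_items : iterable of item_id
        Items given separate parameters per group (DIF purification); all
        other items share one parameter set across groups.
    tol, max_iter
        EM stops when the max absolute parameter change drops below ``tol``;
        exceeding ``max_iter`` raises :class:`ConvergenceError` carrying the
        log-likelihood trajectory.

    Returns
    -------
    (GRMCalibration, ndarray)
        The calibration and the responses in collapsed category coding
        (feed these to :func:`eap_score` and the per-item DIF tests).
    """
    y = np.asarray(y, dtype=float)
    n, J = y.shape
    if J < 2:
        raise DataError("GRM calibration needs at least 2 items")
    item_ids = list(item_ids)
    dif_items = set(dif_items)
    groups = (np.zeros(n, dtype=int) if groups is None
              else np.asarray(groups))
    group_levels = list(np.unique(groups))
    if dif_items and len(group_levels) != 2:
        raise DataError("group-specific calibration needs exactly two groups")

    # collapse sparse categories once, on the pooled two-group table
    y_c = np.empty_like(y)
    cat_maps = {}
    K_item = []
    for j, iid in enumerate(item_ids):
        y_c[:, j], cat_maps[iid] = collapse_sparse_categories(
            y[:, j], groups if len(group_levels) > 1 else None, min_category_count
        )
        K_item.append(int(np.nanmax(y_c[:, j])) + 1)

    nodes, weights = make_quadrature(n_quad, quad_range)
    Q = nodes.size

    # parameter store: item -> {group or None: (a, b)}
    est = {}
    for j, iid in enumerate(item_ids):
        a0, b0 = _start_values(y_c[:, j], K_item[j])
        if iid in dif_items:
            est[iid] = {g: (a0, b0.copy()) for g in group_levels}
        else:
            est[iid] = {None: (a0, b0.copy())}

    onehot = {}
    for j in range(J):
        yj = y_c[:, j]
        oh = np.zeros((n, K_item[j]))
        ok = ~np.isnan(yj)
        oh[np.flatnonzero(ok), yj[ok].astype(int)] = 1.0
        onehot[j] = oh

    log_w = np.log(weights)
    trajectory = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step -----------------------------------------------------------
        probs_by_group = {}
        for g in group_levels:
            tables = []
            for iid in item_ids:
                a_g, b_g = est[iid][None] if None in est[iid] else est[iid][g]
                tables.append(np.log(np.clip(
                    grm_category_probs(nodes, a_g, b_g), 1e-12, None)))
            probs_by_group[g] = tables
        logL = _item_loglik_tables(y_c, probs_by_group, groups, group_levels)
        log_post = logL + log_w[None, :]
        ll = float(np.sum(logsumexp(log_post, axis=1)))
        trajectory.append(ll)
        post = np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))

        # M-step -----------------------------------------------------------
        max_change = 0.0
        for j, iid in enumerate(item_ids):
            for g in list(est[iid]):
                rows = slice(None) if g is None else np.flatnonzero(groups == g)
                r = post[rows].T @ onehot[j][rows]             # (Q, K)
                a_old, b_old = est[iid][g]
                x0 = _pack(a_old, b_old)
                res = minimize(_neg_q_and_grad, x0, args=(nodes, r),
                               jac=True, method="L-BFGS-B",
                               options={"maxiter": 200, "ftol": 1e-10})
                a_new, b_new = _unpack(res.x)
                a_new = min(max(a_new, 1e-3), 50.0)
                est[iid][g] = (a_new, b_new)
                max_change = max(max_change,
                                 abs(a_new - a_old),
                                 float(np.max(np.abs(b_new - b_old))))
        if max_change < tol:
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"GRM EM did not converge in {max_iter} iterations "
            f"(last max parameter change above {tol})", trajectory
        )

    params = {}
    for iid in item_ids:
        if None in est[iid]:
            a, b = est[iid][None]
            params[iid] = GRMItemParams(iid, a, tuple(b))
        else:
            params[iid] = {g: GRMItemParams(iid, est[iid][g][0],
                                            tuple(est[iid][g][1]), group=g)
                           for g in est[iid]}
    return GRMCalibration(item_ids, params, trajectory, converged, it,
                          nodes, weights, cat_maps), y_c


def eap_score(y, calibration: GRMCalibration, groups=None):
    """Expected-a-posteriori trait estimates under a N(0,1) prior.

    ``y`` uses the calibration's collapsed category coding.  Missing items
    contribute nothing to the likelihood; the posterior SD is below 1 as
    soon as one item is answered (shrinkage).

    Returns
    -------
    (theta, posterior_sd) : ndarray, ndarray
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = y.shape[0]
    groups = np.zeros(n, dtype=int) if groups is None else np.asarray(groups)
    nodes, weights = calibration.quad_nodes, calibration.quad_weights
    group_levels = list(np.unique(groups))
    probs_by_group = {}
    for g in group_levels:
        tables = []
        for iid in calibration.item_ids:
            p = calibration.params[iid]
            p = p[g] if isinstance(p, dict) else p
            tables.append(np.log(np.clip(
                grm_category_probs(nodes, p.a, p.b), 1e-12, None)))
        probs_by_group[g] = tables
    logL = _item_loglik_tables(y, probs_by_group, groups, group_levels)
    log_post = logL + np.log(weights)[None, :]
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    theta = post @ nodes
    var = post @ (nodes**2) - theta**2
    return theta, np.sqrt(np.clip(var, 0.0, None))
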