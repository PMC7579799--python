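"""Proportional-odds models and per-item DIF statistics.

Three nested cumulative-logit models are fitted to each item, matching on
the IRT trait estimate:

    Model 1:  logit P(Y >= k) = alpha_k + beta1 * trait
    Model 2:  logit P(Y >= k) = alpha_k + beta1 * trait + beta2 * group
    Model 3:  logit P(Y >= k) = alpha_k + beta1 * trait + beta2 * group
                                        + beta3 * trait * group

Uniform DIF is tested by the likelihood-ratio comparison of Models 1 and 2
(beta2 != 0), non-uniform DIF by Models 2 and 3 (beta3 != 0); twice the
log-likelihood difference is referred to chi-square with one degree of
freedom.  DIF magnitude is quantified by the McFadden pseudo-R^2 difference
between adjacent models and by the Crane–van Belle–Larson proportionate
change of the trait coefficient, |beta1(M1) - beta1(M2)| / |beta1(M1)|.

Sign convention: the group indicator codes the focal (second) label as 1,
so beta2 > 0 means the focal group endorses higher response categories than
the reference group at equal trait.

The fitter is a quasi-Newton maximizer of the multinomial log-likelihood
with analytic gradient; the intercepts are reparameterized (alpha_1 free,
decrements log-transformed) so the cumulative probabilities stay ordered.
The intercept-only null model has a closed-form solution (empirical
cumulative log-odds) used directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2

from ._exceptions import DataError, FitError

__all__ = [
    "OLRFit",
    "DIFResultRow",
    "fit_polr",
    "fit_null_polr",
    "lrt_chi2",
    "mcfadden_delta_r2",
    "cvbl_delta_beta1",
    "classify_item",
    "dif_statistics",
]


@dataclass(frozen=True)
class OLRFit:
    """One fitted cumulative-logit model for a single item."""

    model_id: int                 # 0 = intercept-only null, 1..3 per above
    alpha: tuple                  # intercepts, one per cumulative split (k >= 1)
    beta1: float | None = None    # trait effect
    beta2: float | None = None    # group effect
    beta3: float | None = None    # trait x group interaction
    loglik: float = np.nan
    converged: bool = True
    n_obs: int = 0

    @property
    def coefs(self):
        return tuple(b for b in (self.beta1, self.beta2, self.beta3) if b is not None)


@dataclass
class DIFResultRow:
    """Per-item DIF statistics and classification — one table row.

    Thresholds are either the nominal alpha (analytic mode; statistic
    thresholds infinite, i.e. descriptive) or Monte-Carlo empirical values.
    """

    item_id: str
    p_uniform: float
    p_nonuniform: float
    delta_r2_uniform: float
    delta_r2_nonuniform: float
    delta_beta1: float
    thr_p_uniform: float
    thr_p_nonuniform: float
    thr_dr2_uniform: float
    thr_dr2_nonuniform: float
    thr_dbeta1: float
    flag: str = "none"                  # none | uniform | nonuniform
    practically_important: bool = False
    beta2: float = np.nan               # Model-2 group effect (signed)
    beta2_sign: int = 0
    chi2_uniform: float = np.nan
    chi2_nonuniform: float = np.nan


def _design(trait, group01, model_id):
    if model_id == 0:
        return np.empty((len(trait), 0))
    cols = [np.asarray(trait, dtype=float)]
    if model_id >= 2:
        cols.append(np.asarray(group01, dtype=float))
    if model_id >= 3:
        cols.append(cols[0] * cols[1])
    return np.column_stack(cols)


def _nll_and_grad(x, X, onehot):
    """Negative log-likelihood and gradient under the >=-parameterization.

    ``x`` = [alpha_1, log decrements (K-2), betas]; eta_k = alpha_k + X b;
    P(Y>=k) = sigmoid(eta_k), alpha_k strictly decreasing in k.
    """
    n, K = onehot.shape
    p_cov = X.shape[1]
    n_alpha = K - 1
    alpha = np.empty(n_alpha)
    alpha[0] = x[0]
    if n_alpha > 1:
        alpha[1:] = x[0] - np.cumsum(np.exp(x[1:n_alpha]))
    beta = x[n_alpha:]
    eta = alpha[None, :] + (X @ beta)[:, None]             # (n, K-1)
    c = expit(eta)
    dcdeta = c * (1 - c)
    p = np.hstack([np.ones((n, 1)), c]) - np.hstack([c, np.zeros((n, 1))])
    p = np.clip(p, 1e-12, None)
    f = -np.sum(onehot * np.log(p))
    w = onehot / p
    # df/d eta_k  (threshold k):  dcdeta_k * (w_{k-1} - w_k)
    deta = dcdeta * (w[:, :-1] - w[:, 1:])
    # -- grad wrt alpha_k then chain to reparameterization
    g_alpha = deta.sum(axis=0)
    grad = np.empty_like(x)
    grad[0] = g_alpha.sum()
    if n_alpha > 1:
        suffix = np.cumsum(g_alpha[::-1])[::-1]            # sum_{j>=k} g_alpha[j]
        grad[1:n_alpha] = -np.exp(x[1:n_alpha]) * suffix[1:]
    if p_cov:
        grad[n_alpha:] = X.T @ deta.sum(axis=1)
    return f, grad


def _nll_grad_hess(alpha, beta, X, onehot, want_hess=True):
    """NLL, gradient and Hessian in the direct (alpha, beta) coordinates.

    Per observation only the two cumulative curves adjacent to the observed
    category enter the likelihood, so the Hessian accumulates category by
    category.  Returns (f, grad, hess) with hess=None when not requested.
    """
    n, K = onehot.shape
    nA = K - 1
    p_cov = X.shape[1]
    eta = alpha[None, :] + (X @ beta)[:, None] if p_cov else \
        np.broadcast_to(alpha, (n, nA)).copy()
    c = expit(eta)
    dc = c * (1 - c)
    d2c = dc * (1 - 2 * c)
    probs = np.hstack([np.ones((n, 1)), c]) - np.hstack([c, np.zeros((n, 1))])
    y_idx = onehot.argmax(axis=1)
    p_obs = probs[np.arange(n), y_idx]
    if np.any(p_obs <= 0):
        return np.inf, None, None
    f = -np.sum(np.log(p_obs))

    dim = nA + p_cov
    grad = np.zeros(dim)
    hess = np.zeros((dim, dim)) if want_hess else None
    rows = np.arange(n)
    for v in range(K):
        sel = y_idx == v
        if not np.any(sel):
            continue
        p = p_obs[sel]
        k1 = v - 1 if v >= 1 else None          # 0-based threshold index (c_v)
        k2 = v if v <= K - 2 else None          # c_{v+1}
        q1 = dc[sel, k1] if k1 is not None else None    # dp/deta_{k1} (s=+1)
        q2 = -dc[sel, k2] if k2 is not None else None   # dp/deta_{k2} (s=-1)
        Xs = X[sel] if p_cov else None
        # gradient: df/deta_k = -q_k / p
        if k1 is not None:
            g1 = -q1 / p
            grad[k1] += g1.sum()
            if p_cov:
                grad[nA:] += Xs.T @ g1
        if k2 is not None:
            g2 = -q2 / p
            grad[k2] += g2.sum()
            if p_cov:
                grad[nA:] += Xs.T @ g2
        if not want_hess:
            continue
        # second derivatives
        a11 = a22 = a12 = None
        if k1 is not None:
            a11 = q1 * q1 / p**2 - d2c[sel, k1] / p
        if k2 is not None:
            a22 = q2 * q2 / p**2 - (-d2c[sel, k2]) / p
        if k1 is not None and k2 is not None:
            a12 = q1 * q2 / p**2
        if k1 is not None:
            hess[k1, k1] += a11.sum()
        if k2 is not None:
            hess[k2, k2] += a22.sum()
        if a12 is not None:
            hess[k1, k2] += a12.sum()
            hess[k2, k1] += a12.sum()
        if p_cov:
            srow = np.zeros(sel.sum())
            if a11 is not None:
                srow += a11
            if a22 is not None:
                srow += a22
            if a12 is not None:
                srow += 2 * a12
            hb = Xs.T @ (srow[:, None] * Xs)
            hess[nA:, nA:] += hb
            if k1 is not None:
                row = a11 + (a12 if a12 is not None else 0)
                hess[k1, nA:] += Xs.T @ row
                hess[nA:, k1] += Xs.T @ row
            if k2 is not None:
                row = a22 + (a12 if a12 is not None else 0)
                hess[k2, nA:] += Xs.T @ row
                hess[nA:, k2] += Xs.T @ row
    return f, grad, hess


def _newton_polr(X, onehot, alpha0, beta0, max_iter=50, gtol=1e-8):
    """Damped Newton maximization; returns (alpha, beta, loglik) or None."""
    nA = onehot.shape[1] - 1
    alpha = alpha0.copy()
    beta = beta0.copy()
    f, grad, hess = _nll_grad_hess(alpha, beta, X, onehot)
    if not np.isfinite(f):
        return None
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < gtol:
            break
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(hess.shape[0]), grad)
        except np.linalg.LinAlgError:
            return None
        scale = 1.0
        for _half in range(30):
            a_new = alpha - scale * step[:nA]
            b_new = beta - scale * step[nA:]
            f_new, g_new, h_new = _nll_grad_hess(a_new, b_new, X, onehot)
            if np.isfinite(f_new) and f_new <= f + 1e-12:
                alpha, beta, f, grad, hess = a_new, b_new, f_new, g_new, h_new
                break
            scale *= 0.5
        else:
            return None
    else:
        if np.max(np.abs(grad)) > 1e-4:
            return None
    if np.any(np.diff(alpha) >= 0):
        return None
    return alpha, beta, f


def fit_null_polr(y):
    """Closed-form intercept-only cumulative-logit fit (exact ML).

    The fitted alpha_k are the empirical cumulative log-odds of P(Y >= k);
    the log-likelihood is the saturated multinomial value over categories.
    """
    y = np.asarray(y, dtype=float)
    y = y[~np.isnan(y)].astype(int)
    K = int(y.max()) + 1
    counts = np.bincount(y, minlength=K).astype(float)
    if np.count_nonzero(counts) < 2:
        raise DataError("item has fewer than 2 observed categories")
    n = counts.sum()
    tail = np.cumsum(counts[::-1])[::-1]                   # n * P(Y >= k)
    with np.errstate(divide="ignore"):
        alpha = np.log(tail[1:]) - np.log(n - tail[1:])
    pk = counts / n
    ll = float(np.sum(counts[counts > 0] * np.log(pk[counts > 0])))
    return OLRFit(model_id=0, alpha=tuple(alpha), loglik=ll, n_obs=int(n))


def fit_polr(y, trait, group01=None, model_id: int = 1, start=None) -> OLRFit:
    """Maximum-likelihood proportional-odds fit of Model 1, 2 or 3.

    ``y`` must show at least two observed levels (values are compacted to
    consecutive integers internally); observations with missing ``y`` are
    dropped.  The primary solver is a damped Newton iteration on the exact
    Hessian; a quasi-Newton run in the monotone-intercept parameterization
    is the fallback.  ``start=(alpha, beta_partial)`` warm-starts from a
    smaller nested model.  Raises :class:`FitError` on non-convergence or a
    degenerate (separated) fit.
    """
    y = np.asarray(y, dtype=float)
    trait = np.asarray(trait, dtype=float)
    keep = ~np.isnan(y)
    y, trait = y[keep], trait[keep]
    group01 = None if group01 is None else np.asarray(group01)[keep]
    if model_id >= 2:
        if group01 is None:
            raise DataError("Models 2 and 3 need the group indicator")
        if len(np.unique(group01)) < 2:
            raise DataError("group indicator must contain both levels")
    levels = np.unique(y)
    if levels.size < 2:
        raise DataError("response needs >= 2 observed levels")
    y = np.searchsorted(levels, y)
    K = levels.size
    n = y.size
    onehot = np.zeros((n, K))
    onehot[np.arange(n), y.astype(int)] = 1.0

    X = _design(trait, group01, model_id)
    n_alpha = K - 1
    if start is not None:
        alpha0 = np.asarray(start[0], dtype=float).copy()
        beta0 = np.zeros(X.shape[1])
        b_prev = np.asarray(start[1], dtype=float)
        beta0[:b_prev.size] = b_prev
    else:
        null = fit_null_polr(y)
        alpha0 = np.asarray(null.alpha, dtype=float)
        beta0 = np.zeros(X.shape[1])

    sol = _newton_polr(X, onehot, alpha0, beta0)
    if sol is not None:
        alpha, betas, nll = sol
    else:
        x0 = np.zeros(n_alpha + X.shape[1])
        x0[0] = alpha0[0]
        if n_alpha > 1:
            x0[1:n_alpha] = np.log(np.clip(-np.diff(alpha0), 1e-3, None))
        x0[n_alpha:] = beta0
        res = minimize(_nll_and_grad, x0, args=(X, onehot), jac=True,
                       method="BFGS", options={"maxiter": 500, "gtol": 1e-7})
        if not np.isfinite(res.fun):
            raise FitError(f"model {model_id}: non-finite likelihood "
                           "(separation?)")
        # BFGS may report line-search stalls at the optimum; accept small grad
        if not res.success and np.max(np.abs(res.jac)) > 1e-3:
            raise FitError(f"model {model_id}: optimizer did not converge "
                           f"(|grad|={np.max(np.abs(res.jac)):.2e})")
        alpha = np.empty(n_alpha)
        alpha[0] = res.x[0]
        if n_alpha > 1:
            alpha[1:] = res.x[0] - np.cumsum(np.exp(res.x[1:n_alpha]))
        betas = res.x[n_alpha:]
        nll = res.fun
    kw = {}
    if model_id >= 1 and betas.size:
        kw["beta1"] = float(betas[0])
    if model_id >= 2:
        kw["beta2"] = float(betas[1])
    if model_id >= 3:
        kw["beta3"] = float(betas[2])
    return OLRFit(model_id=model_id, alpha=tuple(alpha), loglik=float(-nll),
                  converged=True, n_obs=n, **kw)


def lrt_chi2(small: OLRFit, big: OLRFit):
    """Likelihood-ratio test of two nested fits, chi-square df = 1."""
    stat = 2.0 * (big.loglik - small.loglik)
    if stat < -1e-6:
        raise FitError(f"negative LRT statistic {stat:.3g}: fits inconsistent")
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df=1))


def mcfadden_delta_r2(small: OLRFit, big: OLRFit, null: OLRFit):
    """McFadden pseudo-R^2 difference between two nested fits.

    R^2 = 1 - loglik(model)/loglik(null); the difference reduces to
    (loglik_small - loglik_big) / loglik_null >= 0.
    """
    if null.loglik == 0:
        raise DataError("degenerate one-category data: null log-likelihood is 0")
    return (small.loglik - big.loglik) / null.loglik


def cvbl_delta_beta1(m1: OLRFit, m2: OLRFit):
    """Crane–van Belle–Larson proportionate change of the trait coefficient.

    |beta1(M1) - beta1(M2)| / |beta1(M1)|; NaN when beta1(M1) is zero.
    """
    if m1.beta1 == 0:
        return float("nan")
    return abs((m1.beta1 - m2.beta1) / m1.beta1)


def classify_item(row: DIFResultRow) -> DIFResultRow:
    """Apply the flagging rules to a computed statistics row (in place).

    Non-uniform DIF takes precedence: an item significant on both tests is
    classified non-uniform (uniform subsumed).  ``practically_important``
    holds when the flagged comparison's delta-R^2 exceeds its threshold;
    uniform flags additionally report the CvBL delta-beta1 against its own
    threshold via ``delta_beta1`` / ``thr_dbeta1`` (descriptive).
    """
    if row.p_nonuniform < row.thr_p_nonuniform:
        row.flag = "nonuniform"
        row.practically_important = row.delta_r2_nonuniform > row.thr_dr2_nonuniform
    elif row.p_uniform < row.thr_p_uniform:
        row.flag = "uniform"
        row.practically_important = row.delta_r2_uniform > row.thr_dr2_uniform
    else:
        row.flag = "none"
        row.practically_important = False
    return row


def dif_statistics(item_id, y, trait, group01, thresholds=None,
                   alpha: float = 0.01) -> DIFResultRow:
    """Fit Models 0–3 to one item and assemble its classified result row.

    ``thresholds`` — mapping with keys ``p_uniform``, ``p_nonuniform``,
    ``dr2_uniform``, ``dr2_nonuniform``, ``dbeta1`` (a Monte-Carlo
    empirical-threshold row); when absent, the nominal ``alpha`` is used for
    both p-value tests and the magnitude thresholds are infinite
    (descriptive only).
    """
    null = fit_null_polr(y[~np.isnan(y)])
    m1 = fit_polr(y, trait, group01, model_id=1)
    m2 = fit_polr(y, trait, group01, model_id=2, start=(m1.alpha, m1.coefs))
    m3 = fit_polr(y, trait, group01, model_id=3, start=(m2.alpha, m2.coefs))
    chi_u, p_u = lrt_chi2(m1, m2)
    chi_nu, p_nu = lrt_chi2(m2, m3)
    if thresholds is None:
        thr = dict(p_uniform=alpha, p_nonuniform=alpha,
                   dr2_uniform=np.inf, dr2_nonuniform=np.inf, dbeta1=np.inf)
    else:
        thr = thresholds
    row = DIFResultRow(
        item_id=item_id,
        p_uniform=p_u,
        p_nonuniform=p_nu,
        delta_r2_uniform=mcfadden_delta_r2(m1, m2, null),
        delta_r2_nonuniform=mcfadden_delta_r2(m2, m3, null),
        delta_beta1=cvbl_delta_beta1(m1, m2),
        thr_p_uniform=float(thr["p_uniform"]),
        thr_p_nonuniform=float(thr["p_nonuniform"]),
        thr_dr2_uniform=float(thr["dr2_uniform"]),
        thr_dr2_nonuniform=float(thr["dr2_nonuniform"]),
        thr_dbeta1=float(thr["dbeta1"]),
        beta2=float(m2.beta2),
        beta2_sign=int(np.sign(m2.beta2)) if m2.beta2 else 0,
        chi2_uniform=chi_u,
        chi2_nonuniform=chi_nu,
    )
    return classify_item(row)
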