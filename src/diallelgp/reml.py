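"""Restricted maximum likelihood for dense multi-component mixed models.

Two solvers are provided:

* :func:`reml_grouped` — the two-component model y = Xb + Zu + e with a
  single grouping factor (blocks).  The marginal covariance is block-diagonal,
  so the variance ratio is profiled with per-group Sherman–Morrison closed
  forms; fast at field-trial scale.
* :func:`reml_ai` — general Sigma = sum_k s2_k K_k + s2_e I by average
  information updates with EM fallback steps; used for crossed random
  effects and genomic kinships.

Both return REML variance components, the GLS fixed-effect solution and the
restricted log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize


@dataclass
class RemlFit:
    varcomps: dict[str, float]
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    Sigma: np.ndarray | None = None  # marginal covariance at the optimum


def _check_design(y, X):
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.size:
        raise ValueError("X rows must match len(y)")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"fixed-effect design is rank deficient (rank {r} of "
            f"{X.shape[1]} columns)")
    return y, X


# ---------------------------------------------------------------------------
# grouped two-component model
# ---------------------------------------------------------------------------

def reml_grouped(y, X, groups, tol: float = 1e-10, max_iter: int = 200
                 ) -> RemlFit:
    """REML for y = Xb + (group effect) + e with iid group effects.

    The ratio gamma = s2_group / s2_e is profiled: for each group of size m,
    inv(I + gamma J) = I - gamma/(1 + gamma m) J, and s2_e has a closed-form
    maximizer given gamma.  ``max_iter`` bounds the scalar optimizer's
    function evaluations.
    """
    y, X = _check_design(y, X)
    n, p = X.shape
    codes, inv = np.unique(np.asarray(groups), return_inverse=True)
    members = [np.flatnonzero(inv == k) for k in range(codes.size)]

    def profile(log_gamma):
        gamma = np.exp(log_gamma)
        XtSiX = np.zeros((p, p))
        XtSiy = np.zeros(p)
        ytSiy = 0.0
        logdet = 0.0
        for idx in members:
            m = idx.size
            Xg, yg = X[idx], y[idx]
            c = gamma / (1.0 + gamma * m)
            sx = Xg.sum(axis=0)
            sy = yg.sum()
            XtSiX += Xg.T @ Xg - c * np.outer(sx, sx)
            XtSiy += Xg.T @ yg - c * sx * sy
            ytSiy += yg @ yg - c * sy * sy
            logdet += np.log1p(gamma * m)
        beta = np.linalg.solve(XtSiX, XtSiy)
        q = ytSiy - XtSiy @ beta
        s2e = q / (n - p)
        sign, ld_xx = np.linalg.slogdet(XtSiX)
        ll = -0.5 * ((n - p) * np.log(s2e) + logdet + ld_xx + (n - p))
        return ll, beta, s2e, gamma

    neg = lambda lg: -profile(lg)[0]
    res = optimize.minimize_scalar(neg, bounds=(np.log(1e-8), np.log(1e6)),
                                   method="bounded",
                                   options={"xatol": 1e-10,
                                            "maxiter": max_iter})
    ll, beta, s2e, gamma = profile(res.x)
    # boundary: gamma pinned at the lower bound means s2_group ~ 0
    s2g = gamma * s2e if gamma > 2e-8 else 0.0
    return RemlFit(varcomps={"sigma2_group": s2g, "sigma2_e": s2e},
                   beta=beta, loglik=float(ll), converged=bool(res.success),
                   n_iter=int(res.nfev))


# ---------------------------------------------------------------------------
# general AI-REML
# ---------------------------------------------------------------------------

def reml_ai(y, X, kernels: dict[str, np.ndarray], tol: float = 1e-8,
            max_iter: int = 200, verbose: bool = False) -> RemlFit:
    """Average-information REML for Sigma = sum_k s2_k K_k + s2_e I.

    ``kernels`` maps component names to n x n PSD matrices (residual identity
    is added automatically under the name ``sigma2_e``).  AI steps that leave
    the parameter space fall back to damped EM-style updates; components are
    clamped at a small positive floor and reported as 0 when pinned there.
    """
    y, X = _check_design(y, X)
    n, p = X.shape
    names = list(kernels)
    Ks = [np.asarray(kernels[k], dtype=float) for k in names]
    for k, K in zip(names, Ks):
        if K.shape != (n, n):
            raise ValueError(f"kernel {k!r} has shape {K.shape}, expected "
                             f"({n}, {n})")
    Ks.append(np.eye(n))
    names.append("sigma2_e")
    nk = len(Ks)

    vary = y.var()
    if vary == 0.0:
        raise ValueError("phenotype has zero variance")
    theta = np.full(nk, vary / nk)
    floor = 1e-8 * vary

    def restricted_ll(th):
        Sigma = sum(t * K for t, K in zip(th, Ks))
        cf = linalg.cho_factor(Sigma, lower=True)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        SiX = linalg.cho_solve(cf, X)
        Siy = linalg.cho_solve(cf, y)
        XtSiX = X.T @ SiX
        beta = np.linalg.solve(XtSiX, SiX.T @ y)
        Py = Siy - SiX @ np.linalg.solve(XtSiX, SiX.T @ y)
        sign, ld_xx = np.linalg.slogdet(XtSiX)
        ll = -0.5 * (logdet + ld_xx + y @ Py)
        return ll, beta, Py, cf, SiX, XtSiX

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, beta, Py, cf, SiX, XtSiX = restricted_ll(theta)
        # P M = Sigma^-1 M - Sigma^-1 X (X'Si X)^-1 X' Sigma^-1 M
        KPy = [K @ Py for K in Ks]
        PKPy = []
        for v in KPy:
            Siv = linalg.cho_solve(cf, v)
            PKPy.append(Siv - SiX @ np.linalg.solve(XtSiX, SiX.T @ v))
        yPKPy = np.array([Py @ v for v in KPy])
        tr_PK = np.empty(nk)
        XtSiX_inv = np.linalg.inv(XtSiX)
        for k, K in enumerate(Ks):
            SiK = linalg.cho_solve(cf, K)
            tr_PK[k] = np.trace(SiK) - np.einsum("ij,ji->", SiX.T @ K,
                                                 SiX @ XtSiX_inv)
        score = -0.5 * (tr_PK - yPKPy)
        AI = 0.5 * np.array([[KPy[a] @ PKPy[b] for b in range(nk)]
                             for a in range(nk)])
        # freeze components pinned at the floor with outward score
        pinned = (theta <= 2 * floor) & (score < 0)
        free = ~pinned
        delta = np.zeros(nk)
        if free.any():
            try:
                delta[free] = np.linalg.solve(AI[np.ix_(free, free)],
                                              score[free])
            except np.linalg.LinAlgError:
                delta[free] = (score * theta ** 2 / n)[free]
        # line search on the AI direction
        step, ll_new, new = 1.0, -np.inf, theta
        for _ in range(12):
            cand = np.maximum(theta + step * delta, floor)
            try:
                ll_cand = restricted_ll(cand)[0]
            except np.linalg.LinAlgError:
                ll_cand = -np.inf
            if ll_cand >= ll - 1e-10:
                new, ll_new = cand, ll_cand
                break
            step *= 0.5
        else:  # multiplicative EM-style fallback (score fixed point)
            ratio = np.where(tr_PK > 0, yPKPy / np.maximum(tr_PK, 1e-12), 1.0)
            cand = np.maximum(theta * np.clip(ratio, 0.1, 10.0), floor)
            cand[pinned] = floor
            new = cand
            ll_new = restricted_ll(new)[0]
        rel_change = np.max(np.abs(new - theta) / (np.abs(theta) + floor))
        if abs(ll_new - ll) < tol * (1.0 + abs(ll_new)) and rel_change < 1e-6:
            theta = new
            converged = True
            break
        theta = new
    ll, beta, Py, cf, SiX, XtSiX = restricted_ll(theta)
    out = {}
    for nm, t in zip(names, theta):
        out[nm] = 0.0 if t <= 2 * floor else float(t)
    if any(t <= 2 * floor for t in theta):
        warnings.warn("variance component estimated at the zero boundary")
    Sigma = sum(t * K for t, K in zip(theta, Ks))
    return RemlFit(varcomps=out, beta=beta, loglik=float(ll),
                   converged=converged, n_iter=it, Sigma=Sigma)


def reml_single_kernel(y, X, K, tol: float = 1e-10) -> RemlFit:
    """Exact REML for Sigma = s2_g K + s2_e I via the eigenbasis of K.

    Rotating by the eigenvectors of K diagonalizes Sigma, so the likelihood
    profile over the ratio s2_g/s2_e costs O(n^2) per evaluation.
    """
    y, X = _check_design(y, X)
    n, p = X.shape
    K = np.asarray(K, dtype=float)
    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def profile(log_ratio):
        ratio = np.exp(log_ratio)
        w = ratio * lam + 1.0  # Sigma = s2_e (ratio K + I)
        XtWX = (Xt / w[:, None]).T @ Xt
        XtWy = (Xt / w[:, None]).T @ yt
        beta = np.linalg.solve(XtWX, XtWy)
        resid_q = yt @ (yt / w) - XtWy @ beta
        s2e = resid_q / (n - p)
        sign, ld_xx = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * np.log(s2e) + np.log(w).sum() + ld_xx
                     + (n - p))
        return ll, beta, s2e, ratio

    neg = lambda lr: -profile(lr)[0]
    res = optimize.minimize_scalar(neg, bounds=(np.log(1e-8), np.log(1e8)),
                                   method="bounded", options={"xatol": 1e-10})
    ll, beta, s2e, ratio = profile(res.x)
    s2g = ratio * s2e if ratio > 2e-8 else 0.0
    Sigma = s2g * K + s2e * np.eye(n)
    return RemlFit(varcomps={"sigma2_g": float(s2g), "sigma2_e": float(s2e)},
                   beta=beta, loglik=float(ll), converged=bool(res.success),
                   n_iter=int(res.nfev), Sigma=Sigma)


def gls(y, X, Sigma) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed effects and their covariance under a known Sigma."""
    y, X = _check_design(y, X)
    cf = linalg.cho_factor(Sigma, lower=True)
    SiX = linalg.cho_solve(cf, X)
    XtSiX = X.T @ SiX
    beta = np.linalg.solve(XtSiX, SiX.T @ y)
    return beta, np.linalg.inv(XtSiX)
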