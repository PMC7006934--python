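"""Prediction of hybrid performance: MAS, GBLUP, RKHS, BayesB and
fixed-marker hybrids of them, with training-testing cross-validation.

Model menu (g = adjusted phenotype of hybrids):

* MAS        g = mu + M f + e          (f fixed; A, D or AD marker codings)
* BayesB     g = mu + Z b + e          (b spike-and-slab, Gibbs)
* GBLUP/RKHS g = mu + h + e            (h ~ N(0, s2_g G),  G = G_Z or a
                                        Gaussian kernel)
* MAS|GP     g = mu + M f + s + e      (s ~ N(0, s2_s G_W) from the
                                        non-significant markers only)

Two engines solve the kernel models: an exact REML/eigen path and a Gibbs
sampler with scaled-inverse-chi-square priors (degrees of freedom 5, scales
from the R2 rule).  Test-set genetic values follow the joint-model-with-
missing-responses convention: the conditional expectation given the training
records through the kernel.  Predictive ability is the Pearson correlation
of observed and predicted values on the held-out 25%, averaged over
replicated random splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix, grm_trace_norm, gaussian_kernel
from .reml import reml_single_kernel

METHODS = ("mas_a", "mas_d", "mas_ad", "bayesb", "gblup", "rkhs",
           "mas_gblup", "mas_rkhs")


# ---------------------------------------------------------------------------
# marker codings and the M/W partition
# ---------------------------------------------------------------------------

def additive_coding(dosages: np.ndarray) -> np.ndarray:
    """aa = -1, Aa = 0, AA = +1."""
    return np.asarray(dosages, dtype=float) - 1.0


def dominance_coding(dosages: np.ndarray) -> np.ndarray:
    """aa = 0, Aa = 1, AA = 0."""
    return (np.asarray(dosages) == 1).astype(float)


@dataclass
class MarkerPartition:
    """Split of the marker panel into significant (M) and complement (W)."""

    significant_ids: list[str]
    all_ids: np.ndarray

    def __post_init__(self) -> None:
        allset = set(self.all_ids)
        unknown = [m for m in self.significant_ids if m not in allset]
        if unknown:
            raise ValueError(f"significant markers not in panel: {unknown[:5]}")
        if len(set(self.significant_ids)) != len(self.significant_ids):
            raise ValueError("duplicate significant marker ids")

    @property
    def complement_ids(self) -> list[str]:
        sig = set(self.significant_ids)
        return [m for m in self.all_ids if m not in sig]

    @property
    def n_significant(self) -> int:
        return len(self.significant_ids)


@dataclass
class McmcConfig:
    """Gibbs-chain settings; defaults are full-run scale."""

    n_iter: int = 30_000
    burn_in: int = 5_000
    thin: int = 5
    r2_prior: float = 0.5
    df_prior: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def desk(cls, seed: int = 0) -> "McmcConfig":
        """Reduced chain for interactive work and tests."""
        return cls(n_iter=3_000, burn_in=500, thin=2, seed=seed)


@dataclass
class GPFit:
    method: str
    mu: float
    gebv: np.ndarray                    # one value per sample in the panel
    fixed_effects: np.ndarray | None = None   # f-hat for MAS terms
    marker_effects: np.ndarray | None = None  # b-hat (BayesB)
    genetic_values: np.ndarray | None = None  # h-hat / s-hat
    varcomps: dict = field(default_factory=dict)


@dataclass
class CVResult:
    method: str
    replicates: np.ndarray      # per-replicate Pearson r (NaN = undefined)
    n_reps: int
    train_frac: float

    @property
    def valid(self) -> np.ndarray:
        return self.replicates[np.isfinite(self.replicates)]

    @property
    def mean(self) -> float:
        return float(np.mean(self.valid)) if self.valid.size else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.valid, ddof=1)) if self.valid.size > 1 \
            else float("nan")

    @property
    def t_pvalue(self) -> float:
        """One-sample t-test of mean predictive ability against zero."""
        if self.valid.size < 2:
            return float("nan")
        return float(stats.ttest_1samp(self.valid, 0.0).pvalue)

    @property
    def not_different_from_zero(self) -> bool:
        p = self.t_pvalue
        return bool(np.isnan(p) or p >= 0.05)

    def summary(self) -> dict:
        return {"method": self.method, "mean_pa": self.mean, "sd": self.sd,
                "t_pvalue": self.t_pvalue,
                "n_valid": int(self.valid.size),
                "not_different_from_zero": self.not_different_from_zero}


# ---------------------------------------------------------------------------
# MAS: ordinary least squares on a handful of markers
# ---------------------------------------------------------------------------

def _mas_design(dosages: np.ndarray, effect: str) -> np.ndarray:
    if effect == "A":
        return additive_coding(dosages)
    if effect == "D":
        return dominance_coding(dosages)
    if effect == "AD":
        return np.hstack([additive_coding(dosages),
                          dominance_coding(dosages)])
    raise ValueError("effect must be 'A', 'D' or 'AD'")


def _drop_aliased(X: np.ndarray) -> np.ndarray:
    """Greedy full-rank column subset (first-come precedence)."""
    keep = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
    return np.array(keep, dtype=int)


def fit_mas(y: np.ndarray, M_dosages: np.ndarray, effect: str = "A",
            train_idx: np.ndarray | None = None) -> GPFit:
    """OLS of the phenotype on significant-marker codings; GEBV = M f-hat."""
    y = np.asarray(y, dtype=float)
    if M_dosages.ndim != 2 or M_dosages.shape[1] == 0:
        raise ValueError("MAS needs a non-empty marker matrix M")
    S_all = _mas_design(M_dosages, effect)
    tr = np.arange(y.size) if train_idx is None else np.asarray(train_idx)
    X = np.column_stack([np.ones(tr.size), S_all[tr]])
    if tr.size <= X.shape[1]:
        raise ValueError("more MAS parameters than training samples")
    cols = _drop_aliased(X)
    if cols.size < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - cols.size} aliased MAS "
                      "column(s)")
    beta = np.zeros(X.shape[1])
    sol, *_ = np.linalg.lstsq(X[:, cols], y[tr], rcond=None)
    beta[cols] = sol
    f_hat = beta[1:]
    gebv = S_all @ f_hat
    resid = y[tr] - X @ beta
    dof = max(tr.size - cols.size, 1)
    return GPFit(method=f"mas_{effect.lower()}", mu=float(beta[0]),
                 gebv=gebv, fixed_effects=f_hat,
                 varcomps={"sigma2_g": 0.0,
                           "sigma2_e": float(resid @ resid / dof)})


# ---------------------------------------------------------------------------
# kernel models (GBLUP / RKHS / MAS|GP): REML and Gibbs engines
# ---------------------------------------------------------------------------

def _as_matrix(G) -> np.ndarray:
    return G.values if isinstance(G, KinshipMatrix) else np.asarray(G, float)


def _kernel_blup(y, K, X_all, train_idx):
    """Exact REML fit and conditional-mean prediction for all samples."""
    K = _as_matrix(K)
    n = K.shape[0]
    tr = np.arange(n) if train_idx is None else np.asarray(train_idx)
    K_tr = K[np.ix_(tr, tr)]
    w = np.linalg.eigvalsh((K_tr + K_tr.T) / 2.0)
    if w.min() < -1e-6 * max(w.max(), 1.0):
        raise ValueError(f"kernel is not PSD (min eigenvalue {w.min():.3g})")
    fit = reml_single_kernel(y[tr], X_all[tr], K_tr)
    s2g, s2e = fit.varcomps["sigma2_g"], fit.varcomps["sigma2_e"]
    Sigma_tr = s2g * K_tr + s2e * np.eye(tr.size)
    resid = y[tr] - X_all[tr] @ fit.beta
    alpha = np.linalg.solve(Sigma_tr, resid)
    u_all = s2g * (K[:, tr] @ alpha)
    return fit.beta, u_all, {"sigma2_g": s2g, "sigma2_e": s2e}


def _sample_scaled_inv_chi2(rng, df, scale):
    return df * scale / rng.chisquare(df)


def _gibbs_kernel(y, K, X_all, train_idx, cfg: McmcConfig):
    """Gibbs sampler for g = X beta + u + e with u ~ N(0, s2_g K).

    Sampling is done in the eigenbasis of the training-set kernel where the
    conditional of u is diagonal; scaled-inverse-chi-square priors with
    ``df_prior`` degrees of freedom and R2-rule scales.
    """
    K = _as_matrix(K)
    n = K.shape[0]
    tr = np.arange(n) if train_idx is None else np.asarray(train_idx)
    K_tr = K[np.ix_(tr, tr)]
    lam, U = np.linalg.eigh((K_tr + K_tr.T) / 2.0)
    pos = lam > 1e-10 * lam.max()
    lam, U = lam[pos], U[:, pos]
    ytr, Xtr = y[tr], X_all[tr]
    nt, p = Xtr.shape
    XtX_inv = np.linalg.inv(Xtr.T @ Xtr)
    chol_beta = np.linalg.cholesky(XtX_inv)

    rng = np.random.default_rng(cfg.seed)
    vary = ytr.var()
    df = cfg.df_prior
    S_g = cfg.r2_prior * vary / np.mean(np.diag(K_tr)) * (df + 2) / df
    S_e = (1.0 - cfg.r2_prior) * vary * (df + 2) / df
    s2g, s2e = S_g * df / (df + 2), S_e * df / (df + 2)

    beta = np.linalg.lstsq(Xtr, ytr, rcond=None)[0]
    gamma = np.zeros(lam.size)
    keep_beta, keep_u, keep_v = [], [], []
    for it in range(cfg.n_iter):
        u = U @ gamma
        # beta | rest (flat prior)
        bhat = XtX_inv @ (Xtr.T @ (ytr - u))
        beta = bhat + np.sqrt(s2e) * (chol_beta @ rng.standard_normal(p))
        # gamma | rest: diagonal in the eigenbasis
        r = U.T @ (ytr - Xtr @ beta)
        denom = s2g * lam + s2e
        mean = s2g * lam * r / denom
        sd = np.sqrt(s2g * lam * s2e / denom)
        gamma = mean + sd * rng.standard_normal(lam.size)
        u = U @ gamma
        # variance components
        s2g = _sample_scaled_inv_chi2(
            rng, df + lam.size,
            (df * S_g + np.sum(gamma ** 2 / lam)) / (df + lam.size))
        e = ytr - Xtr @ beta - u
        s2e = _sample_scaled_inv_chi2(
            rng, df + nt, (df * S_e + e @ e) / (df + nt))
        if not np.isfinite(s2e) or s2e <= 0:
            raise FloatingPointError(f"residual variance diverged at "
                                     f"iteration {it}")
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            keep_beta.append(beta.copy())
            keep_u.append(u.copy())
            keep_v.append((s2g, s2e))
    beta_bar = np.mean(keep_beta, axis=0)
    u_bar_tr = np.mean(keep_u, axis=0)
    s2g_bar, s2e_bar = np.mean(keep_v, axis=0)
    # conditional mean for unobserved samples through the kernel
    lam_inv = np.where(lam > 0, 1.0 / lam, 0.0)
    Ktr_pinv = (U * lam_inv) @ U.T
    u_all = K[:, tr] @ (Ktr_pinv @ u_bar_tr)
    u_all[tr] = u_bar_tr
    return beta_bar, u_all, {"sigma2_g": float(s2g_bar),
                             "sigma2_e": float(s2e_bar)}


def _fit_kernel_model(y, K, X_all, train_idx, engine, cfg, method,
                      M_coded=None):
    if engine == "reml":
        beta, u_all, vc = _kernel_blup(y, K, X_all, train_idx)
    elif engine == "gibbs":
        cfg = cfg or McmcConfig()
        beta, u_all, vc = _gibbs_kernel(y, K, X_all, train_idx, cfg)
    else:
        raise ValueError("engine must be 'reml' or 'gibbs'")
    f_hat = beta[1:] if beta.size > 1 else None
    gebv = u_all.copy()
    if M_coded is not None and f_hat is not None and f_hat.size:
        gebv = M_coded @ f_hat + u_all
    return GPFit(method=method, mu=float(beta[0]), gebv=gebv,
                 fixed_effects=f_hat, genetic_values=u_all, varcomps=vc)


def fit_gblup(y, G, train_idx=None, engine: str = "gibbs",
              mcmc: McmcConfig | None = None) -> GPFit:
    """GBLUP on a trace-normalized (or any PSD) genomic relationship matrix."""
    y = np.asarray(y, dtype=float)
    n = _as_matrix(G).shape[0]
    X = np.ones((n, 1))
    return _fit_kernel_model(y, G, X, train_idx, engine, mcmc, "gblup")


def fit_rkhs(y, K, train_idx=None, engine: str = "gibbs",
             mcmc: McmcConfig | None = None) -> GPFit:
    """Gaussian-kernel regression; identical machinery to GBLUP with K."""
    y = np.asarray(y, dtype=float)
    n = _as_matrix(K).shape[0]
    X = np.ones((n, 1))
    fit = _fit_kernel_model(y, K, X, train_idx, engine, mcmc, "rkhs")
    return fit


def fit_mas_gp(y, M_dosages, G_W, effect: str = "A", train_idx=None,
               engine: str = "gibbs", mcmc: McmcConfig | None = None,
               kernel_tag: str = "mas_gblup") -> GPFit:
    """Significant markers as fixed effects plus a polygenic term on G_W.

    With an empty M this degenerates to plain GBLUP/RKHS on G_W; GEBV is
    M f-hat + s-hat.
    """
    y = np.asarray(y, dtype=float)
    n = _as_matrix(G_W).shape[0]
    if M_dosages is None or M_dosages.shape[1] == 0:
        fit = _fit_kernel_model(y, G_W, np.ones((n, 1)), train_idx, engine,
                                mcmc, kernel_tag)
        return fit
    S = _mas_design(M_dosages, effect)
    X = np.column_stack([np.ones(n), S])
    cols = _drop_aliased(X)
    X_use = X[:, cols]
    fit = _fit_kernel_model(y, G_W, X_use, train_idx, engine, mcmc,
                            kernel_tag, M_coded=X_use[:, 1:])
    return fit


# ---------------------------------------------------------------------------
# BayesB
# ---------------------------------------------------------------------------

def _bayesb_python(y, Z, n_iter, burn_in, thin, df_b, S_b, df_e, S_e,
                   pi_a, pi_b, seed):
    """Reference spike-and-slab Gibbs chain (plain numpy)."""
    rng = np.random.default_rng(seed)
    n, m = Z.shape
    zz = (Z ** 2).sum(axis=0)
    b = np.zeros(m)
    s2b = np.full(m, S_b * df_b / (df_b + 2))
    pi = 0.5
    mu = y.mean()
    s2e = S_e * df_e / (df_e + 2)
    e = y - mu
    keep_b = np.zeros(m)
    keep_mu = 0.0
    keep_v = np.zeros(2)
    kept = 0
    for it in range(n_iter):
        mu_new = rng.normal((e + mu).mean(), np.sqrt(s2e / n))
        e += mu - mu_new
        mu = mu_new
        n_in = 0
        for j in range(m):
            if zz[j] == 0.0:
                continue
            if b[j] != 0.0:
                e += Z[:, j] * b[j]
            rhs = Z[:, j] @ e
            v = s2e + s2b[j] * zz[j]
            log_lr = (-0.5 * np.log(v / s2e)
                      + 0.5 * s2b[j] * rhs ** 2 / (s2e * v))
            odds = (1.0 - pi) / pi * np.exp(min(log_lr, 700.0))
            p_in = odds / (1.0 + odds)
            if rng.random() < p_in:
                c = zz[j] + s2e / s2b[j]
                b[j] = rng.normal(rhs / c, np.sqrt(s2e / c))
                e -= Z[:, j] * b[j]
                n_in += 1
                s2b[j] = (df_b * S_b + b[j] ** 2) / rng.chisquare(df_b + 1)
            else:
                b[j] = 0.0
                s2b[j] = df_b * S_b / rng.chisquare(df_b)
        pi = rng.beta(pi_a + m - n_in, pi_b + n_in)
        pi = min(max(pi, 1e-6), 1.0 - 1e-6)
        s2e = (df_e * S_e + e @ e) / rng.chisquare(df_e + n)
        if not np.isfinite(s2e):
            raise FloatingPointError(f"residual variance diverged at "
                                     f"iteration {it}")
        if it >= burn_in and (it - burn_in) % thin == 0:
            keep_b += b
            keep_mu += mu
            keep_v += (s2e, pi)
            kept += 1
    return keep_b / kept, keep_mu / kept, keep_v / kept


def fit_bayesb(y, Z_dosages, cfg: McmcConfig | None = None, train_idx=None,
               pi_prior_counts: tuple[float, float] = (5.0, 5.0),
               backend: str = "auto") -> GPFit:
    """Spike-and-slab Gibbs sampler over all markers; GEBV = Z b-hat.

    Each marker effect is exactly zero with probability pi (pi itself gets a
    Beta prior) or drawn from a normal slab whose per-marker variance has a
    scaled-inverse-chi-square prior (a scaled-t slab marginally).  Scales
    follow the R2 rule: the slab prior mode lets markers explain
    ``r2_prior`` of the phenotypic variance given the prior inclusion rate.
    """
    cfg = cfg or McmcConfig()
    y = np.asarray(y, dtype=float)
    Z_all = additive_coding(Z_dosages)
    tr = np.arange(y.size) if train_idx is None else np.asarray(train_idx)
    ytr = y[tr]
    Z = np.ascontiguousarray(Z_all[tr])
    n, m = Z.shape
    vary = ytr.var()
    df = cfg.df_prior
    pi_a, pi_b = pi_prior_counts
    prior_in = pi_b / (pi_a + pi_b)  # expected inclusion probability
    msx = np.mean(Z.var(axis=0)) * m
    S_b = cfg.r2_prior * vary / max(prior_in * msx, 1e-12) * (df + 2) / df
    S_e = (1.0 - cfg.r2_prior) * vary * (df + 2) / df

    runner = _bayesb_kernel(backend)
    b_bar, mu_bar, (s2e_bar, pi_bar) = runner(
        ytr, Z, cfg.n_iter, cfg.burn_in, cfg.thin, df, S_b, df, S_e,
        pi_a, pi_b, cfg.seed)
    gebv = Z_all @ b_bar
    return GPFit(method="bayesb", mu=float(mu_bar), gebv=gebv,
                 marker_effects=b_bar,
                 varcomps={"sigma2_g": float(np.var(Z @ b_bar)),
                           "sigma2_e": float(s2e_bar),
                           "pi_null": float(pi_bar)})


def _bayesb_kernel(backend: str):
    if backend == "python":
        return _bayesb_python
    global _BAYESB_JIT
    try:
        return _BAYESB_JIT
    except NameError:
        pass
    try:
        from numba import njit
        import numba  # noqa: F401

        _BAYESB_JIT = njit(cache=True)(_numba_source())
    except Exception:  # pragma: no cover - numba always present in practice
        _BAYESB_JIT = _bayesb_python
    return _BAYESB_JIT


def _numba_source():
    """Numba-compilable clone of the reference chain (seeded np.random)."""
    def _chain(y, Z, n_iter, burn_in, thin, df_b, S_b, df_e, S_e,
               pi_a, pi_b, seed):
        np.random.seed(seed)
        n, m = Z.shape
        zz = np.zeros(m)
        for j in range(m):
            for i in range(n):
                zz[j] += Z[i, j] * Z[i, j]
        b = np.zeros(m)
        s2b = np.full(m, S_b * df_b / (df_b + 2.0))
        pi = 0.5
        mu = y.mean()
        s2e = S_e * df_e / (df_e + 2.0)
        e = y - mu
        keep_b = np.zeros(m)
        keep_mu = 0.0
        keep_v = np.zeros(2)
        kept = 0
        for it in range(n_iter):
            mu_new = np.random.normal((e + mu).mean(), np.sqrt(s2e / n))
            for i in range(n):
                e[i] += mu - mu_new
            mu = mu_new
            n_in = 0
            for j in range(m):
                if zz[j] == 0.0:
                    continue
                if b[j] != 0.0:
                    for i in range(n):
                        e[i] += Z[i, j] * b[j]
                rhs = 0.0
                for i in range(n):
                    rhs += Z[i, j] * e[i]
                v = s2e + s2b[j] * zz[j]
                log_lr = (-0.5 * np.log(v / s2e)
                          + 0.5 * s2b[j] * rhs * rhs / (s2e * v))
                if log_lr > 700.0:
                    log_lr = 700.0
                odds = (1.0 - pi) / pi * np.exp(log_lr)
                p_in = odds / (1.0 + odds)
                if np.random.random() < p_in:
                    c = zz[j] + s2e / s2b[j]
                    b[j] = np.random.normal(rhs / c, np.sqrt(s2e / c))
                    for i in range(n):
                        e[i] -= Z[i, j] * b[j]
                    n_in += 1
                    s2b[j] = ((df_b * S_b + b[j] * b[j])
                              / np.random.chisquare(df_b + 1.0))
                else:
                    b[j] = 0.0
                    s2b[j] = df_b * S_b / np.random.chisquare(df_b)
            pi = np.random.beta(pi_a + m - n_in, pi_b + n_in)
            if pi < 1e-6:
                pi = 1e-6
            if pi > 1.0 - 1e-6:
                pi = 1.0 - 1e-6
            ee = 0.0
            for i in range(n):
                ee += e[i] * e[i]
            s2e = (df_e * S_e + ee) / np.random.chisquare(df_e + n)
            if it >= burn_in and (it - burn_in) % thin == 0:
                for j in range(m):
                    keep_b[j] += b[j]
                keep_mu += mu
                keep_v[0] += s2e
                keep_v[1] += pi
                kept += 1
        return keep_b / kept, keep_mu / kept, keep_v / kept
    return _chain


# ---------------------------------------------------------------------------
# assembled data bundle and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class PredictionData:
    """Everything the eight methods need, built once per marker panel."""

    hybrids: GenotypeMatrix
    partition: MarkerPartition
    G_Z: KinshipMatrix
    G_W: KinshipMatrix
    K_Z: KinshipMatrix
    K_W: KinshipMatrix
    M_dosages: np.ndarray  # (n, n_significant)


def build_prediction_data(hybrids: GenotypeMatrix, significant_ids,
                          bandwidth: float = 1.0) -> PredictionData:
    part = MarkerPartition(list(significant_ids), hybrids.marker_ids)
    G_Z = grm_trace_norm(hybrids)
    if part.n_significant:
        G_W = grm_trace_norm(hybrids, marker_subset=part.complement_ids)
        M = hybrids.dosages[:, hybrids.marker_index(part.significant_ids)]
    else:
        G_W = G_Z
        M = np.empty((hybrids.n_samples, 0))
    K_Z = gaussian_kernel(G_Z, bandwidth)
    K_W = gaussian_kernel(G_W, bandwidth)
    return PredictionData(hybrids, part, G_Z, G_W, K_Z, K_W, M)


def fit_predict(method: str, data: PredictionData, y: np.ndarray,
                train_idx=None, engine: str = "gibbs",
                mcmc: McmcConfig | None = None,
                mas_gp_effect: str = "A") -> GPFit:
    """Dispatch one prediction method; returns GEBVs for every hybrid."""
    y = np.asarray(y, dtype=float)
    if method == "mas_a":
        return fit_mas(y, data.M_dosages, "A", train_idx)
    if method == "mas_d":
        return fit_mas(y, data.M_dosages, "D", train_idx)
    if method == "mas_ad":
        return fit_mas(y, data.M_dosages, "AD", train_idx)
    if method == "bayesb":
        return fit_bayesb(y, data.hybrids.dosages, mcmc, train_idx)
    if method == "gblup":
        return fit_gblup(y, data.G_Z, train_idx, engine, mcmc)
    if method == "rkhs":
        return fit_rkhs(y, data.K_Z, train_idx, engine, mcmc)
    if method == "mas_gblup":
        return fit_mas_gp(y, data.M_dosages, data.G_W, mas_gp_effect,
                          train_idx, engine, mcmc, "mas_gblup")
    if method == "mas_rkhs":
        return fit_mas_gp(y, data.M_dosages, data.K_W, mas_gp_effect,
                          train_idx, engine, mcmc, "mas_rkhs")
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def cross_validate(y, data: PredictionData, method: str, n_reps: int = 50,
                   train_frac: float = 0.75, seed: int = 0,
                   engine: str = "gibbs", mcmc: McmcConfig | None = None
                   ) -> CVResult:
    """Replicated training-testing evaluation of one method.

    Each replicate k draws a seeded random ``train_frac`` split (seed + k, so
    single replicates can be re-run), fits on the training hybrids, predicts
    GEBVs of the rest and records the Pearson correlation between observed
    and predicted values on the test set.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 20:
        raise ValueError("cross-validation needs at least 20 samples")
    n_train = int(round(train_frac * n))
    if not 1 < n_train < n:
        raise ValueError("train_frac leaves an empty train or test set")
    rs = np.empty(n_reps)
    for k in range(n_reps):
        rng = np.random.default_rng(seed + k)
        perm = rng.permutation(n)
        tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        rep_mcmc = mcmc
        if mcmc is not None:
            rep_mcmc = McmcConfig(mcmc.n_iter, mcmc.burn_in, mcmc.thin,
                                  mcmc.r2_prior, mcmc.df_prior,
                                  mcmc.seed + k)
        fit = fit_predict(method, data, y, tr, engine, rep_mcmc)
        pred = fit.gebv[te]
        if np.std(pred) == 0.0 or np.std(y[te]) == 0.0:
            warnings.warn(f"constant predictions in replicate {k}; "
                          "correlation undefined")
            rs[k] = np.nan
        else:
            rs[k] = np.corrcoef(y[te], pred)[0, 1]
    return CVResult(method=method, replicates=rs, n_reps=n_reps,
                    train_frac=train_frac)
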