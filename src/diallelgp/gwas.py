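"""Additive/dominance single-marker association with polygenic control.

The scan model per marker is

    g = X mu + S m + [v + o] + eps,
    v ~ N(0, G_A s2_a),  o ~ N(0, G_D s2_d),  eps ~ N(0, I s2_e),

where X holds the intercept and 0-3 dosage principal components, and S is
the additive ({-1,0,1}), dominance ({0,1,0}) or stacked additive+dominance
coding of the marker.  Variance components are estimated once on the
marker-free null model and reused for every marker test (P3D), which turns
each test into weighted least squares in a whitened basis.  Family-wise
significance uses the permutation null distribution of the minimum p-value;
model choice across codings/kinships/PC counts is by the genomic inflation
factor closest to 1.  Per-marker heritabilities follow the allele-frequency
decompositions H2 = 2pq a^2 / Var(g) (additive scan),
2pq [a + d(q-p)]^2 / Var(g) and 4 p^2 q^2 d^2 / Var(g) (additive +
dominance scan).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix, grm_additive, grm_dominance, pca_covariates
from .predict import additive_coding, dominance_coding
from .reml import reml_single_kernel, reml_ai

CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549...


@dataclass
class GwasConfig:
    coding: str = "A"               # A | D | AD
    kinship: tuple[str, ...] = ("G_A",)   # subset of {"G_A", "G_D"}
    n_pc: int = 0
    n_perm: int = 400
    alpha: float = 0.05
    p3d: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coding not in ("A", "D", "AD"):
            raise ValueError("coding must be 'A', 'D' or 'AD'")
        bad = set(self.kinship) - {"G_A", "G_D"}
        if bad:
            raise ValueError(f"unknown kinships {bad}")
        if self.n_pc not in (0, 1, 2, 3):
            raise ValueError("n_pc must be 0..3")
        if self.n_perm < 20:
            raise ValueError("n_perm must be >= 20")


@dataclass
class NullModel:
    """P3D cache: REML variance components and the whitening transform."""

    varcomps: dict[str, float]
    whitener: np.ndarray    # W with W Sigma W' = I
    X: np.ndarray           # fixed covariates (intercept + PCs)
    loglik: float


@dataclass
class GwasResult:
    table: pd.DataFrame     # per-marker effects and p-values
    config: GwasConfig
    threshold: float | None = None   # p-value scale
    lambda_gc: float | None = None

    @property
    def significant(self) -> pd.DataFrame:
        if self.threshold is None:
            raise ValueError("no permutation threshold attached")
        pcols = [c for c in ("p_A", "p_D") if c in self.table.columns]
        mask = np.zeros(len(self.table), dtype=bool)
        for c in pcols:
            mask |= (self.table[c] <= self.threshold).to_numpy()
        return self.table[mask]

    @property
    def min_p(self) -> float:
        pcols = [c for c in ("p_A", "p_D") if c in self.table.columns]
        return float(np.nanmin(self.table[pcols].to_numpy()))


@dataclass
class MarkerH2:
    p: float
    mode: str               # additive | AD-additive | AD-dominance
    h2: float
    alpha: float | None = None
    a: float | None = None
    d: float | None = None
    var_g: float | None = None

    @property
    def q(self) -> float:
        return 1.0 - self.p


# ---------------------------------------------------------------------------
# null model and whitening
# ---------------------------------------------------------------------------

def fit_null_varcomp(y, covariates: np.ndarray | None,
                     kinships: dict[str, KinshipMatrix | np.ndarray]
                     ) -> NullModel:
    """REML of the marker-free polygenic model and its whitening transform.

    One kinship: exact eigen-profile REML.  Two kinships: AI-REML for the
    ratios, then a single spectral decomposition of the fitted covariance
    (the P3D convention).  An empty kinship dict gives the iid model.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.ones((n, 1)) if covariates is None or covariates.size == 0 \
        else np.column_stack([np.ones(n), covariates])

    mats = {k: (v.values if isinstance(v, KinshipMatrix) else np.asarray(v))
            for k, v in kinships.items()}
    for k, K in mats.items():
        w = np.linalg.eigvalsh((K + K.T) / 2.0)
        if w.min() < -1e-6 * max(abs(w).max(), 1.0):
            raise ValueError(f"kinship {k} is not PSD")
    if len(mats) == 0:
        vc = {"sigma2_e": float(np.var(y))}
        return NullModel(vc, np.eye(n), X, float("nan"))
    if len(mats) == 1:
        (name, K), = mats.items()
        fit = reml_single_kernel(y, X, K)
        vc = {name: fit.varcomps["sigma2_g"],
              "sigma2_e": fit.varcomps["sigma2_e"]}
        Sigma = fit.Sigma
    else:
        keys = list(mats)
        if np.allclose(mats[keys[0]], mats[keys[1]]):
            warnings.warn("identical kinships supplied: only their sum is "
                          "identified")
        fit = reml_ai(y, X, mats)
        vc = dict(fit.varcomps)
        Sigma = fit.Sigma
    lam, U = np.linalg.eigh((Sigma + Sigma.T) / 2.0)
    lam = np.clip(lam, 1e-12, None)
    W = (U / np.sqrt(lam)) @ U.T  # symmetric inverse square root
    return NullModel(vc, W, X, fit.loglik)


def _whiten_residualize(null: NullModel, y=None):
    """Q (orthonormal basis of whitened X) and optional whitened y."""
    Xw = null.whitener @ null.X
    Q, _ = np.linalg.qr(Xw)
    if y is None:
        return Q, None
    yw = null.whitener @ np.asarray(y, dtype=float)
    return Q, yw - Q @ (Q.T @ yw)


def _marker_codings(genotypes: GenotypeMatrix, coding: str):
    dos = genotypes.dosages
    out = {}
    if coding in ("A", "AD"):
        out["A"] = additive_coding(dos)
    if coding in ("D", "AD"):
        out["D"] = dominance_coding(dos)
    return out


def _scan_stats_single(Sr: np.ndarray, Yr: np.ndarray, dof: int):
    """Per-marker slope/p for one coding against one or many phenotypes.

    ``Sr``: (n, m) residualized whitened codings; ``Yr``: (n,) or (n, P)
    residualized whitened phenotypes.  Returns beta, p with shape (m, P).
    """
    Y = Yr if Yr.ndim == 2 else Yr[:, None]
    ss = (Sr ** 2).sum(axis=0)
    ok = ss > 1e-12
    num = Sr.T @ Y                      # (m, P)
    yy = (Y ** 2).sum(axis=0)           # (P,)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / ss[:, None]
        rss = yy[None, :] - num ** 2 / ss[:, None]
        rss = np.clip(rss, 0.0, None)
        sigma2 = rss / dof
        tstat = num / np.sqrt(sigma2 * ss[:, None])
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    beta[~ok] = np.nan
    pval[~ok] = np.nan
    return beta, pval


def _scan_stats_ad(Ar, Dr, Yr, dof):
    """Marginal 1-df tests of the additive and dominance coefficients in the
    joint two-column model, vectorized over markers (single phenotype)."""
    y = Yr.ravel()
    saa = (Ar ** 2).sum(axis=0)
    sdd = (Dr ** 2).sum(axis=0)
    sad = (Ar * Dr).sum(axis=0)
    say = Ar.T @ y
    sdy = Dr.T @ y
    det = saa * sdd - sad ** 2
    scale = np.maximum(saa, 1e-12) * np.maximum(sdd, 1e-12)
    ok = det > 1e-10 * scale
    yy = y @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        bA = (sdd * say - sad * sdy) / det
        bD = (saa * sdy - sad * say) / det
        rss = np.clip(yy - bA * say - bD * sdy, 0.0, None)
        sigma2 = rss / dof
        varA = sigma2 * sdd / det
        varD = sigma2 * saa / det
        tA = bA / np.sqrt(varA)
        tD = bD / np.sqrt(varD)
    pA = 2.0 * stats.t.sf(np.abs(tA), dof)
    pD = 2.0 * stats.t.sf(np.abs(tD), dof)
    for arr in (bA, bD, pA, pD):
        arr[~ok] = np.nan
    return bA, pA, bD, pD, ok


def scan(y, genotypes: GenotypeMatrix, cfg: GwasConfig,
         null: NullModel | None = None) -> GwasResult:
    """GLS single-marker scan under the P3D null covariance.

    Markers whose coding has no variance after projection (monomorphic, or
    heterozygote-free under D) are reported with NaN effects and a recorded
    skip reason.
    """
    y = np.asarray(y, dtype=float)
    if null is None:
        null = build_null(y, genotypes, cfg)
    Q, yr = _whiten_residualize(null, y)
    n = y.size
    p_fixed = null.X.shape[1]
    codings = _marker_codings(genotypes, cfg.coding)
    W = null.whitener

    def residualize(S):
        Sw = W @ S
        return Sw - Q @ (Q.T @ Sw)

    tab = {"marker_id": genotypes.marker_ids,
           "chrom": genotypes.markers["chrom"].to_numpy(),
           "pos": genotypes.markers["pos"].to_numpy(),
           "maf": genotypes.maf()}
    skip_reason = np.array([""] * genotypes.n_markers, dtype=object)
    if cfg.coding in ("A", "D"):
        S = codings[cfg.coding]
        Sr = residualize(S)
        dof = n - p_fixed - 1
        beta, pval = _scan_stats_single(Sr, yr, dof)
        bad = ~np.isfinite(pval[:, 0])
        skip_reason[bad] = "zero-variance coding"
        tab[f"beta_{cfg.coding}"] = beta[:, 0]
        tab[f"p_{cfg.coding}"] = pval[:, 0]
    else:
        Ar = residualize(codings["A"])
        Dr = residualize(codings["D"])
        dof = n - p_fixed - 2
        bA, pA, bD, pD, ok = _scan_stats_ad(Ar, Dr, yr, dof)
        skip_reason[~ok] = "collinear or zero-variance codings"
        tab.update({"beta_A": bA, "p_A": pA, "beta_D": bD, "p_D": pD})
    tab["skip_reason"] = skip_reason
    df = pd.DataFrame(tab)
    res = GwasResult(table=df, config=cfg)
    res.lambda_gc = inflation_factor(res)
    return res


def build_null(y, genotypes: GenotypeMatrix, cfg: GwasConfig) -> NullModel:
    """Convenience: PCs + requested kinships -> fitted null model."""
    cov = pca_covariates(genotypes, cfg.n_pc)
    kin = {}
    if "G_A" in cfg.kinship:
        kin["sigma2_a"] = grm_additive(genotypes)
    if "G_D" in cfg.kinship:
        kin["sigma2_d"] = grm_dominance(genotypes)
    return fit_null_varcomp(y, cov, kin)


def permutation_threshold(y, genotypes: GenotypeMatrix, cfg: GwasConfig,
                          null: NullModel | None = None,
                          return_minp: bool = False):
    """Family-wise p-value threshold from the permutation min-p distribution.

    The phenotype vector is permuted ``n_perm`` times (covariates and kinship
    rows stay put), the scan is re-run under the fixed null covariance, and
    the empirical alpha-quantile (order statistic ceil(alpha * n_perm)) of
    the per-permutation minimum p-value is returned.
    """
    y = np.asarray(y, dtype=float)
    if cfg.n_perm < 1.0 / cfg.alpha:
        raise ValueError(f"n_perm={cfg.n_perm} cannot resolve "
                         f"alpha={cfg.alpha}")
    if null is None:
        null = build_null(y, genotypes, cfg)
    rng = np.random.default_rng(cfg.seed)
    n = y.size
    P = cfg.n_perm
    Yp = np.empty((n, P))
    for k in range(P):
        Yp[:, k] = y[rng.permutation(n)]
    Q, _ = _whiten_residualize(null)
    W = null.whitener
    Ypw = W @ Yp
    Ypr = Ypw - Q @ (Q.T @ Ypw)
    p_fixed = null.X.shape[1]
    codings = _marker_codings(genotypes, cfg.coding)

    def residualize(S):
        Sw = W @ S
        return Sw - Q @ (Q.T @ Sw)

    if cfg.coding in ("A", "D"):
        Sr = residualize(codings[cfg.coding])
        _, pval = _scan_stats_single(Sr, Ypr, n - p_fixed - 1)
        min_p = np.nanmin(pval, axis=0)
    else:
        Ar, Dr = residualize(codings["A"]), residualize(codings["D"])
        dof = n - p_fixed - 2
        mins = np.empty(P)
        for k in range(P):
            _, pA, _, pD, _ = _scan_stats_ad(Ar, Dr, Ypr[:, k], dof)
            mins[k] = np.nanmin([np.nanmin(pA), np.nanmin(pD)])
        min_p = mins
    k_order = int(np.ceil(cfg.alpha * cfg.n_perm))
    thr = float(np.sort(min_p)[k_order - 1])
    if return_minp:
        return thr, min_p
    return thr


def inflation_factor(result: GwasResult) -> float:
    """Genomic inflation: median observed chi-square over its null median."""
    pcols = [c for c in ("p_A", "p_D") if c in result.table.columns]
    pv = result.table[pcols].to_numpy().ravel()
    pv = pv[np.isfinite(pv)]
    if pv.size == 0:
        return float("nan")
    chi = stats.chi2.isf(pv, 1)
    return float(np.median(chi) / CHI2_MEDIAN_1DF)


def select_model(results: list[GwasResult]) -> GwasResult:
    """Pick the scan whose inflation factor is closest to 1.

    Mirrors choosing the best-behaved QQ plot; ties break toward fewer
    principal components.
    """
    if not results:
        raise ValueError("no candidate scans")
    for r in results:
        if r.lambda_gc is None:
            r.lambda_gc = inflation_factor(r)
    return min(results, key=lambda r: (abs(r.lambda_gc - 1.0),
                                       r.config.n_pc))


# ---------------------------------------------------------------------------
# allele-substitution effects and per-marker heritability
# ---------------------------------------------------------------------------

def ase(a: float, d: float, p: float) -> float:
    """Allele substitution effect alpha = a + d (q - p)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    q = 1.0 - p
    return a + d * (q - p)


def marker_h2(p: float, var_g: float, mode: str = "additive",
              alpha: float | None = None, a: float | None = None,
              d: float | None = None) -> MarkerH2:
    """Variance fraction a significant marker explains of the phenotype.

    additive scan:       H2 = 2 p q alpha^2 / var_g
    AD scan, additive:   H2 = 2 p q [a + d (q - p)]^2 / var_g
    AD scan, dominance:  H2 = 4 p^2 q^2 d^2 / var_g
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if var_g <= 0.0:
        raise ValueError("var_g must be > 0")
    q = 1.0 - p
    if mode == "additive":
        if alpha is None:
            raise ValueError("additive mode needs alpha")
        h2 = 2.0 * p * q * alpha ** 2 / var_g
        return MarkerH2(p=p, mode=mode, h2=h2, alpha=alpha, var_g=var_g)
    if mode == "AD-additive":
        if a is None or d is None:
            raise ValueError("AD-additive mode needs a and d")
        al = ase(a, d, p)
        h2 = 2.0 * p * q * al ** 2 / var_g
        return MarkerH2(p=p, mode=mode, h2=h2, alpha=al, a=a, d=d,
                        var_g=var_g)
    if mode == "AD-dominance":
        if d is None:
            raise ValueError("AD-dominance mode needs d")
        h2 = 4.0 * p ** 2 * q ** 2 * d ** 2 / var_g
        return MarkerH2(p=p, mode=mode, h2=h2, a=a, d=d, var_g=var_g)
    raise ValueError("mode must be 'additive', 'AD-additive' or "
                     "'AD-dominance'")


def significant_marker_h2(result: GwasResult, y) -> pd.DataFrame:
    """Heritability decomposition of every significant marker in a scan.

    ``var_g`` defaults to the sample variance of the adjusted phenotype.
    """
    y = np.asarray(y, dtype=float)
    var_g = float(np.var(y, ddof=1))
    rows = []
    sig = result.significant
    ad = "beta_A" in sig.columns and "beta_D" in sig.columns
    for _, r in sig.iterrows():
        p = float(r["maf"])
        if ad:
            mh_a = marker_h2(p, var_g, "AD-additive", a=r["beta_A"],
                             d=r["beta_D"])
            mh_d = marker_h2(p, var_g, "AD-dominance", d=r["beta_D"])
            rows.append({"marker_id": r["marker_id"], "maf": p,
                         "h2_additive": mh_a.h2, "h2_dominance": mh_d.h2,
                         "alpha": mh_a.alpha, "var_g": var_g})
        else:
            col = "beta_A" if "beta_A" in sig.columns else "beta_D"
            mh = marker_h2(p, var_g, "additive", alpha=r[col])
            rows.append({"marker_id": r["marker_id"], "maf": p,
                         "h2_additive": mh.h2, "h2_dominance": np.nan,
                         "alpha": r[col], "var_g": var_g})
    return pd.DataFrame(rows)
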