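"""Adjusted means, heritabilities and the low-nitrogen tolerance index.

Plot yields from unreplicated augmented-block trials are analysed per
nitrogen regime with the mixed model

    y = X beta + V b + eps,     b ~ N(0, I s2_b),  eps ~ N(0, I s2_e),

where the fixed part holds check/hybrid entries, environments (site x year)
and check x environment, and blocks-within-environment are random.  The
replicated checks carry the information on s2_b and s2_e; each hybrid's
adjusted mean is its GLS entry effect on the common environment baseline.

Heritabilities come from a second fit with hybrid, environment and
check x environment random:

    plot-level       H2 = s2_g / (s2_g + s2_ga + s2_e)
    entry-mean level H2 = s2_g / (s2_g + s2_ga/a + s2_e/(a r))

with a environments and r replications.  The tolerance index per hybrid is
LNTI = (1 - GY_LN/GY_IN) * 100 (negative values = yield gain under low N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reml import reml_grouped, reml_ai, RemlFit

PLOT_COLUMNS = ["entry_id", "is_check", "site", "year", "n_regime",
                "block_id", "yield_mg_ha"]


@dataclass
class VarianceComponents:
    sigma2_g: float = 0.0    # genotypic (hybrids)
    sigma2_ga: float = 0.0   # check x environment
    sigma2_b: float = 0.0    # block within environment
    sigma2_e: float = 0.0    # residual

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_ga", "sigma2_b", "sigma2_e"):
            v = getattr(self, name)
            if v < 0:
                warnings.warn(f"negative {name}={v:.4g} clamped at 0")
                setattr(self, name, 0.0)

    def to_dict(self) -> dict:
        return {"sigma2_g": self.sigma2_g, "sigma2_ga": self.sigma2_ga,
                "sigma2_b": self.sigma2_b, "sigma2_e": self.sigma2_e}


@dataclass
class AdjustedMeans:
    """Per-hybrid adjusted means and tolerance index."""

    table: pd.DataFrame  # hybrid_id, gy_ln, gy_in, lnti, excluded

    @property
    def lnti(self) -> pd.Series:
        ok = ~self.table["excluded"]
        return self.table.loc[ok].set_index("hybrid_id")["lnti"]

    def phenotype(self, trait: str) -> pd.Series:
        ok = ~self.table["excluded"]
        return self.table.loc[ok].set_index("hybrid_id")[trait]


def _validate_plots(plots: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLOT_COLUMNS if c not in plots.columns]
    if missing:
        raise ValueError(f"plot table lacks columns {missing}")
    if (plots["yield_mg_ha"] < 0).any():
        raise ValueError("negative yields in plot table")
    env = plots["site"].astype(str) + ":" + plots["year"].astype(str) + ":" \
        + plots["n_regime"].astype(str)
    block_env = plots.groupby("block_id")[plots.columns[0]].count()
    nuniq = plots.assign(env=env).groupby("block_id")["env"].nunique()
    if (nuniq > 1).any():
        raise ValueError("a block spans more than one environment")
    return plots.assign(env=env)


def _deviation_coding(labels: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero contrasts: one column per non-reference level."""
    levels = sorted(labels.unique())
    ref = levels[-1]
    cols = levels[:-1]
    mat = np.zeros((len(labels), len(cols)))
    arr = labels.to_numpy()
    for j, lev in enumerate(cols):
        mat[arr == lev, j] = 1.0
        mat[arr == ref, j] = -1.0
    return mat, cols


def fit_adjusted_means(plots: pd.DataFrame, regime: str,
                       ) -> tuple[pd.DataFrame, VarianceComponents, RemlFit]:
    """REML + GLS adjusted means for one nitrogen regime.

    Returns a table (entry_id, adjusted_mean, is_check), the variance
    components (block and residual; genotypic terms are fixed here) and the
    underlying REML fit.
    """
    plots = _validate_plots(plots)
    sub = plots[plots["n_regime"] == regime]
    if sub.empty:
        raise ValueError(f"no plots for regime {regime!r}")
    if sub["env"].nunique() < 2:
        raise ValueError("need at least 2 environments for adjusted means")

    entries = pd.Categorical(sub["entry_id"])
    X_entry = np.eye(len(entries.categories))[entries.codes]
    X_env, _ = _deviation_coding(sub["env"])
    # check x environment deviations (per check, sum to zero over envs)
    checks = sorted(sub.loc[sub["is_check"], "entry_id"].unique())
    env_mat, env_cols = X_env, None
    blocks_ce = []
    for chk in checks:
        mask = (sub["entry_id"] == chk).to_numpy()[:, None]
        blocks_ce.append(X_env * mask)
    X = np.hstack([X_entry, X_env] + blocks_ce) if blocks_ce else \
        np.hstack([X_entry, X_env])

    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        raise np.linalg.LinAlgError(
            "confounded fixed effects: entry/environment/check-by-environment "
            f"design has rank {r} < {X.shape[1]} columns")

    y = sub["yield_mg_ha"].to_numpy()
    fit = reml_grouped(y, X, sub["block_id"].to_numpy())
    vc = VarianceComponents(sigma2_b=fit.varcomps["sigma2_group"],
                            sigma2_e=fit.varcomps["sigma2_e"])
    coefs = fit.beta[:len(entries.categories)]
    is_chk = pd.Series(False, index=entries.categories)
    is_chk[checks] = True
    means = pd.DataFrame({"entry_id": entries.categories,
                          "adjusted_mean": coefs,
                          "is_check": is_chk.to_numpy()})
    return means, vc, fit


def heritability(plots: pd.DataFrame, regime: str | None = None,
                 n_env: int | None = None, n_rep: int = 1
                 ) -> tuple[float, float, VarianceComponents]:
    """Plot and entry-mean heritability from the random-genotype model.

    Hybrid, environment and check x environment enter as random effects
    (blocks stay random); checks keep fixed entry effects so the genotypic
    variance refers to hybrids.  ``n_env``/``n_rep`` weight the entry-mean
    formula (defaults: observed environment count, 1 replication).
    """
    plots = _validate_plots(plots)
    sub = plots if regime is None else plots[plots["n_regime"] == regime]
    if sub.empty:
        raise ValueError(f"no plots for regime {regime!r}")
    a = sub["env"].nunique() if n_env is None else n_env
    r = n_rep

    y = sub["yield_mg_ha"].to_numpy()
    n = y.size
    checks = sorted(sub.loc[sub["is_check"], "entry_id"].unique())
    chk_cols = [(sub["entry_id"] == c).to_numpy(float) for c in checks]
    X = np.column_stack([np.ones(n)] + chk_cols)

    def indicator(labels):
        cats = pd.Categorical(labels)
        Z = np.zeros((n, len(cats.categories)))
        Z[np.arange(n), cats.codes] = 1.0
        return Z

    hyb_labels = sub["entry_id"].where(~sub["is_check"], "_check_")
    Z_g = indicator(hyb_labels)
    # the pooled _check_ column must not contribute genotypic variance
    cats = pd.Categorical(hyb_labels).categories
    Z_g[:, [i for i, c in enumerate(cats) if c == "_check_"]] = 0.0
    Z_env = indicator(sub["env"])
    ce = sub["entry_id"].astype(str) + "|" + sub["env"]
    ce = ce.where(sub["is_check"], "_none_")
    Z_ce = indicator(ce)
    cats_ce = pd.Categorical(ce).categories
    Z_ce[:, [i for i, c in enumerate(cats_ce) if c == "_none_"]] = 0.0
    Z_b = indicator(sub["block_id"])

    kernels = {"sigma2_g": Z_g @ Z_g.T, "sigma2_env": Z_env @ Z_env.T,
               "sigma2_ga": Z_ce @ Z_ce.T, "sigma2_b": Z_b @ Z_b.T}
    fit = reml_ai(y, X, kernels)
    vc = VarianceComponents(sigma2_g=fit.varcomps["sigma2_g"],
                            sigma2_ga=fit.varcomps["sigma2_ga"],
                            sigma2_b=fit.varcomps["sigma2_b"],
                            sigma2_e=fit.varcomps["sigma2_e"])
    h2_plot = heritability_from_components(vc, level="plot")
    h2_entry = heritability_from_components(vc, level="entry", n_env=a,
                                            n_rep=r)
    return h2_plot, h2_entry, vc


def heritability_from_components(vc: VarianceComponents, level: str = "plot",
                                 n_env: int = 4, n_rep: int = 1) -> float:
    """Evaluate the heritability formulas at given variance components."""
    g, ga, e = vc.sigma2_g, vc.sigma2_ga, vc.sigma2_e
    if level == "plot":
        denom = g + ga + e
    elif level == "entry":
        denom = g + ga / n_env + e / (n_env * n_rep)
    else:
        raise ValueError("level must be 'plot' or 'entry'")
    return g / denom if denom > 0 else float("nan")


def lnti(means_ln: pd.DataFrame, means_in: pd.DataFrame,
         lnti_bounds: tuple[float, float] | None = None) -> AdjustedMeans:
    """Combine per-regime adjusted means into GY_LN, GY_IN and LNTI.

    Entries with non-positive GY_IN are flagged and excluded downstream;
    ``lnti_bounds`` optionally flags hybrids with LNTI outside an absolute
    band (no exclusion by default).
    """
    ln = means_ln[~means_ln["is_check"]].set_index("entry_id")["adjusted_mean"]
    inn = means_in[~means_in["is_check"]].set_index("entry_id")["adjusted_mean"]
    common = ln.index.intersection(inn.index)
    gy_ln, gy_in = ln[common], inn[common]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (1.0 - gy_ln / gy_in) * 100.0
    excluded = (gy_in <= 0).to_numpy()
    if lnti_bounds is not None:
        lo, hi = lnti_bounds
        excluded |= ((vals < lo) | (vals > hi)).to_numpy()
    tab = pd.DataFrame({"hybrid_id": common, "gy_ln": gy_ln.to_numpy(),
                        "gy_in": gy_in.to_numpy(),
                        "lnti": vals.to_numpy(), "excluded": excluded})
    return AdjustedMeans(tab)


def adjust_both_regimes(plots: pd.DataFrame,
                        lnti_bounds: tuple[float, float] | None = None
                        ) -> tuple[AdjustedMeans, dict[str, VarianceComponents]]:
    """Adjusted means for LN and IN plus the combined LNTI table."""
    means_ln, vc_ln, _ = fit_adjusted_means(plots, "LN")
    means_in, vc_in, _ = fit_adjusted_means(plots, "IN")
    return lnti(means_ln, means_in, lnti_bounds), {"LN": vc_ln, "IN": vc_in}


def joint_factor_screen(plots: pd.DataFrame) -> pd.DataFrame:
    """Wald-type significance screen of site, year and regime on yield.

    A reporting convenience only: OLS with entry effects absorbed; nothing
    downstream is gated on it (the per-regime split is always performed).
    """
    plots = _validate_plots(plots)
    import statsmodels.formula.api as smf
    df = plots.rename(columns={"yield_mg_ha": "y"}).copy()
    df["site"] = df["site"].astype(str)
    df["year"] = df["year"].astype(str)
    model = smf.ols("y ~ C(site) + C(year) + C(n_regime) + C(entry_id)",
                    data=df).fit()
    from statsmodels.stats.anova import anova_lm
    tab = anova_lm(model, typ=2)
    return tab.loc[[r for r in tab.index if "entry" not in r]]
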