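"""Synthetic partial-diallel hybrid populations with known genetic values.

The generator emulates a tropical-maize single-cross program: two heterotic
groups of fully homozygous inbred parents, a partial diallel of their crosses,
and unreplicated augmented-block yield trials run under two nitrogen regimes
in several environments.  True additive and dominance values are returned so
downstream estimators can be checked against the simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotypes import GenotypeMatrix, DiallelDesign, MARKER_COLUMNS


@dataclass
class SimConfig:
    """Parameters of the simulated breeding experiment.

    Defaults mirror the study design this package models: 35 flint + 15 dent
    inbred parents crossed into 906 single-crosses, trials at 2 sites x
    2 years under low and ideal nitrogen, augmented blocks of 16 entries plus
    2 checks, a 0.87 Mg/ha mean yield gap between regimes and a target plot
    heritability of 0.25.
    """

    n_parents_group1: int = 35
    n_parents_group2: int = 15
    n_markers: int = 34571
    n_chromosomes: int = 10
    group_divergence: float = 0.2   # Fst-like Balding-Nichols parameter
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_hybrids: int = 906
    allow_intragroup: bool = True
    n_qtl: int = 300
    dominance_ratio: float = 1.0    # Var_D / Var_A at the QTL level
    h2_plot: float = 0.25
    n_sites: int = 2
    n_years: int = 2
    block_size: int = 16            # regular entries per incomplete block
    n_checks: int = 2
    regime_effect: float = 0.87     # mean(IN) - mean(LN), Mg/ha
    grand_mean: float = 6.935       # Mg/ha; with regime_effect -> 7.37 / 6.50
    genetic_sd: float = 0.55        # SD of total genotypic value, Mg/ha
    genetic_corr: float = 0.8       # LN/IN genetic correlation
    env_sd: float = 0.5             # environment main-effect SD, Mg/ha
    block_sd: float = 0.55          # block-within-environment SD
    checkenv_sd: float = 0.22       # check x environment SD
    ld_block_len: int = 10          # markers per LD block
    ld_rho: float = 0.7             # within-block latent correlation
    line_h2: float = 0.13           # heritability of the per-se line trait
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(n_parents_group1=self.n_parents_group1,
                      n_parents_group2=self.n_parents_group2,
                      n_markers=self.n_markers, n_chromosomes=self.n_chromosomes,
                      n_hybrids=self.n_hybrids, n_qtl=self.n_qtl,
                      n_sites=self.n_sites, n_years=self.n_years,
                      block_size=self.block_size, n_checks=self.n_checks)
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v}")
        if not 0 < self.h2_plot < 1:
            raise ValueError("h2_plot must be in (0, 1)")
        if not 0 <= self.group_divergence < 1:
            raise ValueError("group_divergence must be in [0, 1)")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.dominance_ratio < 0:
            raise ValueError("dominance_ratio must be >= 0")
        if not 0 <= self.line_h2 <= 1:
            raise ValueError("line_h2 must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrueGeneticValues:
    """Simulated truth: per-hybrid values and per-QTL effects."""

    hybrids: pd.DataFrame  # hybrid_id, additive_{in,ln}, dominance_{in,ln},
                           # total_{in,ln}, true_lnti
    qtl: pd.DataFrame      # marker_id, qtl_index, a_in, a_ln, d_in, d_ln, p
    check_values: pd.DataFrame | None = None  # check_id, value


# ---------------------------------------------------------------------------
# parents and diallel
# ---------------------------------------------------------------------------

def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chrom = np.sort(rng.integers(1, cfg.n_chromosomes + 1, size=cfg.n_markers))
    pos = np.empty(cfg.n_markers, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = np.cumsum(rng.integers(500, 50_000, size=idx.size))
    ids = [f"M{i:06d}" for i in range(cfg.n_markers)]
    return pd.DataFrame({"marker_id": ids, "chrom": chrom, "pos": pos})


def simulate_parents(cfg: SimConfig) -> GenotypeMatrix:
    """Two heterotic groups of fully homozygous inbred parents.

    Ancestral allele frequencies are drawn within the configured MAF band and
    diverged between groups with the Balding-Nichols Beta construction at
    Fst = ``group_divergence``.  Linkage disequilibrium within chromosomes is
    induced by a Gaussian-copula block model (markers within a block share a
    latent factor with correlation ``ld_rho``), which preserves every
    marker's marginal allele frequency exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg, rng)

    p0 = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_markers)
    flip = rng.random(cfg.n_markers) < 0.5
    p0 = np.where(flip, 1.0 - p0, p0)

    F = cfg.group_divergence
    group_freqs = []
    for _ in range(2):
        if F == 0:
            group_freqs.append(p0.copy())
        else:
            shape = (1.0 - F) / F
            pg = rng.beta(np.maximum(p0 * shape, 1e-6),
                          np.maximum((1.0 - p0) * shape, 1e-6))
            group_freqs.append(np.clip(pg, 1e-4, 1.0 - 1e-4))

    # block ids restart at chromosome boundaries
    block_id = np.empty(cfg.n_markers, dtype=int)
    b = 0
    for c in np.unique(markers["chrom"]):
        idx = np.flatnonzero(markers["chrom"].to_numpy() == c)
        block_id[idx] = b + np.arange(idx.size) // cfg.ld_block_len
        b = block_id[idx].max() + 1
    n_blocks = b

    n1, n2 = cfg.n_parents_group1, cfg.n_parents_group2
    n = n1 + n2
    groups = np.array([1] * n1 + [2] * n2)
    rho = cfg.ld_rho
    z_core = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, cfg.n_markers))
    z = rho * z_core[:, block_id] + np.sqrt(1.0 - rho ** 2) * eps

    thresh = np.empty(cfg.n_markers)
    dos = np.empty((n, cfg.n_markers))
    for g, pg in zip((1, 2), group_freqs):
        rows = groups == g
        thresh = norm.ppf(pg)
        dos[rows] = np.where(z[rows] < thresh, 2.0, 0.0)

    sample_ids = ([f"F{i + 1:03d}" for i in range(n1)]
                  + [f"D{i + 1:03d}" for i in range(n2)])
    return GenotypeMatrix(dosages=dos, sample_ids=sample_ids, markers=markers,
                          role="parents", groups=groups)


def make_diallel(parents: GenotypeMatrix, n_hybrids: int, seed: int = 0,
                 allow_intragroup: bool = False,
                 groups: np.ndarray | None = None) -> DiallelDesign:
    """Sample a partial diallel: unique unordered crosses between parents.

    By default only inter-group (flint x dent) crosses are candidates; with
    ``allow_intragroup`` every unordered pair is, which is needed to reach
    cross counts beyond the inter-group maximum.
    """
    groups = parents.groups if groups is None else np.asarray(groups)
    if groups is None:
        raise ValueError("parent group labels are required")
    ids = parents.sample_ids
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if allow_intragroup or groups[i] != groups[j]:
                pairs.append((ids[i], ids[j]))
    if n_hybrids > len(pairs):
        raise ValueError(
            f"requested {n_hybrids} hybrids but only {len(pairs)} distinct "
            f"crosses are available"
            + ("" if allow_intragroup else " (set allow_intragroup=True?)"))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=n_hybrids, replace=False)
    chosen.sort()
    rows = [(f"H{k + 1:04d}", *pairs[c]) for k, c in enumerate(chosen)]
    return DiallelDesign(pd.DataFrame(rows, columns=["hybrid_id", "parent1",
                                                     "parent2"]))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _scaled_effects(rng, n_qtl, corr):
    """Correlated effect vectors for the two nitrogen regimes."""
    base = rng.standard_normal(n_qtl)
    other = corr * base + np.sqrt(1.0 - corr ** 2) * rng.standard_normal(n_qtl)
    return base, other


def simulate_phenotypes(hybrids: GenotypeMatrix, design: DiallelDesign,
                        cfg: SimConfig
                        ) -> tuple[pd.DataFrame, TrueGeneticValues]:
    """Plot-level yields for an augmented-block trial plus the truth.

    QTL get additive effects on the {-1, 0, 1} dosage coding and positive-mean
    dominance deviations on the heterozygote indicator, rescaled so the
    realized Var_D/Var_A among hybrids matches ``dominance_ratio`` and the
    total genotypic SD matches ``genetic_sd``.  LN and IN genotypic values
    share QTL but have effects correlated at ``genetic_corr``.  The residual
    variance is set from the realized genetic variance so that
    sigma2_g / (sigma2_g + sigma2_ga + sigma2_e) = ``h2_plot``.
    """
    if cfg.n_qtl > hybrids.n_markers:
        raise ValueError(f"n_qtl={cfg.n_qtl} exceeds {hybrids.n_markers} markers")
    if hybrids.has_missing():
        raise ValueError("hybrid genotypes must be complete")
    rng = np.random.default_rng(cfg.seed + 1)

    m = hybrids.n_markers
    qtl_idx = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    Zq = hybrids.dosages[:, qtl_idx] - 1.0
    Wq = (hybrids.dosages[:, qtl_idx] == 1.0).astype(float)

    a_in, a_ln = _scaled_effects(rng, cfg.n_qtl, cfg.genetic_corr)
    d_raw = np.abs(rng.standard_normal(cfg.n_qtl))  # directional dominance
    d_in = d_raw.copy()
    d_ln = (cfg.genetic_corr * d_raw
            + np.sqrt(1.0 - cfg.genetic_corr ** 2)
            * np.abs(rng.standard_normal(cfg.n_qtl)))

    out = {}
    for regime, a, d in (("in", a_in, d_in), ("ln", a_ln, d_ln)):
        if np.isinf(cfg.dominance_ratio):
            # pure biological dominance: no additive QTL effects at all
            a = np.zeros_like(a)
        A = Zq @ a
        var_a = A.var()
        if cfg.dominance_ratio == 0.0:
            d = np.zeros_like(d)
            D = np.zeros_like(A)
        elif np.isinf(cfg.dominance_ratio):
            D = Wq @ d
        else:
            D0 = Wq @ d
            v0 = D0.var()
            c = np.sqrt(cfg.dominance_ratio * var_a / v0) if v0 > 0 else 0.0
            d = d * c
            D = Wq @ d
        A = A - A.mean()          # genotypic values as deviations
        D = D - D.mean()
        G = A + D
        s = cfg.genetic_sd / G.std() if G.std() > 0 else 1.0
        out[regime] = dict(a=a * s, d=d * s, A=A * s, D=D * s, G=G * s)

    mean_in = cfg.grand_mean + cfg.regime_effect / 2.0
    mean_ln = cfg.grand_mean - cfg.regime_effect / 2.0
    g_in, g_ln = out["in"]["G"], out["ln"]["G"]
    true_lnti = (1.0 - (mean_ln + g_ln) / (mean_in + g_in)) * 100.0

    hyb_ids = design.hybrid_ids
    truth_h = pd.DataFrame({
        "hybrid_id": hyb_ids,
        "additive_in": out["in"]["A"], "dominance_in": out["in"]["D"],
        "total_in": g_in,
        "additive_ln": out["ln"]["A"], "dominance_ln": out["ln"]["D"],
        "total_ln": g_ln,
        "true_lnti": true_lnti,
    })
    p_qtl = hybrids.allele_freq()[qtl_idx]
    truth_q = pd.DataFrame({
        "marker_id": hybrids.marker_ids[qtl_idx], "qtl_index": qtl_idx,
        "a_in": out["in"]["a"], "a_ln": out["ln"]["a"],
        "d_in": out["in"]["d"], "d_ln": out["ln"]["d"], "p": p_qtl,
    })

    check_ids = [f"CHK{c + 1}" for c in range(cfg.n_checks)]
    check_vals = rng.normal(0.0, cfg.genetic_sd, size=cfg.n_checks)
    checks_df = pd.DataFrame({"check_id": check_ids, "value": check_vals})

    n_hyb = len(hyb_ids)
    n_blocks = int(np.ceil(n_hyb / cfg.block_size))
    records = []
    sigma_ga2 = cfg.checkenv_sd ** 2
    for regime, gvals, mu in (("LN", g_ln, mean_ln), ("IN", g_in, mean_in)):
        var_g = gvals.var()
        sig_e2 = max(var_g * (1.0 / cfg.h2_plot - 1.0) - sigma_ga2, 1e-3)
        sig_e = np.sqrt(sig_e2)
        for site in range(1, cfg.n_sites + 1):
            for year in range(1, cfg.n_years + 1):
                env = f"S{site}Y{year}{regime}"
                env_eff = rng.normal(0.0, cfg.env_sd)
                order = rng.permutation(n_hyb)
                block_eff = rng.normal(0.0, cfg.block_sd, size=n_blocks)
                chk_env = rng.normal(0.0, cfg.checkenv_sd, size=cfg.n_checks)
                for b in range(n_blocks):
                    members = order[b * cfg.block_size:(b + 1) * cfg.block_size]
                    bid = f"{env}B{b + 1:03d}"
                    for i in members:
                        y = (mu + env_eff + block_eff[b] + gvals[i]
                             + rng.normal(0.0, sig_e))
                        records.append((hyb_ids[i], False, site, year, regime,
                                        bid, max(y, 0.0)))
                    for c in range(cfg.n_checks):
                        y = (mu + env_eff + block_eff[b] + check_vals[c]
                             + chk_env[c] + rng.normal(0.0, sig_e))
                        records.append((check_ids[c], True, site, year, regime,
                                        bid, max(y, 0.0)))
    plots = pd.DataFrame(records, columns=["entry_id", "is_check", "site",
                                           "year", "n_regime", "block_id",
                                           "yield_mg_ha"])
    truth = TrueGeneticValues(hybrids=truth_h, qtl=truth_q,
                              check_values=checks_df)
    return plots, truth


def line_phenotypes(parents: GenotypeMatrix, truth: TrueGeneticValues,
                    cfg: SimConfig, line_h2: float | None = None,
                    seed: int | None = None) -> pd.Series:
    """Per-se trait values of the inbred parents.

    Homozygous lines express additive QTL contributions only (no
    heterozygotes, so dominance deviations never appear); noise is added to
    reach heritability ``line_h2``.  The additive effects used are the
    across-regime means, mimicking an index trait measured on the lines.
    """
    if np.any(parents.dosages == 1.0):
        raise ValueError("parents must be fully homozygous")
    h2 = cfg.line_h2 if line_h2 is None else line_h2
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    qtl_idx = truth.qtl["qtl_index"].to_numpy()
    a = 0.5 * (truth.qtl["a_in"].to_numpy() + truth.qtl["a_ln"].to_numpy())
    signal = (parents.dosages[:, qtl_idx] - 1.0) @ a
    var_sig = signal.var()
    if h2 >= 1.0:
        noise = np.zeros_like(signal)
    elif var_sig == 0.0 or h2 <= 0.0:
        signal = np.zeros_like(signal)
        noise = rng.standard_normal(signal.size)
    else:
        noise = rng.normal(0.0, np.sqrt(var_sig * (1.0 / h2 - 1.0)),
                           size=signal.size)
    return pd.Series(signal + noise, index=parents.sample_ids,
                     name="line_value")
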