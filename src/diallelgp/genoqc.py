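"""Marker quality control and in-silico single-cross genotypes.

The pipeline order mirrors array-genotyped inbred panels feeding a hybrid
program: call-rate filter -> drop markers with any heterozygote (inbreds
should be fixed) -> seeded homozygous imputation -> LD prune to a target mean
adjacent-pair r^2 -> build hybrid dosages from the mating design -> MAF
filter on the hybrids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genotypes import GenotypeMatrix, DiallelDesign


@dataclass
class QcReport:
    """Per-step accounting of markers removed and retained."""

    step: str
    n_input: int
    n_removed: int
    n_retained: int
    details: dict = field(default_factory=dict)
    per_marker: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.n_removed + self.n_retained != self.n_input:
            raise ValueError("retained + removed must equal input count")

    def to_dict(self) -> dict:
        return {"step": self.step, "n_input": self.n_input,
                "n_removed": self.n_removed, "n_retained": self.n_retained,
                **self.details}


def filter_call_rate(g: GenotypeMatrix, min_rate: float = 0.95
                     ) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers observed in fewer than ``min_rate`` of samples."""
    if not 0.0 < min_rate <= 1.0:
        raise ValueError("min_rate must be in (0, 1]")
    cr = g.call_rate()
    keep = cr >= min_rate
    if not keep.any():
        warnings.warn("call-rate filter removed every marker")
    rep = QcReport("call_rate", g.n_markers, int((~keep).sum()),
                   int(keep.sum()), {"min_rate": min_rate},
                   per_marker=pd.DataFrame({"marker_id": g.marker_ids,
                                            "call_rate": cr, "kept": keep}))
    return g.take_markers(keep), rep


def drop_het_markers(parents: GenotypeMatrix) -> tuple[GenotypeMatrix, QcReport]:
    """Remove loci with at least one heterozygous call among the inbreds."""
    if parents.role != "parents":
        raise ValueError("heterozygote drop applies to parents only")
    any_het = np.nansum(parents.dosages == 1.0, axis=0) > 0
    keep = ~any_het
    rep = QcReport("drop_het", parents.n_markers, int(any_het.sum()),
                   int(keep.sum()))
    return parents.take_markers(keep), rep


def impute_homozygous(parents: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Fill missing inbred calls with seeded draws from {0, 2}.

    Each missing entry is drawn Bernoulli with the marker's observed
    homozygote frequencies, so imputation never introduces heterozygotes and
    is reproducible for a given seed.
    """
    dos = parents.dosages.copy()
    if np.any(dos == 1.0):
        raise ValueError("heterozygous markers must be removed before "
                         "homozygous imputation")
    miss = np.isnan(dos)
    if not miss.any():
        return parents
    n_obs = (~miss).sum(axis=0)
    if np.any(n_obs == 0):
        bad = parents.marker_ids[n_obs == 0][:5]
        raise ValueError(f"markers entirely missing, cannot impute: {list(bad)}")
    p2 = np.nansum(dos == 2.0, axis=0) / n_obs  # observed P(hom alt)
    rng = np.random.default_rng(seed)
    draws = rng.random(dos.shape)
    fill = np.where(draws < p2[None, :], 2.0, 0.0)
    dos[miss] = fill[miss]
    out = GenotypeMatrix(dosages=dos, sample_ids=parents.sample_ids,
                         markers=parents.markers.copy(), role=parents.role,
                         groups=parents.groups)
    return out


def adjacent_mean_r2(g: GenotypeMatrix) -> float:
    """Mean composite-LD r^2 of physically adjacent marker pairs.

    Pairs involving a monomorphic marker are skipped (their LD is
    undefined).
    """
    vals = []
    chrom = g.markers["chrom"].to_numpy()
    sd = g.dosages.std(axis=0)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        for a, b in zip(idx[:-1], idx[1:]):
            if sd[a] == 0.0 or sd[b] == 0.0:
                continue
            r = np.corrcoef(g.dosages[:, a], g.dosages[:, b])[0, 1]
            vals.append(r * r)
    return float(np.mean(vals)) if vals else 0.0


def _prune_at_cut(g: GenotypeMatrix, cut: float, window: int, step: int
                  ) -> np.ndarray:
    """Greedy windowed prune (indep-pairwise style); returns keep mask."""
    m = g.n_markers
    keep = np.ones(m, dtype=bool)
    maf = g.maf()
    chrom = g.markers["chrom"].to_numpy()
    # column-standardized dosages for fast r^2
    X = g.dosages - g.dosages.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0.0] = np.inf
    X = X / sd
    n = X.shape[0]
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < idx.size:
            win = idx[start:start + window]
            live = win[keep[win]]
            if live.size > 1:
                R = (X[:, live].T @ X[:, live]) / n
                r2 = R ** 2
                for ii in range(live.size):
                    if not keep[live[ii]]:
                        continue
                    for jj in range(ii + 1, live.size):
                        if not keep[live[jj]]:
                            continue
                        if r2[ii, jj] > cut:
                            a, b = live[ii], live[jj]
                            drop = a if maf[a] < maf[b] else b
                            keep[drop] = False
            start += step
    return keep


def ld_prune(parents: GenotypeMatrix, target_mean_r2: float = 0.9,
             window: int = 50, step: int = 25
             ) -> tuple[GenotypeMatrix, QcReport]:
    """Prune so the mean adjacent-pair r^2 of the retained panel is <= target.

    A pairwise-r^2 cut drives a greedy sliding-window prune (remove the
    lower-MAF member of any pair above the cut); the cut itself is found by
    bisection as the largest value whose pruned panel meets the target, so
    pruning is as light as the constraint allows.
    """
    if not 0.0 < target_mean_r2 <= 1.0:
        raise ValueError("target_mean_r2 must be in (0, 1]")
    if parents.has_missing():
        raise ValueError("impute before LD pruning")

    # near-duplicate pairs (r^2 > 0.99) are always resolved
    max_cut = 0.99
    keep0 = _prune_at_cut(parents, max_cut, window, step)
    base = parents.take_markers(keep0)
    if adjacent_mean_r2(base) <= target_mean_r2:
        rep = QcReport("ld_prune", parents.n_markers, int((~keep0).sum()),
                       int(keep0.sum()),
                       {"target_mean_r2": target_mean_r2, "cut": max_cut,
                        "achieved_mean_r2": adjacent_mean_r2(base)})
        return base, rep

    lo, hi = 0.0, max_cut
    best_keep = None
    best_cut = 0.0
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        keep = _prune_at_cut(parents, mid, window, step)
        achieved = adjacent_mean_r2(parents.take_markers(keep))
        if achieved <= target_mean_r2:
            best_keep, best_cut = keep, mid
            lo = mid
        else:
            hi = mid
    if best_keep is None:  # even cut ~0 failed; keep the most aggressive prune
        best_cut = 0.0
        best_keep = _prune_at_cut(parents, best_cut, window, step)
    pruned = parents.take_markers(best_keep)
    rep = QcReport("ld_prune", parents.n_markers,
                   int((~best_keep).sum()), int(best_keep.sum()),
                   {"target_mean_r2": target_mean_r2, "cut": best_cut,
                    "achieved_mean_r2": adjacent_mean_r2(pruned)})
    return pruned, rep


def make_hybrid_genotypes(parents: GenotypeMatrix, design: DiallelDesign
                          ) -> GenotypeMatrix:
    """Single-cross dosages: the parental-mean dosage at every marker.

    For fixed homozygous lines the F1 is deterministic, so
    ``(d1 + d2) / 2`` gives 0, 1 or 2 exactly.
    """
    if parents.has_missing():
        raise ValueError("parents must be imputed before building hybrids")
    if np.any(parents.dosages == 1.0):
        raise ValueError("parents must be fully homozygous")
    lookup = {s: i for i, s in enumerate(parents.sample_ids)}
    try:
        i1 = np.array([lookup[p] for p in design.table["parent1"]])
        i2 = np.array([lookup[p] for p in design.table["parent2"]])
    except KeyError as err:
        raise KeyError(f"design references unknown parent {err.args[0]!r}"
                       ) from None
    dos = (parents.dosages[i1] + parents.dosages[i2]) / 2.0
    return GenotypeMatrix(dosages=dos, sample_ids=design.hybrid_ids,
                          markers=parents.markers.copy(), role="hybrids")


def maf_filter(hybrids: GenotypeMatrix, min_maf: float = 0.05
               ) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers whose minor allele frequency is below ``min_maf``."""
    if hybrids.has_missing():
        raise ValueError("MAF filter expects complete genotypes")
    maf = hybrids.maf()
    keep = maf >= min_maf
    rep = QcReport("maf_filter", hybrids.n_markers, int((~keep).sum()),
                   int(keep.sum()), {"min_maf": min_maf},
                   per_marker=pd.DataFrame({"marker_id": hybrids.marker_ids,
                                            "maf": maf, "kept": keep}))
    return hybrids.take_markers(keep), rep


def hwe_test(hybrids: GenotypeMatrix) -> pd.DataFrame:
    """1-df chi-square Hardy-Weinberg test per marker.

    Observed genotype counts are compared with the p^2 / 2pq / q^2
    expectations at the sample allele frequency.
    """
    if hybrids.has_missing():
        raise ValueError("HWE test expects complete genotypes")
    n = hybrids.n_samples
    if n < 5:
        warnings.warn("fewer than 5 samples: HWE chi-square is unreliable")
    dos = hybrids.dosages
    n_aa = (dos == 0.0).sum(axis=0)
    n_ab = (dos == 1.0).sum(axis=0)
    n_bb = (dos == 2.0).sum(axis=0)
    p = (2 * n_bb + n_ab) / (2.0 * n)
    q = 1.0 - p
    exp = np.stack([q * q * n, 2 * p * q * n, p * p * n])
    obs = np.stack([n_aa, n_ab, n_bb]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    pval = chi2.sf(stat, df=1)
    # monomorphic markers fit HWE trivially
    mono = (p == 0.0) | (p == 1.0)
    stat = np.where(mono, 0.0, stat)
    pval = np.where(mono, 1.0, pval)
    return pd.DataFrame({"marker_id": hybrids.marker_ids, "chi2": stat,
                         "p_value": pval, "maf": np.minimum(p, q),
                         "low_n": n < 5})


def run_qc_pipeline(parents: GenotypeMatrix, design: DiallelDesign,
                    min_call_rate: float = 0.95, min_maf: float = 0.05,
                    target_mean_r2: float = 0.9, window: int = 50,
                    step: int = 25, seed: int = 0
                    ) -> tuple[GenotypeMatrix, GenotypeMatrix, list[QcReport]]:
    """Full QC chain; returns (clean parents, hybrid genotypes, reports)."""
    reports = []
    g, rep = filter_call_rate(parents, min_call_rate)
    reports.append(rep)
    g, rep = drop_het_markers(g)
    reports.append(rep)
    g = impute_homozygous(g, seed=seed)
    reports.append(QcReport("impute", g.n_markers, 0, g.n_markers))
    g, rep = ld_prune(g, target_mean_r2, window, step)
    reports.append(rep)
    hyb = make_hybrid_genotypes(g, design)
    hyb, rep = maf_filter(hyb, min_maf)
    reports.append(rep)
    g = g.take_markers(g.markers["marker_id"].isin(hyb.markers["marker_id"])
                       .to_numpy())
    return g, hyb, reports
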