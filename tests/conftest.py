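import numpy as np
import pandas as pd
import pytest

from diallelgp import (SimConfig, simulate_parents, make_diallel,
                       make_hybrid_genotypes, simulate_phenotypes,
                       adjust_both_regimes)
from diallelgp.genotypes import GenotypeMatrix


SMALL_CFG = dict(n_parents_group1=15, n_parents_group2=10, n_markers=600,
                 n_hybrids=120, n_qtl=50, seed=2, allow_intragroup=False,
                 n_sites=2, n_years=2, dominance_ratio=1.0)


@pytest.fixture(scope="session")
def small_sim():
    """One simulated experiment shared across tests (seeded, read-only)."""
    cfg = SimConfig(**SMALL_CFG)
    parents = simulate_parents(cfg)
    design = make_diallel(parents, cfg.n_hybrids, seed=cfg.seed)
    hybrids = make_hybrid_genotypes(parents, design)
    plots, truth = simulate_phenotypes(hybrids, design, cfg)
    means, vcs = adjust_both_regimes(plots)
    return dict(cfg=cfg, parents=parents, design=design, hybrids=hybrids,
                plots=plots, truth=truth, means=means, vcs=vcs)


def toy_genotypes(dosages, role="parents", chrom=None, groups=None):
    """Wrap a small dosage array (samples x markers) in a GenotypeMatrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = np.empty(m, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = np.arange(1, idx.size + 1) * 1000
    markers = pd.DataFrame({"marker_id": [f"m{j}" for j in range(m)],
                            "chrom": chrom, "pos": pos})
    return GenotypeMatrix(dosages=dosages,
                          sample_ids=[f"s{i}" for i in range(n)],
                          markers=markers, role=role, groups=groups)
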