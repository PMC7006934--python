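"""Simulate a two-group inbred panel and a partial diallel of hybrids.

Builds 35 flint + 15 dent fully homozygous parents, crosses them into 300
single-crosses and prints genotype summaries.  The printed Fst-style
divergence should sit near the configured value (0.2), and hybrid
heterozygosity reflects between-group allele-frequency differences.
"""

import numpy as np

from diallelgp import (SimConfig, simulate_parents, make_diallel,
                       make_hybrid_genotypes)

cfg = SimConfig(n_markers=2000, n_hybrids=300, seed=42)
parents = simulate_parents(cfg)
design = make_diallel(parents, cfg.n_hybrids, seed=42, allow_intragroup=True)
hybrids = make_hybrid_genotypes(parents, design)

p1 = parents.dosages[parents.groups == 1].mean(axis=0) / 2
p2 = parents.dosages[parents.groups == 2].mean(axis=0) / 2
fst = ((p1 - p2) ** 2).mean() / (p1 * (1 - p2) + p2 * (1 - p1)).mean()

print(f"parents: {parents.n_samples} x {parents.n_markers} markers, "
      f"all homozygous: {not np.any(parents.dosages == 1)}")
print(f"hybrids: {hybrids.n_samples} crosses "
      f"({design.usage_table().max()} uses of the busiest parent)")
print(f"between-group divergence (naive Fst): {fst:.3f}  (target 0.2)")
print(f"mean hybrid heterozygosity: {hybrids.het_rate().mean():.3f}")
print(f"mean hybrid MAF: {hybrids.maf().mean():.3f}")
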