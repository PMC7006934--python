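"""Genomic relationship matrices, Gaussian kernels and PCA covariates.

Four kinship flavours are used downstream:

* ``trace_norm`` — G = ZZ' * n / trace(ZZ') on the raw {-1, 0, 1} dosage
  coding (no frequency centering); built from all markers (G_Z) or from the
  non-significant complement (G_W) for the fixed-marker prediction models.
* ``vanraden_A`` — columns centered at 2p_j, denominator 2 sum p_j(1-p_j).
* ``dominance_D`` — heterozygote indicators centered at 2p_j q_j,
  denominator sum 2 p_j q_j (1 - p_j q_j).
* ``gaussian_K`` — exp(-h d_ij / median(d)) on the squared genomic distance
  d_ij = G_ii + G_jj - 2 G_ij of an additive GRM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


@dataclass
class KinshipMatrix:
    values: np.ndarray
    sample_ids: list[str]
    kind: str            # trace_norm | vanraden_A | dominance_D | gaussian_K
    marker_ids: np.ndarray | None = None  # provenance

    def __post_init__(self) -> None:
        G = np.asarray(self.values, dtype=float)
        if G.shape[0] != G.shape[1] or G.shape[0] != len(self.sample_ids):
            raise ValueError("kinship must be square and match sample ids")
        if np.abs(G - G.T).max() > 1e-10:
            raise ValueError("kinship must be symmetric")
        self.values = (G + G.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, idx_rows, idx_cols=None) -> np.ndarray:
        idx_cols = idx_rows if idx_cols is None else idx_cols
        return self.values[np.ix_(idx_rows, idx_cols)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str = "trace_norm") -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), list(df.columns), kind)


def _marker_matrix(g: GenotypeMatrix, marker_subset=None) -> tuple[np.ndarray, np.ndarray]:
    if g.has_missing():
        raise ValueError("kinship requires complete genotypes")
    if marker_subset is None:
        return g.dosages, g.marker_ids
    idx = g.marker_index(marker_subset)
    if idx.size == 0:
        raise ValueError("empty marker subset")
    return g.dosages[:, idx], g.marker_ids[idx]


def grm_trace_norm(g: GenotypeMatrix, marker_subset=None,
                   centered: bool = False) -> KinshipMatrix:
    """Trace-normalized GRM on the {-1, 0, 1} coding: trace(G) = n exactly."""
    dos, mids = _marker_matrix(g, marker_subset)
    if dos.shape[1] == 0:
        raise ValueError("empty marker subset")
    Z = dos - 1.0
    if centered:
        Z = Z - Z.mean(axis=0)
    ZZt = Z @ Z.T
    tr = np.trace(ZZt)
    if tr <= 0:
        raise ValueError("degenerate genotypes: trace(ZZ') <= 0")
    G = ZZt * (g.n_samples / tr)
    return KinshipMatrix(G, list(g.sample_ids), "trace_norm", mids)


def grm_additive(g: GenotypeMatrix, marker_subset=None) -> KinshipMatrix:
    """VanRaden additive GRM: centered dosages over 2 sum p_j (1 - p_j)."""
    dos, mids = _marker_matrix(g, marker_subset)
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic markers "
                      "from the additive GRM")
        dos, p, mids = dos[:, poly], p[poly], mids[poly]
    Z = dos - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = Z @ Z.T / denom
    return KinshipMatrix(G, list(g.sample_ids), "vanraden_A", mids)


def grm_dominance(g: GenotypeMatrix, marker_subset=None) -> KinshipMatrix:
    """Dominance GRM: het indicators centered at 2pq over sum 2pq(1-pq)."""
    dos, mids = _marker_matrix(g, marker_subset)
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic markers "
                      "from the dominance GRM")
        dos, p, mids = dos[:, poly], p[poly], mids[poly]
    q = 1.0 - p
    H = (dos == 1.0).astype(float) - 2.0 * p * q
    denom = np.sum(2.0 * p * q * (1.0 - p * q))
    G = H @ H.T / denom
    return KinshipMatrix(G, list(g.sample_ids), "dominance_D", mids)


def gaussian_kernel(G: KinshipMatrix, bandwidth: float = 1.0) -> KinshipMatrix:
    """Gaussian kernel on the genomic distance implied by an additive GRM.

    d_ij = G_ii + G_jj - 2 G_ij is scaled by its median off-diagonal value so
    ``bandwidth`` is unitless; K has unit diagonal and entries in (0, 1].
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    A = G.values
    diag = np.diag(A)
    d = diag[:, None] + diag[None, :] - 2.0 * A
    d = np.clip(d, 0.0, None)
    off = d[~np.eye(G.n, dtype=bool)]
    med = np.median(off)
    if med <= 0:
        med = 1.0
    K = np.exp(-bandwidth * d / med)
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(K, list(G.sample_ids), "gaussian_K", G.marker_ids)


def pca_covariates(g: GenotypeMatrix, n_pc: int) -> np.ndarray:
    """Leading principal-component scores of the centered dosage matrix.

    Sign convention: the largest-|loading| entry of each component is made
    positive, so results are deterministic across LAPACK builds.
    """
    if n_pc < 0 or n_pc > min(3, g.n_samples - 1):
        raise ValueError(f"n_pc must be in 0..{min(3, g.n_samples - 1)}")
    if n_pc == 0:
        return np.empty((g.n_samples, 0))
    if g.has_missing():
        raise ValueError("PCA requires complete genotypes")
    Xc = g.dosages - g.dosages.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_pc] * s[:n_pc]
    for j in range(n_pc):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            scores[:, j] *= -1.0
    return scores
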