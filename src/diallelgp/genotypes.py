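"""Genotype containers and marker-map I/O.

Dosages are stored as a dense ``(n_samples, n_markers)`` float array with
values 0/1/2 counting copies of the reference (higher-dosage) allele and
``NaN`` for missing calls.  Fully homozygous inbred parents therefore carry
only 0/2; single-cross hybrids built in silico carry 0/1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MARKER_COLUMNS = ["marker_id", "chrom", "pos"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus marker map.

    Parameters
    ----------
    dosages
        ``(n_samples, n_markers)`` float array, entries in {0, 1, 2, NaN}.
    sample_ids
        Sample names, length ``n_samples``.
    markers
        Marker map with columns ``marker_id``, ``chrom``, ``pos`` (1-based bp,
        sorted within chromosome).
    role
        ``"parents"`` or ``"hybrids"``.
    groups
        Optional per-sample group labels (heterotic groups for parents).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    markers: pd.DataFrame
    role: str = "parents"
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x markers)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker rows for {m} columns")
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise ValueError(f"marker map lacks columns {missing_cols}")
        self.markers = self.markers.reset_index(drop=True)
        for _, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(pos < 0) or np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be non-negative and strictly "
                                 "increasing within each chromosome")

    # -- basic shapes ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["marker_id"].to_numpy()

    # -- per-marker summaries ---------------------------------------------
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the allele coded by dosage (mean dosage / 2)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def het_rate(self) -> np.ndarray:
        return np.nanmean(self.dosages == 1, axis=0)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    # -- subsetting --------------------------------------------------------
    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            dosages=self.dosages[:, index],
            markers=self.markers.iloc[index].reset_index(drop=True),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        groups = None if self.groups is None else np.asarray(self.groups)[index]
        return replace(
            self,
            dosages=self.dosages[index],
            sample_ids=[self.sample_ids[i] for i in index],
            groups=groups,
        )

    def marker_index(self, marker_ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"unknown marker id {err.args[0]!r}") from None

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, geno_path, map_path=None) -> None:
        """Write markers x samples dosage TSV (and optionally the map)."""
        df = pd.DataFrame(self.dosages.T, index=self.marker_ids,
                          columns=self.sample_ids)
        df.index.name = "marker_id"
        df.to_csv(geno_path, sep="\t", na_rep="NA")
        if map_path is not None:
            self.markers.to_csv(map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, geno_path, map_path, role: str = "parents") -> "GenotypeMatrix":
        df = pd.read_csv(geno_path, sep="\t", index_col=0, na_values=["NA"])
        markers = pd.read_csv(map_path, sep="\t")
        markers = markers.set_index("marker_id").loc[df.index].reset_index()
        return cls(dosages=df.to_numpy(dtype=float).T,
                   sample_ids=list(df.columns), markers=markers, role=role)

    @classmethod
    def from_vcf(cls, vcf_path, role: str = "parents") -> "GenotypeMatrix":
        """Read diploid GT dosages from a VCF (uses cyvcf2)."""
        from cyvcf2 import VCF

        vcf = VCF(str(vcf_path), gts012=True)
        samples = list(vcf.samples)
        rows, recs = [], []
        for var in vcf:
            gts = var.gt_types  # 0=hom ref, 1=het, 2=hom alt, 3=unknown
            dos = gts.astype(float)
            dos[gts == 3] = np.nan
            rows.append(dos)
            recs.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS))
        markers = pd.DataFrame(recs, columns=MARKER_COLUMNS)
        return cls(dosages=np.array(rows).T, sample_ids=samples,
                   markers=markers, role=role)

    def to_vcf(self, path) -> None:
        """Write a minimal VCF with GT fields (alt-dosage coding).

        Homozygous calls come out phased (0|0 / 1|1), heterozygotes as 0/1,
        missing as ./. — sufficient for array-style dosage exchange.
        """
        gt_map = {0.0: "0|0", 1.0: "0/1", 2.0: "1|1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in pd.unique(self.markers["chrom"]):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.sample_ids) + "\n")
            for j, row in self.markers.iterrows():
                calls = [gt_map.get(d, "./.") if not np.isnan(d) else "./."
                         for d in self.dosages[:, j]]
                fh.write(f"{row['chrom']}\t{row['pos']}\t{row['marker_id']}"
                         f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls)
                         + "\n")


@dataclass
class DiallelDesign:
    """Hybrid -> (parent1, parent2) mating table for a partial diallel."""

    table: pd.DataFrame  # columns hybrid_id, parent1, parent2
    REQUIRED = ("hybrid_id", "parent1", "parent2")

    def __post_init__(self) -> None:
        for c in self.REQUIRED:
            if c not in self.table.columns:
                raise ValueError(f"design table lacks column {c!r}")
        pairs = [frozenset((a, b)) for a, b in
                 zip(self.table["parent1"], self.table["parent2"])]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate crosses in diallel design")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_hybrids(self) -> int:
        return len(self.table)

    @property
    def hybrid_ids(self) -> list[str]:
        return list(self.table["hybrid_id"])

    def usage_table(self) -> pd.Series:
        """Times each parent appears as a genitor (mirrors a diallel audit)."""
        both = pd.concat([self.table["parent1"], self.table["parent2"]])
        return both.value_counts().rename("n_crosses")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DiallelDesign":
        return cls(pd.read_csv(path))
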