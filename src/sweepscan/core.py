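"""Core in-memory containers shared by every stage of the scan.

Coordinates are stored 0-based half-open internally; all file I/O converts
at the boundary (VCF positions are 1-based, BED intervals are 0-based
half-open already).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: allele codes in the haplotype matrix
ANCESTRAL = 0
DERIVED = 1
MISSING = -1


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes polarized so 1 = derived allele.

    Attributes
    ----------
    alleles
        int8 matrix, one row per haplotype, one column per site.
        Codes: 0 ancestral, 1 derived, -1 missing.
    positions
        1-based base-pair coordinate per site (as printed in VCF).
    chromosome
        chromosome identifier per site.
    sample_ids
        one id per diploid sample; haplotype rows 2*i and 2*i+1 belong
        to sample i.
    pop_of_haplotype
        population label per haplotype row.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chromosome: np.ndarray
    sample_ids: list[str]
    pop_of_haplotype: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.pop_of_haplotype = np.asarray(self.pop_of_haplotype, dtype=object)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n_hap, n_site = self.alleles.shape
        if n_hap != 2 * len(self.sample_ids):
            raise ValueError(
                f"haplotype count {n_hap} != 2 x sample count {len(self.sample_ids)}"
            )
        if len(self.positions) != n_site or len(self.chromosome) != n_site:
            raise ValueError("positions/chromosome length mismatch with allele matrix")
        if len(self.pop_of_haplotype) != n_hap:
            raise ValueError("pop_of_haplotype length mismatch")
        bad = ~np.isin(self.alleles, (ANCESTRAL, DERIVED, MISSING))
        if bad.any():
            raise ValueError("allele codes must be 0, 1 or -1 (missing)")
        for chrom in pd.unique(self.chromosome):
            pos = self.positions[self.chromosome == chrom]
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        pops, counts = np.unique(self.pop_of_haplotype.astype(str), return_counts=True)
        for p, c in zip(pops, counts):
            if c < 2:
                raise ValueError(f"population {p!r} has fewer than 2 haplotypes")

    # -- convenience ---------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.pop_of_haplotype.astype(str)))

    def hap_indices(self, pop: str) -> np.ndarray:
        """Row indices of the haplotypes belonging to *pop*."""
        idx = np.flatnonzero(self.pop_of_haplotype.astype(str) == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population label: {pop!r}")
        return idx

    def subset_pop(self, pop: str) -> np.ndarray:
        """Allele matrix restricted to one population (view when possible)."""
        return self.alleles[self.hap_indices(pop)]


@dataclass
class GeneTable:
    """Gene intervals in internal 0-based half-open coordinates."""

    table: pd.DataFrame  # columns: gene_id, chromosome, start, end, strand

    def __post_init__(self) -> None:
        req = {"gene_id", "chromosome", "start", "end"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"gene table needs columns {sorted(req)}")
        if "strand" not in self.table.columns:
            self.table = self.table.assign(strand=".")
        if (self.table["start"] >= self.table["end"]).any():
            bad = self.table[self.table["start"] >= self.table["end"]]
            raise ValueError(f"gene intervals with start >= end: {bad['gene_id'].tolist()}")
        if self.table["gene_id"].duplicated().any():
            dup = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dup}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCatalog:
    """Mapping set label -> set of gene ids (e.g. 'CGC', 'TAG')."""

    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, genes in self.sets.items():
            if not label:
                raise ValueError("empty gene-set label")
            if any(not g for g in genes):
                raise ValueError(f"empty gene id in set {label!r}")

    def __getitem__(self, label: str) -> set[str]:
        return self.sets[label]

    def labels(self) -> list[str]:
        return sorted(self.sets)
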