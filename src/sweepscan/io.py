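"""Readers and writers for the formats the scan touches.

VCF (phased GT, ancestral allele from the AA INFO key or a side table),
two-column panel files, BED4 gene annotation, plain-text gene-set lists,
and tab-separated score tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import ANCESTRAL, DERIVED, MISSING, GeneSetCatalog, GeneTable, HaplotypeSet

FLOAT_FMT = "%.6g"


@dataclass
class DropReport:
    """Accounting of VCF records excluded while building a HaplotypeSet."""

    multiallelic: int = 0
    non_snp: int = 0
    missing_ancestral: int = 0
    ancestral_mismatch: int = 0
    sites_kept: int = 0

    @property
    def sites_dropped(self) -> int:
        return (
            self.multiallelic
            + self.non_snp
            + self.missing_ancestral
            + self.ancestral_mismatch
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "multiallelic": self.multiallelic,
            "non_snp": self.non_snp,
            "missing_ancestral": self.missing_ancestral,
            "ancestral_mismatch": self.ancestral_mismatch,
            "sites_kept": self.sites_kept,
            "sites_dropped": self.sites_dropped,
        }


def read_panel(panel_path: str) -> dict[str, str]:
    """Read a two-column (sample, population) whitespace-separated panel.

    Lines starting with ``#`` are comments.
    """
    mapping: dict[str, str] = {}
    with open(panel_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{panel_path}:{lineno}: expected 'sample population'")
            mapping[parts[0]] = parts[1]
    if not mapping:
        raise ValueError(f"panel file {panel_path} defines no samples")
    return mapping


def _read_ancestral_table(path: str) -> dict[tuple[str, int], str]:
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", names=["chrom", "pos", "allele"], dtype=str
    )
    return {
        (row.chrom, int(row.pos)): row.allele.upper() for row in df.itertuples()
    }


def read_haplotypes(
    vcf_path: str,
    panel_path: str,
    ancestral: str = "AA",
) -> tuple[HaplotypeSet, DropReport]:
    """Read a phased VCF into a polarized HaplotypeSet.

    Parameters
    ----------
    vcf_path
        Phased diploid VCF (plain or compressed).
    panel_path
        Two-column sample -> population panel; every VCF sample must appear.
    ancestral
        ``"AA"`` to take the ancestral allele from the AA INFO key, or a
        path to a whitespace-separated chrom/pos/allele table.

    Sites whose ancestral allele is missing, ambiguous, or matches neither
    REF nor ALT are dropped and counted in the returned DropReport, as are
    multi-allelic and non-SNP records.
    """
    panel = read_panel(panel_path)
    aa_table = None if ancestral == "AA" else _read_ancestral_table(ancestral)

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    for s in samples:
        if s not in panel:
            raise ValueError(f"sample {s!r} absent from panel {panel_path}")

    report = DropReport()
    columns: list[np.ndarray] = []
    positions: list[int] = []
    chroms: list[str] = []
    seen: set[tuple[str, int]] = set()

    for v in vcf:
        if len(v.ALT) != 1:
            report.multiallelic += 1
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            report.non_snp += 1
            continue
        key = (v.CHROM, v.POS)
        if key in seen:
            raise ValueError(f"duplicate position {v.CHROM}:{v.POS}")
        seen.add(key)

        if aa_table is None:
            aa = v.INFO.get("AA")
            aa = None if aa is None else str(aa).upper()
        else:
            aa = aa_table.get(key)
        if aa is None or aa in (".", "N", "-", ""):
            report.missing_ancestral += 1
            continue
        if aa not in (ref, alt):
            report.ancestral_mismatch += 1
            continue

        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 >= 0 and a1 >= 0 and not phased:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]!r} at {v.CHROM}:{v.POS}"
                )
            col[2 * i] = MISSING if a0 < 0 else a0
            col[2 * i + 1] = MISSING if a1 < 0 else a1
        if aa == alt:  # ALT is ancestral -> flip polarity
            flip = col >= 0
            col[flip] = 1 - col[flip]
        columns.append(col)
        positions.append(v.POS)
        chroms.append(v.CHROM)

    report.sites_kept = len(columns)
    alleles = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    pops = np.array([panel[s] for s in samples for _ in range(2)], dtype=object)
    hapset = HaplotypeSet(
        alleles=alleles,
        positions=np.array(positions, dtype=np.int64),
        chromosome=np.array(chroms, dtype=object),
        sample_ids=samples,
        pop_of_haplotype=pops,
    )
    return hapset, report


def read_genes(bed_path: str) -> GeneTable:
    """Read a BED4+ file (0-based half-open) into a GeneTable."""
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(f"{bed_path}:{lineno}: need >=4 BED columns")
            chrom, start_s, end_s, name = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{bed_path}:{lineno}: start >= end for {name!r}")
            strand = parts[5] if len(parts) >= 6 else "."
            rows.append((name, chrom, start, end, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])
    return GeneTable(df)


def read_gene_sets(paths: dict[str, str]) -> GeneSetCatalog:
    """Read labeled gene-list files (one gene id per line) into a catalog."""
    sets: dict[str, set[str]] = {}
    for label, path in paths.items():
        if not label:
            raise ValueError("empty gene-set label")
        if not os.path.exists(path):
            raise FileNotFoundError(f"gene-set file not found: {path}")
        with open(path) as fh:
            genes = {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}
        sets[label] = genes
    return GeneSetCatalog(sets)


# ---------------------------------------------------------------------------
# score tables

def write_scores(table: pd.DataFrame, path: str) -> None:
    """Write a score table as TSV with fixed float precision and NA tokens."""
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep="NA")


def read_scores(path: str) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_scores`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
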