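"""End-to-end scan orchestration: inputs -> per-site statistics ->
composite -> gene ranking -> window scan -> gene-set enrichment, with a
run manifest and deterministic TSV/JSON outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .composite import (
    IHS_SIG,
    TOP_K,
    WINDOW_SIZE,
    WINDOW_STEP,
    XPEHH_SIG,
    empirical_selection_probability,
    gene_scores,
    ifxd_sites,
    window_scan,
)
from .core import GeneSetCatalog, GeneTable, HaplotypeSet
from .genesets import gene_level_compare, snp_level_compare
from .haplotype import EHH_CUTOFF, MAF_MIN, MAX_GAP, ihs_scan, xpehh_scan
from .io import read_gene_sets, read_genes, read_haplotypes, write_scores
from .persite import delta_daf, derived_allele_freqs, weir_cockerham_fst
from .simulate import SimulationConfig, export_fixtures, simulate_two_pop

log = logging.getLogger("sweepscan")

DEFAULT_METHODS = ("fst", "xpehh", "ddaf")

#: statistic column and ranking direction feeding each method's Ps
_METHOD_SPEC = {
    "fst": ("fst_floor", "high"),
    "ddaf": ("ddaf", "high"),
    "xpehh": ("xpehh_std", "high"),
    "ihs": ("ihs_std", "absolute"),
}


@dataclass
class ScanConfig:
    """Everything a scan run needs; file inputs or a simulation config."""

    vcf: str | None = None
    panel: str | None = None
    bed: str | None = None
    gene_sets: dict[str, str] = field(default_factory=dict)
    ancestral: str = "AA"
    sim: SimulationConfig | None = None
    highland: str = "highland"
    lowland: str = "lowland"
    methods: tuple[str, ...] = DEFAULT_METHODS
    maf_min: float = MAF_MIN
    ehh_cutoff: float = EHH_CUTOFF
    max_gap: int = MAX_GAP
    ihs_sig: float = IHS_SIG
    xpehh_sig: float = XPEHH_SIG
    window_size: int = WINDOW_SIZE
    window_step: int = WINDOW_STEP
    top_k: int = TOP_K
    out_dir: str = "scan_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < self.window_step:
            raise ValueError("window size must be >= step")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        unknown = set(self.methods) - set(_METHOD_SPEC)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def compute_site_stats(
    hapset: HaplotypeSet,
    highland: str,
    lowland: str,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    maf_min: float = MAF_MIN,
    ehh_cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
) -> pd.DataFrame:
    """Per-SNP statistic table feeding the composite.

    Columns: chromosome, position, per-pop DAF, fst, ddaf, xpehh_raw/std,
    optionally ihs_raw/std, ps_<method> per configured method, ifxd,
    log_ifxd.
    """
    if highland not in hapset.populations or lowland not in hapset.populations:
        raise ValueError(
            f"populations {highland!r}/{lowland!r} not both present "
            f"(panel has {hapset.populations})"
        )
    stats = derived_allele_freqs(hapset)
    stats["fst"] = weir_cockerham_fst(hapset, highland, lowland)
    stats["ddaf"] = delta_daf(hapset, highland, lowland)
    xp = xpehh_scan(
        hapset, highland, lowland, maf_min=maf_min, cutoff=ehh_cutoff, max_gap=max_gap
    )
    stats["xpehh_raw"] = xp["xpehh_raw"].to_numpy()
    stats["xpehh_std"] = xp["xpehh_std"].to_numpy()
    stats.attrs["xpehh_edge_truncated"] = xp.attrs.get("n_edge_truncated", 0)
    if "ihs" in methods:
        ih = ihs_scan(
            hapset, highland, maf_min=maf_min, cutoff=ehh_cutoff, max_gap=max_gap
        )
        stats["ihs_raw"] = ih["ihs_raw"].to_numpy()
        stats["ihs_std"] = ih["ihs_std"].to_numpy()
        stats.attrs["ihs_edge_truncated"] = ih.attrs.get("n_edge_truncated", 0)

    # negative F_ST carries no selection signal: floor before ranking
    stats["fst_floor"] = np.maximum(stats["fst"], 0)
    ps_cols = []
    for m in methods:
        col, direction = _METHOD_SPEC[m]
        stats[f"ps_{m}"] = empirical_selection_probability(
            stats[col].to_numpy(), direction
        )
        ps_cols.append(f"ps_{m}")
    ifxd, log_ifxd, n_skipped = ifxd_sites(stats[ps_cols].to_numpy())
    stats["ifxd"] = ifxd
    stats["log_ifxd"] = log_ifxd
    stats.attrs["ifxd_sites_skipped"] = n_skipped
    return stats.drop(columns=["fst_floor"])


def _enrichment_reports(
    stats: pd.DataFrame,
    genes: GeneTable,
    catalog: GeneSetCatalog,
    gene_table: pd.DataFrame,
    methods: tuple[str, ...],
) -> list[dict]:
    reports = []
    gene_summaries = ["fst_max", "xpehh_sig_num", "ifxd_mean"]
    if "ihs" in methods:
        gene_summaries.insert(1, "ihs_sig_num")
    snp_stats = [c for c in ("fst", "xpehh_std", "ddaf") if c in stats.columns]
    for label in catalog.labels():
        for summary in gene_summaries:
            try:
                reports.append(
                    gene_level_compare(gene_table, catalog, label, summary).as_dict()
                    | {"level": "gene"}
                )
            except ValueError as exc:
                log.warning("gene-level %s/%s skipped: %s", label, summary, exc)
        for stat in snp_stats:
            try:
                reports.append(
                    snp_level_compare(stats, genes, catalog, label, stat).as_dict()
                    | {"level": "snp"}
                )
            except ValueError as exc:
                log.warning("snp-level %s/%s skipped: %s", label, stat, exc)
    return reports


def run_scan(cfg: ScanConfig) -> dict:
    """Execute the full scan; returns the manifest (also written to disk).

    Writes sites.tsv, genes.tsv, windows.tsv, topk.json, enrichment.json
    and manifest.json under ``cfg.out_dir``. Identical config and inputs
    produce byte-identical outputs.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "stages": {},
    }

    if cfg.sim is not None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        hapset, genes, catalog, truth = simulate_two_pop(sim_cfg)
        manifest["truth"] = truth.as_dict()
        drop_report = None
    else:
        if not (cfg.vcf and cfg.panel and cfg.bed):
            raise ValueError("need vcf, panel and bed paths (or a simulation config)")
        hapset, drop = read_haplotypes(cfg.vcf, cfg.panel, cfg.ancestral)
        drop_report = drop.as_dict()
        genes = read_genes(cfg.bed)
        catalog = (
            read_gene_sets(cfg.gene_sets) if cfg.gene_sets else GeneSetCatalog({})
        )
        truth = None
    manifest["stages"]["input"] = {
        "n_haplotypes": hapset.n_haplotypes,
        "n_sites": hapset.n_sites,
        "n_genes": len(genes),
        "drop_report": drop_report,
    }

    stats = compute_site_stats(
        hapset,
        cfg.highland,
        cfg.lowland,
        methods=cfg.methods,
        maf_min=cfg.maf_min,
        ehh_cutoff=cfg.ehh_cutoff,
        max_gap=cfg.max_gap,
    )
    manifest["stages"]["site_stats"] = {
        "n_sites": len(stats),
        "n_ifxd_scored": int(stats["ifxd"].notna().sum()),
        "n_ifxd_skipped": stats.attrs["ifxd_sites_skipped"],
        "xpehh_edge_truncated": stats.attrs.get("xpehh_edge_truncated", 0),
    }
    write_scores(stats, os.path.join(cfg.out_dir, "sites.tsv"))

    gene_table, topk = gene_scores(
        stats, genes, ihs_sig=cfg.ihs_sig, xpehh_sig=cfg.xpehh_sig, top_k=cfg.top_k
    )
    manifest["stages"]["gene_scores"] = {
        "n_scored": topk["n_genes_scored"],
        "n_omitted": topk["n_genes_omitted"],
    }
    write_scores(gene_table, os.path.join(cfg.out_dir, "genes.tsv"))
    with open(os.path.join(cfg.out_dir, "topk.json"), "w") as fh:
        json.dump(topk, fh, indent=2, sort_keys=True)
        fh.write("\n")

    windows = window_scan(stats, "ifxd", size=cfg.window_size, step=cfg.window_step)
    manifest["stages"]["windows"] = {"n_windows": len(windows)}
    write_scores(windows, os.path.join(cfg.out_dir, "windows.tsv"))

    reports = _enrichment_reports(stats, genes, catalog, gene_table, cfg.methods)
    with open(os.path.join(cfg.out_dir, "enrichment.json"), "w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["stages"]["enrichment"] = {"n_comparisons": len(reports)}

    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _config_dict(cfg: ScanConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def demo_config(out_dir: str, seed: int = 0) -> ScanConfig:
    """Small fixed-seed sweep demo: simulate, scan, enrich in well under a
    minute."""
    sim = SimulationConfig(
        n_diploid=300,
        sample_diploids=40,
        burn_in=60,
        t_split=100,
        n_sites=1200,
        chrom_length=600_000,
        sweep=dataclasses.replace(
            SimulationConfig().sweep, enabled=True, s=0.05, init_freq=0.05
        ),
        sweep_gene_set="force_in",
        seed=seed,
    )
    return ScanConfig(sim=sim, out_dir=out_dir, seed=seed)
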