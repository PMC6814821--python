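"""Composite selection scan: per-method selection probabilities, the
product-of-odds composite statistic (iFXD), gene-level aggregation and
ranking, and the sliding-window empirical-p scan.

The composite over n per-SNP methods is

    iFXD = prod_i  Ps_i / (1 - Ps_i)

where Ps_i is the probability that the SNP is under positive selection
according to method i. Ps is realized here as the one-sided empirical rank
probability r/(N+1): r is the SNP's rank among the N genome-wide
non-missing values of the method's statistic, with rank 1 the least
selection-like value under the stated direction and average ranks for
ties. This keeps every Ps strictly inside (0, 1) — no infinite odds — and
makes iFXD a pure rank composite. A parametric alternative (z-score to
normal upper-tail probability, clipped away from 0 and 1) is provided for
standardized statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneTable

IHS_SIG = 2.0
XPEHH_SIG = 2.0
WINDOW_SIZE = 50_000
WINDOW_STEP = 25_000
TOP_K = 2


def empirical_selection_probability(values, direction: str = "high") -> np.ndarray:
    """Per-site Ps = rank/(N+1) under the stated direction.

    direction 'high': larger values are more selection-like; 'low': smaller
    values are; 'absolute': larger |values| are. Missing values stay
    missing and do not enter N.
    """
    values = np.asarray(values, dtype=float)
    if direction == "high":
        keyed = values
    elif direction == "low":
        keyed = -values
    elif direction == "absolute":
        keyed = np.abs(values)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    ok = np.isfinite(keyed)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    ranks = sps.rankdata(keyed[ok], method="average")
    if np.ptp(keyed[ok]) == 0:
        warnings.warn("all values identical; every Ps = 0.5")
    ps = np.full(values.shape, np.nan)
    ps[ok] = ranks / (n + 1)
    return ps


def parametric_selection_probability(
    zscores, direction: str = "high", eps: float = 1e-6
) -> np.ndarray:
    """Ps from a standardized statistic via the normal upper tail,
    clipped to [eps, 1-eps] so the odds stay finite."""
    z = np.asarray(zscores, dtype=float)
    if direction == "absolute":
        z = np.abs(z)
    elif direction == "low":
        z = -z
    elif direction != "high":
        raise ValueError(f"unknown direction {direction!r}")
    ps = sps.norm.cdf(z)
    return np.where(np.isfinite(z), np.clip(ps, eps, 1 - eps), np.nan)


def ifxd_sites(ps_matrix) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-site iFXD and log-iFXD from an (n_sites, n_methods) Ps matrix.

    Sites missing any method's Ps are skipped (NaN) and counted. Returns
    (ifxd, log_ifxd, n_skipped). Ps values outside (0, 1) are an error —
    rank construction guarantees the open interval.
    """
    ps = np.asarray(ps_matrix, dtype=float)
    if ps.ndim == 1:
        ps = ps[:, None]
    ok = np.isfinite(ps).all(axis=1)
    if ((ps[ok] <= 0) | (ps[ok] >= 1)).any():
        raise ValueError("Ps values must lie strictly inside (0, 1)")
    log_ifxd = np.full(ps.shape[0], np.nan)
    with np.errstate(invalid="ignore"):
        log_ifxd[ok] = np.log(ps[ok] / (1 - ps[ok])).sum(axis=1)
    ifxd = np.exp(log_ifxd)
    return ifxd, log_ifxd, int((~ok).sum())


def assign_genes(site_stats: pd.DataFrame, genes: GeneTable) -> pd.Series:
    """Gene id per SNP (NaN when intergenic).

    A SNP belongs to a gene when its 0-based position falls inside the
    gene's half-open interval. SNPs in overlapping genes are assigned to
    the first gene in table order.
    """
    gene_of = pd.Series(np.nan, index=site_stats.index, dtype=object)
    pos0 = site_stats["position"].to_numpy() - 1  # VCF 1-based -> internal
    chrom = site_stats["chromosome"].astype(str).to_numpy()
    for g in genes.table.itertuples():
        hit = (chrom == str(g.chromosome)) & (pos0 >= g.start) & (pos0 < g.end)
        unassigned = gene_of.isna().to_numpy()
        gene_of.iloc[np.flatnonzero(hit & unassigned)] = g.gene_id
    return gene_of


def gene_scores(
    site_stats: pd.DataFrame,
    genes: GeneTable,
    ihs_sig: float = IHS_SIG,
    xpehh_sig: float = XPEHH_SIG,
    top_k: int = TOP_K,
) -> tuple[pd.DataFrame, dict]:
    """Aggregate per-SNP statistics per gene and rank by mean iFXD.

    Per gene: ifxd_mean (arithmetic mean of member-SNP iFXD), n_snps,
    fst_max, ihs_sig_num (|ihs_std| > ihs_sig), xpehh_sig_num
    (xpehh_std > xpehh_sig). Genes containing no scored SNP are omitted
    and counted. Returns the scored table (rank 1 = highest ifxd_mean,
    ties broken by gene id) and a report dict with the top-k genes.
    """
    if len(genes) == 0:
        raise ValueError("empty gene table")
    df = site_stats.copy()
    df["gene_id"] = assign_genes(df, genes)
    member = df[df["gene_id"].notna() & df["ifxd"].notna()]

    rows = []
    for gid, grp in member.groupby("gene_id", sort=False):
        row = {
            "gene_id": gid,
            "n_snps": len(grp),
            "ifxd_mean": grp["ifxd"].mean(),
        }
        row["fst_max"] = grp["fst"].max() if "fst" in grp else np.nan
        row["ihs_sig_num"] = (
            int((grp["ihs_std"].abs() > ihs_sig).sum()) if "ihs_std" in grp else 0
        )
        row["xpehh_sig_num"] = (
            int((grp["xpehh_std"] > xpehh_sig).sum()) if "xpehh_std" in grp else 0
        )
        rows.append(row)
    scored = pd.DataFrame(rows)
    if len(scored):
        scored = scored.sort_values(
            ["ifxd_mean", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)
        scored["rank"] = np.arange(1, len(scored) + 1)
    else:
        scored = pd.DataFrame(
            columns=["gene_id", "n_snps", "ifxd_mean", "fst_max",
                     "ihs_sig_num", "xpehh_sig_num", "rank"]
        )
    report = {
        "top_genes": scored.head(top_k)["gene_id"].tolist(),
        "top_ifxd_mean": scored.head(top_k)["ifxd_mean"].tolist(),
        "n_genes_scored": len(scored),
        "n_genes_omitted": len(genes) - len(scored),
    }
    return scored, report


def window_scan(
    site_stats: pd.DataFrame,
    value_col: str,
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    anchor: int = 0,
) -> pd.DataFrame:
    """Sliding-window mean of a per-SNP statistic with empirical p.

    Windows [start, start + size) stepped by ``step`` tile each
    chromosome from ``anchor``; windows without SNPs are omitted. The
    empirical p of a window is the fraction of windows (itself included)
    whose mean is at least as large, out of N + 1 — strictly inside
    (0, 1), so -log10 p is finite.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if size < step:
        raise ValueError("window size must be >= step")
    rows = []
    df = site_stats[site_stats[value_col].notna()]
    for chrom, grp in df.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        vals = grp[value_col].to_numpy()
        if len(pos) == 0:
            continue
        last = int(pos.max())
        start = anchor
        while start <= last:
            in_w = (pos >= start) & (pos < start + size)
            if in_w.any():
                rows.append(
                    {
                        "chromosome": chrom,
                        "start": start,
                        "end": start + size,
                        "n_snps": int(in_w.sum()),
                        "mean_stat": float(vals[in_w].mean()),
                    }
                )
            start += step
    windows = pd.DataFrame(rows)
    if len(windows) == 0:
        return windows.reindex(
            columns=["chromosome", "start", "end", "n_snps", "mean_stat",
                     "empirical_p", "neg_log10_p"]
        )
    means = windows["mean_stat"].to_numpy()
    n = len(means)
    count_ge = (means[:, None] <= means[None, :]).sum(axis=1) if n <= 4000 else np.array(
        [int((means >= m).sum()) for m in means]
    )
    windows["empirical_p"] = count_ge / (n + 1)
    windows["neg_log10_p"] = -np.log10(windows["empirical_p"])
    return windows
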