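"""Gene-set enrichment of selection statistics by Mann-Whitney U.

Two granularities mirror the two standard views of a cancer-gene-set scan:
gene-level (per-gene summaries such as the maximum F_ST among a gene's
SNPs, or counts of significant iHS / XP-EHH SNPs) and SNP-level (the raw
per-SNP statistic for SNPs inside set-member genes versus SNPs inside all
other genes; intergenic SNPs are excluded by default, since the contrast
is gene set versus other genes, not versus intergenic background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneSetCatalog, GeneTable


@dataclass
class SetComparison:
    set_label: str
    summary: str
    n_in_set: int
    n_other: int
    u_statistic: float
    p_value: float
    neg_log10_p: float
    mean_set: float
    mean_other: float
    alternative: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def mwu_compare(
    values_set,
    values_other,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mann-Whitney U of the set group against the other group.

    U is the statistic for the set group with average ranks for ties.
    The p-value is exact (full enumeration) when the combined sample has
    at most 12 tie-free observations, otherwise the normal approximation
    with tie and continuity corrections is used. ``alternative="greater"``
    tests set > other.
    """
    x = np.asarray(values_set, dtype=float)
    y = np.asarray(values_other, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _comparison(
    label: str, summary: str, vals_set, vals_other, alternative: str
) -> SetComparison:
    u, p = mwu_compare(vals_set, vals_other, alternative)
    return SetComparison(
        set_label=label,
        summary=summary,
        n_in_set=len(vals_set),
        n_other=len(vals_other),
        u_statistic=u,
        p_value=p,
        neg_log10_p=float(-np.log10(p)),
        mean_set=float(np.mean(vals_set)),
        mean_other=float(np.mean(vals_other)),
        alternative=alternative,
    )


def gene_level_compare(
    gene_scores: pd.DataFrame,
    catalog: GeneSetCatalog,
    set_label: str,
    summary: str,
    alternative: str = "greater",
) -> SetComparison:
    """Compare a per-gene summary column between set genes and the rest.

    ``summary`` names a column of the gene-score table (fst_max,
    ihs_sig_num, xpehh_sig_num, ifxd_mean, ...). Catalog ids not among
    the scored genes are ignored.
    """
    members = catalog[set_label]
    in_set = gene_scores["gene_id"].isin(members)
    vals = gene_scores[summary]
    ok = vals.notna()
    x = vals[in_set & ok].to_numpy()
    y = vals[~in_set & ok].to_numpy()
    if x.size == 0:
        raise ValueError(f"no scored gene belongs to set {set_label!r}")
    if y.size == 0:
        raise ValueError(f"every scored gene belongs to set {set_label!r}")
    return _comparison(set_label, summary, x, y, alternative)


def _gene_membership_masks(
    site_stats: pd.DataFrame, genes: GeneTable, members: set[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(in a set gene, in a non-set gene) masks per SNP."""
    pos0 = site_stats["position"].to_numpy() - 1
    chrom = site_stats["chromosome"].astype(str).to_numpy()
    in_set = np.zeros(len(site_stats), dtype=bool)
    in_other = np.zeros(len(site_stats), dtype=bool)
    for g in genes.table.itertuples():
        hit = (chrom == str(g.chromosome)) & (pos0 >= g.start) & (pos0 < g.end)
        if g.gene_id in members:
            in_set |= hit
        else:
            in_other |= hit
    return in_set, in_other


def snp_level_compare(
    site_stats: pd.DataFrame,
    genes: GeneTable,
    catalog: GeneSetCatalog,
    set_label: str,
    statistic: str,
    alternative: str = "greater",
    include_intergenic: bool = False,
) -> SetComparison:
    """Compare a per-SNP statistic between SNPs in set genes and others.

    SNPs inside both a set and a non-set gene count as set SNPs. By
    default intergenic SNPs are excluded; ``include_intergenic=True``
    folds them into the 'other' group.
    """
    vals = site_stats[statistic]
    if vals.notna().sum() == 0:
        raise ValueError(f"statistic {statistic!r} entirely missing")
    in_set, in_other = _gene_membership_masks(site_stats, genes, catalog[set_label])
    other_mask = (
        ~in_set if include_intergenic else (in_other & ~in_set)
    )
    ok = vals.notna().to_numpy()
    x = vals.to_numpy()[in_set & ok]
    y = vals.to_numpy()[other_mask & ok]
    if x.size == 0:
        raise ValueError(f"no scored SNP falls inside set {set_label!r} genes")
    if y.size == 0:
        raise ValueError("no scored SNP in the comparison group")
    return _comparison(set_label, f"snp:{statistic}", x, y, alternative)
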