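"""Per-SNP frequency statistics: derived allele frequencies, Weir-Cockerham
F_ST and the highland-lowland derived-allele-frequency difference (dDAF).

F_ST is the Weir-Cockerham (1984) variance-components estimator theta-hat.
Because the inputs are phased haplotypes, the default variant treats each
haplotype as an independently sampled allele ("haploid" ANOVA on allele
indicators); the classical diploid genotype variant, which additionally
uses observed heterozygosity, is available via ``variant="diploid"``.
Negative estimates are retained (they arise when between-population
variance is below its sampling expectation); clipping to zero happens only
later, when values are converted to selection probabilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DERIVED, MISSING, HaplotypeSet


def derived_allele_freqs(hapset: HaplotypeSet) -> pd.DataFrame:
    """Per-population derived allele frequency at every site.

    Missing calls are excluded from the denominator; a site with zero
    non-missing calls in a population gets NaN there.
    """
    out = {"chromosome": hapset.chromosome, "position": hapset.positions}
    for pop in hapset.populations:
        sub = hapset.subset_pop(pop)
        derived = (sub == DERIVED).sum(axis=0).astype(float)
        called = (sub != MISSING).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"daf_{pop}"] = np.where(called > 0, derived / called, np.nan)
    return pd.DataFrame(out)


def _pop_counts(hapset: HaplotypeSet, pop: str) -> tuple[np.ndarray, np.ndarray]:
    """(derived count, called count) per site for one population."""
    sub = hapset.subset_pop(pop)
    return (
        (sub == DERIVED).sum(axis=0).astype(float),
        (sub != MISSING).sum(axis=0).astype(float),
    )


def weir_cockerham_fst(
    hapset: HaplotypeSet,
    pop_a: str,
    pop_b: str,
    variant: str = "haploid",
) -> np.ndarray:
    """Per-site Weir-Cockerham theta-hat between two populations.

    ``variant="haploid"`` (default) treats haplotypes as alleles;
    ``variant="diploid"`` uses the genotype-level 1984 a/b/c components
    including the heterozygosity term. Sites monomorphic in both
    populations, or with fewer than two called haplotypes in either,
    yield NaN.
    """
    if variant == "haploid":
        return _wc_haploid(hapset, pop_a, pop_b)
    if variant == "diploid":
        return _wc_diploid(hapset, pop_a, pop_b)
    raise ValueError(f"unknown variant {variant!r}")


def _wc_haploid(hapset: HaplotypeSet, pop_a: str, pop_b: str) -> np.ndarray:
    d1, n1 = _pop_counts(hapset, pop_a)
    d2, n2 = _pop_counts(hapset, pop_b)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = d1 / n1, d2 / n2
        n = n1 + n2
        pbar = (d1 + d2) / n
        # one-way ANOVA on allele indicators, r = 2 groups
        msb = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # / (r-1) = 1
        msw = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n - 2)
        n_c = n - (n1**2 + n2**2) / n  # / (r-1)
        denom = msb + (n_c - 1) * msw
        theta = np.where(denom != 0, (msb - msw) / denom, np.nan)
    theta = np.where(valid, theta, np.nan)
    return theta


def _wc_diploid(hapset: HaplotypeSet, pop_a: str, pop_b: str) -> np.ndarray:
    n_sites = hapset.n_sites
    r = 2
    n_i = np.zeros((r, n_sites))
    p_i = np.zeros((r, n_sites))
    h_i = np.zeros((r, n_sites))
    for k, pop in enumerate((pop_a, pop_b)):
        sub = hapset.subset_pop(pop)
        a0, a1 = sub[0::2], sub[1::2]
        called = (a0 != MISSING) & (a1 != MISSING)
        n_i[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(
                n_i[k] > 0,
                ((a0 == DERIVED) & called).sum(axis=0)
                + ((a1 == DERIVED) & called).sum(axis=0),
                np.nan,
            ) / (2 * np.maximum(n_i[k], 1))
            h_i[k] = np.where(
                n_i[k] > 0, ((a0 != a1) & called).sum(axis=0), np.nan
            ) / np.maximum(n_i[k], 1)
    valid = (n_i >= 1).all(axis=0) & (n_i.sum(axis=0) >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.mean(axis=0)
        n_c = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    return np.where(valid, theta, np.nan)


def delta_daf(hapset: HaplotypeSet, highland: str, lowland: str) -> np.ndarray:
    """Per-site dDAF = DAF(highland) - DAF(lowland)."""
    if highland == lowland:
        raise ValueError("highland and lowland labels must differ")
    daf = derived_allele_freqs(hapset)
    return (daf[f"daf_{highland}"] - daf[f"daf_{lowland}"]).to_numpy()
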