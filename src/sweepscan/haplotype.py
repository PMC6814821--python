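"""Extended-haplotype-homozygosity statistics: EHH curves, integrated
haplotype homozygosity (iHH), iHS and cross-population XP-EHH.

EHH at a flanking site s, for a set of n haplotypes carrying a core
allele, is the probability that two carriers drawn without replacement are
identical over the interval from the core to s:

    EHH(s) = sum_h C(n_h, 2) / C(n, 2)

where n_h are the sizes of the distinct extended haplotypes. iHH is the
trapezoidal integral of EHH over physical distance (bp), each direction
truncated at the first site where EHH drops below a cutoff (default 0.05)
or at a gap larger than ``max_gap`` (default 200 kb). Physical rather than
genetic distance is used throughout: no genetic maps are assumed for the
target species, and a constant per-bp rate would only rescale every iHH by
the same factor, leaving the log-ratio statistics unchanged.

iHS at a site is ln(iHH_ancestral / iHH_derived), standardized to zero
mean and unit variance within derived-allele-frequency bins. XP-EHH is
ln(iHH_popA / iHH_popB) with EHH computed over all haplotypes of each
population from the shared core site, standardized genome-wide; positive
values mean longer haplotypes (a more recent or ongoing sweep) in popA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ANCESTRAL, DERIVED, MISSING, HaplotypeSet

EHH_CUTOFF = 0.05
MAX_GAP = 200_000
MAF_MIN = 0.05
N_DAF_BINS = 50
MIN_PER_BIN = 20


class UninformativeCoreError(ValueError):
    """Raised when fewer than two haplotypes carry the requested core allele."""


@dataclass
class EHHCurve:
    """EHH values at increasing distance from a core site, per direction.

    ``left`` and ``right`` are lists of (distance_bp, ehh) pairs starting
    at (0, ehh(core)); for single-allele groups ehh(core) = 1.
    """

    core_index: int
    group: str
    left: list[tuple[int, float]] = field(default_factory=list)
    right: list[tuple[int, float]] = field(default_factory=list)


def _pair_fraction(counts: np.ndarray, n: int) -> float:
    return float((counts * (counts - 1)).sum()) / (n * (n - 1))


def _chrom_bounds(hapset: HaplotypeSet, core: int) -> tuple[int, int]:
    """[lo, hi) index range of the core's chromosome (positions sorted)."""
    chrom = hapset.chromosome[core]
    same = np.flatnonzero(hapset.chromosome == chrom)
    return int(same[0]), int(same[-1]) + 1


def _walk(
    mat: np.ndarray,
    positions: np.ndarray,
    core: int,
    rows: np.ndarray,
    groups: np.ndarray,
    step: int,
    stop: int,
    cutoff: float | None,
    max_gap: int | None,
):
    """Walk outward from the core refining the haplotype partition.

    Yields (site_index, distance_bp, ehh). Haplotypes hitting a missing
    call are removed from the carrier set. Returns a status string:
    'decayed' (EHH < cutoff), 'edge' (chromosome end reached), 'gap'
    (inter-site gap exceeded max_gap), 'lost' (fewer than 2 carriers
    remain).
    """
    n = rows.size
    status = "edge"
    j = core
    out = []
    while True:
        j += step
        if j < 0 or (step > 0 and j >= stop) or (step < 0 and j < stop):
            break
        gap = abs(int(positions[j]) - int(positions[j - step]))
        if max_gap is not None and gap > max_gap:
            status = "gap"
            break
        col = mat[rows, j]
        keep = col != MISSING
        if not keep.all():
            rows, groups, col = rows[keep], groups[keep], col[keep]
            n = rows.size
            if n < 2:
                status = "lost"
                break
        _, groups, counts = np.unique(
            groups * 2 + col, return_inverse=True, return_counts=True
        )
        ehh = _pair_fraction(counts, n)
        out.append((j, abs(int(positions[j]) - int(positions[core])), ehh))
        if cutoff is not None and ehh < cutoff:
            status = "decayed"
            break
    return out, status


def _carrier_setup(
    hapset: HaplotypeSet, pop: str, core: int, group: str
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rows, initial partition and EHH(0) for a core/group choice."""
    rows = hapset.hap_indices(pop)
    col = hapset.alleles[rows, core]
    if group == "all":
        keep = col != MISSING
        rows, col = rows[keep], col[keep]
        if rows.size < 2:
            raise UninformativeCoreError(
                f"uninformative core: <2 called haplotypes at site {core} in {pop!r}"
            )
        _, groups, counts = np.unique(col, return_inverse=True, return_counts=True)
        return rows, groups, _pair_fraction(counts, rows.size)
    allele = {"ancestral": ANCESTRAL, "derived": DERIVED}[group]
    rows = rows[col == allele]
    if rows.size < 2:
        raise UninformativeCoreError(
            f"uninformative core: <2 {group} carriers at site {core} in {pop!r}"
        )
    return rows, np.zeros(rows.size, dtype=np.int64), 1.0


def ehh_curve(hapset: HaplotypeSet, pop: str, core: int, group: str) -> EHHCurve:
    """Full EHH curve (no cutoff truncation) out to the chromosome edges.

    ``group`` is ``"ancestral"``, ``"derived"`` (carriers of that core
    allele, EHH(0) = 1) or ``"all"`` (every called haplotype, partitioned
    by core allele, as used by XP-EHH).
    """
    rows, groups, ehh0 = _carrier_setup(hapset, pop, core, group)
    lo, hi = _chrom_bounds(hapset, core)
    mat, pos = hapset.alleles, hapset.positions
    curve = EHHCurve(core_index=core, group=group)
    for step, stop, side in ((-1, lo, "left"), (1, hi, "right")):
        pts, _ = _walk(mat, pos, core, rows.copy(), groups.copy(), step, stop, None, None)
        side_pts = [(0, ehh0)] + [(d, e) for _, d, e in pts]
        setattr(curve, side, side_pts)
    return curve


def integrated_hh(
    curve: EHHCurve, cutoff: float = EHH_CUTOFF, max_gap: int = MAX_GAP
) -> tuple[float, bool]:
    """Trapezoidal integral of an EHH curve, both directions summed.

    Each direction is truncated at the first point where EHH < cutoff
    (that point's trapezoid is still included) or at a gap > max_gap.
    Returns (iHH in bp*EHH units, edge_truncated flag): the flag is set
    when either direction ran off the chromosome before decaying.
    """
    total = 0.0
    edge_truncated = False
    for pts in (curve.left, curve.right):
        prev_d, prev_e = pts[0]
        decayed = False
        for d, e in pts[1:]:
            gap = d - prev_d
            if gap > max_gap:
                decayed = True  # gap truncation: stop, not an edge case
                break
            total += 0.5 * (prev_e + e) * gap
            prev_d, prev_e = d, e
            if e < cutoff:
                decayed = True
                break
        if not decayed:
            edge_truncated = True
    return total, edge_truncated


def _ihh_from_core(
    hapset: HaplotypeSet,
    pop: str,
    core: int,
    group: str,
    cutoff: float,
    max_gap: int,
) -> tuple[float, bool, bool]:
    """Fused EHH walk + trapezoid integration with early stopping.

    Returns (iHH, edge_truncated, gap_truncated). Equivalent to
    ``integrated_hh(ehh_curve(...))``; avoids materializing full curves.
    """
    rows, groups, ehh0 = _carrier_setup(hapset, pop, core, group)
    lo, hi = _chrom_bounds(hapset, core)
    mat, pos = hapset.alleles, hapset.positions
    total = 0.0
    edge = gap_trunc = False
    for step, stop in ((-1, lo), (1, hi)):
        pts, status = _walk(
            mat, pos, core, rows.copy(), groups.copy(), step, stop, cutoff, max_gap
        )
        prev_d, prev_e = 0, ehh0
        for _, d, e in pts:
            total += 0.5 * (prev_e + e) * (d - prev_d)
            prev_d, prev_e = d, e
        if status == "edge":
            edge = True
        elif status == "gap":
            gap_trunc = True
    return total, edge, gap_trunc


def _pooled_maf(hapset: HaplotypeSet) -> np.ndarray:
    derived = (hapset.alleles == DERIVED).sum(axis=0).astype(float)
    called = (hapset.alleles != MISSING).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        daf = np.where(called > 0, derived / called, np.nan)
    return np.minimum(daf, 1 - daf)


def _merge_daf_bins(bin_idx: np.ndarray, n_bins: int, min_per_bin: int) -> np.ndarray:
    """Merge sparse frequency bins with their right neighbor (last bin
    merges left), so every standardization stratum has enough sites."""
    counts = np.bincount(bin_idx, minlength=n_bins)
    merged_of = np.zeros(n_bins, dtype=int)
    cur, acc = 0, 0
    n_merged = 0
    for b in range(n_bins):
        merged_of[b] = cur
        acc += counts[b]
        if acc >= min_per_bin:
            cur += 1
            n_merged += 1
            acc = 0
    if acc > 0:  # trailing underfull group joins the previous one
        if n_merged == 0:
            warnings.warn("all DAF bins merged into one for iHS standardization")
        merged_of[merged_of == cur] = max(cur - 1, 0)
    return merged_of[bin_idx]


def ihs_scan(
    hapset: HaplotypeSet,
    pop: str,
    maf_min: float = MAF_MIN,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
    n_bins: int = N_DAF_BINS,
    min_per_bin: int = MIN_PER_BIN,
) -> pd.DataFrame:
    """Per-site iHS within one population.

    Columns: position, daf (within pop), ihs_raw, ihs_std. Sites failing
    the pooled-MAF filter, with <2 carriers of either allele, with zero
    iHH, or edge-truncated on either allele are NaN; truncation counts are
    reported in the frame's ``attrs``.
    """
    rows = hapset.hap_indices(pop)
    sub = hapset.alleles[rows]
    derived = (sub == DERIVED).sum(axis=0).astype(float)
    called = (sub != MISSING).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        daf = np.where(called > 0, derived / called, np.nan)
    maf = _pooled_maf(hapset)

    n_sites = hapset.n_sites
    raw = np.full(n_sites, np.nan)
    n_edge = n_gap = 0
    for j in range(n_sites):
        if not (maf[j] >= maf_min):
            continue
        try:
            ihh_a, edge_a, gap_a = _ihh_from_core(hapset, pop, j, "ancestral", cutoff, max_gap)
            ihh_d, edge_d, gap_d = _ihh_from_core(hapset, pop, j, "derived", cutoff, max_gap)
        except UninformativeCoreError:
            continue
        if edge_a or edge_d:
            n_edge += 1
            continue
        if gap_a or gap_d:
            n_gap += 1
        if ihh_a <= 0 or ihh_d <= 0:
            continue
        raw[j] = np.log(ihh_a / ihh_d)

    std = standardize_by_daf(raw, daf, n_bins=n_bins, min_per_bin=min_per_bin)
    out = pd.DataFrame(
        {
            "chromosome": hapset.chromosome,
            "position": hapset.positions,
            "daf": daf,
            "ihs_raw": raw,
            "ihs_std": std,
        }
    )
    out.attrs["n_edge_truncated"] = n_edge
    out.attrs["n_gap_truncated"] = n_gap
    return out


def standardize_by_daf(
    raw: np.ndarray,
    daf: np.ndarray,
    n_bins: int = N_DAF_BINS,
    min_per_bin: int = MIN_PER_BIN,
) -> np.ndarray:
    """Z-score raw values within derived-allele-frequency bins."""
    std = np.full_like(raw, np.nan, dtype=float)
    ok = np.isfinite(raw) & np.isfinite(daf)
    if ok.sum() < 2:
        return std
    bin_idx = np.clip((daf[ok] * n_bins).astype(int), 0, n_bins - 1)
    merged = _merge_daf_bins(bin_idx, n_bins, min_per_bin)
    vals = raw[ok]
    z = np.full(vals.shape, np.nan)
    for b in np.unique(merged):
        sel = merged == b
        mu, sd = vals[sel].mean(), vals[sel].std()
        if sd > 0:
            z[sel] = (vals[sel] - mu) / sd
    std[ok] = z
    return std


def _xpehh_at_core(
    hapset: HaplotypeSet,
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    core: int,
    cutoff: float,
    max_gap: int,
) -> tuple[float, float, bool]:
    """Both populations' iHH from one core, integrated over the shared
    interval where the POOLED two-population EHH stays above the cutoff.

    Truncating both integrals at the same boundary (the pooled decay
    point) keeps the log-ratio comparable across sites; truncating each
    population at its own decay would censor exactly the swept
    population, whose EHH can stay high to the chromosome edge.
    Returns (ihh_a, ihh_b, edge_truncated).
    """
    mat, pos = hapset.alleles, hapset.positions
    rows = np.concatenate([rows_a, rows_b])
    in_b = np.zeros(rows.size, dtype=bool)
    in_b[rows_a.size :] = True
    col = mat[rows, core]
    keep = col != MISSING
    rows, in_b, col = rows[keep], in_b[keep], col[keep]
    if (~in_b).sum() < 2 or in_b.sum() < 2:
        raise UninformativeCoreError(f"<2 called haplotypes at site {core}")
    lo, hi = _chrom_bounds(hapset, core)

    def _ehh3(groups: np.ndarray, b_mask: np.ndarray) -> tuple[float, float, float]:
        n_groups = groups.max() + 1
        c_all = np.bincount(groups, minlength=n_groups)
        c_b = np.bincount(groups[b_mask], minlength=n_groups)
        c_a = c_all - c_b
        return (
            _pair_fraction(c_a, int((~b_mask).sum())),
            _pair_fraction(c_b, int(b_mask.sum())),
            _pair_fraction(c_all, len(groups)),
        )

    _, groups0 = np.unique(col, return_inverse=True)
    ihh_a = ihh_b = 0.0
    edge = False
    for step, stop in ((-1, lo), (1, hi)):
        groups = groups0.copy()
        loc_rows, loc_in_b = rows.copy(), in_b.copy()
        e_a, e_b, e_p = _ehh3(groups, loc_in_b)
        prev_d, prev_a, prev_b = 0, e_a, e_b
        j = core
        decayed = False
        while True:
            j += step
            if j < 0 or (step > 0 and j >= stop) or (step < 0 and j < stop):
                break
            gap = abs(int(pos[j]) - int(pos[j - step]))
            if gap > max_gap:
                decayed = True
                break
            colj = mat[loc_rows, j]
            keepj = colj != MISSING
            if not keepj.all():
                loc_rows, colj = loc_rows[keepj], colj[keepj]
                loc_in_b = loc_in_b[keepj]
                groups = groups[keepj]
                if (~loc_in_b).sum() < 2 or loc_in_b.sum() < 2:
                    decayed = True
                    break
            _, groups = np.unique(groups * 2 + colj, return_inverse=True)
            e_a, e_b, e_p = _ehh3(groups, loc_in_b)
            d = abs(int(pos[j]) - int(pos[core]))
            ihh_a += 0.5 * (prev_a + e_a) * (d - prev_d)
            ihh_b += 0.5 * (prev_b + e_b) * (d - prev_d)
            prev_d, prev_a, prev_b = d, e_a, e_b
            if e_p < cutoff:
                decayed = True
                break
        if not decayed:
            edge = True
    return ihh_a, ihh_b, edge


def xpehh_scan(
    hapset: HaplotypeSet,
    pop_a: str,
    pop_b: str,
    maf_min: float = MAF_MIN,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
) -> pd.DataFrame:
    """Per-site XP-EHH of pop_a versus pop_b.

    xpehh_raw = ln(iHH_a / iHH_b) with EHH over all haplotypes of each
    population from the shared core, both integrals truncated where the
    pooled EHH decays below the cutoff; xpehh_std is the genome-wide
    z-score. Positive values indicate extended haplotypes in pop_a.
    """
    maf = _pooled_maf(hapset)
    n_sites = hapset.n_sites
    raw = np.full(n_sites, np.nan)
    n_edge = 0
    rows_a = hapset.hap_indices(pop_a)
    rows_b = hapset.hap_indices(pop_b)
    for j in range(n_sites):
        if not (maf[j] >= maf_min):
            continue
        try:
            ihh_a, ihh_b, edge = _xpehh_at_core(
                hapset, rows_a, rows_b, j, cutoff, max_gap
            )
        except UninformativeCoreError:
            continue
        if edge:
            n_edge += 1
            continue
        if ihh_a <= 0 or ihh_b <= 0:
            continue
        raw[j] = np.log(ihh_a / ihh_b)

    ok = np.isfinite(raw)
    std = np.full(n_sites, np.nan)
    if ok.sum() >= 2 and raw[ok].std() > 0:
        std[ok] = (raw[ok] - raw[ok].mean()) / raw[ok].std()
    out = pd.DataFrame(
        {
            "chromosome": hapset.chromosome,
            "position": hapset.positions,
            "xpehh_raw": raw,
            "xpehh_std": std,
        }
    )
    out.attrs["n_edge_truncated"] = n_edge
    return out
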