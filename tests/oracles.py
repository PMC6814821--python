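"""Independent brute-force oracles used only by the test suite.

Each oracle is a direct transcription of the defining formula or an
exhaustive enumeration, deliberately sharing no code with the package.
"""

import itertools
import math

import numpy as np


def wc84_haploid(d1, n1, d2, n2):
    """Weir-Cockerham theta-hat treating haplotypes as sampled alleles:
    one-way ANOVA variance components on allele indicators, r = 2."""
    p1, p2 = d1 / n1, d2 / n2
    n = n1 + n2
    pbar = (d1 + d2) / n
    msb = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (2 - 1)
    msw = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n - 2)
    n_c = (n - (n1**2 + n2**2) / n) / (2 - 1)
    denom = msb + (n_c - 1) * msw
    if denom == 0:
        return math.nan
    return (msb - msw) / denom


def wc84_diploid(genos1, genos2):
    """Weir-Cockerham (1984) theta-hat from diploid genotypes (0/1/2
    derived-allele dosage), r = 2, transcribed variance components."""
    r = 2
    n_i, p_i, h_i = [], [], []
    for genos in (genos1, genos2):
        genos = np.asarray(genos)
        n_i.append(len(genos))
        p_i.append(genos.mean() / 2)
        h_i.append((genos == 1).mean())
    n_i, p_i, h_i = map(np.asarray, (n_i, p_i, h_i))
    nbar = n_i.mean()
    n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    a = (nbar / n_c) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    if a + b + c == 0:
        return math.nan
    return a / (a + b + c)


def ehh_pairs(matrix, rows, core, target):
    """EHH by direct pair counting: fraction of carrier pairs identical
    over the inclusive span core..target."""
    lo, hi = min(core, target), max(core, target)
    n = len(rows)
    if n < 2:
        return math.nan
    same = 0
    for i, j in itertools.combinations(rows, 2):
        if (matrix[i, lo : hi + 1] == matrix[j, lo : hi + 1]).all():
            same += 1
    return same / (n * (n - 1) / 2)


def ihh_pairs(matrix, positions, rows, core, cutoff, max_gap, init_groups_by_core):
    """Quadratic-time iHH from the core: trapezoid over pair-counted EHH.

    init_groups_by_core=True mirrors the cross-population convention
    (all haplotypes, partitioned by the core allele, EHH(0) < 1);
    False mirrors the single-allele-carrier convention (EHH(0) = 1).
    Returns (ihh, edge_truncated).
    """
    S = matrix.shape[1]
    total, edge = 0.0, False
    for step, stop in ((-1, -1), (1, S)):
        if init_groups_by_core:
            prev_e = ehh_pairs(matrix, rows, core, core)
        else:
            prev_e = 1.0
        prev_d = 0
        j = core
        decayed = False
        while True:
            j += step
            if j == stop:
                break
            gap = abs(int(positions[j]) - int(positions[j - step]))
            if gap > max_gap:
                decayed = True
                break
            e = ehh_pairs(matrix, rows, core, j)
            d = abs(int(positions[j]) - int(positions[core]))
            total += 0.5 * (prev_e + e) * (d - prev_d)
            prev_d, prev_e = d, e
            if e < cutoff:
                decayed = True
                break
        if not decayed:
            edge = True
    return total, edge


def xpehh_pairs(matrix, positions, rows_a, rows_b, core, cutoff, max_gap):
    """Quadratic-time cross-population iHH pair: both populations'
    trapezoidal EHH integrals over the shared interval where the POOLED
    EHH (pair counting over both populations together) stays >= cutoff.
    Returns (ihh_a, ihh_b, edge_truncated)."""
    S = matrix.shape[1]
    pooled = list(rows_a) + list(rows_b)
    ihh_a = ihh_b = 0.0
    edge = False
    for step, stop in ((-1, -1), (1, S)):
        prev_a = ehh_pairs(matrix, rows_a, core, core)
        prev_b = ehh_pairs(matrix, rows_b, core, core)
        prev_d = 0
        j = core
        decayed = False
        while True:
            j += step
            if j == stop:
                break
            gap = abs(int(positions[j]) - int(positions[j - step]))
            if gap > max_gap:
                decayed = True
                break
            e_a = ehh_pairs(matrix, rows_a, core, j)
            e_b = ehh_pairs(matrix, rows_b, core, j)
            e_p = ehh_pairs(matrix, pooled, core, j)
            d = abs(int(positions[j]) - int(positions[core]))
            ihh_a += 0.5 * (prev_a + e_a) * (d - prev_d)
            ihh_b += 0.5 * (prev_b + e_b) * (d - prev_d)
            prev_d, prev_a, prev_b = d, e_a, e_b
            if e_p < cutoff:
                decayed = True
                break
        if not decayed:
            edge = True
    return ihh_a, ihh_b, edge


def mwu_exact_greater(x, y):
    """One-sided exact Mann-Whitney p (x > y) by enumerating every
    assignment of the pooled ranks to the x group. Tie-free data only."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    nx = len(x)

    def u_of(group):
        return sum(ranks[v] for v in group) - nx * (nx + 1) / 2

    u_obs = u_of(x)
    count = total = 0
    for combo in itertools.combinations(pooled, nx):
        total += 1
        if u_of(combo) >= u_obs:
            count += 1
    return count / total


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration over all tables
    with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-12))
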