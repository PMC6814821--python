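"""Tissue-microarray style contingency analysis: positivity percentages
and 2x2 association tests (chi-square with or without Yates continuity
correction, or Fisher's exact test)."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps


@dataclass
class CountTable2x2:
    """Labeled 2x2 table of non-negative integer counts.

    counts[i][j]: row i (e.g. marker A positive/negative), column j
    (e.g. marker B positive/negative).
    """

    counts: np.ndarray
    row_labels: tuple[str, str] = ("row+", "row-")
    col_labels: tuple[str, str] = ("col+", "col-")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("table must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def positivity_rate(positive: int, total: int) -> tuple[float, float]:
    """Percentage of positives, rounded half-up to one decimal.

    Returns (percentage, raw fraction); e.g. 272 of 487 -> (55.9,
    0.5585...). Half-up rounding matches how such percentages are
    conventionally printed (55.85...% -> 55.9%).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= positive <= total:
        raise ValueError("need 0 <= positive <= total")
    frac = positive / total
    pct = float(
        (Decimal(positive) * 100 / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    return pct, frac


def odds_ratio(table: CountTable2x2) -> float:
    """Cross-product odds ratio ad/bc; NaN when any off-diagonal product
    is zero (no continuity correction applied)."""
    a, b = table.counts[0]
    c, d = table.counts[1]
    if b * c == 0 or a * d == 0:
        return float("nan")
    return float(a * d) / float(b * c)


def association_2x2(
    table: CountTable2x2, method: str = "chi-square-yates"
) -> dict:
    """Association test on a 2x2 table.

    method: 'chi-square' (Pearson, no correction), 'chi-square-yates'
    (continuity-corrected; the default), or 'fisher' (exact, two-sided).
    Chi-square requires all row/column marginals positive; Fisher does
    not. Returns {'statistic', 'p_value', 'odds_ratio', 'method'}.
    """
    counts = table.counts
    if method in ("chi-square", "chi-square-yates"):
        if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
            raise ValueError("zero marginal: chi-square undefined (use fisher)")
        stat, p, _, _ = sps.chi2_contingency(
            counts, correction=(method == "chi-square-yates")
        )
    elif method == "fisher":
        stat, p = sps.fisher_exact(counts, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "odds_ratio": odds_ratio(table),
        "method": method,
    }
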