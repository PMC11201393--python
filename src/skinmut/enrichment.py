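"""Category over-representation by Pearson chi-square.

For each category the 2x2 table (differentially expressed or not x in or out
of the category) is built over a fixed background gene universe and tested
with the 1-df Pearson chi-square without continuity correction.  The
enrichment score is -log10(p).  When any expected cell count falls below 5
a warning is emitted and Fisher's exact test can be requested instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclass
class EnrichmentRow:
    """One category's over-representation result."""

    category: str
    k_de_in: int  # DE genes inside the category
    n_in: int  # category size in the background
    k_de: int  # total DE genes
    n_bg: int  # background size
    chi2: float
    p: float
    score: float  # -log10(p)


def chisq_2x2(
    a: float, b: float, c: float, d: float, *, fisher: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on [[a, b], [c, d]].

    With ``fisher=True`` the p-value comes from Fisher's exact test instead
    (the statistic is still the Pearson chi-square).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square table has a zero margin")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected < 5):
        warnings.warn(
            "expected cell count < 5; chi-square approximation is rough "
            "(consider fisher=True)",
            stacklevel=2,
        )
    if fisher:
        _, p = stats.fisher_exact(np.rint(table).astype(int))
    return float(chi2), float(p)


def enrichment_test(
    de_genes: Iterable[str],
    category_genes: Iterable[str],
    background_genes: Iterable[str],
    *,
    category: str = "",
    fisher: bool = False,
) -> EnrichmentRow:
    """Test whether DE genes fall in a category more often than chance."""
    background = set(background_genes)
    de = set(de_genes) & background
    cat = set(category_genes) & background
    if not cat:
        raise ValueError(
            f"category {category!r} empty after background intersection"
        )
    a = len(de & cat)  # DE, in category
    b = len(de - cat)  # DE, outside
    c = len(cat - de)  # not DE, in category
    d = len(background) - a - b - c  # not DE, outside
    chi2, p = chisq_2x2(a, b, c, d, fisher=fisher)
    return EnrichmentRow(
        category=category,
        k_de_in=a,
        n_in=len(cat),
        k_de=len(de),
        n_bg=len(background),
        chi2=chi2,
        p=p,
        score=float(-np.log10(p)) if p > 0 else np.inf,
    )


def rank_categories(rows: Sequence[EnrichmentRow]) -> list[EnrichmentRow]:
    """Sort by enrichment score descending, ties by category name."""
    if not rows:
        raise ValueError("no enrichment rows")
    return sorted(rows, key=lambda r: (-r.score, r.category))
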