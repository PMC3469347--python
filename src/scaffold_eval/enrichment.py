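"""Functional-category comparison of two gene lists by Fisher exact tests.

For each category present in either list, a 2x2 table (in-category vs not,
list 1 vs list 2) is tested with the two-tailed Fisher exact test
(probability-mass definition: the p-value sums hypergeometric
probabilities of all tables with the same margins no more probable than
the observed one).  Raw p-values are compared against a strict alpha,
and Benjamini-Hochberg adjusted values are always reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One category's 2x2 table, odds ratio, p-values and direction.

    a = list1 genes in the category, b = list1 genes not in it,
    c/d likewise for list2.  ``direction`` is "over" when the category is
    over-represented in list1 relative to list2.
    """

    category: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_raw: float
    p_adj: float
    direction: str


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p-value for the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b + c + d < 1:
        raise ValueError("empty table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def compare_lists(
    list1: Iterable[str],
    list2: Iterable[str],
    ann: AnnotationTable,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every category of either list for unequal representation.

    Lists are deduplicated; genes absent from the annotation table are
    kept with zero categories (logged).  Results are sorted by raw
    p-value.  ``alpha`` is carried for callers' significance counting; no
    filtering happens here.
    """
    genes1 = sorted(set(list1))
    genes2 = sorted(set(list2))
    missing = [g for g in (*genes1, *genes2) if g not in ann]
    if missing:
        logger.warning("%d genes missing from annotation table", len(missing))

    categories = sorted(
        set().union(*(ann.get(g, set()) for g in (*genes1, *genes2))) or set()
    )
    n1, n2 = len(genes1), len(genes2)
    results: list[EnrichmentResult] = []
    p_raws: list[float] = []
    for category in categories:
        a = sum(1 for g in genes1 if category in ann.get(g, ()))
        c = sum(1 for g in genes2 if category in ann.get(g, ()))
        b, d = n1 - a, n2 - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        direction = "over" if (a / n1 if n1 else 0) > (c / n2 if n2 else 0) else "under"
        results.append(
            EnrichmentResult(
                category=category,
                a=a, b=b, c=c, d=d,
                odds_ratio=float(odds) if math.isfinite(odds) else math.inf,
                p_raw=float(p),
                p_adj=float("nan"),  # filled below
                direction=direction,
            )
        )
        p_raws.append(float(p))

    if results:
        adjusted = multipletests(p_raws, method="fdr_bh")[1]
        results = [
            EnrichmentResult(
                category=r.category, a=r.a, b=r.b, c=r.c, d=r.d,
                odds_ratio=r.odds_ratio, p_raw=r.p_raw,
                p_adj=float(p_adj), direction=r.direction,
            )
            for r, p_adj in zip(results, adjusted)
        ]
    results.sort(key=lambda r: (r.p_raw, r.category))
    return results


def count_significant(
    results: Sequence[EnrichmentResult], alpha: float = 0.05, adjusted: bool = False
) -> int:
    """Number of categories with p < alpha (strict), raw or BH-adjusted."""
    return sum(
        1 for r in results if (r.p_adj if adjusted else r.p_raw) < alpha
    )
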