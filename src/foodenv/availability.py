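"""Category availability per region and between-region comparisons.

Availability of a category in a region is the proportion of that region's
food businesses carrying the category: ``N_cs / N_s``, where ``N_s`` is
the region's total business count and ``N_cs`` the count carrying category
``c``. A business with several categories counts once in the denominator
but once toward each of its categories, so availabilities need not sum
to 1 across categories.

Two regions are compared category-by-category through the *net value*
(absolute availability difference), ranked descending, with a pooled
two-proportion z-test per category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .records import BusinessRecord

__all__ = [
    "AvailabilityTable",
    "ComparisonResult",
    "compute_availability",
    "rank_net_differences",
    "two_proportion_ztest",
    "significance_tier",
    "significant_fraction",
]


@dataclass
class AvailabilityTable:
    """Region x category availability with the underlying counts.

    ``counts`` is a DataFrame indexed by region with one column per
    category (category business counts); ``totals`` maps region -> N_s.
    """

    counts: pd.DataFrame
    totals: pd.Series

    @classmethod
    def from_counts(
        cls, counts: dict[str, dict[str, int]], totals: dict[str, int]
    ) -> "AvailabilityTable":
        """Build directly from {region: {category: count}} and {region: N}."""
        df = pd.DataFrame(counts).T.fillna(0).astype(int)
        df = df.reindex(sorted(df.index)).reindex(sorted(df.columns), axis=1)
        return cls(df, pd.Series(totals).reindex(df.index))

    @property
    def regions(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    def availability(self, region: str, category: str) -> float:
        """N_cs / N_s; a category absent from the table counts as 0."""
        n = int(self.totals.loc[region])
        if n == 0:
            raise ValueError(f"region {region!r} has no businesses")
        x = int(self.counts.loc[region, category]) if category in self.counts.columns else 0
        return x / n

    def proportions(self) -> pd.DataFrame:
        """Full region x category availability matrix."""
        return self.counts.div(self.totals, axis=0)

    def row(self, region: str) -> pd.Series:
        """Per-category availability for one region."""
        return self.counts.loc[region] / self.totals.loc[region]


@dataclass(frozen=True)
class ComparisonResult:
    """One category's availability contrast between two regions."""

    category: str
    availability_a: float
    availability_b: float
    net_value: float  # |availability_a - availability_b|
    direction: str  # region code with the larger availability, or "tie"
    z_stat: float
    p_value: float


def compute_availability(businesses: Iterable[BusinessRecord]) -> AvailabilityTable:
    """Tabulate availability from a business list.

    Each business increments its region's denominator once and each of its
    (up to three) categories' counts once. Raises on an empty list; a
    region only enters the table if it has at least one business, so
    zero-business regions are flagged by absence rather than reported as 0.
    """
    businesses = list(businesses)
    if not businesses:
        raise ValueError("compute_availability: empty business list")
    rows = [
        {"region": b.region, "category": c}
        for b in businesses
        for c in b.categories
    ]
    long = pd.DataFrame(rows)
    counts = (
        long.groupby(["region", "category"]).size().unstack(fill_value=0).sort_index()
    )
    counts = counts.reindex(sorted(counts.columns), axis=1)
    totals = pd.Series(
        pd.Series([b.region for b in businesses]).value_counts().sort_index(),
        name="n_businesses",
    ).reindex(counts.index)
    return AvailabilityTable(counts, totals)


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled
    p = (x1+x2)/(n1+n2). A degenerate pooled proportion (0 or 1) carries
    no information and returns (0.0, 1.0).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError(f"invalid counts x={x}, n={n}")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def significance_tier(p: float) -> str:
    """Threshold annotation: '***' p<=.001, '**' p<=.01, '*' p<=.05, else ''."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def rank_net_differences(
    table: AvailabilityTable,
    region_a: str,
    region_b: str,
    benjamini_hochberg: bool = False,
) -> list[ComparisonResult]:
    """Rank category availability differences between two regions.

    One result per category present in either region (absent means count
    0), sorted by descending net value with lexicographic category order
    breaking ties. ``benjamini_hochberg`` additionally FDR-adjusts the raw
    p-values (raw comparison is the default).
    """
    for r in (region_a, region_b):
        if r not in table.counts.index:
            raise KeyError(f"region {r!r} not in availability table")
    n_a = int(table.totals.loc[region_a])
    n_b = int(table.totals.loc[region_b])
    cats = [
        c
        for c in table.categories
        if table.counts.loc[region_a, c] > 0 or table.counts.loc[region_b, c] > 0
    ]
    results = []
    for c in cats:
        x_a = int(table.counts.loc[region_a, c])
        x_b = int(table.counts.loc[region_b, c])
        p_a, p_b = x_a / n_a, x_b / n_b
        z, p = two_proportion_ztest(x_a, n_a, x_b, n_b)
        if p_a > p_b:
            direction = region_a
        elif p_b > p_a:
            direction = region_b
        else:
            direction = "tie"
        results.append(
            ComparisonResult(
                category=c,
                availability_a=p_a,
                availability_b=p_b,
                net_value=abs(p_a - p_b),
                direction=direction,
                z_stat=z,
                p_value=p,
            )
        )
    if benjamini_hochberg and results:
        _, adj, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        results = [
            ComparisonResult(
                r.category, r.availability_a, r.availability_b,
                r.net_value, r.direction, r.z_stat, float(q),
            )
            for r, q in zip(results, adj)
        ]
    results.sort(key=lambda r: (-r.net_value, r.category))
    return results


def significant_fraction(
    results: Sequence[ComparisonResult], alpha: float = 0.05
) -> tuple[int, int]:
    """(number significant at alpha, number of categories compared)."""
    sig = sum(1 for r in results if r.p_value <= alpha)
    return sig, len(results)


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Comparison results as a tidy DataFrame with significance tiers."""
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "availability_a": r.availability_a,
                "availability_b": r.availability_b,
                "net_value": r.net_value,
                "direction": r.direction,
                "z_stat": r.z_stat,
                "p_value": r.p_value,
                "tier": significance_tier(r.p_value),
            }
            for r in results
        ]
    )
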