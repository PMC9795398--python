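"""Region-by-feature matrix assembly for obesity-rate prediction.

Three feature sets:

* ``availability`` — per-category availability proportions;
* ``afford_accept`` — per-category mean price tier (affordability) and
  mean star rating and mean review count (acceptability);
* ``weighted_score`` — the single availability-weighted caloric-density
  score per region.

Category-region combinations with no businesses are zero-filled across
all four per-category columns; the fraction of zero-filled cells is
tracked since it measures how sparse the category coverage is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .availability import AvailabilityTable
from .caloric import StateScoreTable
from .records import BusinessRecord, ObesityTable

log = logging.getLogger(__name__)

__all__ = [
    "FEATURE_SETS",
    "FeatureMatrix",
    "price_to_numeric",
    "build_features",
    "zero_fill_fraction",
    "fill_fraction",
]

FEATURE_SETS = ("availability", "afford_accept", "weighted_score")
_METRICS = ("availability", "price", "rating", "reviews")


def price_to_numeric(tier_symbol: str) -> int:
    """Convert a price symbol of 1-4 dollar signs to its ordinal 1-4."""
    if tier_symbol and set(tier_symbol) == {"$"} and 1 <= len(tier_symbol) <= 4:
        return len(tier_symbol)
    raise ValueError(f"not a price-tier symbol: {tier_symbol!r}")


@dataclass
class FeatureMatrix:
    """Dense region x feature matrix with per-column set tags.

    ``n_zero_filled`` / ``n_per_category_cells`` track the zero-fill
    bookkeeping over the per-category columns (the weighted-score column
    is never zero-filled).
    """

    regions: list[str]
    feature_names: list[str]
    values: np.ndarray
    set_tags: list[str]
    n_zero_filled: int = 0
    n_per_category_cells: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regions, columns=self.feature_names)

    def select_sets(self, sets: Sequence[str]) -> "FeatureMatrix":
        """Sub-matrix restricted to the given feature sets."""
        keep = [i for i, t in enumerate(self.set_tags) if t in sets]
        return FeatureMatrix(
            regions=list(self.regions),
            feature_names=[self.feature_names[i] for i in keep],
            values=self.values[:, keep],
            set_tags=[self.set_tags[i] for i in keep],
            n_zero_filled=self.n_zero_filled,
            n_per_category_cells=self.n_per_category_cells,
        )


def fill_fraction(n_filled: int, n_total: int) -> float:
    """Proportion of zero-filled cells among per-category feature cells."""
    if n_total == 0:
        return 0.0
    return n_filled / n_total


def zero_fill_fraction(matrix: FeatureMatrix) -> float:
    """Zero-filled per-category cells / total per-category cells."""
    return fill_fraction(matrix.n_zero_filled, matrix.n_per_category_cells)


def build_features(
    businesses: Iterable[BusinessRecord],
    availability: AvailabilityTable,
    scores: Optional[StateScoreTable] = None,
    sets: Sequence[str] = FEATURE_SETS,
    obesity: Optional[ObesityTable] = None,
) -> FeatureMatrix:
    """Assemble the requested feature sets into one dense matrix.

    Columns are ordered by category label, then metric (availability,
    price, rating, reviews), with the weighted-score column last. Per
    category and region the affordability/acceptability metrics are means
    over that region's businesses carrying the category; businesses
    without a listed price are excluded from the price mean only. Absent
    category-region combinations are zero-filled in all four per-category
    columns. Regions missing from ``obesity`` (when given) are dropped
    with a warning.
    """
    sets = tuple(sets)
    for s in sets:
        if s not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {s!r}")
    if "weighted_score" in sets and scores is None:
        raise ValueError("weighted_score requested but no score table given")

    businesses = list(businesses)
    if "afford_accept" in sets and not businesses:
        raise ValueError("afford_accept requested but no business data given")

    regions = list(availability.regions)
    if obesity is not None:
        missing = [r for r in regions if r not in obesity.rates]
        if missing:
            log.warning("dropping regions without an obesity outcome: %s", missing)
            regions = [r for r in regions if r in obesity.rates]

    categories = list(availability.categories)
    props = availability.proportions()

    # per-(region, category) means of price / rating / reviews, as
    # region x category matrices aligned with the availability grid
    need_aa = "afford_accept" in sets
    present = (props.reindex(index=regions, columns=categories, fill_value=0) > 0)
    metric_grids: dict[str, pd.DataFrame] = {}
    if "availability" in sets:
        metric_grids["availability"] = props.reindex(
            index=regions, columns=categories, fill_value=0.0
        )
    if need_aa:
        rows = [
            {
                "region": b.region,
                "category": c,
                "price": np.nan if b.price_tier is None else float(b.price_tier),
                "rating": b.rating,
                "reviews": float(b.review_count),
            }
            for b in businesses
            for c in b.categories
        ]
        long = pd.DataFrame(rows)
        agg = long.groupby(["region", "category"]).mean()
        for metric in ("price", "rating", "reviews"):
            metric_grids[metric] = (
                agg[metric].unstack().reindex(index=regions, columns=categories)
            )

    per_cat_metrics = [m for m in _METRICS if m in metric_grids]

    names: list[str] = []
    tags: list[str] = []
    cols: list[np.ndarray] = []
    n_zero = 0
    n_cells = 0
    for cat in categories:
        for metric in per_cat_metrics:
            names.append(f"{cat}::{metric}")
            tags.append("availability" if metric == "availability" else "afford_accept")
            raw = metric_grids[metric][cat].to_numpy(dtype=float)
            here = present[cat].to_numpy()
            # absent category-region combination, or (for price) a present
            # category whose businesses all lack a price: zero-fill
            filled = ~here | np.isnan(raw)
            col = np.where(filled, 0.0, raw)
            n_cells += len(regions)
            n_zero += int(filled.sum())
            cols.append(col)

    if "weighted_score" in sets:
        names.append("weighted_score")
        tags.append("weighted_score")
        cols.append(np.array([scores.scores[r] for r in regions]))

    values = np.column_stack(cols) if cols else np.zeros((len(regions), 0))
    return FeatureMatrix(
        regions=regions,
        feature_names=names,
        values=values,
        set_tags=tags,
        n_zero_filled=n_zero,
        n_per_category_cells=n_cells,
    )
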