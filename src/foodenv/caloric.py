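"""Caloric-density estimation and the availability-weighted state score.

The chain is: nutrition records -> dish densities (kcal/gram, gram-unit
records only) -> category densities (unweighted mean over a category's
popular dishes) -> a per-region weighted score (availability-weighted
mean of category densities). The score summarizes how calorie-dense a
region's restaurant mix is; it is then correlated with the region's
obesity prevalence.

Crowd-sourced records use many serving-unit dialects ("g", "grams",
"oz", "slice", ...). Only gram-denominated records enter density
estimates, because calories per gram is only defined when the serving
quantity is a mass in grams.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .availability import AvailabilityTable
from .records import BusinessRecord, NutritionRecord, ObesityTable, PopularDishTable

log = logging.getLogger(__name__)

__all__ = [
    "GRAM_UNITS",
    "is_gram_unit",
    "dish_density",
    "category_density",
    "DensityRegistry",
    "build_density_registry",
    "StateScoreTable",
    "state_weighted_score",
    "state_scores",
    "score_obesity_correlation",
    "compare_regions_ztest",
]

GRAM_UNITS = frozenset({"g", "gr", "gram", "grams"})


def is_gram_unit(unit: str) -> bool:
    """True iff the trimmed, lowercased unit is a gram spelling."""
    return unit.strip().lower() in GRAM_UNITS


def dish_density(
    records: Sequence[NutritionRecord], max_density: Optional[float] = None
) -> Optional[float]:
    """Mean calories-per-gram over a dish's gram-unit records.

    Non-gram records are ignored; returns None when no gram record
    survives. ``max_density`` optionally drops implausible records above
    the cap (off by default: raw crowd data is taken at face value).
    """
    ratios = []
    for r in records:
        if not is_gram_unit(r.serving_unit):
            continue
        d = r.calories / r.serving_qty
        if max_density is not None and d > max_density:
            log.warning("dish %r: dropping record with density %.2f > cap", r.dish, d)
            continue
        ratios.append(d)
    if not ratios:
        return None
    return float(np.mean(ratios))


def category_density(
    dishes: Sequence[str], dish_densities: dict[str, float]
) -> Optional[float]:
    """Unweighted mean density over the category's distinct popular dishes.

    Dishes without a density estimate are excluded; duplicates in the
    popularity list count once. None when no dish has a density.
    """
    vals = [dish_densities[d] for d in dict.fromkeys(dishes) if d in dish_densities]
    if not vals:
        return None
    return float(np.mean(vals))


@dataclass
class DensityRegistry:
    """Dish and category caloric densities (kcal/gram) with record counts."""

    dish: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["density", "n_gram_records"])
    )
    category: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["density", "n_dishes"])
    )

    def dish_density_of(self, dish: str) -> Optional[float]:
        return float(self.dish.loc[dish, "density"]) if dish in self.dish.index else None

    def category_density_of(self, category: str) -> Optional[float]:
        if category in self.category.index:
            return float(self.category.loc[category, "density"])
        return None

    @property
    def category_densities(self) -> pd.Series:
        return self.category["density"]


def build_density_registry(
    nutrition: Iterable[NutritionRecord],
    popular: PopularDishTable,
    max_density: Optional[float] = None,
) -> DensityRegistry:
    """Estimate dish densities, then roll them up to category densities.

    Categories with no density-bearing popular dish are excluded from the
    registry with a warning.
    """
    by_dish: dict[str, list[NutritionRecord]] = {}
    for r in nutrition:
        by_dish.setdefault(r.dish, []).append(r)

    dish_rows = {}
    for dish, recs in sorted(by_dish.items()):
        d = dish_density(recs, max_density=max_density)
        if d is not None:
            n_gram = sum(1 for r in recs if is_gram_unit(r.serving_unit))
            dish_rows[dish] = {"density": d, "n_gram_records": n_gram}
    dish_df = pd.DataFrame.from_dict(dish_rows, orient="index")

    densities = {d: row["density"] for d, row in dish_rows.items()}
    cat_rows = {}
    for cat in popular.categories:
        dishes = popular.dishes[cat]
        cd = category_density(dishes, densities)
        if cd is None:
            log.warning("category %r: no popular dish has a density; excluded", cat)
            continue
        n = sum(1 for d in dict.fromkeys(dishes) if d in densities)
        cat_rows[cat] = {"density": cd, "n_dishes": n}
    cat_df = pd.DataFrame.from_dict(cat_rows, orient="index")
    return DensityRegistry(dish_df, cat_df)


@dataclass
class StateScoreTable:
    """Region -> availability-weighted caloric-density score (kcal/gram)."""

    scores: dict[str, float]

    @property
    def regions(self) -> list[str]:
        return sorted(self.scores)

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, name="weighted_score").sort_index()


def state_weighted_score(
    avail_row: pd.Series, registry: DensityRegistry, region: str = "?"
) -> float:
    """Normalized availability-weighted mean of category densities.

    score = sum_c a_c * d_c / sum_c a_c over categories with both an
    availability > 0 and a density. The normalization makes the score a
    convex combination of category densities (availabilities do not sum
    to 1, since businesses carry up to three categories), so it always
    lies inside the range of contributing densities.
    """
    dens = registry.category_densities
    common = [c for c in avail_row.index if c in dens.index and avail_row[c] > 0]
    if not common:
        raise ValueError(
            f"region {region!r}: no category with availability and density"
        )
    a = avail_row[common].to_numpy(dtype=float)
    d = dens[common].to_numpy(dtype=float)
    return float((a * d).sum() / a.sum())


def state_scores(
    table: AvailabilityTable, registry: DensityRegistry
) -> StateScoreTable:
    """Weighted score for every region in the availability table."""
    props = table.proportions()
    return StateScoreTable(
        {r: state_weighted_score(props.loc[r], registry, region=r) for r in props.index}
    )


def score_obesity_correlation(
    scores: StateScoreTable, obesity: ObesityTable
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between region scores and obesity rates.

    Uses the regions common to both tables; needs at least 3 and
    non-constant values on each side.
    """
    common = sorted(set(scores.scores) & set(obesity.rates))
    if len(common) < 3:
        raise ValueError(f"need >= 3 common regions, have {len(common)}")
    x = np.array([scores.scores[r] for r in common])
    y = np.array([obesity.rates[r] for r in common])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in scores or obesity rates")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def business_density(
    business: BusinessRecord, registry: DensityRegistry
) -> Optional[float]:
    """Mean category density over the business's density-bearing categories."""
    vals = [
        registry.category_density_of(c)
        for c in business.categories
        if registry.category_density_of(c) is not None
    ]
    if not vals:
        return None
    return float(np.mean(vals))


def compare_regions_ztest(
    region_a: str,
    region_b: str,
    businesses: Iterable[BusinessRecord],
    registry: DensityRegistry,
) -> tuple[float, float]:
    """Two-sample z-test on business-level caloric densities of two regions.

    Each business contributes the mean density of its categories; the two
    per-business samples are compared with an unpooled-variance z
    statistic, z = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with a
    two-sided normal p-value.
    """
    samples: dict[str, list[float]] = {region_a: [], region_b: []}
    for b in businesses:
        if b.region in samples:
            d = business_density(b, registry)
            if d is not None:
                samples[b.region].append(d)
    for r, vals in samples.items():
        if len(vals) < 2:
            raise ValueError(
                f"region {r!r}: need >= 2 businesses with defined density, "
                f"have {len(vals)}"
            )
    a = np.array(samples[region_a])
    b = np.array(samples[region_b])
    se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if se == 0:
        return 0.0, 1.0
    z = (a.mean() - b.mean()) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
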