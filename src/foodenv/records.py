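"""Core record types for the food-environment data model.

Four tables drive the analysis:

* business listings (one row per food business, with region, categories,
  price tier, star rating and review count),
* crowd-sourced nutrition records (dish, calories, serving size and a
  free-text serving unit),
* popular-dish rankings per category, and
* region-level adult obesity prevalence.

A fifth table, the category registry, flags which listing categories are
food-related; non-food categories are stripped at ingest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "BusinessRecord",
    "NutritionRecord",
    "PopularDishTable",
    "ObesityTable",
    "CategoryRegistry",
    "DEFAULT_REGIONS",
    "normalize_dish_name",
]

# 49 US states plus the District of Columbia. New Jersey is excluded from
# the default analysis universe because its outcome row is unavailable in
# the BRFSS extract this pipeline mirrors.
DEFAULT_REGIONS: tuple[str, ...] = (
    "AL", "AK", "AZ", "AR", "CA", "CO", "CT", "DE", "DC", "FL",
    "GA", "HI", "ID", "IL", "IN", "IA", "KS", "KY", "LA", "ME",
    "MD", "MA", "MI", "MN", "MS", "MO", "MT", "NE", "NV", "NH",
    "NM", "NY", "NC", "ND", "OH", "OK", "OR", "PA", "RI", "SC",
    "SD", "TN", "TX", "UT", "VT", "VA", "WA", "WV", "WI", "WY",
)

_WS = re.compile(r"\s+")


def normalize_dish_name(name: str) -> str:
    """Lowercase and collapse internal whitespace.

    Dish names arrive from two independent sources (restaurant pages and a
    nutrition database); this canonical form is applied before any join.
    """
    return _WS.sub(" ", name.strip().lower())


@dataclass(frozen=True)
class BusinessRecord:
    """One listed food business.

    ``categories`` holds 1-3 distinct labels (listings allow up to three).
    ``price_tier`` is the ordinal 1-4 translation of the $..$$$$ symbols,
    or ``None`` when the listing carries no price. ``rating`` is a
    half-step star value in [0.5, 5.0].
    """

    business_id: str
    region: str
    categories: tuple[str, ...]
    price_tier: Optional[int]
    rating: float
    review_count: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.categories) <= 3:
            raise ValueError(
                f"business {self.business_id!r}: expected 1-3 categories, "
                f"got {len(self.categories)}"
            )
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(
                f"business {self.business_id!r}: duplicate category labels"
            )
        if self.price_tier is not None and self.price_tier not in (1, 2, 3, 4):
            raise ValueError(
                f"business {self.business_id!r}: price tier must be 1-4, "
                f"got {self.price_tier}"
            )
        if not 0.5 <= self.rating <= 5.0 or round(self.rating * 2) != self.rating * 2:
            raise ValueError(
                f"business {self.business_id!r}: rating must be a half-step "
                f"value in [0.5, 5.0], got {self.rating}"
            )
        if self.review_count < 0:
            raise ValueError(
                f"business {self.business_id!r}: negative review count"
            )


@dataclass(frozen=True)
class NutritionRecord:
    """One crowd-sourced calorie entry for a dish.

    ``serving_unit`` is kept raw; the caloric module decides which units
    denote grams. ``calories`` is kcal per the stated serving.
    """

    dish: str
    calories: float
    serving_qty: float
    serving_unit: str

    def __post_init__(self) -> None:
        if self.calories <= 0:
            raise ValueError(f"dish {self.dish!r}: calories must be > 0")
        if self.serving_qty <= 0:
            raise ValueError(f"dish {self.dish!r}: serving_qty must be > 0")


@dataclass
class PopularDishTable:
    """Ranked popular dishes per category (rank 1 = most popular)."""

    dishes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat, names in self.dishes.items():
            if not names:
                raise ValueError(f"category {cat!r} has no popular dishes")

    @property
    def categories(self) -> list[str]:
        return sorted(self.dishes)


@dataclass
class ObesityTable:
    """Region code -> adult obesity prevalence in percent."""

    rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, rate in self.rates.items():
            if not 0.0 < rate < 100.0:
                raise ValueError(
                    f"region {region!r}: obesity rate {rate} outside (0, 100)"
                )

    @property
    def regions(self) -> list[str]:
        return sorted(self.rates)

    def __len__(self) -> int:
        return len(self.rates)


@dataclass
class CategoryRegistry:
    """Category label -> whether the category is food-related."""

    flags: dict[str, bool] = field(default_factory=dict)

    def is_food(self, category: str) -> bool:
        return self.flags.get(category, False)

    @property
    def food_categories(self) -> list[str]:
        return sorted(c for c, ok in self.flags.items() if ok)

    @classmethod
    def all_food(cls, categories) -> "CategoryRegistry":
        """Registry that flags every given category as food."""
        return cls({c: True for c in categories})
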