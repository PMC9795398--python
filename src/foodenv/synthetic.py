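"""Synthetic food-environment worlds with a planted obesity link.

A *world* is a complete, internally consistent set of the four input
tables (businesses, nutrition records, popular dishes, region obesity
rates) plus the ground truth that generated them. Each region draws a
category mix; the mix-weighted mean of the categories' true caloric
densities is the region's true environment score ``E_s``; obesity is a
linear function of ``E_s`` plus Gaussian noise, clamped to a plausible
range. Because the link is planted and tunable, every downstream stage
(availability, density recovery, weighted score, prediction) can be
tested for recovery, and a zero-slope world provides a null control.

What the generator emulates from real crowd-sourced data: businesses
carrying 1-3 categories, ordinal price tiers with occasional missing
prices, half-step star ratings, heavy-tailed (log-normal) review counts,
mixed serving-unit dialects with per-record multiplicative calorie
noise, and region-to-region differences in category mixes. It does not
emulate geography, chains, text reviews, or temporal change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .records import (
    DEFAULT_REGIONS,
    BusinessRecord,
    CategoryRegistry,
    NutritionRecord,
    ObesityTable,
    PopularDishTable,
    normalize_dish_name,
)

log = logging.getLogger(__name__)

__all__ = [
    "CategorySpec",
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "default_config",
    "default_categories",
]

# Obesity prevalences outside this band are not plausible for US states;
# generated rates are clamped to it.
OBESITY_CLAMP = (5.0, 60.0)

GRAM_DIALECTS = ("g", "gram", "grams", "gr", " G ", "Grams")
NON_GRAM_DIALECTS = ("oz", "piece", "slice", "package", "serving", "breast", "cup")


@dataclass(frozen=True)
class CategorySpec:
    """One food category with its true caloric density (kcal/gram)."""

    label: str
    true_density: float
    obesogenic_weight: float


# Roughly sixty restaurant categories spanning the caloric-density range
# seen in crowd-sourced dish data (salads/soups near 1 kcal/g, fried and
# bakery food up to ~5). Labels are generic but realistic.
_CATEGORY_SEED: tuple[tuple[str, float], ...] = (
    ("Salad", 0.8), ("Soup", 0.9), ("Juice Bars", 1.0), ("Poke", 1.2),
    ("Sushi Bars", 1.3), ("Seafood", 1.5), ("Vegan", 1.4), ("Vegetarian", 1.5),
    ("Mediterranean", 1.7), ("Greek", 1.8), ("Vietnamese", 1.6), ("Thai", 1.9),
    ("Japanese", 1.7), ("Korean", 2.0), ("Chinese", 2.1), ("Dim Sum", 2.2),
    ("Indian", 2.3), ("Middle Eastern", 2.0), ("Tapas", 2.1), ("Ramen", 1.8),
    ("Breakfast & Brunch", 2.4), ("Diners", 2.5), ("Cafes", 2.3),
    ("Coffee & Tea", 2.2), ("Sandwiches", 2.6), ("Delis", 2.5),
    ("Food Trucks", 2.6), ("Mexican", 2.4), ("Tex-Mex", 2.7), ("Tacos", 2.3),
    ("Latin American", 2.4), ("Cuban", 2.6), ("Caribbean", 2.5),
    ("American (New)", 2.8), ("American (Traditional)", 3.0), ("Bars", 2.9),
    ("Sports Bars", 3.0), ("Pubs", 2.9), ("Breweries", 2.8),
    ("Italian", 2.9), ("Pasta Shops", 3.0), ("Pizza", 3.1), ("Steakhouses", 3.2),
    ("Barbeque", 3.3), ("Smokehouse", 3.3), ("Burgers", 3.4), ("Hot Dogs", 3.4),
    ("Chicken Wings", 3.5), ("Chicken Shop", 3.4), ("Fish & Chips", 3.5),
    ("Cajun/Creole", 3.4), ("Southern", 3.6), ("Soul Food", 3.6),
    ("Comfort Food", 3.5), ("Buffets", 3.6), ("Fast Food", 3.8),
    ("Fried Chicken", 4.0), ("Donuts", 4.3), ("Bakeries", 4.2),
    ("Desserts", 4.4), ("Ice Cream & Frozen Yogurt", 4.1), ("Candy Stores", 4.8),
)


def default_categories(n: Optional[int] = None) -> list[CategorySpec]:
    """The built-in category panel with densities and obesogenic weights.

    The obesogenic weight is the standardized true density: calorie-dense
    categories are the ones whose prevalence tilts a region toward
    obesity.
    """
    pairs = _CATEGORY_SEED if n is None else _CATEGORY_SEED[:n]
    dens = np.array([d for _, d in pairs])
    z = (dens - dens.mean()) / dens.std()
    return [
        CategorySpec(label, float(d), float(w))
        for (label, _), d, w in zip(pairs, dens, z)
    ]


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic world.

    The defaults describe a study-scale world: 50 regions (49 states plus
    DC), ~60 categories, 2000 businesses per region, log-normal review
    counts with a heavy tail, a quarter of nutrition records in non-gram
    units, and a linear obesity link calibrated so that generated rates
    span roughly 20-42%.
    """

    n_regions: int = 50
    categories: tuple[CategorySpec, ...] = tuple(default_categories())
    businesses_per_region: int = 2000
    region_mix_skew: float = 1.2
    n_categories_probs: tuple[float, float, float] = (0.50, 0.35, 0.15)
    price_tier_probs: tuple[float, float, float, float] = (0.50, 0.38, 0.09, 0.03)
    price_missing_prob: float = 0.10
    rating_mean: float = 4.0
    rating_noise_sd: float = 0.75
    review_count_log_mean: float = 3.6
    review_count_log_sd: float = 1.4
    dishes_per_category: int = 5
    records_per_dish: int = 8
    non_gram_fraction: float = 0.25
    calorie_noise_cv: float = 0.15
    category_absence_fraction: float = 0.22
    obesity_intercept: float = 4.0
    obesity_slope: float = 10.0
    obesity_noise_sd: float = 0.8
    seed: int = 0
    regions: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError("n_regions must be >= 3")
        for name in ("n_categories_probs", "price_tier_probs"):
            probs = getattr(self, name)
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be a probability vector")
        for name in (
            "region_mix_skew", "rating_noise_sd", "review_count_log_sd",
            "calorie_noise_cv", "obesity_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.category_absence_fraction < 1.0:
            raise ValueError("category_absence_fraction must be in [0, 1)")
        if self.regions is not None and len(self.regions) != self.n_regions:
            raise ValueError("len(regions) must equal n_regions")

    def region_codes(self) -> tuple[str, ...]:
        if self.regions is not None:
            return self.regions
        if self.n_regions <= len(DEFAULT_REGIONS):
            return DEFAULT_REGIONS[: self.n_regions]
        raise ValueError(
            f"n_regions={self.n_regions} exceeds the built-in region "
            "universe; pass explicit region codes"
        )


def default_config(seed: int = 0, **overrides) -> WorldConfig:
    """The study-scale default configuration (see :class:`WorldConfig`)."""
    return replace(WorldConfig(seed=seed), **overrides)


@dataclass
class SyntheticWorld:
    """A generated world: the four input tables plus ground truth.

    ``truth`` has one row per region with the category-mix-weighted true
    environment score ``environment_score`` (kcal/gram) and the noiseless
    obesity expectation.
    """

    businesses: list[BusinessRecord]
    nutrition: list[NutritionRecord]
    popular_dishes: PopularDishTable
    obesity: ObesityTable
    truth: pd.DataFrame
    registry: CategoryRegistry
    config: WorldConfig


def _dish_names(category: str, k: int) -> list[str]:
    return [normalize_dish_name(f"{category} dish {j + 1:02d}") for j in range(k)]


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic world, deterministically per seed."""
    rng = np.random.default_rng(config.seed)
    regions = config.region_codes()
    cats = config.categories
    labels = [c.label for c in cats]
    dens = np.array([c.true_density for c in cats])
    weight = np.array([c.obesogenic_weight for c in cats])
    n_cat = len(cats)

    # Region category mixes: Dirichlet base sharpened toward high- or
    # low-obesogenic categories by a per-region tilt in [-1, 1].
    tilt = rng.uniform(-1.0, 1.0, size=len(regions))
    base = rng.dirichlet(np.full(n_cat, 2.0), size=len(regions))
    mix = base * np.exp(config.region_mix_skew * tilt[:, None] * weight[None, :])
    mix /= mix.sum(axis=1, keepdims=True)
    # Plant category absence: each region drops its lowest-weight slice of
    # categories entirely (real regions lack many listing categories).
    n_absent = int(config.category_absence_fraction * n_cat)
    if n_absent > 0:
        cutoff = np.sort(mix, axis=1)[:, n_absent - 1]
        mix = np.where(mix <= cutoff[:, None], 0.0, mix)
        mix /= mix.sum(axis=1, keepdims=True)
    env_score = mix @ dens  # E_s

    # Obesity: linear in E_s with Gaussian noise, clamped to plausibility.
    noise = rng.normal(0.0, config.obesity_noise_sd, size=len(regions))
    expected = config.obesity_intercept + config.obesity_slope * env_score
    rates = np.clip(expected + noise, *OBESITY_CLAMP)
    signal = abs(config.obesity_slope) * np.ptp(env_score)
    if config.obesity_noise_sd > 0 and signal < config.obesity_noise_sd:
        log.warning(
            "degenerate obesity link: planted signal %.3g below noise sd %.3g",
            signal, config.obesity_noise_sd,
        )

    # Businesses.
    n_b = config.businesses_per_region
    businesses: list[BusinessRecord] = []
    k_choices = rng.choice(
        [1, 2, 3], size=len(regions) * n_b, p=config.n_categories_probs
    )
    # Gumbel top-k gives a weighted draw without replacement per business.
    gumbel = rng.gumbel(size=(len(regions) * n_b, n_cat))
    tier_draw = rng.choice([1, 2, 3, 4], size=len(regions) * n_b,
                           p=config.price_tier_probs)
    tier_missing = rng.random(len(regions) * n_b) < config.price_missing_prob
    ratings = np.clip(
        np.round(rng.normal(config.rating_mean, config.rating_noise_sd,
                            size=len(regions) * n_b) * 2) / 2,
        0.5, 5.0,
    )
    reviews = np.round(
        rng.lognormal(config.review_count_log_mean, config.review_count_log_sd,
                      size=len(regions) * n_b)
    ).astype(int)

    idx = 0
    with np.errstate(divide="ignore"):  # log(0) -> -inf marks absent categories
        log_mix = np.log(mix)
    for s, region in enumerate(regions):
        keys = log_mix[s][None, :] + gumbel[idx: idx + n_b]
        order = np.argsort(-keys, axis=1)
        for i in range(n_b):
            k = int(k_choices[idx])
            chosen = tuple(labels[j] for j in sorted(order[i, :k]))
            businesses.append(
                BusinessRecord(
                    business_id=f"B{idx:06d}",
                    region=region,
                    categories=chosen,
                    price_tier=None if tier_missing[idx] else int(tier_draw[idx]),
                    rating=float(ratings[idx]),
                    review_count=int(reviews[idx]),
                )
            )
            idx += 1

    # Popular dishes and nutrition records. Every dish of a category has
    # the category's true density; gram-unit records recover it exactly
    # when calorie_noise_cv is 0.
    popular = PopularDishTable(
        {c.label: _dish_names(c.label, config.dishes_per_category) for c in cats}
    )
    cv = config.calorie_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    qty_choices = np.array([50.0, 100.0, 150.0, 200.0, 250.0])
    nutrition: list[NutritionRecord] = []
    for c in cats:
        for dish in popular.dishes[c.label]:
            for _ in range(config.records_per_dish):
                non_gram = rng.random() < config.non_gram_fraction
                factor = (
                    math.exp(rng.normal(-sigma * sigma / 2.0, sigma))
                    if sigma > 0 else 1.0
                )
                if non_gram:
                    unit = NON_GRAM_DIALECTS[
                        int(rng.integers(len(NON_GRAM_DIALECTS)))
                    ]
                    qty = float(rng.integers(1, 4))
                    calories = c.true_density * 150.0 * factor
                else:
                    unit = GRAM_DIALECTS[int(rng.integers(len(GRAM_DIALECTS)))]
                    qty = float(rng.choice(qty_choices))
                    calories = c.true_density * qty * factor
                nutrition.append(
                    NutritionRecord(
                        dish=dish,
                        calories=float(calories),
                        serving_qty=qty,
                        serving_unit=unit,
                    )
                )

    truth = pd.DataFrame(
        {
            "region": list(regions),
            "environment_score": env_score,
            "expected_obesity": expected,
            "obesity_rate": rates,
        }
    ).set_index("region")

    return SyntheticWorld(
        businesses=businesses,
        nutrition=nutrition,
        popular_dishes=popular,
        obesity=ObesityTable(dict(zip(regions, rates))),
        truth=truth,
        registry=CategoryRegistry.all_food(labels),
        config=config,
    )
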