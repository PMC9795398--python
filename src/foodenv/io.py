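"""Readers and writers for the five tabular inputs.

All tables are UTF-8 CSV. The ``categories`` column of the business table
is a JSON-encoded list so that multi-category businesses stay one row and
fixtures remain diffable. Readers enforce the record invariants and fail
hard, naming the offending line, rather than silently coercing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

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
    "read_businesses",
    "write_businesses",
    "filter_food_categories",
    "read_nutrition",
    "write_nutrition",
    "read_obesity",
    "write_obesity",
    "read_popular_dishes",
    "write_popular_dishes",
    "read_category_registry",
    "write_category_registry",
]


class MalformedRowError(ValueError):
    """A row failed parsing or violated a record invariant."""


def _parse_price(raw) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    return int(raw)


def read_businesses(
    path: str | Path,
    registry: Optional[CategoryRegistry] = None,
    regions: Sequence[str] = DEFAULT_REGIONS,
) -> list[BusinessRecord]:
    """Read business listings, dropping non-food categories.

    With a ``registry``, each record's non-food labels are removed; records
    whose category list becomes empty are excluded (the count is logged).
    Unknown region codes and malformed rows raise, naming the line.
    """
    df = pd.read_csv(path, dtype={"business_id": str, "region": str})
    region_set = set(regions)
    out: list[BusinessRecord] = []
    excluded = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        if row.region not in region_set:
            raise MalformedRowError(
                f"{path}, line {line_no}: unknown region code {row.region!r}"
            )
        try:
            cats = tuple(json.loads(row.categories))
            if registry is not None:
                cats = tuple(c for c in cats if registry.is_food(c))
            if not cats:
                excluded += 1
                continue
            out.append(
                BusinessRecord(
                    business_id=row.business_id,
                    region=row.region,
                    categories=cats,
                    price_tier=_parse_price(row.price_tier),
                    rating=float(row.rating),
                    review_count=int(row.review_count),
                )
            )
        except MalformedRowError:
            raise
        except (ValueError, TypeError, json.JSONDecodeError) as exc:
            raise MalformedRowError(f"{path}, line {line_no}: {exc}") from exc
    if excluded:
        log.info("read_businesses: excluded %d records with no food category", excluded)
    return out


def write_businesses(records: Iterable[BusinessRecord], path: str | Path) -> None:
    rows = [
        {
            "business_id": r.business_id,
            "region": r.region,
            "categories": json.dumps(list(r.categories)),
            "price_tier": "" if r.price_tier is None else r.price_tier,
            "rating": r.rating,
            "review_count": r.review_count,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "business_id", "region", "categories",
            "price_tier", "rating", "review_count",
        ],
    ).to_csv(path, index=False)


def filter_food_categories(
    records: Iterable[BusinessRecord], registry: CategoryRegistry
) -> tuple[list[BusinessRecord], int]:
    """Drop non-food labels from each record; drop emptied records.

    Returns (kept records, number excluded). Idempotent: filtering an
    already-filtered list is a no-op.
    """
    kept: list[BusinessRecord] = []
    excluded = 0
    for r in records:
        cats = tuple(c for c in r.categories if registry.is_food(c))
        if not cats:
            excluded += 1
        elif cats == r.categories:
            kept.append(r)
        else:
            kept.append(
                BusinessRecord(
                    r.business_id, r.region, cats,
                    r.price_tier, r.rating, r.review_count,
                )
            )
    return kept, excluded


def read_nutrition(path: str | Path) -> list[NutritionRecord]:
    """Read nutrition records; dish names are normalized on ingest."""
    df = pd.read_csv(path, dtype={"dish": str, "serving_unit": str})
    if df.empty:
        log.warning("read_nutrition: %s is empty", path)
        return []
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                NutritionRecord(
                    dish=normalize_dish_name(row.dish),
                    calories=float(row.calories),
                    serving_qty=float(row.serving_qty),
                    serving_unit=str(row.serving_unit),
                )
            )
        except (ValueError, TypeError) as exc:
            raise MalformedRowError(f"{path}, line {i + 2}: {exc}") from exc
    return out


def write_nutrition(records: Iterable[NutritionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "dish": r.dish,
                "calories": r.calories,
                "serving_qty": r.serving_qty,
                "serving_unit": r.serving_unit,
            }
            for r in records
        ],
        columns=["dish", "calories", "serving_qty", "serving_unit"],
    ).to_csv(path, index=False)


def read_obesity(path: str | Path) -> ObesityTable:
    """Read the region -> obesity prevalence table; duplicate regions raise."""
    df = pd.read_csv(path, dtype={"region": str})
    if df.empty:
        log.warning("read_obesity: %s is empty", path)
        return ObesityTable({})
    dupes = df["region"][df["region"].duplicated()]
    if not dupes.empty:
        raise MalformedRowError(
            f"{path}: duplicate region rows {sorted(dupes.unique())}"
        )
    return ObesityTable(dict(zip(df["region"], df["obesity_rate"].astype(float))))


def write_obesity(table: ObesityTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"region": r, "obesity_rate": table.rates[r]} for r in table.regions],
        columns=["region", "obesity_rate"],
    ).to_csv(path, index=False)


def read_popular_dishes(path: str | Path) -> PopularDishTable:
    """Read ranked popular dishes; names are normalized on ingest."""
    df = pd.read_csv(path, dtype={"category": str, "dish": str})
    if df.empty:
        log.warning("read_popular_dishes: %s is empty", path)
        return PopularDishTable({})
    df = df.sort_values(["category", "rank"], kind="stable")
    dishes: dict[str, list[str]] = {}
    for cat, grp in df.groupby("category", sort=True):
        dishes[cat] = [normalize_dish_name(d) for d in grp["dish"]]
    return PopularDishTable(dishes)


def write_popular_dishes(table: PopularDishTable, path: str | Path) -> None:
    rows = []
    for cat in table.categories:
        for rank, dish in enumerate(table.dishes[cat], start=1):
            rows.append({"category": cat, "rank": rank, "dish": dish})
    pd.DataFrame(rows, columns=["category", "rank", "dish"]).to_csv(path, index=False)


def read_category_registry(path: str | Path) -> CategoryRegistry:
    df = pd.read_csv(path, dtype={"category": str})
    flags = {}
    for row in df.itertuples(index=False):
        raw = row.is_food
        flags[row.category] = bool(raw) if isinstance(raw, (bool, int)) else (
            str(raw).strip().lower() in ("1", "true", "yes")
        )
    return CategoryRegistry(flags)


def write_category_registry(registry: CategoryRegistry, path: str | Path) -> None:
    pd.DataFrame(
        [{"category": c, "is_food": registry.flags[c]} for c in sorted(registry.flags)],
        columns=["category", "is_food"],
    ).to_csv(path, index=False)
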