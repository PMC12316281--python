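"""Food-outlet taxonomy.

Ten categories: eight store types (butcher, bakery, drive-through
supermarket, fish shop, greengrocer, grocery store, market, supermarket) and
two restaurant groups (traditional, fast food — cafeterias fold into fast
food).  Fruit-and-vegetable sellers are the five store types that stock fresh
produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import UnknownLabelError

STORE_CATEGORIES = (
    "butcher",
    "bakery",
    "drive_through_supermarket",
    "fish_shop",
    "greengrocer",
    "grocery_store",
    "market",
    "supermarket",
)
RESTAURANT_CATEGORIES = ("traditional_restaurant", "fast_food_restaurant")
ALL_CATEGORIES = STORE_CATEGORIES + RESTAURANT_CATEGORIES

FV_CATEGORIES = frozenset(
    {
        "drive_through_supermarket",
        "greengrocer",
        "grocery_store",
        "market",
        "supermarket",
    }
)

#: default raw-label → category map (identity on canonical names plus the
#: common business-register labels that need folding)
DEFAULT_TAXONOMY: dict[str, str] = {c: c for c in ALL_CATEGORIES}
DEFAULT_TAXONOMY.update(
    {
        "cafeteria": "fast_food_restaurant",
        "fast_food": "fast_food_restaurant",
        "restaurant": "traditional_restaurant",
        "hypermarket": "supermarket",
        "butcher_shop": "butcher",
        "bakery_pastry": "bakery",
        "fishmonger": "fish_shop",
    }
)


@dataclass(frozen=True)
class FoodOutlet:
    """A categorized food outlet located in the plane (meters)."""

    id: str
    location: tuple[float, float]
    category: str

    def __post_init__(self):
        if self.category not in ALL_CATEGORIES:
            raise UnknownLabelError(f"unknown category {self.category!r}")

    @property
    def is_store(self) -> bool:
        return self.category in STORE_CATEGORIES

    @property
    def is_restaurant(self) -> bool:
        return self.category in RESTAURANT_CATEGORIES

    @property
    def sells_fv(self) -> bool:
        return self.category in FV_CATEGORIES

    @property
    def is_fastfood(self) -> bool:
        return self.category == "fast_food_restaurant"


def classify_outlet(
    raw_category_label: str,
    taxonomy_map: Mapping[str, str] = DEFAULT_TAXONOMY,
) -> str:
    """Map a raw register label onto one of the ten outlet categories."""
    try:
        cat = taxonomy_map[raw_category_label]
    except KeyError:
        raise UnknownLabelError(
            f"label {raw_category_label!r} not present in the taxonomy map"
        ) from None
    if cat not in ALL_CATEGORIES:
        raise UnknownLabelError(
            f"taxonomy maps {raw_category_label!r} to unknown category {cat!r}"
        )
    return cat
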