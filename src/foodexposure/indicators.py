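"""The five food-environment exposure indicators and their codings.

For each household × exposure-area kind: number of food stores, number of
restaurants, diversity of food stores (0–8 distinct store categories),
relative density of fruit-and-vegetable sellers among stores, and relative
density of fast-food restaurants among restaurants.  Counts are coded into
sample tertiles, diversity into the fixed bands 0–2 / 3–5 / 6–8, and the two
relative densities at a 50 % cutoff (≥ 0.5 is the upper class; an undefined
ratio — empty denominator — codes as below 50 %).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree

from .errors import DegenerateDistributionError, RatioError
from .exposure import ExposureArea
from .outlets import FoodOutlet

TERTILE_LABELS = ("T1", "T2", "T3")
DIVERSITY_LABELS = ("0-2", "3-5", "6-8")
RATIO_LABELS = ("lt50", "ge50")

RAW_COLUMNS = (
    "n_stores",
    "n_restaurants",
    "diversity",
    "fv_ratio",
    "fastfood_ratio",
)
CLASS_COLUMNS = (
    "n_stores_class",
    "n_restaurants_class",
    "diversity_class",
    "fv_class",
    "fastfood_class",
)


@dataclass
class ExposureProfile:
    """Raw and coded indicator values for one household × one area kind."""

    household_id: str
    area_kind: str
    n_stores: int
    n_restaurants: int
    diversity: int
    fv_ratio: Optional[float]
    fastfood_ratio: Optional[float]
    n_stores_class: Optional[str] = None
    n_restaurants_class: Optional[str] = None
    diversity_class: Optional[str] = None
    fv_class: Optional[str] = None
    fastfood_class: Optional[str] = None


# ------------------------------------------------------------------ counting
def count_in_area(
    outlets: Iterable[FoodOutlet],
    area: ExposureArea,
    predicate=None,
) -> int:
    """Number of outlets inside or on the boundary of the area's polygon.

    The closed-region convention is used: a point exactly on the boundary
    counts.  ``predicate`` filters outlets (e.g. ``lambda o: o.is_store``).
    """
    poly = area.polygon
    if poly.is_empty:
        return 0
    n = 0
    for o in outlets:
        if predicate is not None and not predicate(o):
            continue
        if poly.covers(Point(o.location)):
            n += 1
    return n


def diversity_in_area(
    outlets: Iterable[FoodOutlet], area: ExposureArea
) -> int:
    """Number of distinct *store* categories present (restaurants excluded)."""
    poly = area.polygon
    if poly.is_empty:
        return 0
    cats = set()
    for o in outlets:
        if o.is_store and poly.covers(Point(o.location)):
            cats.add(o.category)
    return len(cats)


def relative_density(
    numerator_count: int, denominator_count: int
) -> Optional[float]:
    """numerator/denominator, or None when the denominator is zero."""
    if numerator_count < 0 or denominator_count < 0:
        raise ValueError("counts must be >= 0")
    if numerator_count > denominator_count:
        raise RatioError(
            f"numerator {numerator_count} exceeds denominator "
            f"{denominator_count}"
        )
    if denominator_count == 0:
        return None
    return numerator_count / denominator_count


def profile_area(
    household_id: str,
    area: ExposureArea,
    outlets: Sequence[FoodOutlet],
    tree: Optional[STRtree] = None,
) -> ExposureProfile:
    """Compute the five raw indicators for one household × area.

    When profiling many areas against one outlet layer, pass a prebuilt
    ``STRtree`` over the outlet points (same order as ``outlets``) to restrict
    the point-in-polygon tests to candidates in the polygon's envelope.
    """
    poly = area.polygon
    if tree is not None and not poly.is_empty:
        idx = tree.query(poly)
        cand = [outlets[i] for i in idx]
    else:
        cand = list(outlets)
    inside = [o for o in cand if not poly.is_empty and poly.covers(Point(o.location))]
    n_stores = sum(1 for o in inside if o.is_store)
    n_rest = sum(1 for o in inside if o.is_restaurant)
    n_fv = sum(1 for o in inside if o.sells_fv)
    n_ff = sum(1 for o in inside if o.is_fastfood)
    diversity = len({o.category for o in inside if o.is_store})
    return ExposureProfile(
        household_id=household_id,
        area_kind=area.kind,
        n_stores=n_stores,
        n_restaurants=n_rest,
        diversity=diversity,
        fv_ratio=relative_density(n_fv, n_stores),
        fastfood_ratio=relative_density(n_ff, n_rest),
    )


# -------------------------------------------------------------------- coding
def tertile_bounds(values: Sequence[float]) -> tuple[float, float]:
    """Empirical 1/3 and 2/3 quantiles (linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    q1, q2 = np.quantile(arr, [1 / 3, 2 / 3])
    return float(q1), float(q2)


def tertile_class(x: float, bounds: tuple[float, float]) -> str:
    """Right-closed tertile assignment: ties at a boundary fall low."""
    q1, q2 = bounds
    if x <= q1:
        return TERTILE_LABELS[0]
    if x <= q2:
        return TERTILE_LABELS[1]
    return TERTILE_LABELS[2]


def diversity_class(d: int) -> str:
    if not 0 <= d <= 8:
        raise ValueError("diversity must be in 0..8")
    if d <= 2:
        return DIVERSITY_LABELS[0]
    if d <= 5:
        return DIVERSITY_LABELS[1]
    return DIVERSITY_LABELS[2]


def ratio_class(r: Optional[float]) -> str:
    """50 % cutoff; an undefined ratio codes as the lower class."""
    if r is None or (isinstance(r, float) and math.isnan(r)):
        return RATIO_LABELS[0]
    return RATIO_LABELS[1] if r >= 0.5 else RATIO_LABELS[0]


def code_profiles(
    profiles: pd.DataFrame, area_kind: Optional[str] = None
) -> pd.DataFrame:
    """Attach categorical codings to a frame of raw indicators.

    Tertile boundaries are computed on the unweighted sample distribution,
    separately per area kind.  Requires ≥ 3 households per area kind and
    raises :class:`DegenerateDistributionError` if any tertile class would be
    empty after tie handling (e.g. more than a third of the sample shares one
    value spanning a boundary).
    """
    df = profiles.copy()
    kinds = [area_kind] if area_kind else sorted(df["area_kind"].unique())
    for kind in kinds:
        mask = df["area_kind"] == kind
        sub = df.loc[mask]
        if len(sub) < 3:
            raise DegenerateDistributionError(
                f"need >= 3 households per area kind, got {len(sub)} "
                f"for {kind!r}"
            )
        for col, cls_col in (
            ("n_stores", "n_stores_class"),
            ("n_restaurants", "n_restaurants_class"),
        ):
            values = sub[col].to_numpy()
            if np.ptp(values) == 0:
                # constant indicator (e.g. a city with no outlets): a single
                # class exists by definition, nothing to split into tertiles
                df.loc[mask, cls_col] = TERTILE_LABELS[0]
                continue
            bounds = tertile_bounds(values)
            classes = sub[col].map(lambda x: tertile_class(x, bounds))
            counts = classes.value_counts()
            if any(counts.get(lbl, 0) == 0 for lbl in TERTILE_LABELS):
                raise DegenerateDistributionError(
                    f"empty tertile class for {col!r} in {kind!r} "
                    f"(bounds {bounds})"
                )
            df.loc[mask, cls_col] = classes
        df.loc[mask, "diversity_class"] = sub["diversity"].map(diversity_class)
        df.loc[mask, "fv_class"] = sub["fv_ratio"].map(ratio_class)
        df.loc[mask, "fastfood_class"] = sub["fastfood_ratio"].map(ratio_class)
    return df


def profiles_to_frame(profiles: Iterable[ExposureProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "household_id": p.household_id,
                "area_kind": p.area_kind,
                "n_stores": p.n_stores,
                "n_restaurants": p.n_restaurants,
                "diversity": p.diversity,
                "fv_ratio": np.nan if p.fv_ratio is None else p.fv_ratio,
                "fastfood_ratio": (
                    np.nan if p.fastfood_ratio is None else p.fastfood_ratio
                ),
            }
        )
    return pd.DataFrame(rows)
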