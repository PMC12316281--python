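"""Delineation of food-environment exposure areas.

Two measures are supported, mirroring standard practice in spatial
epidemiology:

* **home buffer** — the street-network service area within 500 m of the home,
  polygonized by buffering the reachable sub-network;
* **activity space** — the daily-path-area union of (a) the home service
  area, (b) a 500 m service area around every reported anchor point, and
  (c) Euclidean corridors around the fastest routes connecting them, with a
  corridor half-width of 100 m for walking/cycling and 300 m for motorized
  trips.  Public-transit trips contribute their endpoint service areas but no
  route corridor (route data are typically unavailable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from shapely.geometry import LineString, MultiPolygon, Point, Polygon
from shapely.ops import unary_union

from .errors import (
    DisconnectedError,
    FoodExposureError,
    NoPathError,
    SnapError,
    UnknownModeError,
)
from .network import SNAP_TOLERANCE_M, StreetNetwork

WALKBIKE_MODES = frozenset({"walk", "bike"})
MOTOR_MODES = frozenset({"car", "motorcycle", "scooter"})
TRANSIT_MODE = "public_transit"
ALL_MODES = WALKBIKE_MODES | MOTOR_MODES | {TRANSIT_MODE}

HOME_BUFFER = "home_buffer"
ACTIVITY_SPACE = "activity_space"


@dataclass(frozen=True)
class BufferParams:
    """Distance parameters of the delineation.

    anchor_network_radius_m
        Network travel distance bounding the service area around the home and
        every anchor point (500 m is the conventional walkable-neighborhood
        threshold).
    walkbike_corridor_m / motor_corridor_m
        Euclidean half-widths of route corridors (100 m captures the streetscape
        a pedestrian or cyclist encounters; 300 m the roadside strip visible
        from a car).
    edge_halfwidth_m
        Polygonization half-width applied to the reachable sub-network when
        turning a service area into a polygon.
    """

    anchor_network_radius_m: float = 500.0
    walkbike_corridor_m: float = 100.0
    motor_corridor_m: float = 300.0
    edge_halfwidth_m: float = 25.0

    def __post_init__(self):
        for name in (
            "anchor_network_radius_m",
            "walkbike_corridor_m",
            "motor_corridor_m",
            "edge_halfwidth_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class AnchorPoint:
    """A weekly activity location with its usual transport mode."""

    location: tuple[float, float]
    mode: str
    adult_index: int = 1

    def __post_init__(self):
        if self.mode not in ALL_MODES:
            raise UnknownModeError(f"unknown transport mode {self.mode!r}")
        if self.adult_index < 1:
            raise ValueError("adult_index must be >= 1")


@dataclass
class Household:
    """Home location, anchor points of food-shopping adults, and covariates."""

    household_id: str
    home: tuple[float, float]
    anchors: list[AnchorPoint] = field(default_factory=list)
    covariates: dict = field(default_factory=dict)


@dataclass
class ExposureArea:
    """A delineated exposure polygon of one kind for one household."""

    kind: str
    polygon: Polygon | MultiPolygon
    area_m2: float = 0.0
    household_id: Optional[str] = None

    def __post_init__(self):
        self.polygon = _repair(self.polygon)
        self.area_m2 = float(self.polygon.area)


def _repair(geom):
    """Zero-width-buffer repair; keeps valid geometries unchanged."""
    if geom.is_empty:
        return geom
    if not geom.is_valid:
        geom = geom.buffer(0)
    return geom


# ----------------------------------------------------------------- operations
def network_buffer(
    network: StreetNetwork,
    origin: Sequence[float],
    radius_m: float,
    params: BufferParams = BufferParams(),
    kind: str = HOME_BUFFER,
) -> ExposureArea:
    """Service-area polygon: all edge points within ``radius_m`` of ``origin``
    along the network, buffered by ``params.edge_halfwidth_m`` and unioned.

    Partial edges are truncated at the exact residual network distance.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be > 0")
    snap = network.snap(origin, SNAP_TOLERANCE_M)  # SnapError if too far
    frags = network.reachable_edges(snap, radius_m)
    if not frags:
        raise DisconnectedError(
            f"no reachable edges within {radius_m} m of origin"
        )
    poly = unary_union(
        [f.buffer(params.edge_halfwidth_m) for f in frags]
    )
    return ExposureArea(kind=kind, polygon=_repair(poly))


def fastest_path(
    network: StreetNetwork,
    origin: Sequence[float],
    destination: Sequence[float],
) -> tuple[LineString, float]:
    """Minimal-length route between two snapped points.

    All modes share one uniform-speed network, so the fastest path reduces to
    the shortest path.  Returns the route polyline and its length in meters.
    """
    s0 = network.snap(origin, SNAP_TOLERANCE_M)
    s1 = network.snap(destination, SNAP_TOLERANCE_M)
    if s0.point.distance(s1.point) < 1e-9:
        p = s0.point
        return LineString([(p.x, p.y), (p.x, p.y)]), 0.0
    return network._route_between_snaps(s0, s1)


def route_corridor(
    route: LineString,
    mode: str,
    params: BufferParams = BufferParams(),
) -> Polygon:
    """Euclidean buffer of a route at the mode-specific half-width.

    Public-transit trips return an empty polygon: the traversed route is
    unknown, so only their endpoint neighborhoods enter the activity space.
    """
    if mode not in ALL_MODES:
        raise UnknownModeError(f"unknown transport mode {mode!r}")
    if mode == TRANSIT_MODE:
        return Polygon()
    width = (
        params.walkbike_corridor_m
        if mode in WALKBIKE_MODES
        else params.motor_corridor_m
    )
    # 32 segments per quadrant keeps the cap-area discretization error ~1e-4
    return route.buffer(width, quad_segs=32)


def household_activity_space(
    household: Household,
    network: StreetNetwork,
    params: BufferParams = BufferParams(),
) -> ExposureArea:
    """Daily-path-area activity space of a household.

    Union of: the home service area; a service area around every anchor
    (including transit anchors — the visited neighborhood is exposure
    regardless of how it is reached); route corridors home→anchor for every
    non-transit anchor; and route corridors between the two anchors of the
    same adult when both are reached by the same non-transit mode.
    """
    try:
        pieces = [
            network_buffer(
                network, household.home, params.anchor_network_radius_m, params
            ).polygon
        ]
        for a in household.anchors:
            pieces.append(
                network_buffer(
                    network, a.location, params.anchor_network_radius_m, params
                ).polygon
            )
            if a.mode != TRANSIT_MODE:
                route, _ = fastest_path(network, household.home, a.location)
                pieces.append(route_corridor(route, a.mode, params))
        # inter-anchor corridors: same adult, same non-transit mode
        by_adult: dict[int, list[AnchorPoint]] = {}
        for a in household.anchors:
            by_adult.setdefault(a.adult_index, []).append(a)
        for anchors in by_adult.values():
            for i in range(len(anchors)):
                for j in range(i + 1, len(anchors)):
                    ai, aj = anchors[i], anchors[j]
                    if ai.mode == aj.mode and ai.mode != TRANSIT_MODE:
                        route, _ = fastest_path(
                            network, ai.location, aj.location
                        )
                        pieces.append(route_corridor(route, ai.mode, params))
    except (SnapError, NoPathError, DisconnectedError) as exc:
        raise type(exc)(
            f"household {household.household_id}: {exc}"
        ) from exc
    poly = _repair(unary_union(pieces))
    return ExposureArea(
        kind=ACTIVITY_SPACE, polygon=poly, household_id=household.household_id
    )


def home_buffer(
    household: Household,
    network: StreetNetwork,
    params: BufferParams = BufferParams(),
) -> ExposureArea:
    """500 m network buffer around the household's home."""
    try:
        area = network_buffer(
            network, household.home, params.anchor_network_radius_m, params
        )
    except (SnapError, DisconnectedError) as exc:
        raise type(exc)(f"household {household.household_id}: {exc}") from exc
    area.household_id = household.household_id
    return area


def area_km2(area: ExposureArea | Polygon | MultiPolygon) -> float:
    """Polygon area in square kilometers."""
    poly = area.polygon if isinstance(area, ExposureArea) else area
    return float(poly.area) / 1e6
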