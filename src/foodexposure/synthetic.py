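"""Synthetic city generator.

Emulates the spatial and sociodemographic structure the exposure analysis
assumes, so the whole pipeline is testable without external data:

* a perturbed-grid street network on a square extent;
* food outlets from an inhomogeneous Poisson process whose intensity decays
  exponentially with distance from the city center (dense center, sparse
  periphery), with categories drawn i.i.d. from a configurable mix;
* households with homes on the network, home-location zones defined by two
  radii (center / pericentral / peri-urban), up to two anchor points per
  adult with transport modes tied to car ownership, and covariates drawn
  from configurable conditional distributions;
* the generating population margins, for raking-recovery tests.

Each layer draws from its own RNG stream (``seed + offset``), so layers can
be regenerated independently and outputs are bit-identical for a given
seed + config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from shapely.geometry import Point

from .exposure import AnchorPoint, Household
from .network import StreetNetwork
from .outlets import ALL_CATEGORIES, FoodOutlet
from .weights import PopulationMargins

ZONES = ("center", "pericentral", "periurban")
AGE_LEVELS = ("<35", "35-50", ">50")
EDUCATION_LEVELS = ("high_school_or_lower", "undergraduate", "postgraduate")
EMPLOYMENT_LEVELS = ("employed", "unemployed", "student")
COMPOSITION_LEVELS = (
    "one_adult",
    "multiple_adults",
    "one_adult_children",
    "multiple_adults_children",
)
INCOME_LEVELS = ("q1", "q2", "q3", "q4", "refuse")

#: outlet category mix loosely shaped like a French city-region register
DEFAULT_CATEGORY_MIX = {
    "butcher": 0.06,
    "bakery": 0.28,
    "drive_through_supermarket": 0.01,
    "fish_shop": 0.02,
    "greengrocer": 0.05,
    "grocery_store": 0.12,
    "market": 0.03,
    "supermarket": 0.08,
    "traditional_restaurant": 0.25,
    "fast_food_restaurant": 0.10,
}


@dataclass(frozen=True)
class CovariateParams:
    """Marginal and conditional distributions of household covariates.

    Conditionals are deliberately shallow (zone → car → modes; education and
    employment conditional on age only) so weighting-recovery tests stay
    interpretable.
    """

    zone_probs: tuple = (0.19, 0.41, 0.40)
    car_by_zone: dict = field(
        default_factory=lambda: {
            "center": 0.55,
            "pericentral": 0.80,
            "periurban": 0.92,
        }
    )
    age_probs: tuple = (0.34, 0.30, 0.36)
    composition_probs: tuple = (0.33, 0.38, 0.05, 0.24)
    income_probs: tuple = (0.2325, 0.2325, 0.2325, 0.2325, 0.07)
    education_by_age: dict = field(
        default_factory=lambda: {
            "<35": (0.18, 0.40, 0.42),
            "35-50": (0.22, 0.38, 0.40),
            ">50": (0.33, 0.33, 0.34),
        }
    )
    employment_by_age: dict = field(
        default_factory=lambda: {
            "<35": (0.55, 0.10, 0.35),
            "35-50": (0.92, 0.08, 0.00),
            ">50": (0.60, 0.40, 0.00),
        }
    )
    #: P(an adult reports 0, 1, 2 anchor points)
    anchor_count_probs: tuple = (0.2, 0.4, 0.4)
    mode_probs_car: dict = field(
        default_factory=lambda: {
            "car": 0.62,
            "motorcycle": 0.03,
            "scooter": 0.03,
            "walk": 0.17,
            "bike": 0.08,
            "public_transit": 0.07,
        }
    )
    mode_probs_nocar: dict = field(
        default_factory=lambda: {
            "walk": 0.45,
            "bike": 0.22,
            "public_transit": 0.33,
        }
    )


@dataclass(frozen=True)
class CityConfig:
    """Stated world of the synthetic city (all lengths in meters)."""

    seed: int = 0
    grid_extent_m: float = 3000.0  # half-width of the square city
    node_spacing_m: float = 250.0
    node_perturbation_m: float = 10.0
    center: tuple = (0.0, 0.0)
    outlet_intensity0: float = 40.0  # outlets per km^2 at the center
    decay_scale_m: float = 1500.0  # exponential distance-decay scale
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    n_households: int = 699
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    zone_radii_m: tuple = (1000.0, 2000.0)

    def __post_init__(self):
        for name in ("grid_extent_m", "node_spacing_m", "decay_scale_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.node_spacing_m > self.grid_extent_m:
            raise ValueError("node_spacing_m exceeds grid_extent_m")
        if self.node_perturbation_m < 0:
            raise ValueError("node_perturbation_m must be >= 0")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        unknown = set(self.category_mix) - set(ALL_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown outlet categories {sorted(unknown)}")
        if not (0 < self.zone_radii_m[0] < self.zone_radii_m[1]):
            raise ValueError("zone_radii_m must be strictly increasing and > 0")
        if self.n_households < 1:
            raise ValueError("n_households must be >= 1")
        if self.outlet_intensity0 < 0:
            raise ValueError("outlet_intensity0 must be >= 0")

    def zone_of(self, xy) -> str:
        d = float(np.hypot(xy[0] - self.center[0], xy[1] - self.center[1]))
        if d < self.zone_radii_m[0]:
            return "center"
        if d < self.zone_radii_m[1]:
            return "pericentral"
        return "periurban"


# ------------------------------------------------------------------- network
def generate_network(config: CityConfig) -> StreetNetwork:
    """Perturbed-grid street network covering the square city extent."""
    rng = np.random.default_rng(config.seed + 0)
    E, s = config.grid_extent_m, config.node_spacing_m
    cx, cy = config.center
    ticks = np.arange(-E, E + 1e-9, s)
    m = len(ticks)
    G = nx.Graph()
    for i in range(m):
        for j in range(m):
            x = cx + ticks[i]
            y = cy + ticks[j]
            p = config.node_perturbation_m
            if p > 0:
                x += rng.uniform(-p, p)
                y += rng.uniform(-p, p)
            G.add_node(i * m + j, x=float(x), y=float(y))
    for i in range(m):
        for j in range(m):
            n = i * m + j
            if i + 1 < m:
                G.add_edge(n, (i + 1) * m + j)
            if j + 1 < m:
                G.add_edge(n, i * m + (j + 1))
    return StreetNetwork(G)


# ------------------------------------------------------------------- outlets
def generate_outlets(
    config: CityConfig, network: StreetNetwork
) -> list[FoodOutlet]:
    """Inhomogeneous Poisson outlet layer by thinning, snapped to the network.

    Intensity is ``outlet_intensity0 * exp(-d / decay_scale_m)`` with ``d``
    the distance to the city center; candidates farther than 30 m from every
    edge are moved to the nearest edge point.
    """
    rng = np.random.default_rng(config.seed + 1)
    if config.outlet_intensity0 == 0:
        return []
    E = config.grid_extent_m
    cx, cy = config.center
    area_km2 = (2 * E / 1000.0) ** 2
    n_cand = rng.poisson(config.outlet_intensity0 * area_km2)
    xs = rng.uniform(cx - E, cx + E, n_cand)
    ys = rng.uniform(cy - E, cy + E, n_cand)
    d = np.hypot(xs - cx, ys - cy)
    keep = rng.uniform(size=n_cand) < np.exp(-d / config.decay_scale_m)
    xs, ys = xs[keep], ys[keep]
    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    draws = rng.choice(len(cats), size=len(xs), p=probs)
    outlets = []
    for i, (x, y, ci) in enumerate(zip(xs, ys, draws)):
        p = Point(x, y)
        snap = network.snap((x, y), tolerance_m=np.inf)
        if snap.offset_m > 30.0:
            p = snap.point  # relocate onto the street it serves
        outlets.append(
            FoodOutlet(
                id=f"o{i:05d}",
                location=(float(p.x), float(p.y)),
                category=cats[ci],
            )
        )
    return outlets


# ---------------------------------------------------------------- households
def _edge_arrays(network: StreetNetwork):
    edges = list(network.graph.edges(data=True))
    lengths = np.array([d["length_m"] for _, _, d in edges])
    straight = all(len(d["geometry"].coords) == 2 for _, _, d in edges)
    if straight:
        a = np.array([d["geometry"].coords[0] for _, _, d in edges])
        b = np.array([d["geometry"].coords[-1] for _, _, d in edges])
    else:
        a = b = None
    return edges, lengths, a, b


def _sample_network_points(rng, network: StreetNetwork, n: int) -> np.ndarray:
    """Uniform random points on the network (length-weighted edge choice)."""
    edges, lengths, a, b = _edge_arrays(network)
    probs = lengths / lengths.sum()
    idx = rng.choice(len(edges), size=n, p=probs)
    ts = rng.uniform(size=n)
    if a is not None:  # straight edges: exact linear interpolation
        return a[idx] + ts[:, None] * (b[idx] - a[idx])
    pts = np.empty((n, 2))
    for row, (ei, t) in enumerate(zip(idx, ts)):
        geom = edges[ei][2]["geometry"]
        p = geom.interpolate(t * geom.length)
        pts[row] = (p.x, p.y)
    return pts


def _rejection_sample(rng, network, config, n, accept_fn, batch=None):
    """Sample network points until ``n`` pass ``accept_fn`` (vector of bools)."""
    out = []
    batch = batch or max(4 * n, 256)
    got = 0
    for _ in range(10_000):
        pts = _sample_network_points(rng, network, batch)
        ok = accept_fn(pts)
        out.append(pts[ok])
        got += int(ok.sum())
        if got >= n:
            return np.concatenate(out)[:n]
    raise ValueError(
        "rejection sampling failed: the acceptance region is (nearly) empty "
        "on this network"
    )


def generate_households(
    config: CityConfig, network: StreetNetwork
) -> list[Household]:
    """Household sample with homes on the network and mode-linked anchors."""
    rng = np.random.default_rng(config.seed + 2)
    cp = config.covariate_params
    n = config.n_households
    cx, cy = config.center
    # zone feasibility: each ring must intersect the network, otherwise home
    # rejection sampling cannot terminate
    if config.zone_radii_m[1] >= config.grid_extent_m:
        raise ValueError(
            "outer zone radius must be smaller than grid_extent_m so a "
            "peri-urban ring exists on the network"
        )
    if config.zone_radii_m[0] < config.node_spacing_m:
        raise ValueError(
            "inner zone radius must be at least node_spacing_m so the "
            "center ring contains network points"
        )

    zones = rng.choice(len(ZONES), size=n, p=np.asarray(cp.zone_probs))
    homes = np.empty((n, 2))
    for zi, zone in enumerate(ZONES):
        idx = np.flatnonzero(zones == zi)
        if len(idx) == 0:
            continue

        def in_zone(pts, zone=zone):
            d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
            lo = 0.0 if zone == "center" else config.zone_radii_m[
                0 if zone == "pericentral" else 1
            ]
            hi = (
                config.zone_radii_m[0]
                if zone == "center"
                else config.zone_radii_m[1]
                if zone == "pericentral"
                else np.inf
            )
            return (d >= lo) & (d < hi)

        homes[idx] = _rejection_sample(rng, network, config, len(idx), in_zone)

    age = rng.choice(len(AGE_LEVELS), size=n, p=np.asarray(cp.age_probs))
    composition = rng.choice(
        len(COMPOSITION_LEVELS), size=n, p=np.asarray(cp.composition_probs)
    )
    income = rng.choice(len(INCOME_LEVELS), size=n, p=np.asarray(cp.income_probs))
    education = np.empty(n, dtype=int)
    employment = np.empty(n, dtype=int)
    for ai, a in enumerate(AGE_LEVELS):
        idx = age == ai
        education[idx] = rng.choice(
            len(EDUCATION_LEVELS), size=idx.sum(), p=np.asarray(cp.education_by_age[a])
        )
        employment[idx] = rng.choice(
            len(EMPLOYMENT_LEVELS),
            size=idx.sum(),
            p=np.asarray(cp.employment_by_age[a]),
        )
    car = np.empty(n, dtype=bool)
    for zi, zone in enumerate(ZONES):
        idx = zones == zi
        car[idx] = rng.uniform(size=idx.sum()) < cp.car_by_zone[zone]

    def accept_anchor(pts):
        d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        return rng.uniform(size=len(pts)) < np.exp(-d / config.decay_scale_m)

    # anchors: batched draws for all adults at once (anchor locations decay
    # toward the center like outlets — activity sites concentrate downtown)
    n_adults = np.where(
        np.isin(composition, [0, 2]), 1, 2
    )  # one_adult* -> 1 adult
    adult_hh = np.repeat(np.arange(n), n_adults)
    adult_idx = np.concatenate([np.arange(1, k + 1) for k in n_adults])
    anchor_counts = rng.choice(
        3, size=len(adult_hh), p=np.asarray(cp.anchor_count_probs)
    )
    total_anchors = int(anchor_counts.sum())
    locs = (
        _rejection_sample(rng, network, config, total_anchors, accept_anchor)
        if total_anchors
        else np.empty((0, 2))
    )
    anchor_hh = np.repeat(adult_hh, anchor_counts)
    anchor_adult = np.repeat(adult_idx, anchor_counts)
    modes = np.empty(total_anchors, dtype=object)
    car_anchor = car[anchor_hh]
    for owns, probs in ((True, cp.mode_probs_car), (False, cp.mode_probs_nocar)):
        sel = np.flatnonzero(car_anchor == owns)
        if len(sel) == 0:
            continue
        names = list(probs)
        p = np.array([probs[m] for m in names], dtype=float)
        modes[sel] = np.asarray(names, dtype=object)[
            rng.choice(len(names), size=len(sel), p=p / p.sum())
        ]

    anchors_by_hh: dict[int, list[AnchorPoint]] = {}
    for hh_i, adult, loc, mode in zip(anchor_hh, anchor_adult, locs, modes):
        anchors_by_hh.setdefault(int(hh_i), []).append(
            AnchorPoint(
                location=(float(loc[0]), float(loc[1])),
                mode=str(mode),
                adult_index=int(adult),
            )
        )

    households = []
    for i in range(n):
        comp = COMPOSITION_LEVELS[composition[i]]
        households.append(
            Household(
                household_id=f"h{i:04d}",
                home=(float(homes[i, 0]), float(homes[i, 1])),
                anchors=anchors_by_hh.get(i, []),
                covariates={
                    "age": AGE_LEVELS[age[i]],
                    "education": EDUCATION_LEVELS[education[i]],
                    "employment": EMPLOYMENT_LEVELS[employment[i]],
                    "composition": comp,
                    "income": INCOME_LEVELS[income[i]],
                    "car": "yes" if car[i] else "no",
                    "home_location": config.zone_of(homes[i]),
                    "composition_age": f"{comp}|{AGE_LEVELS[age[i]]}",
                },
            )
        )
    return households


# ------------------------------------------------------------------- margins
def true_margins(config: CityConfig) -> PopulationMargins:
    """Generating-distribution margins of the two calibration variables.

    Income per consumption unit, and household composition crossed with the
    age group of the household head (independent in the generator, so the
    cross table is the outer product of the two marginals).
    """
    cp = config.covariate_params
    income = dict(zip(INCOME_LEVELS, (float(p) for p in cp.income_probs)))
    cross = {}
    for comp, pc in zip(COMPOSITION_LEVELS, cp.composition_probs):
        for a, pa in zip(AGE_LEVELS, cp.age_probs):
            cross[f"{comp}|{a}"] = float(pc) * float(pa)
    return PopulationMargins({"income": income, "composition_age": cross})


def with_seed(config: CityConfig, seed: int) -> CityConfig:
    return replace(config, seed=seed)
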