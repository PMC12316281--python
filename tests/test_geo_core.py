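"""Exposure-area delineation: closed forms, brute-force oracles, invariants."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from foodexposure import (
    AnchorPoint,
    BufferParams,
    Household,
    area_km2,
    fastest_path,
    home_buffer,
    household_activity_space,
    network_buffer,
    route_corridor,
)
from foodexposure.errors import NoPathError, SnapError, UnknownModeError
from foodexposure.exposure import ExposureArea
from foodexposure.network import StreetNetwork


# ----------------------------------------------------------- network buffers
def test_single_edge_buffer_closed_form(single_edge_net):
    """500 m along a straight edge: rectangle 2w*500 plus two end caps."""
    area = network_buffer(single_edge_net, (0, 0), 500.0)
    expected = 2 * 25 * 500 + np.pi * 25**2
    assert area.area_m2 == pytest.approx(expected, rel=0.01)
    snap = single_edge_net.snap((0, 0))
    assert single_edge_net.reachable_length_m(snap, 500.0) == pytest.approx(500.0)


def test_star_network_fully_reachable(star_net):
    """Four 300 m spokes within a 500 m radius: 1200 m of reachable length."""
    snap = star_net.snap((0, 0))
    assert star_net.reachable_length_m(snap, 500.0) == pytest.approx(1200.0)
    # and cross-check against brute-force Dijkstra from the hub
    assert star_net.reachable_length_m(snap, 250.0) == pytest.approx(4 * 250.0)


def test_buffer_monotone_in_radius_and_halfwidth(small_city_layers):
    net, _, households = small_city_layers
    home = households[0].home
    a400 = network_buffer(net, home, 400.0)
    a500 = network_buffer(net, home, 500.0)
    assert a400.polygon.buffer(-1e-6).within(a500.polygon)
    wide = network_buffer(net, home, 400.0, BufferParams(edge_halfwidth_m=40.0))
    assert a400.area_m2 <= a500.area_m2
    assert a400.area_m2 <= wide.area_m2


def test_snap_error_far_from_network(single_edge_net):
    with pytest.raises(SnapError):
        network_buffer(single_edge_net, (0, 5000), 500.0)


def test_reachable_length_matches_bruteforce_dijkstra(rng):
    """On random small graphs the reachable length equals a brute-force sum."""
    for trial in range(5):
        n = 8
        pts = rng.uniform(0, 1000, (n, 2))
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.uniform() < 0.45:
                    edges.append((i, j))
        for i in range(n - 1):  # ensure connectivity via a chain
            edges.append((i, i + 1))
        net = StreetNetwork.from_edges(
            {i: tuple(pts[i]) for i in range(n)}, set(edges)
        )
        origin = tuple(pts[0])
        radius = 600.0
        snap = net.snap(origin)
        dist = net.distances_from_snap(snap)
        # oracle: for each edge sum the reachable portion from both ends
        total = 0.0
        for u, v, d in net.graph.edges(data=True):
            L = d["length_m"]
            iv = []
            if dist.get(u, np.inf) < radius:
                iv.append((0.0, min(L, radius - dist[u])))
            if dist.get(v, np.inf) < radius:
                iv.append((max(0.0, L - (radius - dist[v])), L))
            iv.sort()
            covered, end = 0.0, -1.0
            for lo, hi in iv:
                lo = max(lo, end)
                if hi > lo:
                    covered += hi - lo
                    end = hi
            total += covered
        assert net.reachable_length_m(snap, radius) == pytest.approx(total, abs=1e-6)


# ------------------------------------------------------------- fastest paths
def test_zero_length_path(triangle_net):
    _, length = fastest_path(triangle_net, (0, 0), (0, 0))
    assert length == 0.0


def test_triangle_direct_edge_chosen(triangle_net):
    _, length = fastest_path(triangle_net, (0, 0), (3, 0))
    assert length == pytest.approx(3.0)


def test_path_symmetry(small_city_layers):
    net, _, households = small_city_layers
    a = households[0].home
    b = households[1].home
    _, lab = fastest_path(net, a, b)
    _, lba = fastest_path(net, b, a)
    assert lab == pytest.approx(lba, abs=1e-6)


def _bruteforce_shortest(net, src, dst):
    """Exhaustive enumeration of simple paths by DFS (oracle)."""
    G = net.graph
    best = np.inf

    def dfs(node, seen, acc):
        nonlocal best
        if acc >= best:
            return
        if node == dst:
            best = acc
            return
        for nb in G[node]:
            if nb not in seen:
                dfs(nb, seen | {nb}, acc + G.edges[node, nb]["length_m"])

    dfs(src, {src}, 0.0)
    return best


def test_shortest_path_matches_enumeration_on_small_graphs(rng):
    """Dijkstra route length equals brute-force enumeration on <=8-node graphs."""
    for trial in range(8):
        n = int(rng.integers(5, 9))
        pts = rng.uniform(0, 800, (n, 2))
        edges = {(i, i + 1) for i in range(n - 1)}
        for i in range(n):
            for j in range(i + 2, n):
                if rng.uniform() < 0.35:
                    edges.add((i, j))
        net = StreetNetwork.from_edges(
            {i: tuple(pts[i]) for i in range(n)}, edges
        )
        src, dst = tuple(pts[0]), tuple(pts[n - 1])
        _, length = fastest_path(net, src, dst)
        assert length == pytest.approx(
            _bruteforce_shortest(net, 0, n - 1), abs=1e-6
        )


def test_no_path_between_components():
    net = StreetNetwork.from_edges(
        {0: (0, 0), 1: (100, 0), 2: (5000, 5000), 3: (5100, 5000)},
        [(0, 1), (2, 3)],
    )
    with pytest.raises(NoPathError):
        fastest_path(net, (0, 0), (5000, 5000))


def test_same_edge_shortcut_detected():
    """Two points on a long edge may be closer via a parallel short path."""
    # nodes 0-1 joined by a direct 1000 m edge and a 3-hop 120 m detour
    net = StreetNetwork.from_edges(
        {0: (0, 0), 1: (1000, 0), 2: (0, 40), 3: (1000, 40)},
        [(0, 1), (0, 2), (2, 3), (3, 1)],
    )
    # points at 10 m and 990 m along the bottom edge
    _, length = fastest_path(net, (10, 0), (990, 0))
    assert length == pytest.approx(980.0)  # direct is still best here
    _, l2 = fastest_path(net, (10, 0), (10, 40))
    assert l2 == pytest.approx(10 + 0 + 10 + 0, abs=50)  # via node 0 and 2


# ---------------------------------------------------------- route corridors
def test_walk_corridor_closed_form():
    route = LineString([(0, 0), (1000, 0)])
    c = route_corridor(route, "walk")
    expected = 2 * 100 * 1000 + np.pi * 100**2
    assert c.area == pytest.approx(expected, rel=1e-3)


def test_transit_corridor_empty():
    route = LineString([(0, 0), (1000, 0)])
    assert route_corridor(route, "public_transit").is_empty


def test_zero_length_route_motor_disc():
    route = LineString([(5, 5), (5, 5)])
    c = route_corridor(route, "car")
    assert c.area == pytest.approx(np.pi * 300**2, rel=1e-3)


def test_unknown_mode_rejected():
    with pytest.raises(UnknownModeError):
        route_corridor(LineString([(0, 0), (1, 1)]), "teleport")


# ---------------------------------------------------------- activity spaces
def test_zero_anchor_household_equals_home_buffer(small_city_layers):
    net, _, _ = small_city_layers
    h = Household("hh0", home=(10.0, 5.0), anchors=[])
    asp = household_activity_space(h, net)
    hb = home_buffer(h, net)
    assert asp.area_m2 == pytest.approx(hb.area_m2, rel=1e-9)
    assert asp.polygon.symmetric_difference(hb.polygon).area < 1e-6


def test_seven_piece_topology(small_city_layers):
    """Two adults: one with two bike anchors, one with a car and a transit
    anchor — one home buffer, four anchor buffers, three bike corridors
    (home->a1, home->a2, a1->a2) and one car corridor; none for transit."""
    net, _, _ = small_city_layers
    home = (0.0, 0.0)
    a1 = AnchorPoint((750.0, 0.0), "bike", adult_index=1)
    a2 = AnchorPoint((0.0, 750.0), "bike", adult_index=1)
    a3 = AnchorPoint((-750.0, 0.0), "car", adult_index=2)
    a4 = AnchorPoint((0.0, -750.0), "public_transit", adult_index=2)
    h = Household("hh1", home=home, anchors=[a1, a2, a3, a4])
    asp = household_activity_space(h, net)

    params = BufferParams()
    pieces = [network_buffer(net, home, 500.0).polygon]
    for a in (a1, a2, a3, a4):
        pieces.append(network_buffer(net, a.location, 500.0).polygon)
    for a, mode in ((a1, "bike"), (a2, "bike"), (a3, "car")):
        r, _ = fastest_path(net, home, a.location)
        pieces.append(route_corridor(r, mode, params))
    r12, _ = fastest_path(net, a1.location, a2.location)
    pieces.append(route_corridor(r12, "bike", params))
    from shapely.ops import unary_union

    manual = unary_union(pieces)
    assert asp.polygon.symmetric_difference(manual).area < 1e-6
    # dropping the transit anchor shrinks the space (its buffer counts)
    h_no_transit = Household("hh2", home=home, anchors=[a1, a2, a3])
    asp2 = household_activity_space(h_no_transit, net)
    assert asp2.area_m2 < asp.area_m2


def test_colocated_anchors_contain_home_buffer(small_city_layers):
    net, _, _ = small_city_layers
    home = (20.0, -10.0)
    h = Household(
        "hh3",
        home=home,
        anchors=[AnchorPoint(home, "walk", 1), AnchorPoint(home, "car", 2)],
    )
    asp = household_activity_space(h, net)
    hb = home_buffer(h, net)
    assert hb.polygon.buffer(-1e-6).within(asp.polygon)
    # corridors collapse to discs of the corridor radius around the home
    assert asp.area_m2 >= np.pi * 300**2 * 0.99


def test_containment_and_permutation_invariance(small_city_layers):
    net, _, households = small_city_layers
    tested = 0
    for h in households:
        if len(h.anchors) < 2:
            continue
        asp = household_activity_space(h, net)
        hb = home_buffer(h, net)
        assert hb.polygon.buffer(-1e-6).within(asp.polygon)
        perm = Household(
            h.household_id, h.home, list(reversed(h.anchors)), h.covariates
        )
        asp_perm = household_activity_space(perm, net)
        assert asp.polygon.symmetric_difference(asp_perm.polygon).area < 1e-6
        tested += 1
        if tested >= 8:
            break
    assert tested >= 3


# -------------------------------------------------------------------- areas
def test_area_km2_trivia():
    from shapely.geometry import Polygon, box

    assert area_km2(ExposureArea("home_buffer", Polygon())) == 0.0
    assert area_km2(ExposureArea("home_buffer", box(0, 0, 1000, 1000))) == pytest.approx(1.0)


def test_area_km2_monte_carlo_oracle(rng):
    """Polygon area agrees with rejection sampling to within 1%."""
    pts = rng.uniform(0, 1000, (12, 2))
    from shapely.geometry import MultiPoint

    poly = MultiPoint([tuple(p) for p in pts]).convex_hull.buffer(50)
    xmin, ymin, xmax, ymax = poly.bounds
    n = 200_000
    xs = rng.uniform(xmin, xmax, n)
    ys = rng.uniform(ymin, ymax, n)
    import shapely

    inside = shapely.contains_xy(poly, xs, ys).mean()
    mc = inside * (xmax - xmin) * (ymax - ymin) / 1e6
    assert area_km2(ExposureArea("home_buffer", poly)) == pytest.approx(mc, rel=0.01)
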