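"""Street-network container and routing primitives.

The network is an undirected :class:`networkx.Graph` embedded in a local
Cartesian plane (meters).  Nodes carry ``x``/``y`` coordinates; edges carry a
``length_m`` weight and a shapely ``geometry`` polyline oriented from the
lower to the higher endpoint of the stored edge key.  All exposure-area
delineation (service areas, fastest paths) runs on this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import LineString, Point, mapping, shape
from shapely.ops import substring
from shapely.strtree import STRtree

from .errors import NoPathError, SnapError

#: maximum distance (m) a point may lie from the network before snapping fails
SNAP_TOLERANCE_M = 30.0


@dataclass(frozen=True)
class EdgeSnap:
    """Result of projecting a point onto the nearest network edge.

    ``t`` is the arc-length position of the snapped point along the edge
    geometry measured from endpoint ``u``; ``offset_m`` is the Euclidean
    distance from the query point to the snapped point.
    """

    u: int
    v: int
    t: float
    point: Point
    offset_m: float


class StreetNetwork:
    """Planar street network in meters with snapping and routing support."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self._edge_index: list[tuple[int, int]] = []
        geoms = []
        for u, v, data in graph.edges(data=True):
            if "geometry" not in data:
                data["geometry"] = LineString(
                    [self.node_xy(u), self.node_xy(v)]
                )
            if "length_m" not in data:
                data["length_m"] = data["geometry"].length
            self._edge_index.append((u, v))
            geoms.append(data["geometry"])
        self._edge_geoms = geoms
        self._tree = STRtree(geoms) if geoms else None

    # ------------------------------------------------------------------ basic
    def node_xy(self, n) -> tuple[float, float]:
        d = self.graph.nodes[n]
        return (d["x"], d["y"])

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        xs = [d["x"] for _, d in self.graph.nodes(data=True)]
        ys = [d["y"] for _, d in self.graph.nodes(data=True)]
        return (min(xs), min(ys), max(xs), max(ys))

    def total_length_m(self) -> float:
        return float(
            sum(d["length_m"] for _, _, d in self.graph.edges(data=True))
        )

    def edge_geometry(self, u, v) -> LineString:
        """Edge polyline oriented from ``u`` to ``v``."""
        data = self.graph.edges[u, v]
        geom = data["geometry"]
        # stored orientation is from the stored key's first endpoint
        start = Point(self.node_xy(u))
        if geom.coords[0] != (start.x, start.y):
            d0 = Point(geom.coords[0]).distance(start)
            d1 = Point(geom.coords[-1]).distance(start)
            if d1 < d0:
                geom = LineString(list(geom.coords)[::-1])
        return geom

    # --------------------------------------------------------------- snapping
    def snap(self, point, tolerance_m: float = SNAP_TOLERANCE_M) -> EdgeSnap:
        """Project ``point`` onto the nearest edge within ``tolerance_m``.

        Raises
        ------
        SnapError
            If the nearest edge is farther than ``tolerance_m``.
        """
        if self._tree is None:
            raise SnapError("network has no edges")
        p = Point(point)
        idx = int(self._tree.nearest(p))
        geom = self._edge_geoms[idx]
        offset = p.distance(geom)
        if offset > tolerance_m:
            raise SnapError(
                f"point ({p.x:.1f}, {p.y:.1f}) is {offset:.1f} m from the "
                f"network (tolerance {tolerance_m} m)"
            )
        u, v = self._edge_index[idx]
        oriented = self.edge_geometry(u, v)
        t = float(oriented.project(p))
        return EdgeSnap(u=u, v=v, t=t, point=oriented.interpolate(t), offset_m=offset)

    # ---------------------------------------------------------------- routing
    def distances_from_snap(
        self, snap: EdgeSnap, cutoff: float | None = None
    ) -> dict:
        """Shortest network distance from the snapped point to every node.

        Any walk from a point interior to an edge must first reach one of the
        edge's endpoints, so the distance to node *x* is
        ``min(t + d(u, x), (L - t) + d(v, x))``.
        """
        L = self.graph.edges[snap.u, snap.v]["length_m"]
        du = nx.single_source_dijkstra_path_length(
            self.graph, snap.u, cutoff=cutoff, weight="length_m"
        )
        dv = nx.single_source_dijkstra_path_length(
            self.graph, snap.v, cutoff=cutoff, weight="length_m"
        )
        out: dict = {}
        for n, d in du.items():
            out[n] = snap.t + d
        for n, d in dv.items():
            alt = (L - snap.t) + d
            if alt < out.get(n, np.inf):
                out[n] = alt
        if cutoff is not None:
            out = {n: d for n, d in out.items() if d <= cutoff}
        return out

    def _route_between_snaps(
        self, s0: EdgeSnap, s1: EdgeSnap
    ) -> tuple[LineString, float]:
        """Shortest path between two snapped points via temporary virtual nodes."""
        G = self.graph
        SRC, DST = "__src__", "__dst__"
        try:
            for name, s in ((SRC, s0), (DST, s1)):
                G.add_node(name, x=s.point.x, y=s.point.y)
                geom = self.edge_geometry(s.u, s.v)
                L = G.edges[s.u, s.v]["length_m"]
                # partial edges to both endpoints of the host edge
                g_u = substring(geom, 0.0, s.t)
                g_v = substring(geom, s.t, geom.length)
                G.add_edge(name, s.u, length_m=s.t, geometry=g_u, _virtual=True)
                G.add_edge(name, s.v, length_m=L - s.t, geometry=g_v, _virtual=True)
            if (s0.u, s0.v) == (s1.u, s1.v):
                # both points on the same edge: direct along-edge connection
                geom = self.edge_geometry(s0.u, s0.v)
                lo, hi = sorted((s0.t, s1.t))
                G.add_edge(
                    SRC, DST,
                    length_m=hi - lo,
                    geometry=substring(geom, lo, hi),
                    _virtual=True,
                )
            try:
                length, nodes = nx.single_source_dijkstra(
                    G, SRC, DST, weight="length_m"
                )
            except nx.NetworkXNoPath as exc:
                raise NoPathError(
                    "origin and destination lie in different components"
                ) from exc
            parts: list[tuple[float, float]] = []
            prev = None
            for a, b in zip(nodes[:-1], nodes[1:]):
                geom = G.edges[a, b]["geometry"]
                coords = list(geom.coords)
                ax, ay = G.nodes[a]["x"], G.nodes[a]["y"]
                if Point(coords[-1]).distance(Point(ax, ay)) < Point(
                    coords[0]
                ).distance(Point(ax, ay)):
                    coords = coords[::-1]
                if prev is not None and coords and coords[0] == prev:
                    coords = coords[1:]
                parts.extend(coords)
                if coords:
                    prev = coords[-1]
            if len(parts) < 2:
                line = LineString([(s0.point.x, s0.point.y)] * 2)
            else:
                line = LineString(parts)
            return line, float(length)
        finally:
            for name in (SRC, DST):
                if G.has_node(name):
                    G.remove_node(name)

    # ------------------------------------------------------------- reachable
    def reachable_edges(
        self, snap: EdgeSnap, radius_m: float
    ) -> list[LineString]:
        """Edge fragments whose network distance from the snap is <= radius.

        Partial edges are truncated at the exact residual distance, so the
        total fragment length equals the reachable sub-network length.
        """
        dist = self.distances_from_snap(snap, cutoff=radius_m)
        if not dist and radius_m <= 0:
            return []
        frags: list[LineString] = []
        snap_key = frozenset((snap.u, snap.v))
        # only edges touching a reached node (or the snap edge itself) can
        # contain reachable points
        seen = set()
        candidates = []
        for u, v, data in self.graph.edges(nbunch=list(dist), data=True):
            key = frozenset((u, v))
            if key not in seen:
                seen.add(key)
                candidates.append((u, v, data))
        if snap_key not in seen:
            candidates.append(
                (snap.u, snap.v, self.graph.edges[snap.u, snap.v])
            )
        for u, v, data in candidates:
            L = data["length_m"]
            geom = self.edge_geometry(u, v)
            intervals: list[tuple[float, float]] = []
            du = dist.get(u)
            dv = dist.get(v)
            if du is not None and du < radius_m:
                intervals.append((0.0, min(L, radius_m - du)))
            if dv is not None and dv < radius_m:
                intervals.append((max(0.0, L - (radius_m - dv)), L))
            if frozenset((u, v)) == snap_key:
                intervals.append(
                    (max(0.0, snap.t - radius_m), min(L, snap.t + radius_m))
                )
            for lo, hi in _merge_intervals(intervals):
                if hi - lo > 1e-9:
                    frags.append(substring(geom, lo, hi))
        return frags

    def reachable_length_m(self, snap: EdgeSnap, radius_m: float) -> float:
        return float(sum(f.length for f in self.reachable_edges(snap, radius_m)))

    # -------------------------------------------------------------------- IO
    def to_geojson(self, path) -> None:
        feats = []
        for u, v, data in self.graph.edges(data=True):
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(data["geometry"]),
                    "properties": {
                        "u": u,
                        "v": v,
                        "length_m": data["length_m"],
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path) -> "StreetNetwork":
        """Read LineString features; node ids are assigned to unique endpoints.

        An optional ``length_m`` property overrides the geometric length.
        """
        with open(path) as fh:
            fc = json.load(fh)
        G = nx.Graph()
        node_ids: dict[tuple[float, float], int] = {}

        def nid(xy):
            key = (round(xy[0], 6), round(xy[1], 6))
            if key not in node_ids:
                node_ids[key] = len(node_ids)
                G.add_node(node_ids[key], x=key[0], y=key[1])
            return node_ids[key]

        for feat in fc["features"]:
            geom = shape(feat["geometry"])
            if geom.geom_type != "LineString":
                continue
            coords = list(geom.coords)
            u = nid(coords[0])
            v = nid(coords[-1])
            props = feat.get("properties") or {}
            G.add_edge(
                u,
                v,
                geometry=geom,
                length_m=float(props.get("length_m", geom.length)),
            )
        return cls(G)

    @classmethod
    def from_edges(
        cls,
        nodes: Mapping[int, tuple[float, float]],
        edges: Iterable[Sequence],
    ) -> "StreetNetwork":
        """Build from ``{id: (x, y)}`` and ``(u, v)`` pairs (straight edges)."""
        G = nx.Graph()
        for n, (x, y) in nodes.items():
            G.add_node(n, x=float(x), y=float(y))
        for e in edges:
            u, v = e[0], e[1]
            G.add_edge(u, v)
        return cls(G)


def _merge_intervals(
    intervals: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]
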