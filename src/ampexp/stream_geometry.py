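"""Stream-network data model, Strahler ordering and site-slope estimation.

The network is a directed forest: edges point downstream, every component
drains to exactly one outlet.  Each vertex carries projected metric
coordinates and an elevation (DEM-style, metre-rounded elevations are
accepted as-is); each edge carries a 3-D polyline whose endpoints coincide
with its vertices.  All distances used anywhere in this module are
along-channel polyline distances in the horizontal plane, never Euclidean
shortcuts between sites.

Stream slope at a sampling site is estimated from two section end points
located a fixed reach (default 100 m) up- and downstream of the site along
the channel.  Confluences complicate this: if a branching node lies nearer
than the reach on one side only, that side is dropped; if both sides are
obstructed, the branching nodes themselves become the end points at their
true along-channel distances.  Sites within the reach of a spring (source
vertex) use the downstream end point only.  With two candidate slopes the
lower one is returned, a conservative choice that damps DEM noise on the
steeper side.  Negative raw gradients (elevation rising downstream, a DEM
artefact) are clamped to zero before comparison and flagged in the QC
report rather than silently edited.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString

# ---------------------------------------------------------------------------
# Vocabularies

DRAINAGE_CATEGORIES = ("spring", "<10", "10-100", "100-1000", ">1000")
RIVER_ORDER_CATEGORIES = ("spring", "1", "2", "3", "4", "5", "6", "7")
HABITAT_TYPES = ("stream", "spring", "standing water")

SLOPE_QC_MAX_PCT = 60.0          # slopes above this are flagged as suspect
NEGATIVE_GRADIENT_TOL = 1e-9     # raw gradients below -tol are flagged


class StreamNetworkError(ValueError):
    """Raised for structurally invalid networks or invalid slope queries."""


# ---------------------------------------------------------------------------
# Network container


class StreamNetwork:
    """Directed stream network (edges oriented downstream).

    Parameters
    ----------
    graph
        ``networkx.DiGraph`` with vertex attributes ``x``, ``y``,
        ``elevation`` and edge attribute ``geometry`` (sequence of
        ``(x, y, z)`` triples whose first/last points coincide with the
        incident vertices).  Optional edge attribute ``side_channel``
        marks artificial side-channels, which inherit the Strahler order
        of their parent stream instead of contributing to it.
    """

    def __init__(self, graph: nx.DiGraph):
        self.graph = graph
        self._validate()

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        g = self.graph
        if g.number_of_nodes() == 0:
            raise StreamNetworkError("empty network")
        try:
            cycle = nx.find_cycle(g)
            raise StreamNetworkError(
                f"network contains a cycle through edge {cycle[0][:2]}"
            )
        except nx.NetworkXNoCycle:
            pass
        for v, data in g.nodes(data=True):
            for key in ("x", "y", "elevation"):
                if key not in data or not math.isfinite(data[key]):
                    raise StreamNetworkError(f"vertex {v} lacks finite {key!r}")
            main_out = [w for w in g.successors(v)
                        if not g.edges[v, w].get("side_channel", False)]
            if len(main_out) > 1:
                raise StreamNetworkError(
                    f"vertex {v} has multiple downstream edges (not a forest)"
                )
        for u, v, data in g.edges(data=True):
            geom = data.get("geometry")
            if geom is None:
                geom = [
                    (g.nodes[u]["x"], g.nodes[u]["y"], g.nodes[u]["elevation"]),
                    (g.nodes[v]["x"], g.nodes[v]["y"], g.nodes[v]["elevation"]),
                ]
                data["geometry"] = geom
            data["length"] = polyline_length(geom)
            if data["length"] <= 0:
                raise StreamNetworkError(f"edge {(u, v)} has zero length")

    # -- basic queries -------------------------------------------------------

    @property
    def outlets(self) -> list:
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    @property
    def sources(self) -> list:
        return [v for v in self.graph if self.graph.in_degree(v) == 0]

    def edge_length(self, u, v) -> float:
        return self.graph.edges[u, v]["length"]

    def elevation_at(self, u, v, dist: float) -> float:
        """Elevation at ``dist`` metres downstream of ``u`` along edge (u, v)."""
        return interpolate_z(self.graph.edges[u, v]["geometry"], dist)

    def point_at(self, u, v, dist: float) -> tuple[float, float]:
        geom = self.graph.edges[u, v]["geometry"]
        line = LineString([(p[0], p[1]) for p in geom])
        pt = line.interpolate(min(max(dist, 0.0), line.length))
        return (pt.x, pt.y)

    # -- I/O -----------------------------------------------------------------

    def to_geojson(self, path) -> None:
        features = []
        for u, v, data in self.graph.edges(data=True):
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [list(p) for p in data["geometry"]],
                    },
                    "properties": {
                        "from": int(u),
                        "to": int(v),
                        "side_channel": bool(data.get("side_channel", False)),
                        "drainage_km2": float(data.get("drainage_km2", float("nan"))),
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "StreamNetwork":
        with open(path) as fh:
            fc = json.load(fh)
        g = nx.DiGraph()
        for feat in fc["features"]:
            coords = [tuple(p) for p in feat["geometry"]["coordinates"]]
            props = feat.get("properties", {})
            u, v = props["from"], props["to"]
            for node, p in ((u, coords[0]), (v, coords[-1])):
                g.add_node(node, x=p[0], y=p[1], elevation=p[2])
            g.add_edge(
                u,
                v,
                geometry=coords,
                side_channel=bool(props.get("side_channel", False)),
                drainage_km2=props.get("drainage_km2", float("nan")),
            )
        return cls(g)


def polyline_length(geom: Sequence[tuple]) -> float:
    """Horizontal (2-D) length of a polyline of (x, y[, z]) points."""
    pts = np.asarray([(p[0], p[1]) for p in geom], dtype=float)
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


def interpolate_z(geom: Sequence[tuple], dist: float) -> float:
    """Linearly interpolated z at a horizontal distance along the polyline."""
    pts = np.asarray(geom, dtype=float)
    seg = np.sqrt(((pts[1:, :2] - pts[:-1, :2]) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    d = min(max(dist, 0.0), cum[-1])
    return float(np.interp(d, cum, pts[:, 2]))


# ---------------------------------------------------------------------------
# Site records


@dataclass
class SiteRecord:
    """A sampling site anchored to a position on a network edge."""

    site_id: int
    edge: tuple
    dist_along: float                      # metres downstream of edge tail
    x: float = float("nan")
    y: float = float("nan")
    habitat: str = "stream"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.habitat not in HABITAT_TYPES:
            raise ValueError(f"unknown habitat type {self.habitat!r}")


# ---------------------------------------------------------------------------
# Strahler order


def strahler_order(network: StreamNetwork) -> dict:
    """Per-edge Strahler order.

    Source edges have order 1; where two tributaries of equal order *k*
    meet, the downstream edge has order *k* + 1, otherwise the maximum of
    the joining orders.  Edges flagged ``side_channel`` are excluded from
    the junction arithmetic and instead inherit the order of the stream
    they branch from.
    """
    g = network.graph
    order: dict = {}
    main_edges = [
        (u, v) for u, v, d in g.edges(data=True) if not d.get("side_channel", False)
    ]
    sub = nx.DiGraph()
    sub.add_nodes_from(g.nodes)
    sub.add_edges_from(main_edges)
    for v in nx.topological_sort(sub):
        out = list(sub.successors(v))
        incoming = [order[(u, v)] for u in sub.predecessors(v)]
        if not out:
            continue
        w = out[0]
        if not incoming:
            order[(v, w)] = 1
        else:
            top = sorted(incoming, reverse=True)
            if len(top) >= 2 and top[0] == top[1]:
                order[(v, w)] = top[0] + 1
            else:
                order[(v, w)] = top[0]
    # side channels inherit the parent stream's order at their branch point
    for u, v, d in g.edges(data=True):
        if d.get("side_channel", False):
            parent = [order[e] for e in order if e[0] == u or e[1] == u]
            order[(u, v)] = max(parent) if parent else 1
    return order


# ---------------------------------------------------------------------------
# Slope procedure


@dataclass
class SlopeResult:
    slope_pct: float
    upstream_slope_pct: float | None
    downstream_slope_pct: float | None
    upstream_status: str        # clean | confluence | spring | unused
    downstream_status: str      # clean | confluence | outlet | unused
    qc_flags: list


def _walk(network: StreamNetwork, edge: tuple, pos: float, reach: float,
          direction: str):
    """Walk ``reach`` m along the channel; classify the end of the walk.

    Returns (status, node_or_None, distance_walked, elevation_at_endpoint).
    status is one of 'clean', 'confluence', 'spring', 'outlet'.
    """
    g = network.graph
    u, v = edge
    remaining = reach
    travelled = 0.0
    if direction == "up":
        avail = pos
        while True:
            if remaining <= avail:
                elev = network.elevation_at(u, v, pos - remaining)
                return "clean", None, reach, elev
            travelled += avail
            remaining -= avail
            node = u
            preds = list(g.predecessors(node))
            if len(preds) == 0:
                return "spring", node, travelled, g.nodes[node]["elevation"]
            if len(preds) >= 2:
                return "confluence", node, travelled, g.nodes[node]["elevation"]
            u, v = preds[0], node
            pos = network.edge_length(u, v)
            avail = pos
    else:
        avail = network.edge_length(u, v) - pos
        offset = pos
        while True:
            if remaining <= avail:
                elev = network.elevation_at(u, v, offset + remaining)
                return "clean", None, reach, elev
            travelled += avail
            remaining -= avail
            node = v
            succs = list(g.successors(node))
            if len(succs) == 0:
                return "outlet", node, travelled, g.nodes[node]["elevation"]
            if g.in_degree(node) >= 2:
                return "confluence", node, travelled, g.nodes[node]["elevation"]
            u, v = node, succs[0]
            offset = 0.0
            avail = network.edge_length(u, v)


def site_slope(network: StreamNetwork, site: SiteRecord,
               reach: float = 100.0) -> SlopeResult:
    """Stream slope (%) at a site from up-/downstream section end points.

    Implements the end-point rules described in the module docstring;
    raises :class:`StreamNetworkError` when neither side yields a valid
    end point (site squeezed between the outlet and an upstream
    confluence/spring with no usable section).
    """
    if reach <= 0:
        raise ValueError("reach must be positive")
    u, v = site.edge
    if (u, v) not in network.graph.edges:
        raise StreamNetworkError(f"site {site.site_id} anchored to unknown edge {(u, v)}")
    elev_site = network.elevation_at(u, v, site.dist_along)

    up_status, _, up_dist, up_elev = _walk(network, (u, v), site.dist_along, reach, "up")
    dn_status, _, dn_dist, dn_elev = _walk(network, (u, v), site.dist_along, reach, "down")

    qc: list = []

    def side_slope(delta: float, dist: float, label: str) -> float:
        raw = delta / dist
        if raw < -NEGATIVE_GRADIENT_TOL:
            qc.append(f"negative {label} gradient ({raw * 100:.3g}%) clamped to 0")
        return max(raw, 0.0) * 100.0

    up_ok = up_status in ("clean", "confluence")
    dn_ok = dn_status in ("clean", "confluence")

    # spring upstream: downstream end point only
    if up_status == "spring":
        up_ok = False
    # a side with a near confluence is dropped when the other side is clean
    if up_status == "confluence" and dn_status == "clean":
        up_ok = False
    if dn_status == "confluence" and up_status == "clean":
        dn_ok = False

    up_slope = dn_slope = None
    if up_ok:
        up_slope = side_slope(up_elev - elev_site, up_dist, "upstream")
    if dn_ok:
        dn_slope = side_slope(elev_site - dn_elev, dn_dist, "downstream")

    candidates = [s for s in (up_slope, dn_slope) if s is not None]
    if not candidates:
        raise StreamNetworkError(
            f"site {site.site_id}: no valid slope section "
            f"(upstream={up_status}, downstream={dn_status})"
        )
    slope = min(candidates)
    if slope > SLOPE_QC_MAX_PCT:
        qc.append(f"slope {slope:.1f}% exceeds {SLOPE_QC_MAX_PCT}% QC threshold")
    return SlopeResult(
        slope_pct=slope,
        upstream_slope_pct=up_slope,
        downstream_slope_pct=dn_slope,
        upstream_status=up_status,
        downstream_status=dn_status,
        qc_flags=qc,
    )


# ---------------------------------------------------------------------------
# Categorisation


def drainage_category(area_km2: float, is_spring: bool = False) -> str:
    """Five-class drainage-size category with half-open [low, high) bins."""
    if is_spring:
        return "spring"
    if not math.isfinite(area_km2) or area_km2 < 0:
        raise ValueError(f"invalid drainage area {area_km2!r}")
    if area_km2 < 10:
        return "<10"
    if area_km2 < 100:
        return "10-100"
    if area_km2 < 1000:
        return "100-1000"
    return ">1000"


def river_order_category(order: int, is_spring: bool = False) -> str:
    """Eight-class river-order category: spring, then orders 1..7 (capped)."""
    if is_spring:
        return "spring"
    if order < 1:
        raise ValueError(f"invalid river order {order!r}")
    return str(min(int(order), 7))


# ---------------------------------------------------------------------------
# Bulk slope annotation + QC report


def annotate_slopes(network: StreamNetwork, sites: Iterable[SiteRecord],
                    reach: float = 100.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute slopes for many sites; returns (slope table, QC report)."""
    rows, qc_rows = [], []
    for site in sites:
        try:
            res = site_slope(network, site, reach=reach)
            rows.append(
                {
                    "site_id": site.site_id,
                    "slope_pct": res.slope_pct,
                    "upstream_slope_pct": res.upstream_slope_pct,
                    "downstream_slope_pct": res.downstream_slope_pct,
                    "upstream_status": res.upstream_status,
                    "downstream_status": res.downstream_status,
                }
            )
            for flag in res.qc_flags:
                qc_rows.append({"site_id": site.site_id, "flag": flag})
        except StreamNetworkError as exc:
            rows.append(
                {
                    "site_id": site.site_id,
                    "slope_pct": float("nan"),
                    "upstream_slope_pct": None,
                    "downstream_slope_pct": None,
                    "upstream_status": "error",
                    "downstream_status": "error",
                }
            )
            qc_rows.append({"site_id": site.site_id, "flag": str(exc)})
    return pd.DataFrame(rows), pd.DataFrame(qc_rows, columns=["site_id", "flag"])
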