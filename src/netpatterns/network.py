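"""Road-network metric space: graph construction, snapping, lixels, distances.

The road network is the metric space for every analysis in this package:
events (facilities, patients) live on edges as linear references
``(edge_id, offset)`` and all distances are shortest-path distances along
the network, never planar distances.

Coordinates must be planar and in meters (a projected CRS). Longitude /
latitude input is rejected because treating degrees as meters silently
corrupts every downstream statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, Polygon, MultiPolygon
from shapely.ops import substring
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

__all__ = [
    "RoadNetwork",
    "NetworkPoint",
    "NetworkPointSet",
    "LixelSet",
    "SnapReport",
    "build_network",
    "largest_component",
    "snap_to_network",
    "lixelize",
    "network_distance",
    "point_distance_matrix",
    "clip_network",
]

#: default tolerance for merging polyline endpoints into one node (meters)
DEFAULT_NODE_SNAP_TOLERANCE = 0.5
#: default maximum distance for snapping an event onto the network (meters)
DEFAULT_MAX_SNAP_DISTANCE = 500.0


def _looks_geographic(coords: np.ndarray) -> bool:
    """Heuristic: coordinates fit the lon/lat envelope and span only a few
    units — a metric road network never spans less than 10 m."""
    if coords.size == 0:
        return False
    in_envelope = np.all(np.abs(coords[:, 0]) <= 180.0) and np.all(
        np.abs(coords[:, 1]) <= 90.0
    )
    span = coords.max(axis=0) - coords.min(axis=0)
    return bool(in_envelope and np.all(span < 10.0))


@dataclass
class RoadNetwork:
    """Planar undirected road graph with polyline edge geometry.

    Nodes are indexed ``0..n_nodes-1`` with coordinates in meters; edges are
    indexed ``0..n_edges-1`` and connect ``edge_endpoints[e, 0]`` to
    ``edge_endpoints[e, 1]`` along ``edge_geometries[e]``. Edges are
    undirected and carry no travel-time or directionality attributes: road
    segments are treated equally.
    """

    node_coords: np.ndarray  # (N, 2) float
    edge_endpoints: np.ndarray  # (E, 2) int
    edge_geometries: list  # list[LineString]
    edge_lengths: np.ndarray  # (E,) float
    dropped_length: float = 0.0  # meters removed by largest_component
    _node_dist: np.ndarray | None = field(default=None, repr=False, compare=False)
    _edge_tree: STRtree | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_edges(self) -> int:
        return len(self.edge_lengths)

    @property
    def total_length(self) -> float:
        """Total segment length of the network in meters (S-tilde)."""
        return float(self.edge_lengths.sum())

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        xs, ys = self.node_coords[:, 0], self.node_coords[:, 1]
        return float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max())

    def to_graph(self) -> nx.MultiGraph:
        """Expose the network as a networkx MultiGraph (edge key = edge id)."""
        g = nx.MultiGraph()
        g.add_nodes_from(range(self.n_nodes))
        for e, (a, b) in enumerate(self.edge_endpoints):
            g.add_edge(int(a), int(b), key=e, length=float(self.edge_lengths[e]))
        return g

    def node_distance_matrix(self) -> np.ndarray:
        """All-pairs shortest-path distance between graph nodes (meters).

        Computed once and cached; parallel edges are collapsed to the
        shortest one, which is exact for node-to-node distances.
        """
        if self._node_dist is None:
            n = self.n_nodes
            a = self.edge_endpoints[:, 0]
            b = self.edge_endpoints[:, 1]
            w = self.edge_lengths
            # keep only the shortest of any parallel edges per node pair
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            order = np.lexsort((w, hi, lo))
            lo, hi, w = lo[order], hi[order], w[order]
            keep = np.ones(len(w), dtype=bool)
            if len(w) > 1:
                keep[1:] = (lo[1:] != lo[:-1]) | (hi[1:] != hi[:-1])
            lo, hi, w = lo[keep], hi[keep], w[keep]
            mat = csr_matrix((w, (lo, hi)), shape=(n, n))
            self._node_dist = _sp_dijkstra(mat, directed=False)
        return self._node_dist

    def diameter(self) -> float:
        """Largest finite shortest-path distance between nodes (meters)."""
        d = self.node_distance_matrix()
        finite = d[np.isfinite(d)]
        return float(finite.max()) if finite.size else 0.0

    def edge_tree(self) -> STRtree:
        if self._edge_tree is None:
            self._edge_tree = STRtree(self.edge_geometries)
        return self._edge_tree

    def point_coordinate(self, edge_id: int, offset: float) -> tuple[float, float]:
        """Planar coordinate of a linear reference on this network."""
        p = self.edge_geometries[edge_id].interpolate(offset)
        return (p.x, p.y)


@dataclass(frozen=True)
class NetworkPoint:
    """One event snapped onto the network as a linear reference."""

    edge_id: int
    offset: float  # meters from the edge's first node, in [0, edge length]
    weight: float = 1.0
    label: str | None = None
    source_coordinate: tuple[float, float] | None = None
    snap_distance: float = 0.0


class NetworkPointSet:
    """Ordered collection of events on one network, stored columnar.

    Arrays are exposed (``edge_ids``, ``offsets``, ``weights``, ...) so that
    density and K-function kernels can vectorize over the whole set;
    ``__getitem__`` materializes a :class:`NetworkPoint` view of one event.
    """

    def __init__(
        self,
        network: RoadNetwork,
        edge_ids: Sequence[int],
        offsets: Sequence[float],
        weights: Sequence[float] | None = None,
        labels: Sequence[str] | None = None,
        source_coords: np.ndarray | None = None,
        snap_distances: Sequence[float] | None = None,
    ):
        self.network = network
        self.edge_ids = np.asarray(edge_ids, dtype=np.int64)
        self.offsets = np.asarray(offsets, dtype=float)
        n = len(self.edge_ids)
        self.weights = (
            np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        )
        self.labels = list(labels) if labels is not None else [None] * n
        self.source_coords = source_coords
        self.snap_distances = (
            np.zeros(n)
            if snap_distances is None
            else np.asarray(snap_distances, dtype=float)
        )
        if np.any(self.edge_ids < 0) or np.any(self.edge_ids >= network.n_edges):
            raise ValueError("point references an edge not present in the network")
        lens = network.edge_lengths[self.edge_ids]
        if np.any(self.offsets < -1e-9) or np.any(self.offsets > lens + 1e-9):
            raise ValueError("offset outside [0, edge length]")
        self.offsets = np.clip(self.offsets, 0.0, lens)
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.edge_ids)

    def __getitem__(self, i: int) -> NetworkPoint:
        return NetworkPoint(
            edge_id=int(self.edge_ids[i]),
            offset=float(self.offsets[i]),
            weight=float(self.weights[i]),
            label=self.labels[i],
            source_coordinate=(
                tuple(self.source_coords[i]) if self.source_coords is not None else None
            ),
            snap_distance=float(self.snap_distances[i]),
        )

    def coordinates(self) -> np.ndarray:
        """Planar coordinates of the on-network positions, shape (n, 2)."""
        out = np.empty((len(self), 2))
        for i in range(len(self)):
            out[i] = self.network.point_coordinate(
                int(self.edge_ids[i]), float(self.offsets[i])
            )
        return out

    def subset(self, mask: np.ndarray) -> "NetworkPointSet":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return NetworkPointSet(
            self.network,
            self.edge_ids[idx],
            self.offsets[idx],
            self.weights[idx],
            [self.labels[i] for i in idx],
            None if self.source_coords is None else self.source_coords[idx],
            self.snap_distances[idx],
        )


@dataclass
class LixelSet:
    """Equal-length subdivision of every edge: the density evaluation units.

    Per edge, lixels tile ``[0, length]`` without gaps or overlaps, so the
    lixel lengths sum to the network's total length.
    """

    network: RoadNetwork
    edge_ids: np.ndarray  # (L,) int
    start_offsets: np.ndarray  # (L,)
    end_offsets: np.ndarray  # (L,)

    @property
    def lengths(self) -> np.ndarray:
        return self.end_offsets - self.start_offsets

    @property
    def centers(self) -> NetworkPointSet:
        return NetworkPointSet(
            self.network,
            self.edge_ids,
            (self.start_offsets + self.end_offsets) / 2.0,
        )

    def __len__(self) -> int:
        return len(self.edge_ids)

    _geoms: list | None = field(default=None, repr=False, compare=False)

    def geometries(self) -> list:
        """Shapely sub-linestrings of the lixels (computed once, cached)."""
        if self._geoms is None:
            self._geoms = [
                substring(self.network.edge_geometries[int(e)], s, t)
                for e, s, t in zip(
                    self.edge_ids, self.start_offsets, self.end_offsets
                )
            ]
        return self._geoms


@dataclass
class SnapReport:
    """Bookkeeping from :func:`snap_to_network`."""

    n_input: int
    n_snapped: int
    n_excluded: int
    excluded_indices: np.ndarray
    max_snap_distance: float


def build_network(
    polylines: Iterable,
    node_snap_tolerance: float = DEFAULT_NODE_SNAP_TOLERANCE,
    require_projected: bool = True,
) -> RoadNetwork:
    """Build a :class:`RoadNetwork` from polyline coordinate sequences.

    Parameters
    ----------
    polylines
        Iterable of coordinate sequences (or shapely LineStrings) in a
        projected CRS with meter units.
    node_snap_tolerance
        Endpoints within this distance are merged into a single node.
    require_projected
        If True, coordinates that all fit in the lon/lat envelope are
        rejected (degrees are not meters).
    """
    if node_snap_tolerance < 0:
        raise ValueError("node_snap_tolerance must be >= 0")
    geoms: list[LineString] = []
    for pl in polylines:
        geom = pl if isinstance(pl, LineString) else LineString(pl)
        coords = np.asarray(geom.coords, dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("polyline contains non-finite coordinates")
        if geom.length == 0:
            raise ValueError("zero-length polyline")
        geoms.append(geom)
    if not geoms:
        raise ValueError("no polylines supplied")

    endpoints = np.array(
        [c for g in geoms for c in (g.coords[0], g.coords[-1])], dtype=float
    )
    if require_projected and _looks_geographic(endpoints):
        raise ValueError(
            "coordinates look geographic (lon/lat); reproject to a metric CRS "
            "or pass require_projected=False"
        )

    # merge endpoints within tolerance: union-find over close pairs, the
    # representative (lowest input index) supplies the node coordinate
    parent = np.arange(len(endpoints))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # tolerance 0 still merges exactly-coincident endpoints
    merge_radius = max(node_snap_tolerance, 1e-9)
    tree = cKDTree(endpoints)
    for i, j in tree.query_pairs(merge_radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            lo, hi = min(ri, rj), max(ri, rj)
            parent[hi] = lo
    roots = np.array([find(i) for i in range(len(endpoints))])
    uniq, node_of_endpoint = np.unique(roots, return_inverse=True)
    node_coords = endpoints[uniq]

    edge_endpoints = []
    edge_geoms = []
    edge_lengths = []
    n_dropped_loops = 0
    for e, g in enumerate(geoms):
        a = int(node_of_endpoint[2 * e])
        b = int(node_of_endpoint[2 * e + 1])
        if a == b and g.length <= node_snap_tolerance:
            n_dropped_loops += 1  # degenerate self-loop created by snapping
            continue
        edge_endpoints.append((a, b))
        edge_geoms.append(g)
        edge_lengths.append(g.length)
    if not edge_geoms:
        raise ValueError("all polylines degenerate after endpoint merging")
    if n_dropped_loops:
        logger.info("dropped %d degenerate self-loop(s)", n_dropped_loops)
    net = RoadNetwork(
        node_coords=node_coords,
        edge_endpoints=np.asarray(edge_endpoints, dtype=np.int64),
        edge_geometries=edge_geoms,
        edge_lengths=np.asarray(edge_lengths, dtype=float),
    )
    logger.info(
        "built network: %d nodes, %d edges, %.1f m total",
        net.n_nodes,
        net.n_edges,
        net.total_length,
    )
    return net


def largest_component(network: RoadNetwork) -> RoadNetwork:
    """Connected subnetwork of maximal total edge length.

    Ties are broken toward the component containing the lowest node id.
    The removed length is recorded on the result as ``dropped_length``.
    """
    if network.n_edges == 0:
        raise ValueError("empty network")
    g = network.to_graph()
    components = [sorted(c) for c in nx.connected_components(g)]
    node_comp = np.empty(network.n_nodes, dtype=np.int64)
    for ci, comp in enumerate(components):
        node_comp[comp] = ci
    comp_len = np.zeros(len(components))
    np.add.at(comp_len, node_comp[network.edge_endpoints[:, 0]], network.edge_lengths)
    # tie-break: among components of maximal length, lowest node id wins
    min_node = [min(c) for c in components]
    best = max(
        range(len(components)), key=lambda ci: (comp_len[ci], -min_node[ci])
    )
    keep_nodes = np.flatnonzero(node_comp == best)
    remap = -np.ones(network.n_nodes, dtype=np.int64)
    remap[keep_nodes] = np.arange(len(keep_nodes))
    edge_mask = node_comp[network.edge_endpoints[:, 0]] == best
    dropped = float(network.edge_lengths[~edge_mask].sum())
    sub = RoadNetwork(
        node_coords=network.node_coords[keep_nodes],
        edge_endpoints=remap[network.edge_endpoints[edge_mask]],
        edge_geometries=[
            g for g, m in zip(network.edge_geometries, edge_mask) if m
        ],
        edge_lengths=network.edge_lengths[edge_mask],
        dropped_length=dropped,
    )
    if dropped:
        logger.info("largest_component dropped %.1f m of network", dropped)
    return sub


def snap_to_network(
    network: RoadNetwork,
    coordinates: np.ndarray,
    weights: Sequence[float] | None = None,
    labels: Sequence[str] | None = None,
    max_snap_distance: float = DEFAULT_MAX_SNAP_DISTANCE,
) -> tuple[NetworkPointSet, SnapReport]:
    """Project planar points onto their nearest network edge.

    Each point becomes a linear reference ``(edge, offset)`` on the closest
    edge (perpendicular or endpoint projection). Points farther than
    ``max_snap_distance`` from every edge are excluded, not errors: the
    count is in the returned :class:`SnapReport`. Equidistant candidates
    (within 1e-9 m) resolve to the lowest edge id for determinism.
    """
    if max_snap_distance <= 0:
        raise ValueError("max_snap_distance must be > 0")
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    n = len(coords)
    tree = network.edge_tree()
    edge_ids = []
    offsets = []
    snap_d = []
    kept = []
    for i, (x, y) in enumerate(coords):
        pt = Point(x, y)
        nearest_idx = tree.nearest(pt)
        d0 = pt.distance(network.edge_geometries[nearest_idx])
        if d0 > max_snap_distance:
            continue
        # gather all edges tied with the nearest within 1e-9 m
        cand = tree.query(pt.buffer(d0 + 1e-9).envelope)
        best_e, best_d = None, np.inf
        for e in sorted(int(c) for c in cand):
            d = pt.distance(network.edge_geometries[e])
            if d < best_d - 1e-9:
                best_e, best_d = e, d
        geom = network.edge_geometries[best_e]
        off = float(np.clip(geom.project(pt), 0.0, network.edge_lengths[best_e]))
        edge_ids.append(best_e)
        offsets.append(off)
        snap_d.append(best_d)
        kept.append(i)
    kept = np.asarray(kept, dtype=np.int64)
    excluded = np.setdiff1d(np.arange(n), kept)
    points = NetworkPointSet(
        network,
        edge_ids,
        offsets,
        None if weights is None else np.asarray(weights, dtype=float)[kept],
        None if labels is None else [labels[i] for i in kept],
        coords[kept] if len(kept) else np.empty((0, 2)),
        snap_d,
    )
    report = SnapReport(
        n_input=n,
        n_snapped=len(kept),
        n_excluded=len(excluded),
        excluded_indices=excluded,
        max_snap_distance=max_snap_distance,
    )
    if report.n_excluded:
        warnings.warn(
            f"{report.n_excluded} point(s) farther than {max_snap_distance} m "
            "from the network were excluded",
            stacklevel=2,
        )
    return points, report


def lixelize(network: RoadNetwork, lixel_length: float) -> LixelSet:
    """Split every edge into ``ceil(length / lixel_length)`` equal lixels.

    The ceil rule guarantees no lixel exceeds the nominal resolution while
    conserving total length exactly.
    """
    if lixel_length <= 0:
        raise ValueError("lixel_length must be > 0")
    counts = np.ceil(network.edge_lengths / lixel_length).astype(np.int64)
    counts = np.maximum(counts, 1)
    edge_ids = np.repeat(np.arange(network.n_edges), counts)
    within = np.concatenate([np.arange(c) for c in counts])
    sub_len = np.repeat(network.edge_lengths / counts, counts)
    start = within * sub_len
    end = start + sub_len
    # snap the final lixel end to the exact edge length
    last = np.cumsum(counts) - 1
    end[last] = network.edge_lengths
    return LixelSet(network, edge_ids, start, end)


def point_distance_matrix(
    network: RoadNetwork,
    set_a: NetworkPointSet,
    set_b: NetworkPointSet,
) -> np.ndarray:
    """Exact network distances between two point sets, shape (len_a, len_b).

    A shortest path between interior points either stays on a shared edge or
    exits/enters through edge endpoints; the distance is therefore the
    minimum over the four endpoint routings and, on a shared edge, the
    direct along-edge path. Node-to-node distances come from the cached
    all-pairs matrix, so repeated calls (Monte Carlo simulation) are cheap.
    """
    if set_a.network is not network or set_b.network is not network:
        raise ValueError("point sets must reference the given network")
    D = network.node_distance_matrix()
    ends = network.edge_endpoints
    lens = network.edge_lengths
    ea, eb = set_a.edge_ids, set_b.edge_ids
    a0, a1 = ends[ea, 0], ends[ea, 1]
    b0, b1 = ends[eb, 0], ends[eb, 1]
    oa, ob = set_a.offsets, set_b.offsets
    ra, rb = lens[ea] - oa, lens[eb] - ob
    d = D[a0[:, None], b0[None, :]] + oa[:, None] + ob[None, :]
    np.minimum(d, D[a0[:, None], b1[None, :]] + oa[:, None] + rb[None, :], out=d)
    np.minimum(d, D[a1[:, None], b0[None, :]] + ra[:, None] + ob[None, :], out=d)
    np.minimum(d, D[a1[:, None], b1[None, :]] + ra[:, None] + rb[None, :], out=d)
    same = ea[:, None] == eb[None, :]
    if np.any(same):
        direct = np.abs(oa[:, None] - ob[None, :])
        d = np.where(same, np.minimum(d, direct), d)
    return d


def network_distance(
    network: RoadNetwork,
    source: NetworkPoint,
    targets: NetworkPointSet | LixelSet,
    cutoff: float | None = None,
) -> dict[int, float]:
    """Shortest-path distance from one source to many targets.

    Targets beyond ``cutoff`` (if given) are omitted from the result.
    """
    if source.edge_id < 0 or source.edge_id >= network.n_edges:
        raise ValueError("source references an edge absent from the network")
    if cutoff is not None and cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    tset = targets.centers if isinstance(targets, LixelSet) else targets
    src = NetworkPointSet(network, [source.edge_id], [source.offset])
    row = point_distance_matrix(network, src, tset)[0]
    out = {}
    for i, dist in enumerate(row):
        if np.isfinite(dist) and (cutoff is None or dist <= cutoff):
            out[i] = float(dist)
    return out


def clip_network(
    network: RoadNetwork,
    polygon: Polygon | MultiPolygon,
    node_snap_tolerance: float = 1e-6,
) -> RoadNetwork:
    """Clip the network to a polygon, keeping split edge fragments.

    Boundary-crossing edges are cut at the polygon boundary and the inside
    pieces retained as new edges; the clipped network may be disconnected.
    """
    pieces: list[LineString] = []
    for e in network.edge_tree().query(polygon):
        inter = network.edge_geometries[int(e)].intersection(polygon)
        if inter.is_empty:
            continue
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            if isinstance(g, LineString) and g.length > node_snap_tolerance:
                pieces.append(g)
    if not pieces:
        raise ValueError("polygon does not intersect the network")
    return build_network(
        pieces, node_snap_tolerance=node_snap_tolerance, require_projected=False
    )
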