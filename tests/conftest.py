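"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's vectorized distance
machinery: network distances are recomputed with networkx Dijkstra (or full
simple-path enumeration on tiny graphs) on an explicitly augmented graph
with one temporary node per on-network point, and Jenks classifications are
checked against exhaustive enumeration of all ordered partitions.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from netpatterns import NetworkPointSet, RoadNetwork, build_network


# ---------------------------------------------------------------- fixtures
@pytest.fixture
def square_net() -> RoadNetwork:
    """Unit square of side 100 m: 4 nodes, 4 edges, 400 m total."""
    return build_network(
        [
            [(0, 0), (100, 0)],
            [(100, 0), (100, 100)],
            [(100, 100), (0, 100)],
            [(0, 100), (0, 0)],
        ]
    )


def make_grid(n: int = 5, spacing: float = 100.0) -> RoadNetwork:
    polylines = []
    for r in range(n):
        for c in range(n):
            x, y = c * spacing, r * spacing
            if c + 1 < n:
                polylines.append([(x, y), (x + spacing, y)])
            if r + 1 < n:
                polylines.append([(x, y), (x, y + spacing)])
    return build_network(polylines)


@pytest.fixture
def grid5() -> RoadNetwork:
    return make_grid(5, 100.0)


def random_network(rng: np.random.Generator, n: int = 5) -> RoadNetwork:
    """Random connected jittered grid for property tests."""
    from netpatterns import largest_component

    polylines = []
    coords = {}
    for r in range(n):
        for c in range(n):
            coords[(r, c)] = (
                c * 100.0 + rng.uniform(-20, 20),
                r * 100.0 + rng.uniform(-20, 20),
            )
    for r in range(n):
        for c in range(n):
            if c + 1 < n and rng.uniform() < 0.9:
                polylines.append([coords[(r, c)], coords[(r, c + 1)]])
            if r + 1 < n and rng.uniform() < 0.9:
                polylines.append([coords[(r, c)], coords[(r + 1, c)]])
    return largest_component(build_network(polylines))


def random_points(
    net: RoadNetwork, n: int, rng: np.random.Generator
) -> NetworkPointSet:
    edges = rng.integers(0, net.n_edges, n)
    offsets = rng.uniform(0, net.edge_lengths[edges])
    return NetworkPointSet(net, edges, offsets)


# ----------------------------------------------------------------- oracles
def augmented_graph(net: RoadNetwork, point_sets) -> tuple[nx.Graph, list[list]]:
    """Graph with a temporary node inserted for every on-network point.

    Each edge is split into a chain at the offsets of all points lying on
    it. Returns the graph and, per point set, the node name of each point.
    """
    g = nx.Graph()
    for v in range(net.n_nodes):
        g.add_node(("n", v))
    on_edge: dict[int, list] = {}
    names = []
    for si, pts in enumerate(point_sets):
        row = []
        for i in range(len(pts)):
            name = ("p", si, i)
            row.append(name)
            on_edge.setdefault(int(pts.edge_ids[i]), []).append(
                (float(pts.offsets[i]), name)
            )
        names.append(row)
    for e in range(net.n_edges):
        a, b = net.edge_endpoints[e]
        length = float(net.edge_lengths[e])
        chain = sorted(on_edge.get(e, []))
        prev_node, prev_off = ("n", int(a)), 0.0
        for off, name in chain:
            w = off - prev_off
            if g.has_edge(prev_node, name):
                w = min(w, g[prev_node][name]["weight"])
            g.add_edge(prev_node, name, weight=w)
            prev_node, prev_off = name, off
        w = length - prev_off
        end = ("n", int(b))
        if g.has_edge(prev_node, end):
            w = min(w, g[prev_node][end]["weight"])
        g.add_edge(prev_node, end, weight=w)
    return g, names


def oracle_distance_matrix(
    net: RoadNetwork, set_a: NetworkPointSet, set_b: NetworkPointSet
) -> np.ndarray:
    """All pairwise network distances via networkx Dijkstra on the
    augmented graph (independent of the package's matrix code path)."""
    g, (na, nb) = augmented_graph(net, [set_a, set_b])
    out = np.full((len(set_a), len(set_b)), np.inf)
    for i, src in enumerate(na):
        dist = nx.single_source_dijkstra_path_length(g, src, weight="weight")
        for j, tgt in enumerate(nb):
            if tgt in dist:
                out[i, j] = dist[tgt]
    return out


def enumerate_path_distance(
    net: RoadNetwork, point_a, point_b
) -> float:
    """Shortest path by exhaustive simple-path enumeration (tiny graphs)."""
    pa = NetworkPointSet(net, [point_a[0]], [point_a[1]])
    pb = NetworkPointSet(net, [point_b[0]], [point_b[1]])
    g, (na, nb) = augmented_graph(net, [pa, pb])
    best = np.inf
    for path in nx.all_simple_paths(g, na[0], nb[0]):
        w = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
        best = min(best, w)
    if na[0] == nb[0]:
        best = 0.0
    return best


def brute_force_kde(
    net: RoadNetwork, events: NetworkPointSet, r: float, centers: NetworkPointSet
) -> np.ndarray:
    """Exhaustive NetKDE: oracle distances + direct kernel formula."""
    dmat = oracle_distance_matrix(net, events, centers)
    lam = np.zeros(len(centers))
    for i in range(len(events)):
        for j in range(len(centers)):
            d = dmat[i, j]
            if d <= r:
                lam[j] += (
                    (1.0 / np.sqrt(2 * np.pi))
                    * np.exp(-(d**2) / (2 * r**2))
                    * events.weights[i]
                    / r
                )
    return lam


def brute_force_jenks_sse(values, k: int) -> float:
    """Minimal within-class SSE over all ordered partitions (n <= ~14)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def sse(seg):
        seg = np.asarray(seg)
        return float(((seg - seg.mean()) ** 2).sum())

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(sse(x[bounds[i]:bounds[i + 1]]) for i in range(k))
        best = min(best, total)
    return best


def jenks_sse_of_breaks(values, breaks) -> float:
    """Within-class SSE induced by ascending class maxima ``breaks``."""
    x = np.asarray(values, dtype=float)
    labels = np.searchsorted(np.asarray(breaks), x, side="left")
    total = 0.0
    for lab in np.unique(labels):
        seg = x[labels == lab]
        total += float(((seg - seg.mean()) ** 2).sum())
    return total
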