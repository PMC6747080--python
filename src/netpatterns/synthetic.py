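"""Synthetic city generator.

Produces a connected jittered-grid road network, community polygons with
hot-spot-structured populations, four facility tiers (hospitals weighted by
bed number; community health centers, clinics and pharmacies with fixed
tier weights 20 / 10 / 1), and patient points that are either uniform on
the network or clustered around facilities by a network-distance decay.

Every generator is deterministic under the config seed: each stage draws
from its own seeded stream, so regenerating any stage reproduces it
byte-for-byte. The default city is a scaled-down stand-in for a large
metropolitan road network (hundreds of facilities rather than thousands)
so the full pipeline runs in minutes on one CPU; counts keep the relative
proportions of the four facility tiers of a real hierarchical system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

from .aggregation import CommunityInputs
from .network import NetworkPointSet, RoadNetwork, build_network, largest_component

__all__ = [
    "CityConfig",
    "generate_network",
    "generate_communities",
    "generate_facilities",
    "generate_patients",
    "generate_city",
]

#: fixed non-spatial weights of the non-hospital tiers
TIER_WEIGHTS = {"chc": 20.0, "clinic": 10.0, "pharmacy": 1.0}


@dataclass
class CityConfig:
    """Parameters of the synthetic city (all lengths in meters)."""

    rows: int = 30
    cols: int = 30
    spacing: float = 400.0
    edge_keep_prob: float = 0.85
    node_jitter: float = 30.0
    community_cell_size: float = 1200.0
    # log-normal community population (log-scale mean/sd), boosted near
    # hot-spot centers to induce the population-facility association
    population_log_mean: float = 10.4
    population_log_sigma: float = 0.6
    hotspot_centers: tuple = ((0.3, 0.3), (0.65, 0.6))
    hotspot_amplitude: float = 3.0
    hotspot_decay: float = 2500.0
    # facility counts per tier (≈ 500 total, preserving tier proportions)
    n_hospitals: int = 20
    n_chc: int = 43
    n_clinics: int = 118
    n_pharmacies: int = 319
    n_tertiary_hospitals: int = 2  # hospitals with >= 1000 beds
    # 0 = facilities uniform on the network (CSR); 1 = fully
    # population-proportional placement
    population_coupling: float = 0.7
    n_patients: int = 2000
    clustering_decay: float = 200.0  # exponential decay length of patient
    # distance from their anchor facility
    background_fraction: float = 0.2  # patients placed CSR instead
    seed: int = 0

    def __post_init__(self):
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2x2")
        for name in ("edge_keep_prob", "population_coupling", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_hospitals", "n_chc", "n_clinics", "n_pharmacies",
                     "n_patients"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


def generate_network(config: CityConfig) -> RoadNetwork:
    """Jittered grid with random edge deletion, largest component kept."""
    rng = config.rng(0)
    rows, cols, s = config.rows, config.cols, config.spacing
    xs, ys = np.meshgrid(np.arange(cols) * s, np.arange(rows) * s)
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    coords += rng.uniform(-1.0, 1.0, coords.shape) * config.node_jitter

    def nid(r, c):
        return r * cols + c

    pairs = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                pairs.append((nid(r, c), nid(r, c + 1)))
            if r + 1 < rows:
                pairs.append((nid(r, c), nid(r + 1, c)))
    pairs = np.asarray(pairs)
    keep = rng.uniform(size=len(pairs)) < config.edge_keep_prob
    polylines = [
        (tuple(coords[a]), tuple(coords[b])) for a, b in pairs[keep]
    ]
    if not polylines:
        raise ValueError("edge_keep_prob removed every edge")
    net = build_network(polylines, node_snap_tolerance=0.0)
    return largest_component(net)


def generate_communities(config: CityConfig, network: RoadNetwork) -> CommunityInputs:
    """Square community tiling of the network extent with populations.

    Populations are log-normal draws multiplied by a Gaussian bump around
    each hot-spot center, emulating a dense urban core and sparser
    periphery.
    """
    if config.community_cell_size <= 0:
        raise ValueError("community_cell_size must be > 0")
    rng = config.rng(1)
    xmin, ymin, xmax, ymax = network.bounds
    cell = config.community_cell_size
    ncols = max(1, int(np.ceil((xmax - xmin) / cell)))
    nrows = max(1, int(np.ceil((ymax - ymin) / cell)))
    polygons, centers = [], []
    for r in range(nrows):
        for c in range(ncols):
            x0, y0 = xmin + c * cell, ymin + r * cell
            polygons.append(box(x0, y0, x0 + cell, y0 + cell))
            centers.append((x0 + cell / 2, y0 + cell / 2))
    centers = np.asarray(centers)
    base = rng.lognormal(config.population_log_mean, config.population_log_sigma,
                         len(polygons))
    boost = np.ones(len(polygons))
    extent = np.array([xmax - xmin, ymax - ymin])
    for fx, fy in config.hotspot_centers:
        hx, hy = xmin + fx * extent[0], ymin + fy * extent[1]
        d2 = (centers[:, 0] - hx) ** 2 + (centers[:, 1] - hy) ** 2
        boost += config.hotspot_amplitude * np.exp(
            -d2 / (2.0 * config.hotspot_decay**2)
        )
    return CommunityInputs(polygons=polygons, population=base * boost)


def _edge_population_factor(
    config: CityConfig, network: RoadNetwork, communities: CommunityInputs
) -> np.ndarray:
    """Population-density multiplier per edge (mean 1), from the community
    containing the edge midpoint."""
    dens = communities.population / np.array(
        [p.area for p in communities.polygons]
    )
    from shapely.geometry import Point
    from shapely.strtree import STRtree

    tree = STRtree(communities.polygons)
    factor = np.ones(network.n_edges)
    for e in range(network.n_edges):
        mid = network.edge_geometries[e].interpolate(0.5, normalized=True)
        hits = tree.query(Point(mid.x, mid.y))
        if len(hits):
            factor[e] = dens[int(hits[0])]
        else:  # midpoint off the tiling (jitter): nearest community
            factor[e] = dens[int(tree.nearest(Point(mid.x, mid.y)))]
    return factor / factor.mean()


def _sample_on_network(
    network: RoadNetwork, n: int, edge_weight: np.ndarray, rng
) -> tuple[np.ndarray, np.ndarray]:
    probs = edge_weight / edge_weight.sum()
    edges = rng.choice(network.n_edges, size=n, p=probs)
    offsets = rng.uniform(0.0, network.edge_lengths[edges]) if n else np.empty(0)
    return edges, offsets


def generate_facilities(
    config: CityConfig, network: RoadNetwork, communities: CommunityInputs
) -> dict[str, NetworkPointSet]:
    """Sample the four facility tiers on the network.

    Edge selection mixes a length-uniform component with a
    population-proportional one (weight ``population_coupling``); hospitals
    draw bed numbers from a two-part mixture with ``n_tertiary_hospitals``
    large (>= 1000 bed) facilities.
    """
    rng = config.rng(2)
    pop_factor = _edge_population_factor(config, network, communities)
    c = config.population_coupling
    edge_weight = network.edge_lengths * ((1.0 - c) + c * pop_factor)
    counts = {
        "hospital": config.n_hospitals,
        "chc": config.n_chc,
        "clinic": config.n_clinics,
        "pharmacy": config.n_pharmacies,
    }
    out = {}
    for label, n in counts.items():
        edges, offsets = _sample_on_network(network, n, edge_weight, rng)
        if label == "hospital":
            n_big = min(config.n_tertiary_hospitals, n)
            beds = np.empty(n)
            beds[:n_big] = 1000.0 + rng.exponential(400.0, n_big)
            small = rng.lognormal(np.log(150.0), 0.5, n - n_big)
            beds[n_big:] = np.clip(small, 20.0, 999.0)
            if c > 0 and n:
                # tertiary hospitals sit in the dense urban core: hand the
                # largest bed counts to the highest-density locations
                rank = np.argsort(-pop_factor[edges], kind="stable")
                reorder = np.empty(n, dtype=np.int64)
                reorder[rank] = np.arange(n)
                beds = np.sort(beds)[::-1][reorder]
            weights = np.round(beds)
        else:
            weights = np.full(n, TIER_WEIGHTS[label])
        out[label] = NetworkPointSet(network, edges, offsets, weights,
                                     [label] * n)
    return out


def _adjacency(network: RoadNetwork) -> list[list[tuple[int, int]]]:
    adj: list[list[tuple[int, int]]] = [[] for _ in range(network.n_nodes)]
    for e, (a, b) in enumerate(network.edge_endpoints):
        adj[int(a)].append((e, int(b)))
        adj[int(b)].append((e, int(a)))
    return adj


def _walk(network, adj, edge, offset, dist, rng, max_hops=10_000):
    """Travel ``dist`` meters along the network from (edge, offset) in a
    random direction, turning uniformly at intersections."""
    a, b = network.edge_endpoints[edge]
    toward = int(b) if rng.uniform() < 0.5 else int(a)
    remaining = float(dist)
    for _ in range(max_hops):
        length = float(network.edge_lengths[edge])
        to_end = (length - offset) if toward == network.edge_endpoints[edge][1] else offset
        if remaining <= to_end:
            if toward == network.edge_endpoints[edge][1]:
                return edge, offset + remaining
            return edge, offset - remaining
        remaining -= to_end
        node = toward
        choices = adj[node]
        edge, other = choices[rng.integers(len(choices))]
        toward = other
        offset = (
            0.0 if node == int(network.edge_endpoints[edge][0]) else
            float(network.edge_lengths[edge])
        )
        if int(network.edge_endpoints[edge][0]) == int(network.edge_endpoints[edge][1]):
            # loop edge: enter at node 0 moving toward the far end
            offset, toward = 0.0, int(network.edge_endpoints[edge][1])
    return edge, offset


def generate_patients(
    config: CityConfig,
    network: RoadNetwork,
    facilities: dict[str, NetworkPointSet] | NetworkPointSet,
) -> NetworkPointSet:
    """Patient locations: background-uniform or clustered around facilities.

    With probability ``background_fraction`` a patient is CSR on the
    network; otherwise it starts at a uniformly chosen facility and travels
    a network distance drawn from an exponential with mean
    ``clustering_decay`` in a random direction along the network, so the
    clustering signal is purely network-structured.
    """
    rng = config.rng(3)
    n = config.n_patients
    if config.background_fraction < 1.0 and config.clustering_decay <= 0:
        raise ValueError("clustering_decay must be > 0 when clustering is on")
    if isinstance(facilities, dict):
        fac_edges = np.concatenate([f.edge_ids for f in facilities.values()])
        fac_offsets = np.concatenate([f.offsets for f in facilities.values()])
    else:
        fac_edges, fac_offsets = facilities.edge_ids, facilities.offsets
    if len(fac_edges) == 0 and config.background_fraction < 1.0:
        raise ValueError("clustered patients require at least one facility")
    adj = _adjacency(network)
    probs = network.edge_lengths / network.total_length
    edges = np.empty(n, dtype=np.int64)
    offsets = np.empty(n)
    for i in range(n):
        if rng.uniform() < config.background_fraction:
            e = rng.choice(network.n_edges, p=probs)
            edges[i] = e
            offsets[i] = rng.uniform(0.0, network.edge_lengths[e])
        else:
            f = rng.integers(len(fac_edges))
            d = rng.exponential(config.clustering_decay)
            edges[i], offsets[i] = _walk(
                network, adj, int(fac_edges[f]), float(fac_offsets[f]), d, rng
            )
    return NetworkPointSet(network, edges, offsets, labels=["patient"] * n)


def generate_city(config: CityConfig):
    """Run all four generators; returns (network, communities, facilities,
    patients)."""
    net = generate_network(config)
    communities = generate_communities(config, net)
    facilities = generate_facilities(config, net, communities)
    patients = generate_patients(config, net, facilities)
    return net, communities, facilities, patients
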