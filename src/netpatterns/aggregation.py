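"""Community-level covariate construction.

Aggregates the road network and NetKDE fields over community polygons into
the analysis table the geodetector consumes: per community, area, population
density (per km²), road length and road density (m per km²), and the sum of
NetKDE values per facility type. Aggregation works on the network lixels
apportioned by length (not raster cells), which avoids raster-resolution
artifacts; a raster-based route can be had by rasterizing first and summing
cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon
from shapely.strtree import STRtree

from .netkde import DensityField
from .network import RoadNetwork

__all__ = [
    "road_length_by_polygon",
    "aggregate_density",
    "community_table",
    "check_no_overlap",
]


def _validate_polygons(polygons: Sequence) -> None:
    for i, poly in enumerate(polygons):
        if not isinstance(poly, (Polygon, MultiPolygon)) or not poly.is_valid:
            raise ValueError(f"invalid polygon at index {i}")


def check_no_overlap(polygons: Sequence, area_tol: float = 1e-6) -> None:
    """Reject overlapping community polygons (shared boundaries are fine)."""
    tree = STRtree(list(polygons))
    for i, poly in enumerate(polygons):
        for j in tree.query(poly):
            j = int(j)
            if j <= i:
                continue
            inter = poly.intersection(polygons[j])
            if inter.area > area_tol:
                raise ValueError(f"polygons {i} and {j} overlap")


def road_length_by_polygon(
    network: RoadNetwork, polygons: Sequence
) -> np.ndarray:
    """Road length (meters) inside each polygon.

    Boundary-crossing edges are split geometrically and apportioned, so the
    lengths over a polygon partition of the extent sum to the network total.
    """
    _validate_polygons(polygons)
    tree = network.edge_tree()
    out = np.zeros(len(polygons))
    for p, poly in enumerate(polygons):
        total = 0.0
        for e in tree.query(poly):
            total += network.edge_geometries[int(e)].intersection(poly).length
        out[p] = total
    return out


def aggregate_density(field: DensityField, polygons: Sequence) -> np.ndarray:
    """Sum of per-lixel NetKDE values inside each polygon.

    A lixel crossing a boundary contributes its value times the fraction of
    its length inside the polygon, so partition sums are conserved.
    """
    _validate_polygons(polygons)
    lix_geoms = field.lixels.geometries()
    lengths = field.lixels.lengths
    tree = STRtree(lix_geoms)
    out = np.zeros(len(polygons))
    for p, poly in enumerate(polygons):
        total = 0.0
        for li in tree.query(poly):
            li = int(li)
            if lengths[li] <= 0:
                continue
            part = lix_geoms[li].intersection(poly).length
            if part > 0:
                total += field.values[li] * part / lengths[li]
        out[p] = total
    return out


@dataclass
class CommunityInputs:
    """Polygons plus population counts, the raw community layer."""

    polygons: list
    population: np.ndarray
    ids: list | None = None

    def __post_init__(self):
        self.population = np.asarray(self.population, dtype=float)
        if len(self.population) != len(self.polygons):
            raise ValueError("one population count per polygon required")
        if self.ids is None:
            self.ids = list(range(len(self.polygons)))


def community_table(
    communities: CommunityInputs,
    network: RoadNetwork,
    fields: Mapping[str, DensityField],
) -> pd.DataFrame:
    """Analysis-ready community table for the geodetector.

    Columns: area_km2, population, pop_density (per km²), road_length_m,
    road_density (m per km²), one ``agg_<label>`` column per density field,
    and ``agg_total`` (their sum).
    """
    _validate_polygons(communities.polygons)
    check_no_overlap(communities.polygons)
    missing = [
        communities.ids[i]
        for i in range(len(communities.polygons))
        if not np.isfinite(communities.population[i]) or communities.population[i] < 0
    ]
    if missing:
        raise ValueError(f"missing or negative population for communities {missing}")
    area_km2 = np.array([p.area for p in communities.polygons]) / 1e6
    if np.any(area_km2 <= 0):
        raise ValueError("every community polygon must have positive area")
    road_len = road_length_by_polygon(network, communities.polygons)
    df = pd.DataFrame(
        {
            "community_id": communities.ids,
            "area_km2": area_km2,
            "population": communities.population,
            "pop_density": communities.population / area_km2,
            "road_length_m": road_len,
            "road_density": road_len / area_km2,
        }
    )
    total = np.zeros(len(communities.polygons))
    for label, fld in fields.items():
        agg = aggregate_density(fld, communities.polygons)
        df[f"agg_{label}"] = agg
        total += agg
    df["agg_total"] = total
    return df
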