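"""GeoJSON / CSV readers and writers.

All vector exchange uses GeoJSON FeatureCollections (parsed with shapely);
coordinates are expected in a projected CRS with meter units — the readers
apply the same lon/lat heuristic guard as :func:`~netpatterns.network.build_network`.
Rasters are written as ESRI ASCII grids (see
:meth:`~netpatterns.netkde.DensityGrid.to_ascii`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .netkde import DensityField
from .network import NetworkPointSet, SnapReport
from .kfunction import KEnvelope, KResult, PatternLabel

__all__ = [
    "read_geojson",
    "read_polylines",
    "read_points",
    "read_polygons",
    "write_geojson",
    "write_point_set",
    "write_density_field",
    "write_k_result",
]


def read_geojson(path) -> list[tuple]:
    """Read a GeoJSON FeatureCollection; returns (geometry, properties) pairs."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return [
        (shape(f["geometry"]), f.get("properties") or {})
        for f in data["features"]
        if f.get("geometry")
    ]


def read_polylines(path) -> list:
    """Road centerlines: LineString / MultiLineString features."""
    lines = []
    for geom, _ in read_geojson(path):
        if geom.geom_type == "LineString":
            lines.append(geom)
        elif geom.geom_type == "MultiLineString":
            lines.extend(geom.geoms)
        else:
            raise ValueError(f"unexpected geometry type {geom.geom_type} in {path}")
    return lines


def read_points(path, weight_field: str | None = None, label_field: str | None = None):
    """Point features; returns (coords (n,2), weights, labels)."""
    coords, weights, labels = [], [], []
    for geom, props in read_geojson(path):
        if geom.geom_type != "Point":
            raise ValueError(f"unexpected geometry type {geom.geom_type} in {path}")
        coords.append((geom.x, geom.y))
        weights.append(float(props.get(weight_field, 1.0)) if weight_field else 1.0)
        labels.append(str(props[label_field]) if label_field and label_field in props
                      else None)
    return np.asarray(coords, dtype=float), np.asarray(weights), labels


def read_polygons(path, fields: list[str] | None = None):
    """Polygon features; returns (polygons, DataFrame of requested fields)."""
    polys, rows = [], []
    for geom, props in read_geojson(path):
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"unexpected geometry type {geom.geom_type} in {path}")
        polys.append(geom)
        rows.append({f: props.get(f) for f in (fields or [])})
    return polys, pd.DataFrame(rows)


def write_geojson(path, geometries, properties=None) -> None:
    props = properties if properties is not None else [{}] * len(geometries)
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, props)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_point_set(
    points: NetworkPointSet, path_geojson, path_csv=None, report: SnapReport | None = None
) -> None:
    """Write a snapped point set as GeoJSON (+ optional CSV incl. snap report)."""
    from shapely.geometry import Point

    coords = points.coordinates()
    props = [
        {
            "edge_id": int(points.edge_ids[i]),
            "offset_m": float(points.offsets[i]),
            "weight": float(points.weights[i]),
            "label": points.labels[i],
            "snap_distance_m": float(points.snap_distances[i]),
        }
        for i in range(len(points))
    ]
    write_geojson(path_geojson, [Point(*c) for c in coords], props)
    if path_csv is not None:
        df = pd.DataFrame(props)
        df.insert(0, "y", coords[:, 1] if len(points) else [])
        df.insert(0, "x", coords[:, 0] if len(points) else [])
        if report is not None:
            df.attrs["snap_report"] = vars(report)
        df.to_csv(path_csv, index=False)


def write_density_field(field: DensityField, path_geojson, path_csv) -> None:
    """Per-lixel intensity as GeoJSON lines and a (lixel_id, lambda) CSV."""
    geoms = field.lixels.geometries()
    props = [
        {"lixel_id": i, "lambda": float(v)} for i, v in enumerate(field.values)
    ]
    write_geojson(path_geojson, geoms, props)
    pd.DataFrame(props).to_csv(path_csv, index=False)


def write_k_result(
    path_csv,
    observed: KResult,
    env: KEnvelope | None = None,
    label: PatternLabel | None = None,
) -> None:
    """K-curve (+ envelope and per-t pattern label) as CSV."""
    df = pd.DataFrame({"t": observed.t_grid, "K_obs": observed.k})
    if env is not None:
        df["K_mean"] = env.mean
        df["K_lower"] = env.lower
        df["K_upper"] = env.upper
    if label is not None:
        df["label"] = label.labels
    Path(path_csv).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path_csv, index=False)
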