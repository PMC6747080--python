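"""One-command reproduction of the full analysis workflow.

Stages: NetKDE per facility type -> community aggregation -> geodetector
q-statistics and two-factor interaction -> auto-K per facility type and
cross-K of facilities vs patients (city-wide or per district) with Monte
Carlo CSR envelopes -> report bundle (CSVs, ASCII grids, GeoJSON, PNG
plots, JSON summary). Every default applied is logged so a run can be
audited; stage failures halt with a stage-named error and partial outputs
are kept on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import io as npio
from .aggregation import CommunityInputs, community_table
from .geodetector import interaction, jenks_breaks, permutation_p, q_statistic, stratify
from .kfunction import auto_k, classify_pattern, cross_k, envelope
from .netkde import (
    DEFAULT_BANDWIDTHS,
    classify_density,
    estimate_density,
    rasterize_density,
)
from .network import (
    NetworkPointSet,
    RoadNetwork,
    clip_network,
    lixelize,
    snap_to_network,
)
from .plotting import plot_k_envelope

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "run_pipeline", "run_from_files"]


@dataclass
class PipelineParams:
    """Tunable settings of the pipeline (defaults match the analysis design:
    1000 m hospital bandwidth, 500 m for the primary-care tiers, 100 m lixels
    and raster cells, K range up to 10 km, 5 Jenks classes, alpha 0.05)."""

    bandwidths: dict = dc_field(default_factory=lambda: dict(DEFAULT_BANDWIDTHS))
    default_bandwidth: float = 500.0
    lixel_length: float = 100.0
    cell_size: float = 100.0
    t_max: float = 10_000.0
    n_t_steps: int = 50
    n_sims: int = 200
    alpha: float = 0.05
    n_classes: int = 5
    n_perm: int = 999
    seed: int = 0
    min_points_for_k: int = 5  # skip K analyses of sparser sets

    def t_grid(self, network: RoadNetwork) -> np.ndarray:
        tmax = min(self.t_max, 0.5 * network.diameter())
        return np.linspace(0.0, tmax, self.n_t_steps)


def _k_analyses(
    network: RoadNetwork,
    facilities: dict[str, NetworkPointSet],
    patients: NetworkPointSet | None,
    params: PipelineParams,
    outdir: Path,
    tag: str,
    rng: np.random.Generator,
) -> dict:
    t_grid = params.t_grid(network)
    summary = {}
    for label, pts in facilities.items():
        if len(pts) < params.min_points_for_k:
            summary[label] = {"auto": "skipped (too few points)"}
            continue
        obs = auto_k(network, pts, t_grid)
        env = envelope(network, len(pts), t_grid, params.n_sims, params.alpha,
                       rng, mode="auto")
        lab = classify_pattern(obs, env)
        stem = outdir / f"autok_{tag}_{label}"
        npio.write_k_result(f"{stem}.csv", obs, env, lab)
        plot_k_envelope(obs, env, f"{stem}.png", f"auto-K {label} ({tag})")
        entry = {"auto": lab.summary}
        if patients is not None and len(patients) >= params.min_points_for_k:
            obs_x = cross_k(network, pts, patients, t_grid)
            env_x = envelope(network, len(patients), t_grid, params.n_sims,
                             params.alpha, rng, mode="cross", base=pts)
            lab_x = classify_pattern(obs_x, env_x)
            stem = outdir / f"crossk_{tag}_{label}_patients"
            npio.write_k_result(f"{stem}.csv", obs_x, env_x, lab_x)
            plot_k_envelope(obs_x, env_x, f"{stem}.png",
                            f"cross-K {label} vs patients ({tag})")
            entry["cross_patients"] = lab_x.summary
        summary[label] = entry
    return summary


def _clip_points(
    points: NetworkPointSet, clipped: RoadNetwork, polygon
) -> NetworkPointSet:
    coords = points.coordinates()
    from shapely.geometry import Point

    inside = np.array([polygon.covers(Point(*c)) for c in coords])
    if not inside.any():
        return NetworkPointSet(clipped, [], [], [], [])
    sub = points.subset(inside)
    snapped, _ = snap_to_network(clipped, coords[inside], sub.weights, sub.labels,
                                 max_snap_distance=1.0)
    return snapped


def run_pipeline(
    network: RoadNetwork,
    facilities: dict[str, NetworkPointSet],
    patients: NetworkPointSet | None,
    communities: CommunityInputs | None,
    outdir,
    params: PipelineParams | None = None,
    districts: dict[str, object] | None = None,
) -> dict:
    """Run the full workflow and write the report bundle into ``outdir``.

    Returns the machine-readable summary (also written as summary.json):
    per-district x facility-type pattern labels, geodetector q values and
    the interaction category.
    """
    params = params or PipelineParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    summary: dict = {"params": {
        "bandwidths": params.bandwidths,
        "lixel_length": params.lixel_length,
        "cell_size": params.cell_size,
        "t_max": params.t_max,
        "n_sims": params.n_sims,
        "alpha": params.alpha,
        "n_classes": params.n_classes,
        "seed": params.seed,
    }}

    # --- stage 1: NetKDE per facility type -------------------------------
    try:
        lixels = lixelize(network, params.lixel_length)
        fields = {}
        for label, pts in facilities.items():
            bw = params.bandwidths.get(label, params.default_bandwidth)
            logger.info("NetKDE %s: %d events, bandwidth %.0f m", label, len(pts), bw)
            fld = estimate_density(network, pts, bw, lixels)
            fields[label] = fld
            npio.write_density_field(fld, outdir / f"density_{label}.geojson",
                                     outdir / f"density_{label}.csv")
            grid = rasterize_density(fld, params.cell_size)
            grid.to_ascii(outdir / f"density_{label}.asc")
            breaks, _ = classify_density(fld, params.n_classes)
            summary.setdefault("density", {})[label] = {
                "bandwidth_m": bw,
                "max_lambda": float(fld.values.max()) if len(fld.values) else 0.0,
                "jenks_class_maxima": [float(b) for b in breaks],
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'netkde' failed: {exc}") from exc

    # --- stage 2: community aggregation + geodetector --------------------
    if communities is not None:
        try:
            table = community_table(communities, network, fields)
            table.to_csv(outdir / "communities.csv", index=False)
            y = table["agg_total"].to_numpy()
            geo: dict = {}
            strata = {}
            for factor in ("pop_density", "road_density"):
                s = stratify(
                    table[factor].to_numpy(),
                    jenks_breaks(table[factor].to_numpy(), params.n_classes),
                )
                strata[factor] = s
                qr = q_statistic(y, s)
                p = permutation_p(y, s, params.n_perm,
                                  rng.integers(2**31 - 1))
                geo[factor] = {"q": qr.q, "p_permutation": p,
                               "p_method": "label permutation"}
            inter = interaction(y, strata["pop_density"], strata["road_density"])
            geo["interaction"] = {
                "q_pop": inter.q_a,
                "q_road": inter.q_b,
                "q_intersection": inter.q_ab,
                "category": inter.category,
                "comparison": inter.comparison,
            }
            summary["geodetector"] = geo
            with open(outdir / "geodetector.json", "w") as fh:
                json.dump(geo, fh, indent=2)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'geodetector' failed: {exc}") from exc

    # --- stage 3: K-function analyses ------------------------------------
    try:
        kdir = outdir / "kfunctions"
        kdir.mkdir(exist_ok=True)
        patterns = {"citywide": _k_analyses(network, facilities, patients,
                                            params, kdir, "citywide", rng)}
        if districts:
            for name, poly in districts.items():
                sub_net = clip_network(network, poly)
                sub_fac = {lbl: _clip_points(pts, sub_net, poly)
                           for lbl, pts in facilities.items()}
                sub_pat = (_clip_points(patients, sub_net, poly)
                           if patients is not None else None)
                patterns[name] = _k_analyses(sub_net, sub_fac, sub_pat,
                                             params, kdir, name, rng)
        summary["patterns"] = patterns
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'kfunction' failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def run_from_files(config: dict | str, outdir=None) -> dict:
    """File-based entry point: load a YAML/JSON config (or dict) of paths.

    Expected keys: roads (GeoJSON lines), facilities (GeoJSON points with a
    label field and optional weight field), optional patients, communities
    (polygons with a population field), districts (polygons with a name
    field), and any :class:`PipelineParams` field.
    """
    import yaml

    from .network import build_network, largest_component

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    out = Path(outdir or cfg.pop("outdir", "netpatterns_out"))
    param_keys = PipelineParams.__dataclass_fields__.keys()
    params = PipelineParams(**{k: cfg[k] for k in param_keys if k in cfg})
    net = largest_component(build_network(npio.read_polylines(cfg["roads"])))

    coords, weights, labels = npio.read_points(
        cfg["facilities"],
        weight_field=cfg.get("weight_field", "weight"),
        label_field=cfg.get("label_field", "label"),
    )
    snapped, _ = snap_to_network(net, coords, weights, labels)
    facilities = {}
    for label in sorted({l for l in snapped.labels if l is not None}):
        mask = np.array([l == label for l in snapped.labels])
        facilities[label] = snapped.subset(mask)
    if not facilities:
        facilities = {"all": snapped}

    patients = None
    if cfg.get("patients"):
        pc, pw, _ = npio.read_points(cfg["patients"])
        patients, _ = snap_to_network(net, pc, pw, ["patient"] * len(pc))

    communities = None
    if cfg.get("communities"):
        polys, attrs = npio.read_polygons(
            cfg["communities"], [cfg.get("population_field", "population")]
        )
        communities = CommunityInputs(
            polys, attrs.iloc[:, 0].astype(float).to_numpy()
        )

    districts = None
    if cfg.get("districts"):
        polys, attrs = npio.read_polygons(cfg["districts"],
                                          [cfg.get("district_name_field", "name")])
        districts = {
            str(attrs.iloc[i, 0] if attrs.iloc[i, 0] is not None else i): polys[i]
            for i in range(len(polys))
        }
    return run_pipeline(net, facilities, patients, communities, out, params,
                        districts)
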