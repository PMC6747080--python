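"""Weighted network kernel density estimation (NetKDE).

The intensity at a network location ``s`` is a truncated-Gaussian kernel
sum over events within network (shortest-path) bandwidth ``r``:

    lambda(s) = sum_i (1/r) * k(dis_i / r)
    k(dis/r)  = (1 / sqrt(2*pi)) * exp(-dis^2 / (2 r^2)) * w_i   for dis <= r
              = 0                                                 for dis > r

where ``dis_i`` is the shortest-path distance from ``s`` to event ``i`` and
``w_i`` is its non-spatial weight (hospital bed number; fixed tier weights
for CHCs / clinics / pharmacies). The estimator is a plain kernel sum over
network distance: it is not renormalized to integrate to the event count,
and no equal-split correction is applied at intersections, so density near
high-degree nodes carries the known overestimation bias of the uncorrected
estimator.

At ``dis = 0`` the kernel takes its continuous limit ``w / sqrt(2*pi)`` so
an event contributes at its own location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import box

from .network import LixelSet, NetworkPointSet, RoadNetwork, point_distance_matrix

__all__ = [
    "GAUSS_NORM",
    "DensityField",
    "DensityGrid",
    "kernel_value",
    "estimate_density",
    "rasterize_density",
    "classify_density",
    "DEFAULT_BANDWIDTHS",
    "DEFAULT_TYPE_WEIGHTS",
]

GAUSS_NORM = 1.0 / np.sqrt(2.0 * np.pi)

#: default search bandwidths in meters per facility type: hospitals serve a
#: wider catchment than primary-care facilities
DEFAULT_BANDWIDTHS = {"hospital": 1000.0, "chc": 500.0, "clinic": 500.0, "pharmacy": 500.0}
#: default non-spatial weights; hospitals use their bed number instead
DEFAULT_TYPE_WEIGHTS = {"chc": 20.0, "clinic": 10.0, "pharmacy": 1.0}


@dataclass
class DensityField:
    """Per-lixel NetKDE intensity with its bandwidth metadata."""

    lixels: LixelSet
    values: np.ndarray  # lambda(s) at each lixel center
    bandwidth: float
    kernel: str = "gaussian"
    labels_used: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.lixels):
            raise ValueError("one value per lixel required")


@dataclass
class DensityGrid:
    """Regular planar raster of density values transferred from lixels.

    ``values[0, 0]`` is the top-left (north-west) cell, matching the ESRI
    ASCII grid convention; ``origin`` is the lower-left corner.
    """

    values: np.ndarray  # (nrows, ncols), nodata where no lixel intersects
    origin: tuple[float, float]
    cell_size: float
    nodata: float = -9999.0

    def to_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid (plain text)."""
        nrows, ncols = self.values.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {self.origin[0]:.6f}\n")
            fh.write(f"yllcorner {self.origin[1]:.6f}\n")
            fh.write(f"cellsize {self.cell_size:.6f}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            np.savetxt(fh, self.values, fmt="%.8g")


def kernel_value(dis, r: float, w=1.0):
    """Truncated Gaussian kernel mass of an event at network distance ``dis``.

    Vectorized over ``dis`` and ``w``. Zero beyond the bandwidth ``r``; the
    ``dis = 0`` value is the continuous limit ``w / sqrt(2 pi)``.
    """
    if r <= 0:
        raise ValueError("bandwidth r must be > 0")
    dis = np.asarray(dis, dtype=float)
    if np.any(dis < 0):
        raise ValueError("distances must be >= 0")
    val = GAUSS_NORM * np.exp(-(dis**2) / (2.0 * r**2)) * w
    out = np.where(dis <= r, val, 0.0)
    return float(out) if out.ndim == 0 else out


def estimate_density(
    network: RoadNetwork,
    events: NetworkPointSet,
    r: float,
    lixels: LixelSet,
    chunk: int = 512,
) -> DensityField:
    """Evaluate the NetKDE intensity at every lixel center.

    Events beyond network distance ``r`` from a center contribute exactly
    zero. An empty event set yields an all-zero field.
    """
    if r <= 0:
        raise ValueError("bandwidth r must be > 0")
    centers = lixels.centers
    values = np.zeros(len(lixels))
    if len(events):
        for start in range(0, len(events), chunk):
            sub = events.subset(np.arange(start, min(start + chunk, len(events))))
            dmat = point_distance_matrix(network, sub, centers)
            with np.errstate(invalid="ignore"):
                contrib = np.where(
                    dmat <= r,
                    GAUSS_NORM
                    * np.exp(-(dmat**2) / (2.0 * r**2))
                    * sub.weights[:, None],
                    0.0,
                )
            values += contrib.sum(axis=0) / r
    labels = tuple(sorted({str(l) for l in events.labels if l is not None}))
    return DensityField(lixels=lixels, values=values, bandwidth=r, labels_used=labels)


def rasterize_density(
    field: DensityField, cell_size: float, origin: tuple[float, float] | None = None
) -> DensityGrid:
    """Transfer a lixel field onto a regular raster.

    Each covered cell receives the length-weighted mean of the lixel
    portions intersecting it, which conserves the field's scale; cells not
    touched by any lixel carry the nodata value.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    net = field.lixels.network
    xmin, ymin, xmax, ymax = net.bounds
    if origin is None:
        origin = (xmin, ymin)
    x0, y0 = origin
    ncols = max(1, int(np.ceil((xmax - x0) / cell_size)))
    nrows = max(1, int(np.ceil((ymax - y0) / cell_size)))
    num = np.zeros((nrows, ncols))
    den = np.zeros((nrows, ncols))
    for lam, geom in zip(field.values, field.lixels.geometries()):
        gxmin, gymin, gxmax, gymax = geom.bounds
        c0 = max(0, int((gxmin - x0) // cell_size))
        c1 = min(ncols - 1, int((gxmax - x0) // cell_size))
        r0 = max(0, int((gymin - y0) // cell_size))
        r1 = min(nrows - 1, int((gymax - y0) // cell_size))
        for ci in range(c0, c1 + 1):
            for ri in range(r0, r1 + 1):
                cell = box(
                    x0 + ci * cell_size,
                    y0 + ri * cell_size,
                    x0 + (ci + 1) * cell_size,
                    y0 + (ri + 1) * cell_size,
                )
                seg_len = geom.intersection(cell).length
                if seg_len > 0:
                    row = nrows - 1 - ri  # row 0 = top
                    num[row, ci] += lam * seg_len
                    den[row, ci] += seg_len
    grid = np.full((nrows, ncols), -9999.0)
    covered = den > 0
    grid[covered] = num[covered] / den[covered]
    return DensityGrid(values=grid, origin=origin, cell_size=cell_size)


def classify_density(field: DensityField, n_classes: int = 5):
    """Jenks natural-breaks classification of the density values.

    Returns ``(breaks, classes)`` where ``breaks`` are the ascending class
    maxima and ``classes`` the 1-based class label per lixel (class 1 =
    lowest densities). If the field has fewer distinct values than classes
    the class count is reduced with a warning.
    """
    from .geodetector import jenks_breaks, stratify

    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    n_distinct = len(np.unique(field.values))
    if n_distinct == 1:
        warnings.warn("all density values identical; single class", stacklevel=2)
        return np.array([field.values[0]]), np.ones(len(field.values), dtype=np.int64)
    if n_distinct < n_classes:
        warnings.warn(
            f"only {n_distinct} distinct values; reducing classes "
            f"from {n_classes} to {n_distinct}",
            stacklevel=2,
        )
        n_classes = n_distinct
    breaks = jenks_breaks(field.values, n_classes)
    strat = stratify(field.values, breaks)
    return breaks, strat.labels
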