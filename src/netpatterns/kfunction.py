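"""Network auto and cross K-functions with Monte Carlo CSR envelopes.

For points on a network with total segment length S, the pointwise network
K-function at point ``p_i`` is ``K(t | p_i) = n(t | p_i) / rho`` where
``n(t | p_i)`` counts the other points within shortest-path distance ``t``
and ``rho = (n - 1) / S`` is the point density on the network. The global
curve reported here is the average of the pointwise values over all points,
so in auto mode K saturates at S once ``t`` exceeds the network diameter.

The cross K-function counts points of a target type within distance ``t``
of each base point, with ``rho = n_target / S`` (no self-exclusion).
Weights are ignored throughout: the K analysis concerns locations only.

The null model is complete spatial randomness (CSR) on the network: points
i.i.d. uniform over the union of edges (edge chosen proportional to its
length, offset uniform). Envelopes are pointwise empirical quantiles of K
over Monte Carlo CSR realizations — not global rank envelopes, so the
pointwise significance level does not control the familywise error across
the whole t-range. Observed K above the upper envelope reads as clustering,
below the lower envelope as dispersion, inside as randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkPointSet, RoadNetwork, point_distance_matrix

__all__ = [
    "KResult",
    "KEnvelope",
    "PatternLabel",
    "default_t_grid",
    "auto_k",
    "cross_k",
    "simulate_csr",
    "envelope",
    "classify_pattern",
]

#: default plotted distance range ceiling (meters)
DEFAULT_T_MAX = 10_000.0


@dataclass
class KResult:
    """Observed network K-function curve."""

    t_grid: np.ndarray
    k: np.ndarray
    n: int
    rho: float
    mode: str  # "auto" | "cross"
    total_length: float


@dataclass
class KEnvelope:
    """Pointwise Monte Carlo CSR envelope for the K-function."""

    t_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    mean: np.ndarray
    n_sims: int
    alpha: float
    mode: str


@dataclass
class PatternLabel:
    """Per-distance pattern classification against a CSR envelope."""

    t_grid: np.ndarray
    labels: np.ndarray  # "clustered" | "dispersed" | "random" per t
    summary: str  # regime covering the largest t-measure
    summary_t_range: tuple[float, float]  # min/max t where the summary holds


def default_t_grid(
    network: RoadNetwork, t_max: float | None = None, n_steps: int = 50
) -> np.ndarray:
    """Equally spaced distances from 0 to min(10 km, half the diameter)."""
    if t_max is None:
        t_max = min(DEFAULT_T_MAX, 0.5 * network.diameter())
    return np.linspace(0.0, t_max, n_steps)


def _check_t_grid(t_grid: np.ndarray, network: RoadNetwork) -> np.ndarray:
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly ascending")
    if np.any(t_grid < 0):
        raise ValueError("t values must be >= 0")
    return t_grid


def _count_curve(distances: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Total pair count with distance <= t for each t (coincident pairs at 0)."""
    flat = np.sort(distances[np.isfinite(distances)])
    return np.searchsorted(flat, t_grid, side="right").astype(float)


def auto_k(
    network: RoadNetwork, events: NetworkPointSet, t_grid=None
) -> KResult:
    """Network auto K-function of a single event type."""
    n = len(events)
    if n < 2:
        raise ValueError("auto K-function needs at least 2 points")
    if t_grid is None:
        t_grid = default_t_grid(network)
    t_grid = _check_t_grid(t_grid, network)
    s_total = network.total_length
    rho = (n - 1) / s_total
    dmat = point_distance_matrix(network, events, events)
    np.fill_diagonal(dmat, np.inf)  # exclude self-pairs
    counts = _count_curve(dmat, t_grid)
    k = counts / n / rho
    return KResult(t_grid=t_grid, k=k, n=n, rho=rho, mode="auto",
                   total_length=s_total)


def cross_k(
    network: RoadNetwork,
    base: NetworkPointSet,
    target: NetworkPointSet,
    t_grid=None,
) -> KResult:
    """Network cross K-function: target events around base events."""
    if len(base) == 0 or len(target) == 0:
        raise ValueError("cross K-function needs nonempty base and target sets")
    if t_grid is None:
        t_grid = default_t_grid(network)
    t_grid = _check_t_grid(t_grid, network)
    s_total = network.total_length
    rho = len(target) / s_total
    dmat = point_distance_matrix(network, base, target)
    counts = _count_curve(dmat, t_grid)
    k = counts / len(base) / rho
    return KResult(t_grid=t_grid, k=k, n=len(base), rho=rho, mode="cross",
                   total_length=s_total)


def simulate_csr(network: RoadNetwork, n: int, rng=None) -> NetworkPointSet:
    """Draw n i.i.d. uniform points on the network (the CSR null).

    Each point picks an edge with probability proportional to its length,
    then a uniform offset along that edge.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng)
    probs = network.edge_lengths / network.total_length
    edges = rng.choice(network.n_edges, size=n, p=probs)
    offsets = rng.uniform(0.0, network.edge_lengths[edges]) if n else np.empty(0)
    return NetworkPointSet(network, edges, offsets)


def envelope(
    network: RoadNetwork,
    n: int,
    t_grid,
    n_sims: int = 200,
    alpha: float = 0.05,
    rng=None,
    mode: str = "auto",
    base: NetworkPointSet | None = None,
) -> KEnvelope:
    """Monte Carlo CSR envelope of the K-function.

    Auto mode randomizes all ``n`` points each realization; cross mode holds
    the ``base`` set fixed and randomizes ``n`` target points (the question
    being whether targets cluster around the fixed bases). Bounds are the
    pointwise alpha/2 and 1-alpha/2 empirical quantiles over realizations.
    """
    if n_sims < 20:
        raise ValueError("n_sims must be >= 20")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if mode not in ("auto", "cross"):
        raise ValueError("mode must be 'auto' or 'cross'")
    if mode == "cross" and base is None:
        raise ValueError("cross mode requires a base point set")
    if mode == "auto" and base is not None:
        raise ValueError("auto mode takes no base set")
    rng = np.random.default_rng(rng)
    t_grid = _check_t_grid(np.asarray(t_grid, dtype=float), network)
    sims = np.empty((n_sims, len(t_grid)))
    for s in range(n_sims):
        pts = simulate_csr(network, n, rng)
        if mode == "auto":
            sims[s] = auto_k(network, pts, t_grid).k
        else:
            sims[s] = cross_k(network, base, pts, t_grid).k
    return KEnvelope(
        t_grid=t_grid,
        lower=np.quantile(sims, alpha / 2.0, axis=0),
        upper=np.quantile(sims, 1.0 - alpha / 2.0, axis=0),
        mean=sims.mean(axis=0),
        n_sims=n_sims,
        alpha=alpha,
        mode=mode,
    )


def classify_pattern(observed: KResult, env: KEnvelope) -> PatternLabel:
    """Classify the observed K against a CSR envelope, per distance.

    clustered if K(t) > upper(t); dispersed if K(t) < lower(t); random
    otherwise. The summary is the regime covering the largest measure of
    the t-range (each grid point weighted by the span it represents).
    """
    if len(observed.t_grid) != len(env.t_grid) or not np.allclose(
        observed.t_grid, env.t_grid
    ):
        raise ValueError("observed and envelope t_grids do not match")
    labels = np.where(
        observed.k > env.upper,
        "clustered",
        np.where(observed.k < env.lower, "dispersed", "random"),
    )
    t = observed.t_grid
    # measure represented by each grid point: half the span to its neighbors
    w = np.empty(len(t))
    w[1:-1] = (t[2:] - t[:-2]) / 2.0
    w[0] = (t[1] - t[0]) / 2.0
    w[-1] = (t[-1] - t[-2]) / 2.0
    best, best_measure = "random", -1.0
    for regime in ("clustered", "dispersed", "random"):
        measure = float(w[labels == regime].sum())
        if measure > best_measure:
            best, best_measure = regime, measure
    where = t[labels == best]
    t_range = (float(where.min()), float(where.max())) if len(where) else (0.0, 0.0)
    return PatternLabel(t_grid=t, labels=labels, summary=best,
                        summary_t_range=t_range)
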