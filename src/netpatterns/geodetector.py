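"""Spatial stratified heterogeneity: the geographical-detector q-statistic.

Given a response ``Y`` over N spatial units and a stratification into L
strata, the q-statistic is

    q = 1 - sum_h N_h sigma_h^2 / (N sigma^2)

with population-style variances (denominators ``N_h`` and ``N``), under
which the within-stratum sum-of-squares form and the variance form of q
coincide identically. q is 0 when stratum means equal the population mean
(no stratified heterogeneity) and 1 when every stratum is internally
constant (fully stratified); it is invariant under affine rescaling of Y.

Significance is assessed by a label-permutation test (the classical
noncentral-F reference distribution is not used here; the permutation test
is an explicit substitute and is labelled as such in results). The
two-factor interaction detector compares q of the intersection
stratification ``A ∩ B`` with q_A, q_B, their max and their sum.

Stratification of continuous covariates uses exact Fisher-Jenks natural
breaks: the dynamic program that minimizes total within-class sum of
squared deviations, not a heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Stratification",
    "QResult",
    "InteractionResult",
    "jenks_breaks",
    "stratify",
    "q_statistic",
    "permutation_p",
    "interaction",
    "interaction_category",
]

#: exact-comparison tolerance for interaction category boundaries
CATEGORY_TOL = 1e-12


@dataclass
class Stratification:
    """Assignment of units to strata 1..L; every stratum is nonempty."""

    labels: np.ndarray  # (N,) int, values in 1..L
    n_strata: int
    breaks: np.ndarray | None = None  # class maxima when derived from values

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        counts = np.bincount(self.labels, minlength=self.n_strata + 1)[1:]
        if len(counts) < self.n_strata or np.any(counts < 1):
            raise ValueError("every stratum must contain at least one unit")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class QResult:
    """q-statistic decomposition for one stratification."""

    q: float
    n: int
    strata: pd.DataFrame  # per-stratum N_h, mean, variance (population)
    mean: float
    variance: float
    p_value: float | None = None
    p_method: str | None = None


@dataclass
class InteractionResult:
    """Two-factor interaction detector outcome."""

    q_a: float
    q_b: float
    q_ab: float
    category: str
    comparison: dict = field(default_factory=dict)


def jenks_breaks(values, k: int) -> np.ndarray:
    """Exact Fisher-Jenks natural breaks for 1-D data.

    Dynamic program over sorted values minimizing the total within-class sum
    of squared deviations; O(k n^2) with vectorized inner loops. Returns the
    k ascending class maxima (the last break is the data maximum).
    """
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(values)) < k:
        raise ValueError(
            f"need at least {k} distinct values for {k} classes; "
            "reduce k or supply more varied data"
        )
    x = np.sort(values)
    n = len(x)
    # prefix sums: SSE of x[i..j] = s2 - s^2/m computable in O(1)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def seg_sse(i, j):
        # within-class SSE of x[i..j] inclusive; i may be an array
        m = j - i + 1
        s = cs[j + 1] - cs[i]
        s2 = cs2[j + 1] - cs2[i]
        return s2 - s * s / m

    idx = np.arange(n)
    cost = seg_sse(np.zeros(n, dtype=np.int64), idx)  # one class
    cut = np.zeros((k, n), dtype=np.int64)
    for m in range(1, k):
        new_cost = np.empty(n)
        new_cost[:m] = np.nan
        for j in range(m, n):
            i = np.arange(m, j + 1)  # first index of the last class
            cand = cost[i - 1] + seg_sse(i, np.full(len(i), j))
            best = int(np.argmin(cand))
            new_cost[j] = cand[best]
            cut[m, j] = m + best
        cost = new_cost
    # backtrack class boundaries
    breaks = np.empty(k)
    j = n - 1
    for m in range(k - 1, 0, -1):
        breaks[m] = x[j]
        j = cut[m, j] - 1
    breaks[0] = x[j]
    return breaks


def stratify(values, breaks) -> Stratification:
    """Assign values to classes by ascending class maxima ``breaks``.

    Intervals are half-open ``(lower, upper]``; the lowest class is closed
    below. Values above the last break are assigned to the top class with a
    warning (nearest end class).
    """
    values = np.asarray(values, dtype=float)
    breaks = np.asarray(breaks, dtype=float)
    if np.any(np.diff(breaks) < 0):
        raise ValueError("breaks must be ascending")
    labels = np.searchsorted(breaks, values, side="left") + 1
    k = len(breaks)
    if np.any(labels > k):
        warnings.warn(
            "values above the last break assigned to the top class", stacklevel=2
        )
        labels = np.minimum(labels, k)
    return Stratification(labels=labels, n_strata=k, breaks=breaks)


def _coerce_labels(strata) -> np.ndarray:
    if isinstance(strata, Stratification):
        return strata.labels
    labels = np.asarray(strata)
    _, inv = np.unique(labels, return_inverse=True)
    return inv + 1


def _q_from_codes(y: np.ndarray, codes: np.ndarray, n_strata: int) -> float:
    n = len(y)
    counts = np.bincount(codes, minlength=n_strata)
    sums = np.bincount(codes, weights=y, minlength=n_strata)
    sums2 = np.bincount(codes, weights=y * y, minlength=n_strata)
    within_ss = float(np.sum(sums2 - sums**2 / np.maximum(counts, 1)))
    total_ss = float(np.sum(y * y) - y.sum() ** 2 / n)
    return 1.0 - within_ss / total_ss


def q_statistic(y, strata) -> QResult:
    """q-statistic of a stratification (population-variance convention).

    ``strata`` may be a :class:`Stratification` or any array of labels.
    Raises if the response has no variation (sigma^2 = 0: nothing to
    explain).
    """
    y = np.asarray(y, dtype=float)
    labels = _coerce_labels(strata)
    if len(y) != len(labels):
        raise ValueError("y and strata must have equal length")
    if len(y) < 2:
        raise ValueError("need at least 2 units")
    n = len(y)
    var = float(np.var(y))  # population variance
    if var == 0:
        raise ValueError("population variance is zero: no variation to explain")
    uniq = np.unique(labels)
    rows = []
    within = 0.0
    for h in uniq:
        yh = y[labels == h]
        vh = float(np.var(yh))
        rows.append({"stratum": int(h), "n": len(yh), "mean": float(yh.mean()),
                     "variance": vh})
        within += len(yh) * vh
    q = 1.0 - within / (n * var)
    return QResult(
        q=float(q),
        n=n,
        strata=pd.DataFrame(rows),
        mean=float(y.mean()),
        variance=var,
    )


def permutation_p(y, strata, n_perm: int = 999, rng=None) -> float:
    """Permutation p-value for the q-statistic.

    Stratum labels are permuted against Y; ``p = (1 + #{q* >= q_obs}) /
    (n_perm + 1)``. This replaces the noncentral-F reference test with a
    distribution-free procedure.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float)
    labels = _coerce_labels(strata)
    codes = labels - 1
    n_strata = int(codes.max()) + 1
    q_obs = _q_from_codes(y, codes, n_strata)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _q_from_codes(y, perm, n_strata) >= q_obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def interaction_category(
    q_a: float, q_b: float, q_ab: float, tol: float = CATEGORY_TOL
) -> str:
    """Interaction-detector category from the three q values.

    Categories, with C = q(A ∩ B):
    C < min(A, B)            -> "nonlinear-weaken"
    min <= C <= max          -> "uni-weaken"  (equality at max is treated as
                                 non-enhancing: a refinement that adds no
                                 explanatory power)
    max < C < A + B          -> "bi-enhance"       (A ↑ B)
    C == A + B               -> "independent"
    C > A + B                -> "nonlinear-enhance" (A ⇑ B)
    """
    lo, hi, s = min(q_a, q_b), max(q_a, q_b), q_a + q_b
    if q_ab < lo - tol:
        return "nonlinear-weaken"
    if q_ab <= hi + tol:
        return "uni-weaken"
    if abs(q_ab - s) <= tol:
        return "independent"
    return "bi-enhance" if q_ab < s else "nonlinear-enhance"


def interaction(y, strata_a, strata_b) -> InteractionResult:
    """Two-factor interaction detector.

    The intersection stratification takes one stratum per distinct pair of
    (A, B) labels occurring in the data (empty pairs drop out), so it
    refines both factors; consequently q(A ∩ B) >= max(q_A, q_B) and only
    the non-weakening categories can occur for true intersections.
    """
    y = np.asarray(y, dtype=float)
    la = _coerce_labels(strata_a)
    lb = _coerce_labels(strata_b)
    if len(la) != len(lb) or len(la) != len(y):
        raise ValueError("y, strata_a and strata_b must cover the same units")
    q_a = q_statistic(y, la).q
    q_b = q_statistic(y, lb).q
    pair = la * (lb.max() + 1) + lb
    q_ab = q_statistic(y, pair).q
    cat = interaction_category(q_a, q_b, q_ab)
    comparison = {
        "q_a": q_a,
        "q_b": q_b,
        "q_ab": q_ab,
        "a_plus_b": q_a + q_b,
        "max_ab": max(q_a, q_b),
        "min_ab": min(q_a, q_b),
        "C_vs_A_plus_B": (
            "C > A + B" if q_ab > q_a + q_b + CATEGORY_TOL
            else "C < A + B" if q_ab < q_a + q_b - CATEGORY_TOL
            else "C = A + B"
        ),
    }
    return InteractionResult(q_a=q_a, q_b=q_b, q_ab=q_ab, category=cat,
                             comparison=comparison)
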