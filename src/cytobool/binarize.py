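"""Iterative K-means binarization of resampled expression profiles.

Each protein's 50 resampled values are clustered in one dimension under the
absolute-deviation (L1) objective

    J = Σⱼ Σᵢ |xᵢ - Cⱼ|,

whose optimal centroids are cluster *medians*.  Clustering starts at 8
clusters and is reduced one cluster at a time: the two closest centroids
are merged and Lloyd iterations re-fit at the smaller k, down to the final
2 clusters.  (At the last stage the exact optimal contiguous split — cheap
to enumerate in 1-D — is also tried as a candidate seed, so the final
2-clustering is globally optimal under the L1 objective.)  The activation
threshold δ is the midpoint of the two final cluster centroids; values
strictly above δ binarize to 1.  An all-flat profile would yield δ = 0, in
which case δ is replaced by the assay detection floor (1e-6) so that noise
around zero is not read as activation.

A mean-based (L2, cluster-mean centroids) variant and the alternate
threshold reading ("average of the mean within-cluster distances") are
available behind config switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ClusterConfig",
    "BinarizedProfile",
    "l1_kmeans_1d",
    "best_two_cluster_split",
    "iterative_kmeans_threshold",
    "binarize",
    "sensitivity_flag",
]

DETECTION_FLOOR = 1e-6


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering schedule and conventions.

    ``threshold_rule``: ``"midpoint"`` (average of the two final cluster
    centroids; default) or ``"mean_distance"`` (average of the two clusters'
    mean within-cluster distances — the alternate literal reading).
    ``metric``: ``"l1"`` (median centroids, as the objective J is written)
    or ``"l2"`` (mean centroids).
    """

    k_start: int = 8
    k_end: int = 2
    max_iter: int = 100
    threshold_rule: str = "midpoint"
    metric: str = "l1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_end != 2 or self.k_start < self.k_end:
            raise ValueError("require k_start >= k_end = 2")
        if self.threshold_rule not in ("midpoint", "mean_distance"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")
        if self.metric not in ("l1", "l2"):
            raise ValueError(f"unknown metric {self.metric!r}")


def _centroid(points: np.ndarray, metric: str) -> float:
    return float(np.median(points) if metric == "l1" else np.mean(points))


def _objective(x: np.ndarray, centroids: np.ndarray, metric: str) -> float:
    d = np.abs(x[:, None] - centroids[None, :])
    if metric == "l2":
        d = d**2
    return float(np.sum(np.min(d, axis=1)))


def l1_kmeans_1d(
    x: np.ndarray,
    init: np.ndarray,
    metric: str = "l1",
    max_iter: int = 100,
    trace: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations in 1-D from given initial centroids.

    Returns (sorted centroids, assignment, objective J).  Empty clusters are
    dropped.  With median (L1) or mean (L2) updates the objective is
    non-increasing; ``trace``, if given, collects J after every iteration so
    that monotonicity can be checked.
    """
    x = np.asarray(x, dtype=float)
    centroids = np.unique(np.asarray(init, dtype=float))
    if trace is not None:
        trace.append(_objective(x, centroids, metric))
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centroids[None, :])
        assign = np.argmin(d, axis=1)
        new = np.array(
            [
                _centroid(x[assign == j], metric)
                for j in range(len(centroids))
                if np.any(assign == j)
            ]
        )
        new = np.unique(new)
        if trace is not None:
            trace.append(_objective(x, new, metric))
        if len(new) == len(centroids) and np.allclose(new, centroids):
            break
        centroids = new
    d = np.abs(x[:, None] - centroids[None, :])
    assign = np.argmin(d, axis=1)
    return centroids, assign, _objective(x, centroids, metric)


def best_two_cluster_split(
    x: np.ndarray, metric: str = "l1"
) -> tuple[np.ndarray, float]:
    """Exact optimal 2-clustering of 1-D data by contiguous-split
    enumeration (optimal clusters are contiguous in sorted order)."""
    xs = np.sort(np.asarray(x, dtype=float))
    best: tuple[float, np.ndarray] | None = None
    for s in range(1, len(xs)):
        lo, hi = xs[:s], xs[s:]
        c = np.array([_centroid(lo, metric), _centroid(hi, metric)])
        cost = _objective(xs, np.unique(c), metric)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, np.unique(c))
    assert best is not None
    return best[1], best[0]


def iterative_kmeans_threshold(
    values: Sequence[float],
    config: ClusterConfig = ClusterConfig(),
    return_detail: bool = False,
):
    """Activation threshold δ from the iterative K-means cascade.

    Starts at ``k_start`` clusters (quantile-seeded), repeatedly merges the
    two closest centroids and re-fits, down to 2 clusters; δ is then derived
    from the final two clusters per ``config.threshold_rule``.  A
    non-positive δ (flat/zero profile) is replaced by the detection floor.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D series of at least 2 values")
    if np.any(x < 0):
        raise ValueError("negative expression values")

    distinct = np.unique(x)
    if len(distinct) == 1:
        thr = DETECTION_FLOOR if distinct[0] <= 0 else distinct[0]
        # single value: nothing exceeds it (strictly-above rule)
        return (thr, {"centroids": distinct}) if return_detail else thr

    k0 = min(config.k_start, len(distinct))
    # deterministic quantile seeding
    init = np.quantile(x, np.linspace(0, 1, k0))
    centroids, assign, J = l1_kmeans_1d(x, init, config.metric, config.max_iter)
    history = [(len(centroids), J)]
    while len(centroids) > config.k_end:
        gaps = np.diff(centroids)
        j = int(np.argmin(gaps))
        merged = np.delete(centroids, j + 1)
        merged[j] = _centroid(
            x[(assign == j) | (assign == j + 1)], config.metric
        )
        centroids, assign, J = l1_kmeans_1d(
            x, merged, config.metric, config.max_iter
        )
        history.append((len(centroids), J))
    if len(centroids) == 2:
        # candidate seed from the exact 1-D split; keep the better optimum
        exact_c, exact_J = best_two_cluster_split(x, config.metric)
        if len(exact_c) == 2 and exact_J < J - 1e-12:
            centroids, assign, J = l1_kmeans_1d(
                x, exact_c, config.metric, config.max_iter
            )

    if len(centroids) < 2:
        thr = float(centroids[0])
    elif config.threshold_rule == "midpoint":
        thr = float(np.mean(centroids))
    else:  # mean within-cluster distance reading
        d = np.abs(x[:, None] - centroids[None, :])
        assign = np.argmin(d, axis=1)
        mean_dists = [
            float(np.mean(np.abs(x[assign == j] - centroids[j])))
            for j in range(2)
            if np.any(assign == j)
        ]
        thr = float(np.mean(mean_dists))
    if thr <= 0:
        thr = DETECTION_FLOOR
    if return_detail:
        return thr, {
            "centroids": centroids,
            "objective": J,
            "history": history,
        }
    return thr


@dataclass
class BinarizedProfile:
    """A thresholded profile with its sensitivity band."""

    threshold: float
    bits: tuple[int, ...]
    band: tuple[float, float] | None = None
    sensitive_fraction: float = 0.0
    values: np.ndarray | None = field(default=None, repr=False)


def binarize(
    values: Sequence[float],
    threshold: float,
    fit_error: float | None = None,
) -> BinarizedProfile:
    """Threshold a series: strictly above δ → 1, at or below → 0.

    ``fit_error`` (the mean absolute spline error at the measurement
    points) defines the error band δ ± ε; the fraction of resampled values
    falling inside it measures how sensitive the binarization is to fitting
    error.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0 (apply the detection floor)")
    x = np.asarray(values, dtype=float)
    bits = tuple(int(v > threshold) for v in x)
    band = None
    frac = 0.0
    if fit_error is not None:
        eps = abs(float(fit_error))
        band = (threshold - eps, threshold + eps)
        if eps > 0:
            frac = float(np.mean((x >= band[0]) & (x <= band[1])))
    return BinarizedProfile(
        threshold=float(threshold),
        bits=bits,
        band=band,
        sensitive_fraction=frac,
        values=x,
    )


def sensitivity_flag(
    profile: BinarizedProfile, tolerance: float = 0.05
) -> bool:
    """True (pass) iff the share of points inside the error band does not
    exceed ``tolerance`` (default 5%)."""
    return profile.sensitive_fraction <= tolerance
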