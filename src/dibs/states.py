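"""Two-level Manhattan-distance k-means over windowed IBS matrices.

Manhattan (city-block, L1) distance is preferred over Euclidean for these
high-dimensional connectivity vectors.  The L1-optimal centroid update is the
component-wise median, so the algorithm is k-medians with Lloyd iterations;
1,000 random-initialisation replicates guard against local minima and the
lowest-cost replicate is kept.

Clustering is two-level, mirroring the group-then-individual design: the
cohort's window series are averaged window-by-window across dyads and
clustered with the cluster count chosen by the elbow criterion on the
within/between-cluster distance ratio; the resulting group centroids seed a
single k-means run per dyad, whose converged labels are the dyad's state
sequence.  States are re-indexed by descending centroid global efficiency so
that "state 1" always denotes the densest, most efficient pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .ibs_dynamics import IBSWindowSeries

__all__ = [
    "Centroids",
    "StatePartition",
    "vectorize_windows",
    "matrix_from_vector",
    "kmeans_manhattan",
    "validity_index",
    "elbow_select_k",
    "cluster_group_then_dyads",
]


def vectorize_windows(series: IBSWindowSeries | np.ndarray) -> np.ndarray:
    """Flatten symmetric matrices to upper-triangle vectors (diagonal kept).

    13 x 13 symmetric matrices become 91-feature vectors; the mapping is a
    bijection (see :func:`matrix_from_vector`).
    """
    mats = series.windows if isinstance(series, IBSWindowSeries) else np.asarray(series)
    if mats.ndim == 2:
        mats = mats[None]
    if not np.allclose(mats, np.swapaxes(mats, 1, 2), atol=1e-9):
        raise ValueError("matrices must be symmetric (tolerance 1e-9)")
    n = mats.shape[1]
    iu = np.triu_indices(n)
    return mats[:, iu[0], iu[1]]


def matrix_from_vector(vec: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of :func:`vectorize_windows` for a single vector."""
    iu = np.triu_indices(n_rois)
    m = np.zeros((n_rois, n_rois))
    m[iu] = vec
    return np.where(np.eye(n_rois, dtype=bool), m, m + m.T - np.diag(np.diag(m)))


@dataclass
class Centroids:
    """Best-of-replicates k-medians solution."""

    k: int
    centers: np.ndarray  # (k, n_features)
    cost: float  # total within-cluster L1 distance
    labels: np.ndarray  # (n_points,)
    n_replicates: int
    seed: int
    n_iter: int = 0

    def centroid_matrices(self, n_rois: int) -> np.ndarray:
        return np.stack([matrix_from_vector(c, n_rois) for c in self.centers])


@dataclass
class StatePartition:
    """Cohort-level dIBS state solution.

    ``dyad_labels`` maps dyad id -> per-window state labels (0-based, ordered
    by descending group-centroid global efficiency, so label 0 == "state 1",
    the densest state).
    """

    k: int
    group_centroids: np.ndarray  # (k, n_rois, n_rois)
    dyad_labels: dict[str, np.ndarray]
    dyad_centroids: dict[str, np.ndarray]
    task_labels: list[str]  # per window, shared grid
    validity_curve: dict[int, float] = field(default_factory=dict)
    centroid_drift: dict[str, float] = field(default_factory=dict)

    @property
    def n_rois(self) -> int:
        return self.group_centroids.shape[1]


def _lloyd_l1(x: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float, int]:
    """L1 Lloyd iterations from given centers; objective is non-increasing."""
    prev_labels = None
    prev_cost = np.inf
    labels = None
    for it in range(max_iter):
        d = cdist(x, centers, metric="cityblock")
        labels = d.argmin(axis=1)
        cost = float(d[np.arange(x.shape[0]), labels].sum())
        if cost > prev_cost + 1e-8 * max(1.0, abs(prev_cost)):
            raise AssertionError("k-medians objective increased")
        prev_cost = cost
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            return labels, centers, cost, it
        prev_labels = labels
        new_centers = centers.copy()
        for c in range(centers.shape[0]):
            members = x[labels == c]
            if members.shape[0] == 0:
                # re-seed an emptied cluster at the point farthest from its center
                far = d[np.arange(x.shape[0]), labels].argmax()
                new_centers[c] = x[far]
            else:
                new_centers[c] = np.median(members, axis=0)
        centers = new_centers
    d = cdist(x, centers, metric="cityblock")
    labels = d.argmin(axis=1)
    cost = float(d[np.arange(x.shape[0]), labels].sum())
    return labels, centers, cost, max_iter


def kmeans_manhattan(
    x: np.ndarray,
    k: int,
    n_replicates: int = 1000,
    seed: int = 0,
    max_iter: int = 300,
    init_centers: np.ndarray | None = None,
) -> Centroids:
    """k-medians under Manhattan distance, best of ``n_replicates`` random
    initialisations (distinct data points).

    With ``init_centers`` given, a single run starts there instead (the
    dyad-level pass seeded by group centroids).  Deterministic under ``seed``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    if init_centers is not None:
        starts = [np.asarray(init_centers, dtype=float)]
    else:
        starts = [x[rng.choice(n, size=k, replace=False)] for _ in range(n_replicates)]
    for c0 in starts:
        labels, centers, cost, n_iter = _lloyd_l1(x, c0, max_iter)
        if best is None or cost < best[0]:
            best = (cost, centers, labels, n_iter)
    cost, centers, labels, n_iter = best
    return Centroids(
        k=k,
        centers=centers,
        cost=cost,
        labels=labels,
        n_replicates=len(starts),
        seed=seed,
        n_iter=n_iter,
    )


def validity_index(x: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Within- to between-cluster distance ratio (lower is tighter).

    Mean L1 distance of points to their own centroid, divided by the mean
    pairwise L1 distance between centroids.  Infinite when centroids
    coincide.
    """
    x = np.asarray(x, dtype=float)
    k = centers.shape[0]
    if k < 2:
        raise ValueError("validity index needs k >= 2")
    d = cdist(x, centers, metric="cityblock")
    within = float(d[np.arange(x.shape[0]), labels].mean())
    between_d = cdist(centers, centers, metric="cityblock")
    iu = np.triu_indices(k, 1)
    between = float(between_d[iu].mean())
    if between == 0:
        warnings.warn("coincident centroids: validity index infinite", stacklevel=2)
        return float("inf")
    return within / between


def elbow_select_k(
    x: np.ndarray,
    k_range: range | tuple[int, int] = (2, 8),
    n_replicates: int = 50,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Cluster count at the elbow of the validity-index curve.

    The elbow is operationalised as the point of maximum curvature: the
    argmax of the second-order central difference of the index over interior
    k.  A flat curve (range < 1e-6) falls back to the smallest k with a
    warning.  Returns ``(k_star, curve)`` so the curve can be audited.
    """
    if isinstance(k_range, tuple):
        ks = list(range(k_range[0], k_range[1] + 1))
    else:
        ks = list(k_range)
    if ks[0] < 2 or ks[-1] >= x.shape[0]:
        raise ValueError("k_range must lie within [2, n_points)")
    curve: dict[int, float] = {}
    for k in ks:
        res = kmeans_manhattan(x, k, n_replicates=n_replicates, seed=seed + k)
        curve[k] = validity_index(x, res.labels, res.centers)
    vals = np.array([curve[k] for k in ks])
    if not np.all(np.isfinite(vals)) or np.ptp(vals) < 1e-6:
        warnings.warn("validity curve flat or degenerate: defaulting to smallest k", stacklevel=2)
        return ks[0], curve
    if int(np.argmin(vals)) == 0:
        # the curve rises beyond the smallest k: no elbow, the minimum wins
        return ks[0], curve
    if len(ks) < 3:
        return ks[int(np.argmin(vals))], curve
    curvature = vals[:-2] - 2 * vals[1:-1] + vals[2:]
    k_star = ks[1 + int(np.argmax(curvature))]
    return k_star, curve


def cluster_group_then_dyads(
    series_list: list[IBSWindowSeries],
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
    n_replicates: int = 1000,
    seed: int = 0,
    state_order_values: "callable | None" = None,
) -> StatePartition:
    """Group-level clustering followed by centroid-seeded dyad labelling.

    All dyads must share the window grid and ROI set (their windowed series
    pool creative and control tasks on one time axis).  ``k`` defaults to the
    elbow-selected count on the group-mean series.  ``state_order_values``
    maps a (n_rois, n_rois) centroid to a sort key; by default the global
    efficiency of the centroid graph, so states are ordered densest first.
    """
    shapes = {s.windows.shape for s in series_list}
    grids = {tuple(np.round(s.window_starts, 6)) for s in series_list}
    if len(shapes) != 1 or len(grids) != 1:
        raise ValueError("dyads have mismatched window grids")
    task_labels = series_list[0].task_labels
    for s in series_list[1:]:
        if s.task_labels != task_labels:
            raise ValueError("dyads have mismatched task label sequences")
    n_rois = series_list[0].windows.shape[1]
    group_windows = np.mean([s.windows for s in series_list], axis=0)
    gx = vectorize_windows(group_windows)

    validity_curve: dict[int, float] = {}
    if k is None:
        k, validity_curve = elbow_select_k(
            gx, k_range=k_range, n_replicates=max(10, n_replicates // 10), seed=seed
        )
    group = kmeans_manhattan(gx, k, n_replicates=n_replicates, seed=seed)

    if state_order_values is None:
        from .network_metrics import centroid_to_graph, global_efficiency

        def state_order_values(m: np.ndarray) -> float:
            # coherence centroids are non-negative; clip guards the ordering
            # against numerically negative medians on synthetic inputs
            return global_efficiency(centroid_to_graph(np.maximum(m, 0.0)))

    cent_mats = group.centroid_matrices(n_rois)
    order = np.argsort([-state_order_values(m) for m in cent_mats])
    cent_mats = cent_mats[order]
    group_centers = group.centers[order]

    dyad_labels: dict[str, np.ndarray] = {}
    dyad_centroids: dict[str, np.ndarray] = {}
    drift: dict[str, float] = {}
    for s in series_list:
        x = vectorize_windows(s)
        res = kmeans_manhattan(x, k, seed=seed, init_centers=group_centers)
        dyad_labels[s.dyad_id] = res.labels
        dyad_centroids[s.dyad_id] = res.centroid_matrices(n_rois)
        drift[s.dyad_id] = float(np.abs(res.centers - group_centers).sum())
    return StatePartition(
        k=k,
        group_centroids=cent_mats,
        dyad_labels=dyad_labels,
        dyad_centroids=dyad_centroids,
        task_labels=list(task_labels),
        validity_curve=validity_curve,
        centroid_drift=drift,
    )
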