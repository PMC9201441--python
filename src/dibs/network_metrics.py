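"""Graph metrics on dIBS state centroids and temporal state statistics.

Each state centroid is read as a weighted, undirected graph on the ROIs: the
edge weight between ROIs i and j is the centroid's synchrony value, and the
length used for shortest paths is the reciprocal weight (strong synchrony =
short functional distance).  No sparsity threshold is applied.

Global efficiency is the mean inverse shortest-path length over ordered node
pairs (unreachable pairs contribute zero); the characteristic path length Lp
is reported as the harmonic mean of shortest-path lengths over reachable
pairs, with the arithmetic mean kept alongside for audit.

Temporal metrics per dyad and task: the occurrence rate of each state (the
fraction of windows it occupies) and the transition count (adjacent windows
with different states, never counted across the task boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GraphMetrics",
    "centroid_to_graph",
    "global_efficiency",
    "characteristic_path_length",
    "graph_metrics",
    "occurrence_rates",
    "transition_count",
    "state_metrics_frame",
]


@dataclass(frozen=True)
class GraphMetrics:
    globE: float
    Lp: float  # harmonic-mean variant
    Lp_arithmetic: float
    n_nodes: int


def centroid_to_graph(centroid: np.ndarray) -> nx.Graph:
    """Weighted graph from a symmetric non-negative centroid matrix.

    Self-loops are dropped; zero-weight entries produce no edge. Each edge
    carries ``weight`` (the synchrony value) and ``length`` (its reciprocal).
    """
    c = np.asarray(centroid, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("centroid must be a square matrix")
    if not np.allclose(c, c.T, atol=1e-9):
        raise ValueError("centroid must be symmetric")
    if np.any(c < 0):
        raise ValueError("negative edge weights are not meaningful synchrony values")
    n = c.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            w = c[i, j]
            if w > 0:
                g.add_edge(i, j, weight=w, length=1.0 / w)
    return g


def _shortest_lengths(g: nx.Graph) -> dict[int, dict[int, float]]:
    return dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))


def global_efficiency(g: nx.Graph) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    ``globE = (1 / N(N-1)) * sum_{i != j} 1/d_ij`` with unreachable pairs
    contributing zero. Raises for graphs with fewer than 2 nodes or no edges.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    if g.number_of_edges() == 0:
        raise ValueError("global efficiency undefined for an edgeless graph")
    lengths = _shortest_lengths(g)
    acc = 0.0
    for i, row in lengths.items():
        for j, d in row.items():
            if i != j and d > 0:
                acc += 1.0 / d
    return acc / (n * (n - 1))


def characteristic_path_length(g: nx.Graph) -> tuple[float, float]:
    """Harmonic and arithmetic mean shortest-path length over reachable pairs.

    The harmonic variant ``N'(N'-1) / sum(1/d_ij)`` is the headline Lp; the
    arithmetic mean is returned second for audit.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("path length needs >= 2 nodes")
    lengths = _shortest_lengths(g)
    inv_sum, d_sum, n_pairs = 0.0, 0.0, 0
    for i, row in lengths.items():
        for j, d in row.items():
            if i != j and d > 0:
                inv_sum += 1.0 / d
                d_sum += d
                n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no reachable node pairs")
    return n_pairs / inv_sum, d_sum / n_pairs


def graph_metrics(centroid: np.ndarray) -> GraphMetrics:
    g = centroid_to_graph(centroid)
    lp_h, lp_a = characteristic_path_length(g)
    return GraphMetrics(
        globE=global_efficiency(g),
        Lp=lp_h,
        Lp_arithmetic=lp_a,
        n_nodes=g.number_of_nodes(),
    )


def occurrence_rates(
    labels: np.ndarray, task_labels: list[str], k: int
) -> dict[str, dict[int, float]]:
    """Fraction of each task's windows spent in each state.

    Rates sum to 1 within each task.  States are 0-based.
    """
    labels = np.asarray(labels)
    if labels.size != len(task_labels):
        raise ValueError("every window needs a task label")
    out: dict[str, dict[int, float]] = {}
    tasks = list(dict.fromkeys(task_labels))
    task_arr = np.asarray(task_labels)
    for task in tasks:
        sel = labels[task_arr == task]
        out[task] = {s: float(np.mean(sel == s)) for s in range(k)}
    return out


def transition_count(labels: np.ndarray, task_labels: list[str]) -> dict[str, int]:
    """Switches between consecutive windows, per task.

    The pair straddling the boundary between two tasks is never counted.
    """
    labels = np.asarray(labels)
    if labels.size != len(task_labels):
        raise ValueError("every window needs a task label")
    task_arr = np.asarray(task_labels)
    out: dict[str, int] = {}
    for task in dict.fromkeys(task_labels):
        sel = labels[task_arr == task]
        out[task] = int(np.sum(sel[1:] != sel[:-1]))
    return out


def state_metrics_frame(partition, rois: list[str] | None = None) -> pd.DataFrame:
    """Tidy per-dyad, per-task, per-state metric table.

    Columns: dyad, task, state (1-based), occurrence, transitions (per task,
    repeated across its states), globE and Lp of the dyad's state centroid.
    """
    rows = []
    for dyad_id, labels in partition.dyad_labels.items():
        occ = occurrence_rates(labels, partition.task_labels, partition.k)
        trans = transition_count(labels, partition.task_labels)
        cents = partition.dyad_centroids[dyad_id]
        gm = []
        for s in range(partition.k):
            try:
                gm.append(graph_metrics(cents[s]))
            except ValueError:
                gm.append(GraphMetrics(np.nan, np.nan, np.nan, cents[s].shape[0]))
        for task in occ:
            for s in range(partition.k):
                rows.append(
                    {
                        "dyad": dyad_id,
                        "task": task,
                        "state": s + 1,
                        "occurrence": occ[task][s],
                        "transitions": trans[task],
                        "globE": gm[s].globE,
                        "Lp": gm[s].Lp,
                        "Lp_arithmetic": gm[s].Lp_arithmetic,
                    }
                )
    return pd.DataFrame(rows)
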