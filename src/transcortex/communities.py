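"""Community detection: Louvain modularity maximization and consensus
clustering.

Modularity is reported on the standard Newman-Girvan normalization,

    Q = (1/2m) * sum_ij (A_ij - gamma * k_i k_j / 2m) delta(s_i, s_j),

with the resolution parameter gamma multiplying the degree-based null term
(Reichardt-Bornholdt convention).  Because Louvain is stochastic, a stable
partition is obtained by consensus: run the algorithm R times, build the
node x node co-assignment count matrix, recluster it as a weighted graph,
and iterate until all runs of an iteration agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .networks import BinaryGraph

__all__ = ["Partition", "modularity", "louvain_partition",
           "consensus_partition"]


@dataclass
class Partition:
    """Node -> module labels (contiguous ids from 1, ordered by size)."""

    labels: np.ndarray
    q: float
    gamma: float
    converged: bool = True

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]

    def to_frame(self, region_id: np.ndarray | None = None) -> pd.DataFrame:
        ids = region_id if region_id is not None \
            else np.arange(1, len(self.labels) + 1)
        return pd.DataFrame({"region_id": ids, "module": self.labels})


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..K by descending size (ties by first appearance)."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    first = np.array([np.argmax(labels == u) for u in uniq])
    order = np.lexsort((first, -counts))
    mapping = {int(uniq[o]): rank + 1 for rank, o in enumerate(order)}
    return np.array([mapping[int(v)] for v in labels])


def modularity(weights: np.ndarray, labels: np.ndarray,
               gamma: float = 1.0) -> float:
    """Direct evaluation of Q on a (possibly weighted) adjacency matrix."""
    a = np.asarray(weights, float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(0)
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("graph has no edges")
    same = labels[:, None] == labels[None, :]
    return float(((a - gamma * np.outer(k, k) / two_m) * same).sum() / two_m)


def _as_weight_matrix(graph: BinaryGraph | np.ndarray) -> np.ndarray:
    if isinstance(graph, BinaryGraph):
        return graph.adjacency.astype(float)
    return np.asarray(graph, float)


def _louvain_labels(w: np.ndarray, gamma: float, seed: int) -> np.ndarray:
    g = nx.from_numpy_array(w)
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=gamma, seed=int(seed))
    labels = np.zeros(len(w), dtype=int)
    for mod, nodes in enumerate(comms, start=1):
        for node in nodes:
            labels[node] = mod
    return _canonical_labels(labels)


def louvain_partition(graph: BinaryGraph | np.ndarray, gamma: float = 1.0,
                      seed: int = 0) -> Partition:
    """One Louvain run; Q reported on the 1/(2m) normalization."""
    w = _as_weight_matrix(graph)
    np.fill_diagonal(w, 0.0)
    if w.sum() == 0:
        raise ValueError("cannot partition an edgeless graph")
    labels = _louvain_labels(w, gamma, seed)
    return Partition(labels=labels, q=modularity(w, labels, gamma),
                     gamma=gamma)


def consensus_partition(graph: BinaryGraph | np.ndarray, gamma: float = 1.0,
                        runs: int = 1000, seed: int = 0,
                        max_iter: int = 10) -> Partition:
    """Consensus clustering over `runs` Louvain runs.

    The co-assignment fraction matrix from one iteration becomes the
    weighted graph of the next; iteration stops when every run of an
    iteration returns the identical partition (up to relabeling) or after
    `max_iter` iterations (flagged via `converged=False`).
    """
    w = _as_weight_matrix(graph)
    np.fill_diagonal(w, 0.0)
    if w.sum() == 0:
        raise ValueError("cannot partition an edgeless graph")
    rng = np.random.default_rng(seed)
    current = w
    labels = None
    converged = False
    for _ in range(max_iter):
        seeds = rng.integers(2**31 - 1, size=runs)
        parts = [_louvain_labels(current, gamma, s) for s in seeds]
        labels = parts[0]
        if all(np.array_equal(p, labels) for p in parts[1:]):
            converged = True
            break
        m = np.zeros_like(w)
        for p in parts:
            m += p[:, None] == p[None, :]
        m /= runs
        np.fill_diagonal(m, 0.0)
        current = m
    labels = _canonical_labels(labels)
    return Partition(labels=labels, q=modularity(w, labels, gamma),
                     gamma=gamma, converged=converged)
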