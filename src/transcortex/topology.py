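"""Graph-topology battery for binary brain networks.

Global metrics (clustering, path length, efficiencies, assortativity),
small-worldness against degree-preserving rewired nulls, rich-club curves,
nodal degree / connection distance, and the participation coefficient.

Conventions for disconnected graphs: the characteristic path length
averages over reachable pairs only; global efficiency counts unreachable
pairs as zero contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .atlas import ParcelAtlas
from .networks import BinaryGraph

__all__ = ["GlobalMetrics", "NullEnsemble", "RichClubCurve", "global_metrics",
           "rewire_null", "small_worldness", "rich_club",
           "degree_and_distance", "participation_coefficient"]


@dataclass
class GlobalMetrics:
    cp: float          # clustering coefficient (mean nodal)
    lp: float          # characteristic path length over reachable pairs
    eloc: float        # local efficiency
    eglob: float       # global efficiency
    assortativity: float

    def as_dict(self) -> dict:
        return {"Cp": self.cp, "Lp": self.lp, "Eloc": self.eloc,
                "Eglob": self.eglob, "assortativity": self.assortativity}


@dataclass
class NullEnsemble:
    """Degree-preserving rewired surrogates of a source graph."""

    graphs: list[BinaryGraph]
    swaps_per_edge: int
    seed: int

    @property
    def n(self) -> int:
        return len(self.graphs)


@dataclass
class RichClubCurve:
    k: np.ndarray
    phi: np.ndarray
    phi_rand: np.ndarray
    rho_norm: np.ndarray   # phi / mean(phi over nulls); NaN where undefined
    null_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "phi": self.phi,
                             "phi_rand": self.phi_rand,
                             "rho_norm": self.rho_norm,
                             "null_sd": self.null_sd})


def _path_lengths(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(adj.astype(np.int8)), method="D",
                         unweighted=True, directed=False)


def global_metrics(graph: BinaryGraph) -> GlobalMetrics:
    """Cp, Lp, Eloc, Eglob and degree assortativity of a binary graph."""
    adj = graph.adjacency
    n = len(adj)
    if n == 0:
        raise ValueError("empty graph")
    g = nx.from_numpy_array(adj)
    cp = nx.average_clustering(g)

    sp = _path_lengths(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(sp) & off
    lp = float(sp[finite].mean()) if finite.any() else np.nan
    with np.errstate(divide="ignore"):
        inv = np.where(off & np.isfinite(sp) & (sp > 0), 1.0 / sp, 0.0)
    eglob = float(inv[off].mean()) if n > 1 else 0.0

    eloc_terms = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) < 2:
            eloc_terms.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        sps = _path_lengths(sub)
        m = len(nbrs)
        offs = ~np.eye(m, dtype=bool)
        with np.errstate(divide="ignore"):
            invs = np.where(offs & np.isfinite(sps) & (sps > 0), 1.0 / sps, 0.0)
        eloc_terms.append(float(invs[offs].mean()))
    eloc = float(np.mean(eloc_terms))

    deg = adj.sum(0).astype(float)
    e = graph.edges()
    if len(e) < 2:
        a = np.nan
    else:
        x = np.concatenate([deg[e[:, 0]], deg[e[:, 1]]])
        y = np.concatenate([deg[e[:, 1]], deg[e[:, 0]]])
        sx, sy = x.std(), y.std()
        a = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)) \
            if sx > 0 and sy > 0 else np.nan
    return GlobalMetrics(cp=float(cp), lp=lp, eloc=eloc, eglob=eglob,
                         assortativity=a)


def rewire_null(graph: BinaryGraph, n: int = 1000, swaps_per_edge: int = 10,
                seed: int = 0) -> NullEnsemble:
    """Degree-preserving double-edge-swap surrogates.

    Each surrogate applies `swaps_per_edge * m` successful swaps (self-loops
    and multi-edges rejected); connectedness is not enforced.
    """
    edges0 = graph.edges()
    m = len(edges0)
    if m < 2:
        raise ValueError("graph needs at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        edges = [tuple(e) for e in edges0]
        eset = {(min(a, b), max(a, b)) for a, b in edges}
        target = swaps_per_edge * m
        done = tries = 0
        max_tries = 100 * target
        while done < target and tries < max_tries:
            tries += 1
            i, j = rng.integers(m), rng.integers(m)
            if i == j:
                continue
            a, b = edges[i]
            c, d = edges[j]
            if rng.random() < 0.5:
                c, d = d, c
            if a == d or c == b:
                continue
            k1 = (min(a, d), max(a, d))
            k2 = (min(c, b), max(c, b))
            if k1 in eset or k2 in eset:
                continue
            eset.discard((min(a, b), max(a, b)))
            eset.discard((min(edges[j][0], edges[j][1]),
                          max(edges[j][0], edges[j][1])))
            eset.add(k1)
            eset.add(k2)
            edges[i] = (a, d)
            edges[j] = (c, b)
            done += 1
        adj = np.zeros_like(graph.adjacency)
        for a, b in edges:
            adj[a, b] = adj[b, a] = True
        out.append(BinaryGraph(adjacency=adj, density=graph.density,
                               region_id=graph.region_id))
    return NullEnsemble(graphs=out, swaps_per_edge=swaps_per_edge, seed=seed)


def small_worldness(graph: BinaryGraph, nulls: NullEnsemble) -> float:
    """sigma = (Cp / <Cp_rand>) / (Lp / <Lp_rand>)."""
    gm = global_metrics(graph)
    cps, lps = [], []
    for g in nulls.graphs:
        ngm = global_metrics(g)
        cps.append(ngm.cp)
        lps.append(ngm.lp)
    return (gm.cp / np.mean(cps)) / (gm.lp / np.mean(lps))


def _phi_curve(adj: np.ndarray, ks: np.ndarray) -> np.ndarray:
    deg = adj.sum(0)
    phi = np.full(len(ks), np.nan)
    for idx, k in enumerate(ks):
        nodes = np.flatnonzero(deg > k)
        nk = len(nodes)
        if nk < 2:
            continue
        ek = adj[np.ix_(nodes, nodes)].sum() / 2
        phi[idx] = 2.0 * ek / (nk * (nk - 1))
    return phi


def rich_club(graph: BinaryGraph, nulls: NullEnsemble) -> RichClubCurve:
    """Rich-club coefficient Phi(k) = density among nodes of degree > k,
    normalized by the mean over the rewired null ensemble."""
    import warnings

    deg = graph.degree()
    ks = np.arange(0, deg.max())
    phi = _phi_curve(graph.adjacency, ks)
    null_phi = np.stack([_phi_curve(g.adjacency, ks) for g in nulls.graphs])
    with warnings.catch_warnings():
        # thresholds where every null leaves < 2 nodes are legitimately NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        phi_rand = np.nanmean(null_phi, axis=0)
        null_sd = np.nanstd(null_phi, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(phi_rand > 0, phi / phi_rand, np.nan)
    return RichClubCurve(k=ks, phi=phi, phi_rand=phi_rand, rho_norm=rho,
                         null_sd=null_sd)


def degree_and_distance(graph: BinaryGraph, atlas_left: ParcelAtlas
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node degree and mean Euclidean distance of its connections (mm),
    plus the per-edge distance table.  Isolated nodes get NaN distance."""
    if atlas_left.n_regions != graph.n:
        raise ValueError("atlas does not cover the graph's nodes")
    d = atlas_left.distances()
    e = graph.edges()
    edge_d = d[e[:, 0], e[:, 1]]
    deg = graph.degree()
    mean_d = np.full(graph.n, np.nan)
    for i in range(graph.n):
        nbrs = np.flatnonzero(graph.adjacency[i])
        if len(nbrs):
            mean_d[i] = d[i, nbrs].mean()
    nodal = pd.DataFrame({"region_id": atlas_left.region_id, "degree": deg,
                          "mean_distance_mm": mean_d})
    edges = pd.DataFrame({"region_i": atlas_left.region_id[e[:, 0]],
                          "region_j": atlas_left.region_id[e[:, 1]],
                          "distance_mm": edge_d})
    return nodal, edges


def participation_coefficient(graph: BinaryGraph, labels: np.ndarray
                              ) -> np.ndarray:
    """P_i = 1 - sum_s (k_is / k_i)^2 over modules s; P = 0 for isolates."""
    labels = np.asarray(labels)
    if len(labels) != graph.n:
        raise ValueError("partition does not cover all nodes")
    deg = graph.degree().astype(float)
    p = np.zeros(graph.n)
    mods = np.unique(labels)
    for i in range(graph.n):
        if deg[i] == 0:
            continue
        nbr = graph.adjacency[i]
        s = 0.0
        for mod in mods:
            kis = np.count_nonzero(nbr & (labels == mod))
            s += (kis / deg[i]) ** 2
        p[i] = 1.0 - s
    return p
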