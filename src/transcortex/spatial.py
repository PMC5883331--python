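"""Spatially contiguous permutation null for module-level statistics.

Intra-module statistics (e.g., mean within-module co-expression) are
inflated by trivial features of any community partition: its number of
modules, their sizes, and their spatial compactness.  The null model here
redraws module positions on the cortex while preserving all three: each
null partition has exactly the source's multiset of module sizes and every
null module is connected on the atlas spatial-adjacency graph.

Realization (grow-then-repair): modules are seeded at random regions with
their source sizes as quotas and grown in rounds, each unfilled module
claiming the unclaimed spatial neighbor closest to its running centroid;
once the cortex is covered, quota imbalances are repaired by transferring
boundary regions from over-quota modules to adjacent under-quota modules,
allowing only transfers that keep the donor connected.  Draws that cannot
be repaired are rejected and resampled, which leaves the accepted draws
exactly on the constraint set (size multiset + contiguity) without bias
toward any particular placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import ParcelAtlas

__all__ = ["NullPartitionSet", "is_contiguous", "permute_modules"]


@dataclass
class NullPartitionSet:
    """Accepted null partitions, one row of labels per draw."""

    labels: np.ndarray      # (n_draws, n_regions) int
    seed: int
    n_rejected: int

    @property
    def n(self) -> int:
        return len(self.labels)


def is_contiguous(adjacency: np.ndarray, mask: np.ndarray) -> bool:
    """Is the induced subgraph on `mask` connected (singletons count)?"""
    nodes = np.flatnonzero(mask)
    if len(nodes) <= 1:
        return True
    sub = adjacency[np.ix_(nodes, nodes)]
    seen = np.zeros(len(nodes), bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(sub[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return bool(seen.all())


def _connected_without(members: set[int], r: int,
                       nbrs: list[list[int]]) -> bool:
    rest = members - {r}
    if not rest:
        return False
    start = next(iter(rest))
    seen = {start}
    stack = [start]
    while stack:
        i = stack.pop()
        for j in nbrs[i]:
            if j in rest and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == len(rest)


def _one_draw(sizes: np.ndarray, nbrs: list[list[int]], cents: np.ndarray,
              rng: np.random.Generator) -> np.ndarray | None:
    """One candidate partition (labels 0..k-1) or None on failure."""
    k = len(sizes)
    n = len(cents)
    order = np.argsort(-sizes, kind="stable")
    seeds = rng.choice(n, size=k, replace=False)
    lab = -np.ones(n, dtype=int)
    lab[seeds] = np.arange(k)
    members: list[set[int]] = [{int(s)} for s in seeds]
    frontier: list[set[int]] = [set(nbrs[int(s)]) for s in seeds]
    csum = cents[seeds].copy()
    unclaimed = n - k
    while unclaimed:
        progress = False
        for m in order:
            if len(members[m]) >= sizes[m]:
                continue
            fr = {j for j in frontier[m] if lab[j] < 0}
            frontier[m] = fr
            if not fr:
                continue
            cand = np.fromiter(fr, int)
            ctr = csum[m] / len(members[m])
            d = np.linalg.norm(cents[cand] - ctr, axis=1)
            pick = int(cand[np.lexsort((cand, d))[0]])
            lab[pick] = m
            members[m].add(pick)
            csum[m] += cents[pick]
            frontier[m] |= {j for j in nbrs[pick] if lab[j] < 0}
            unclaimed -= 1
            progress = True
            if not unclaimed:
                break
        if not progress:
            # all unfilled modules are walled in; let any module adjacent
            # to free space over-claim one region (repaired below)
            forced = False
            for m in order:
                fr = {j for j in frontier[m] if lab[j] < 0}
                frontier[m] = fr
                if fr:
                    pick = int(next(iter(fr)))
                    lab[pick] = m
                    members[m].add(pick)
                    csum[m] += cents[pick]
                    frontier[m] |= {j for j in nbrs[pick] if lab[j] < 0}
                    unclaimed -= 1
                    forced = True
                    break
            if not forced:
                return None

    def deficit() -> int:
        return sum(abs(len(members[m]) - sizes[m]) for m in range(k))

    guard = 0
    while deficit() > 0 and guard < 6 * n:
        guard += 1
        moved = False
        over = [m for m in range(k) if len(members[m]) > sizes[m]]
        rng.shuffle(over)
        for m in over:
            cands = []
            for r in members[m]:
                receivers = {int(lab[j]) for j in nbrs[r] if lab[j] != m}
                receivers = {q for q in receivers
                             if len(members[q]) < sizes[q]}
                if receivers and _connected_without(members[m], r, nbrs):
                    cands.extend((r, q) for q in receivers)
            if cands:
                r, q = cands[int(rng.integers(len(cands)))]
                members[m].remove(r)
                members[q].add(r)
                lab[r] = q
                moved = True
                break
        if not moved:
            return None
    if deficit() > 0:
        return None
    return lab


def permute_modules(
    labels: np.ndarray,
    atlas_left: ParcelAtlas,
    n: int = 1000,
    seed: int = 0,
    max_rejections: int | None = None,
) -> NullPartitionSet:
    """Draw `n` pseudo-random spatially contiguous partitions that preserve
    the source partition's module-size multiset.

    Requires every source module to be contiguous on the atlas adjacency.
    Raises if the rejection budget (default 100 * n) is exhausted.
    """
    labels = np.asarray(labels)
    adj = atlas_left.adjacency
    cents = atlas_left.centroids
    if len(labels) != atlas_left.n_regions:
        raise ValueError("partition does not cover the atlas")
    mods, sizes = np.unique(labels, return_counts=True)
    for mod in mods:
        if not is_contiguous(adj, labels == mod):
            raise ValueError(
                f"source module {mod} is not spatially contiguous; the null "
                "preserves contiguity and requires it of the source")
    nbrs = [[int(j) for j in np.flatnonzero(adj[i])]
            for i in range(len(labels))]
    if max_rejections is None:
        max_rejections = 100 * n
    rng = np.random.default_rng(seed)
    out = np.zeros((n, len(labels)), dtype=int)
    accepted = 0
    rejected = 0
    while accepted < n:
        lab = _one_draw(sizes, nbrs, cents, rng)
        if lab is not None:
            out[accepted] = mods[lab]
            accepted += 1
        else:
            rejected += 1
            if rejected > max_rejections:
                rate = accepted / (accepted + rejected)
                raise RuntimeError(
                    f"spatial-null rejection budget exhausted "
                    f"(acceptance rate {rate:.3f} after {rejected} rejections)")
    return NullPartitionSet(labels=out, seed=seed, n_rejected=rejected)
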