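"""Parcellated cortical geometry.

The analysis only consumes parcel centroids, Euclidean distances, spatial
adjacency and cytoarchitectonic class labels, so the synthetic substrate is
an idealized half-ellipsoid shell: points are scattered on the left half of
an ellipsoid surface (the left-right axis is the first coordinate, midline
at x = 0), clustered into parcels, and mirrored to produce the right
hemisphere.  Cytoarchitectonic ("von Economo") classes 1..7 are grown as
spatially contiguous patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from sklearn.cluster import KMeans

N_VE_CLASSES = 7

# Semi-axes (mm) of the idealized hemisphere; chosen so that ~150 parcels
# have a few hundred mm^2 each and inter-centroid distances span the range
# typical of a human hemisphere (a few mm up to ~150 mm).
SEMI_AXES = (65.0, 90.0, 60.0)


@dataclass
class ParcelAtlas:
    """Region ids, centroids, spatial adjacency and class labels.

    Attributes
    ----------
    region_id : (n,) int array; unique labels, 1-based.
    centroids : (n, 3) float array, mm.  First coordinate is left-right,
        midline at 0 (left hemisphere negative).
    adjacency : (n, n) bool array; symmetric, irreflexive spatial-neighbor
        relation.  Adjacency never crosses the midline.
    hemisphere : (n,) array of 'L'/'R'.
    ve_class : (n,) int array in 1..7; each class spatially contiguous.
    surface_points : per-region arrays of surface sample points, mm.
    """

    region_id: np.ndarray
    centroids: np.ndarray
    adjacency: np.ndarray
    hemisphere: np.ndarray
    ve_class: np.ndarray
    surface_points: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    def left(self) -> "ParcelAtlas":
        """The left-hemisphere sub-atlas (the analysis frame)."""
        mask = self.hemisphere == "L"
        idx = np.flatnonzero(mask)
        ids = self.region_id[idx]
        return ParcelAtlas(
            region_id=ids,
            centroids=self.centroids[idx],
            adjacency=self.adjacency[np.ix_(idx, idx)],
            hemisphere=self.hemisphere[idx],
            ve_class=self.ve_class[idx],
            surface_points={i: self.surface_points[i] for i in ids
                            if i in self.surface_points},
        )

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances, mm."""
        d = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((d ** 2).sum(-1))

    def validate(self) -> None:
        a = self.adjacency
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency is not symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency is not irreflexive")
        for hemi in np.unique(self.hemisphere):
            idx = np.flatnonzero(self.hemisphere == hemi)
            if not _is_connected(a[np.ix_(idx, idx)]):
                raise ValueError(f"{hemi} hemisphere adjacency is disconnected")
        if not np.isin(self.ve_class, np.arange(1, N_VE_CLASSES + 1)).all():
            raise ValueError("ve_class labels outside 1..7")

    # ------------------------------------------------------------------ I/O
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        regions = pd.DataFrame({
            "region_id": self.region_id,
            "x": self.centroids[:, 0],
            "y": self.centroids[:, 1],
            "z": self.centroids[:, 2],
            "hemisphere": self.hemisphere,
            "ve_class": self.ve_class,
        })
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        edges = pd.DataFrame({
            "region_i": self.region_id[ii],
            "region_j": self.region_id[jj],
        })
        return regions, edges

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        regions, edges = self.to_frames()
        regions.to_csv(outdir / "regions.tsv", sep="\t", index=False)
        edges.to_csv(outdir / "adjacency.tsv", sep="\t", index=False)


def _is_connected(adj: np.ndarray) -> bool:
    n = len(adj)
    if n == 0:
        return True
    seen = np.zeros(n, bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return bool(seen.all())


def _half_ellipsoid_points(n_points: int, rng: np.random.Generator):
    """Sample points on the left (x<=0) half of an ellipsoid shell.

    Returns (points, params) where params are (u, v) surface coordinates:
    u polar angle in (0, pi), v azimuth in (pi/2, 3pi/2) so cos v <= 0.
    """
    a, b, c = SEMI_AXES
    u = np.arccos(rng.uniform(-1, 1, n_points))
    v = rng.uniform(np.pi / 2, 3 * np.pi / 2, n_points)
    pts = np.column_stack([
        a * np.sin(u) * np.cos(v),
        b * np.sin(u) * np.sin(v),
        c * np.cos(u),
    ])
    return pts, np.column_stack([u, v])


def grow_contiguous_patches(
    adjacency: np.ndarray,
    centroids: np.ndarray,
    n_patches: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Partition regions into spatially contiguous patches by seeded growth.

    Seeds are drawn at random; patches take turns claiming the unclaimed
    spatial neighbor closest (Euclidean) to their running centroid.  Every
    patch is non-empty and connected on `adjacency` by construction.
    Returns integer labels 1..n_patches.
    """
    n = len(adjacency)
    if n_patches < 1 or n_patches > n:
        raise ValueError("n_patches must be in 1..n_regions")
    labels = np.zeros(n, dtype=int)
    seeds = rng.choice(n, size=n_patches, replace=False)
    labels[seeds] = np.arange(1, n_patches + 1)
    sums = centroids[seeds].copy()
    counts = np.ones(n_patches)
    remaining = int(n - n_patches)
    while remaining:
        progress = False
        for p in range(1, n_patches + 1):
            members = labels == p
            frontier = np.flatnonzero((adjacency[members].any(0)) & (labels == 0))
            if frontier.size == 0:
                continue
            ctr = sums[p - 1] / counts[p - 1]
            d = np.linalg.norm(centroids[frontier] - ctr, axis=1)
            pick = frontier[np.lexsort((frontier, d))[0]]
            labels[pick] = p
            sums[p - 1] += centroids[pick]
            counts[p - 1] += 1
            remaining -= 1
            progress = True
            if not remaining:
                break
        if not progress:
            raise ValueError("adjacency graph is disconnected; cannot cover it")
    return labels


def make_atlas(
    n_regions: int,
    seed: int,
    points_per_region: int = 60,
) -> ParcelAtlas:
    """Build a two-hemisphere synthetic atlas with `n_regions` per hemisphere.

    Left-hemisphere parcels are centroids of a k-means partition of points
    sampled on a half-ellipsoid shell; adjacency comes from the Delaunay
    triangulation of parcel centers in surface coordinates; the right
    hemisphere is an exact mirror (sign of the first coordinate flipped).
    """
    if n_regions < 8:
        raise ValueError("n_regions must be at least 8")
    if n_regions < 2 * N_VE_CLASSES:
        raise ValueError(
            "n_regions too small to form 7 contiguous cytoarchitectonic "
            f"classes of >=2 regions each (need >= {2 * N_VE_CLASSES})"
        )
    rng = np.random.default_rng(seed)
    pts, params = _half_ellipsoid_points(points_per_region * n_regions, rng)
    km = KMeans(
        n_clusters=n_regions, n_init=1, max_iter=100,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(pts)
    lab = km.labels_

    centroids = np.stack([pts[lab == k].mean(0) for k in range(n_regions)])
    par = np.stack([params[lab == k].mean(0) for k in range(n_regions)])

    tri = Delaunay(par)
    adj_l = np.zeros((n_regions, n_regions), dtype=bool)
    for simplex in tri.simplices:
        for i in range(3):
            for j in range(i + 1, 3):
                adj_l[simplex[i], simplex[j]] = True
                adj_l[simplex[j], simplex[i]] = True

    ve = grow_contiguous_patches(adj_l, centroids, N_VE_CLASSES, rng)

    # Mirror for the right hemisphere; no midline adjacency.
    ids_l = np.arange(1, n_regions + 1)
    ids_r = ids_l + n_regions
    cent = np.vstack([centroids, centroids * np.array([-1.0, 1.0, 1.0])])
    adj = np.zeros((2 * n_regions, 2 * n_regions), dtype=bool)
    adj[:n_regions, :n_regions] = adj_l
    adj[n_regions:, n_regions:] = adj_l
    surface = {}
    for k in range(n_regions):
        sp = pts[lab == k]
        surface[int(ids_l[k])] = sp
        surface[int(ids_r[k])] = sp * np.array([-1.0, 1.0, 1.0])

    atlas = ParcelAtlas(
        region_id=np.concatenate([ids_l, ids_r]),
        centroids=cent,
        adjacency=adj,
        hemisphere=np.array(["L"] * n_regions + ["R"] * n_regions),
        ve_class=np.concatenate([ve, ve]),
        surface_points=surface,
    )
    atlas.validate()
    return atlas
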