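"""From donor expression samples to a regions x genes matrix.

Pipeline: collapse multiple probes per gene (highest mean expression wins),
reflect right-hemisphere samples across the midline, assign each cortical
sample to the parcel whose surface it falls on (with a 2 mm tolerance into
the subjacent "white matter"), z-normalize expression within donor, pool
donors, take per-region medians, and fill the rare parcel with zero samples
from its spatial neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atlas import ParcelAtlas

__all__ = ["MappingReport", "RegionalExpression", "select_probe_per_gene",
           "collapse_probes", "reflect_right_hemisphere",
           "assign_samples_to_parcels", "aggregate_regional_expression"]


@dataclass
class MappingReport:
    """Bookkeeping of the sample -> parcel assignment."""

    n_input: int = 0
    n_noncortical: int = 0
    n_assigned: int = 0
    n_dropped_tolerance: int = 0
    n_genes_dropped: int = 0   # genes with zero annotated probes

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RegionalExpression:
    """Aggregated, normalized regions x genes expression.

    `values` rows are indexed by region_id; `interpolated` is True exactly
    for regions that had zero samples and were filled from neighbors.
    """

    values: pd.DataFrame
    n_samples: pd.Series
    interpolated: pd.Series

    def validate(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("regional expression contains missing values")
        if not ((self.n_samples == 0) == self.interpolated).all():
            raise ValueError("interpolated flags inconsistent with counts")


def select_probe_per_gene(
    probes: pd.DataFrame,
    expression: pd.DataFrame,
    cortical_mask: np.ndarray | pd.Series | None = None,
) -> tuple[dict[str, str], int]:
    """For each gene, pick the probe with highest mean expression across
    (cortical) samples; ties broken by lexicographically smaller probe_id.

    Probes without a gene symbol are excluded first.  Returns the
    gene -> probe_id map and the number of excluded probes.
    """
    expr = expression if cortical_mask is None else expression.loc[
        np.asarray(cortical_mask, bool)]
    means = expr.mean(axis=0)
    annotated = probes.dropna(subset=["gene_symbol"]).copy()
    n_excluded = len(probes) - len(annotated)
    annotated["mean_expr"] = annotated["probe_id"].map(means)
    if annotated["mean_expr"].isna().any():
        raise ValueError("probes without any sample values")
    annotated = annotated.sort_values(
        ["gene_symbol", "mean_expr", "probe_id"],
        ascending=[True, False, True],
    )
    best = annotated.groupby("gene_symbol", sort=True).first()
    return dict(zip(best.index, best["probe_id"])), n_excluded


def collapse_probes(expression: pd.DataFrame,
                    gene_probe: dict[str, str]) -> pd.DataFrame:
    """Samples x genes matrix using each gene's selected probe."""
    genes = sorted(gene_probe)
    out = expression[[gene_probe[g] for g in genes]].copy()
    out.columns = genes
    return out


def reflect_right_hemisphere(samples: pd.DataFrame) -> pd.DataFrame:
    """Mirror right-hemisphere samples to their contralateral position.

    The left-right axis is the x coordinate with midline at 0; reflected
    samples become left-hemisphere samples.  Left samples are unchanged.
    """
    out = samples.copy()
    right = out["hemisphere"] == "R"
    out.loc[right, "x"] = -out.loc[right, "x"]
    out.loc[right, "hemisphere"] = "L"
    return out


def assign_samples_to_parcels(
    samples: pd.DataFrame,
    atlas: ParcelAtlas,
    tolerance_mm: float = 2.0,
) -> tuple[pd.DataFrame, MappingReport]:
    """Map each cortical sample to the nearest parcel surface.

    A sample is assigned to the region whose surface point cloud is closest;
    the assignment is kept only if that distance is within `tolerance_mm`
    (the tolerance stands in for a volumetric parcellation dilated into the
    white matter).  Ties are broken by smaller distance then smaller
    region_id.  Non-cortical samples are dropped and counted.
    """
    left = atlas.left()
    if not left.surface_points:
        raise ValueError("atlas has no surface points; cannot assign samples")
    if (samples["hemisphere"] != "L").any():
        raise ValueError("samples must be reflected to the left hemisphere "
                         "before assignment")
    pts, owner = [], []
    for rid in left.region_id:
        sp = left.surface_points[int(rid)]
        pts.append(sp)
        owner.append(np.full(len(sp), rid))
    pts = np.vstack(pts)
    owner = np.concatenate(owner)
    tree = cKDTree(pts)

    report = MappingReport(n_input=len(samples))
    cortical = samples[samples["cortical"].astype(bool)]
    report.n_noncortical = len(samples) - len(cortical)

    coords = cortical[["x", "y", "z"]].to_numpy(float)
    k = min(8, len(pts))
    dist, idx = tree.query(coords, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    rows = []
    for s in range(len(cortical)):
        cand = {}
        for dd, ii in zip(dist[s], idx[s]):
            r = int(owner[ii])
            if r not in cand or dd < cand[r]:
                cand[r] = dd
        region, d = min(cand.items(), key=lambda kv: (kv[1], kv[0]))
        if d <= tolerance_mm:
            rows.append((cortical.iloc[s]["sample_id"],
                         cortical.iloc[s]["donor_id"], region, d))
        else:
            report.n_dropped_tolerance += 1
    report.n_assigned = len(rows)
    assignment = pd.DataFrame(
        rows, columns=["sample_id", "donor_id", "region_id", "distance_mm"])
    return assignment, report


def aggregate_regional_expression(
    sample_genes: pd.DataFrame,
    assignment: pd.DataFrame,
    atlas: ParcelAtlas,
) -> RegionalExpression:
    """Median normalized expression per region.

    Each gene is z-normalized within donor across that donor's assigned
    cortical samples (making donors with different raw scales
    commensurable), samples from all donors are pooled, and the per-region
    value is the median.  Regions with zero samples are filled with the
    unweighted mean of their spatially adjacent sampled regions and flagged
    as interpolated.
    """
    if assignment.empty:
        raise ValueError("no assigned samples to aggregate")
    left = atlas.left()
    x = sample_genes.loc[assignment["sample_id"]]
    z = np.empty_like(x.to_numpy(float))
    donors = assignment["donor_id"].to_numpy()
    for donor in np.unique(donors):
        mask = donors == donor
        block = x.to_numpy(float)[mask]
        mu = block.mean(0)
        sd = block.std(0)
        sd[sd == 0] = 1.0
        z[mask] = (block - mu) / sd
    zdf = pd.DataFrame(z, columns=x.columns)
    zdf["region_id"] = assignment["region_id"].to_numpy()
    med = zdf.groupby("region_id").median()
    counts = zdf.groupby("region_id").size()

    values = med.reindex(left.region_id)
    n_samples = counts.reindex(left.region_id).fillna(0).astype(int)
    interpolated = n_samples == 0
    adj = left.adjacency
    for pos, rid in enumerate(left.region_id):
        if not interpolated.loc[rid]:
            continue
        nbrs = left.region_id[np.flatnonzero(adj[pos])]
        sampled = [r for r in nbrs if r in med.index]
        if not sampled:
            raise ValueError(
                f"region {rid} has zero samples and no sampled neighbors; "
                "cannot interpolate")
        values.loc[rid] = med.loc[sampled].mean()
    out = RegionalExpression(values=values, n_samples=n_samples,
                             interpolated=interpolated)
    out.validate()
    return out
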