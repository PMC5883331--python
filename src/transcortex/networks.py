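"""Weighted correlation networks and density-thresholded binary graphs.

The structural covariance network (SCN) correlates cortical thickness
between regions across subjects; the transcriptional brain network (TBN)
correlates expression profiles between regions across genes.  Both are
binarized by retaining the top fraction ("connection density") of the most
strongly positive correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["WeightedNetwork", "BinaryGraph", "pearson_network",
           "binarize_density", "coexpression_network"]


@dataclass
class WeightedNetwork:
    """Symmetric regions x regions Pearson correlation matrix.

    The diagonal is not meaningful and is excluded from all statistics.
    `excluded` flags zero-variance columns whose correlations are NaN.
    """

    weights: np.ndarray
    kind: str = "SCN"
    region_id: np.ndarray | None = None
    excluded: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.weights)

    def upper_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n, 1)
        return self.weights[iu]

    def write(self, path: str | Path) -> None:
        ids = self.region_id if self.region_id is not None \
            else np.arange(1, self.n + 1)
        pd.DataFrame(self.weights, index=ids, columns=ids).to_csv(
            path, sep="\t")


@dataclass
class BinaryGraph:
    """Density-thresholded binary adjacency (symmetric, irreflexive)."""

    adjacency: np.ndarray
    density: float
    region_id: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.adjacency)

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> np.ndarray:
        """(m, 2) array of upper-triangle edge index pairs."""
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([ii, jj])

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(0).astype(int)

    def write_edgelist(self, path: str | Path,
                       weights: np.ndarray | None = None) -> None:
        ids = self.region_id if self.region_id is not None \
            else np.arange(1, self.n + 1)
        e = self.edges()
        df = pd.DataFrame({"region_i": ids[e[:, 0]], "region_j": ids[e[:, 1]]})
        if weights is not None:
            df["weight"] = weights[e[:, 0], e[:, 1]]
        df.to_csv(path, sep="\t", index=False)


def _residualize(x: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(x)), covariates])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def pearson_network(
    data: np.ndarray | pd.DataFrame,
    kind: str = "SCN",
    covariates: np.ndarray | None = None,
) -> WeightedNetwork:
    """Pairwise Pearson correlations between the columns of an
    observations x regions matrix.

    Optional covariates (e.g., subject age) are residualized from every
    column before correlating.  Zero-variance columns yield NaN rows and
    are flagged in `excluded`.
    """
    region_id = None
    if isinstance(data, pd.DataFrame):
        region_id = np.asarray(data.columns)
        data = data.to_numpy(float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 observations per pair")
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] == 1:
            cov = cov.T
        data = _residualize(data, cov)
    sd = data.std(axis=0)
    zero = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.corrcoef(data, rowvar=False)
    w[zero, :] = np.nan
    w[:, zero] = np.nan
    np.fill_diagonal(w, 1.0)
    return WeightedNetwork(weights=w, kind=kind, region_id=region_id,
                           excluded=zero)


def coexpression_network(
    regional_expression: pd.DataFrame, kind: str = "TBN"
) -> WeightedNetwork:
    """Region x region co-expression: Pearson correlation of regional
    profiles across genes, after z-scoring each gene across regions.

    Without the per-gene z-scoring, between-gene baseline differences
    dominate and all region pairs correlate near 1.
    """
    x = regional_expression.to_numpy(float)
    z = (x - x.mean(0)) / x.std(0)
    net = pearson_network(z.T, kind=kind)
    net.region_id = np.asarray(regional_expression.index)
    return net


def binarize_density(
    network: WeightedNetwork | np.ndarray, density: float
) -> BinaryGraph:
    """Retain exactly floor(density * N(N-1)/2) strongest positive weights.

    Ties at the cut are broken by larger weight, then by smaller (i, j)
    pair order.  Negative or zero correlations are never admitted.
    """
    if isinstance(network, WeightedNetwork):
        w, region_id = network.weights, network.region_id
    else:
        w, region_id = np.asarray(network, float), None
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = len(w)
    ii, jj = np.triu_indices(n, 1)
    vals = w[ii, jj]
    m_target = int(np.floor(density * n * (n - 1) / 2))
    pos = np.flatnonzero(np.nan_to_num(vals, nan=-np.inf) > 0)
    if len(pos) < m_target:
        raise ValueError(
            f"only {len(pos)} positive weights available, "
            f"{m_target} required at density {density}"
        )
    order = pos[np.lexsort((jj[pos], ii[pos], -vals[pos]))]
    keep = order[:m_target]
    adj = np.zeros((n, n), dtype=bool)
    adj[ii[keep], jj[keep]] = True
    adj |= adj.T
    return BinaryGraph(adjacency=adj, density=density, region_id=region_id)
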