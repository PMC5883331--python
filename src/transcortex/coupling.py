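"""Edge-, module-, node- and class-wise statistics coupling structural
covariance, gene co-expression, physical distance and gene sets.

All quantities live on the table of unordered region pairs: structural
covariance (Pearson r of thickness), whole-genome and per-set
co-expression, Euclidean distance, and the edge / non-edge indicator at a
given connection density.  Distance enters regressions as log distance
unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .atlas import ParcelAtlas
from .genesets import GeneSet
from .networks import BinaryGraph, WeightedNetwork, binarize_density, \
    coexpression_network
from .spatial import NullPartitionSet

__all__ = ["CouplingFit", "ModuleCoexprResult", "build_edge_table",
           "distance_decay_fit", "partial_edge_correlation",
           "intramodule_coexpression_test", "gene_set_index",
           "set_coexpression_screen", "nested_coupling_F",
           "edge_nonedge_contrast", "class_expression_test",
           "variance_partition"]


@dataclass
class CouplingFit:
    form: str
    coefficients: dict
    r2: float
    aic: float
    df_resid: int
    p_value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.aic):
            raise ValueError("AIC is not finite")


@dataclass
class ModuleCoexprResult:
    observed: float
    null: np.ndarray
    percentile95: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.observed > self.percentile95


def _upper(w: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(len(w), 1)
    return w[iu]


def build_edge_table(
    scn: WeightedNetwork,
    coexpr: dict[str, WeightedNetwork],
    atlas_left: ParcelAtlas,
    density: float = 0.10,
) -> pd.DataFrame:
    """One row per unordered region pair: structural covariance, each
    co-expression network, Euclidean distance, and edge membership of the
    SCN binarized at `density`."""
    n = scn.n
    if atlas_left.n_regions != n:
        raise ValueError("atlas and networks disagree on region count")
    for name, net in coexpr.items():
        if net.n != n:
            raise ValueError(f"co-expression network {name!r} has wrong size")
        if not np.allclose(net.weights, net.weights.T, equal_nan=True):
            raise ValueError(f"co-expression network {name!r} not symmetric")
    if not np.allclose(scn.weights, scn.weights.T, equal_nan=True):
        raise ValueError("SCN weights not symmetric")
    ii, jj = np.triu_indices(n, 1)
    graph = binarize_density(scn, density)
    table = pd.DataFrame({
        "region_i": atlas_left.region_id[ii],
        "region_j": atlas_left.region_id[jj],
        "scn": scn.weights[ii, jj],
        "distance_mm": atlas_left.distances()[ii, jj],
        "is_edge": graph.adjacency[ii, jj],
    })
    for name, net in coexpr.items():
        table[f"coexpr_{name}"] = net.weights[ii, jj]
    return table


# ------------------------------------------------------------- model fits


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(rss / n) + 2 * k


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    rss = float(((y - yhat) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return max(0.0, min(1.0, 1.0 - rss / tss))


def distance_decay_fit(y: np.ndarray, distance: np.ndarray,
                       form: str = "exponential") -> CouplingFit:
    """Least-squares fit of y against distance.

    Forms: 'linear' (y = b0 + b1 d) and 'exponential' (y = a exp(-d/lam),
    nonlinear least squares with a multistart over a decay-length grid).
    AIC uses the Gaussian form n ln(RSS/n) + 2k; only AIC orderings between
    forms are meaningful.
    """
    y = np.asarray(y, float)
    d = np.asarray(distance, float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 pairs")
    if form == "linear":
        design = np.column_stack([np.ones(n), d])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        yhat = design @ beta
        rss = float(((y - yhat) ** 2).sum())
        r2 = _r2(y, yhat)
        df = n - 2
        if r2 >= 1.0:
            f = np.inf
        else:
            f = (r2 / 1) / ((1 - r2) / df)
        p = float(stats.f.sf(f, 1, df)) if np.isfinite(f) else 0.0
        return CouplingFit(form="linear",
                           coefficients={"b0": beta[0], "b1": beta[1]},
                           r2=r2, aic=_aic(max(rss, 1e-300), n, 2),
                           df_resid=df, p_value=p)
    if form == "exponential":
        def model(dd, a, lam):
            return a * np.exp(-dd / lam)

        best = None
        for lam0 in (5.0, 10.0, 20.0, 40.0, 80.0, 160.0):
            try:
                popt, _ = optimize.curve_fit(
                    model, d, y, p0=[max(y.max(), 1e-3), lam0],
                    maxfev=10000)
            except RuntimeError:
                continue
            if popt[1] <= 0:
                continue
            rss = float(((y - model(d, *popt)) ** 2).sum())
            if best is None or rss < best[0]:
                best = (rss, popt)
        if best is None:
            raise RuntimeError("exponential fit failed over all starts")
        rss, popt = best
        yhat = model(d, *popt)
        r2 = _r2(y, yhat)
        df = n - 2
        if r2 >= 1.0:
            f = np.inf
        else:
            f = (r2 / 1) / ((1 - r2) / df)
        p = float(stats.f.sf(f, 1, df)) if np.isfinite(f) else 0.0
        return CouplingFit(form="exponential",
                           coefficients={"amplitude": popt[0],
                                         "decay_mm": popt[1]},
                           r2=r2, aic=_aic(max(rss, 1e-300), n, 2),
                           df_resid=df, p_value=p)
    raise ValueError(f"unknown form {form!r}")


def _residuals(v: np.ndarray, control: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), control])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_edge_correlation(x: np.ndarray, y: np.ndarray,
                             control: np.ndarray) -> CouplingFit:
    """Pearson correlation of x and y after residualizing both on a
    control variable (typically log distance); p from t with n-3 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    control = np.asarray(control, float)
    rx = _residuals(x, control)
    ry = _residuals(y, control)
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    df = n - 3
    if abs(r) >= 1.0:
        t, p = np.inf, 0.0
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    rss = float((ry ** 2).sum() * (1 - r * r))
    return CouplingFit(form="partial", coefficients={"r": r},
                       r2=r * r, aic=_aic(max(rss, 1e-300), n, 3),
                       df_resid=df, p_value=p)


# -------------------------------------------------------- module statistics


def _within_mean(w: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(w), 1)
    mask = same[iu]
    return float(w[iu][mask].mean())


def intramodule_coexpression_test(
    coexpr: WeightedNetwork | np.ndarray,
    labels: np.ndarray,
    null_set: NullPartitionSet,
) -> ModuleCoexprResult:
    """Mean co-expression over within-module region pairs, tested against
    the spatially contiguous permutation null.

    The permutation p-value follows the (1 + #{null >= observed}) /
    (1 + n_draws) convention; the 95th percentile of the null is the
    retention threshold.
    """
    w = coexpr.weights if isinstance(coexpr, WeightedNetwork) else \
        np.asarray(coexpr, float)
    labels = np.asarray(labels)
    observed = _within_mean(w, labels)
    null = np.array([_within_mean(w, null_labels)
                     for null_labels in null_set.labels])
    p = (1 + int((null >= observed).sum())) / (1 + len(null))
    return ModuleCoexprResult(observed=observed, null=null,
                              percentile95=float(np.percentile(null, 95)),
                              p_value=p)


# ------------------------------------------------------------ gene sets


def gene_set_index(regional: pd.DataFrame, gene_set: GeneSet
                   ) -> tuple[pd.Series, list[str]]:
    """Per-region gene-set expression index.

    Each set gene present in the matrix is z-scored across regions and the
    z-profiles are averaged.  Returns (index, missing symbols)."""
    present = [g for g in gene_set.genes if g in regional.columns]
    missing = [g for g in gene_set.genes if g not in regional.columns]
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} in the matrix")
    x = regional[present].to_numpy(float)
    z = (x - x.mean(0)) / x.std(0)
    return pd.Series(z.mean(1), index=regional.index,
                     name=f"{gene_set.name}_index"), missing


def set_coexpression_screen(
    regional: pd.DataFrame,
    gene_sets: list[GeneSet],
    scn: WeightedNetwork,
    distance: np.ndarray,
) -> pd.DataFrame:
    """Edge-wise coupling of each gene set's co-expression with structural
    covariance, raw and distance-corrected; one row per scoreable set.

    Sets with fewer than 2 genes present are skipped.  Output is ranked by
    raw R^2 (rank 1 = strongest coupling).
    """
    scn_vals = _upper(scn.weights)
    logd = np.log(_upper(np.asarray(distance, float)))
    rows = []
    for gs in gene_sets:
        present = [g for g in gs.genes if g in regional.columns]
        if len(present) < 2:
            continue
        net = coexpression_network(regional[present], kind=f"set:{gs.name}")
        vals = _upper(net.weights)
        r = float(np.corrcoef(vals, scn_vals)[0, 1])
        pc = partial_edge_correlation(vals, scn_vals, logd)
        rows.append((gs.name, len(present), r * r, pc.r2))
    out = pd.DataFrame(rows, columns=["set", "n_genes", "r2",
                                      "r2_distance_corrected"])
    out["rank"] = out["r2"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("rank").reset_index(drop=True)


# ------------------------------------------------------- nested F and OLS


def nested_coupling_F(
    scn_vals: np.ndarray,
    coexpr_a: np.ndarray,
    coexpr_b: np.ndarray,
    distance: np.ndarray,
) -> tuple[float, int, int, float]:
    """Does co-expression A explain structural covariance beyond
    co-expression B, after regressing out log distance from everything?

    Returns (F, df1, df2, p) comparing scn ~ B against scn ~ B + A on the
    distance-residualized variables; df1 = 1.
    """
    logd = np.log(np.asarray(distance, float))
    y = _residuals(np.asarray(scn_vals, float), logd)
    a = _residuals(np.asarray(coexpr_a, float), logd)
    b = _residuals(np.asarray(coexpr_b, float), logd)
    n = len(y)

    def rss(design):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return float(((y - design @ beta) ** 2).sum())

    ones = np.ones(n)
    rss0 = rss(np.column_stack([ones, b]))
    rss1 = rss(np.column_stack([ones, b, a]))
    df2 = n - 3
    f = ((rss0 - rss1) / 1) / (rss1 / df2)
    p = float(stats.f.sf(f, 1, df2))
    return float(f), 1, df2, p


@dataclass
class GroupContrast:
    mean_edges: float
    mean_nonedges: float
    t: float
    p_value: float
    n_edges: int
    n_nonedges: int


def edge_nonedge_contrast(edge_table: pd.DataFrame,
                          column: str) -> GroupContrast:
    """Mean of a pair-level quantity over SCN edges vs non-edges (Welch t
    reported descriptively)."""
    e = edge_table.loc[edge_table["is_edge"], column].to_numpy(float)
    ne = edge_table.loc[~edge_table["is_edge"], column].to_numpy(float)
    if len(e) == 0 or len(ne) == 0:
        raise ValueError("both edge and non-edge groups must be nonempty")
    t, p = stats.ttest_ind(e, ne, equal_var=False)
    return GroupContrast(mean_edges=float(e.mean()),
                         mean_nonedges=float(ne.mean()),
                         t=float(t), p_value=float(p),
                         n_edges=len(e), n_nonedges=len(ne))


def class_expression_test(index: pd.Series, ve_class: np.ndarray
                          ) -> pd.DataFrame:
    """Per cytoarchitectonic class: one-sample t of the regional set index
    against 0 (the whole-cortex mean on the z scale), Benjamini-Hochberg
    corrected across classes."""
    ve_class = np.asarray(ve_class)
    rows = []
    for cls in np.unique(ve_class):
        vals = index.to_numpy(float)[ve_class == cls]
        if len(vals) < 2:
            raise ValueError(f"class {cls} has fewer than 2 regions")
        t, p = stats.ttest_1samp(vals, 0.0)
        rows.append((int(cls), len(vals), float(vals.mean()), float(t),
                     float(p)))
    out = pd.DataFrame(rows, columns=["ve_class", "n_regions", "mean_index",
                                      "t", "p"])
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def variance_partition(
    scn_vals: np.ndarray,
    log_distance: np.ndarray,
    set_coexpr: np.ndarray,
    class_comembership: np.ndarray,
) -> dict[str, float]:
    """Single-predictor R^2 of structural covariance on log distance, set
    co-expression and same-class membership, plus the combined
    distance + co-expression model."""
    y = np.asarray(scn_vals, float)

    def ols_r2(*cols):
        design = np.column_stack([np.ones(len(y)), *cols])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return _r2(y, design @ beta)

    return {
        "log_distance": ols_r2(np.asarray(log_distance, float)),
        "set_coexpression": ols_r2(np.asarray(set_coexpr, float)),
        "class_comembership": ols_r2(np.asarray(class_comembership, float)),
        "distance_plus_coexpression": ols_r2(
            np.asarray(log_distance, float), np.asarray(set_coexpr, float)),
    }
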