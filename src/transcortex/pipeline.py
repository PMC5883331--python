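"""End-to-end runner: simulate -> map -> networks -> topology ->
communities -> spatial nulls -> coupling, emitting one machine-readable
report.

Null-ensemble and consensus sizes are configurable; the defaults here are
the package's desk-scale working sizes (the individual operations default
to the larger canonical ensemble sizes).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cp
from . import mapping as mp
from .communities import consensus_partition
from .genesets import GeneSet, hse_gene_set
from .networks import BinaryGraph, WeightedNetwork, binarize_density, \
    coexpression_network, pearson_network
from .simulate import SimulationConfig, SyntheticDataset, fullscale_config, \
    simulate_dataset
from .spatial import permute_modules
from .topology import degree_and_distance, global_metrics, \
    participation_coefficient, rewire_null, rich_club, small_worldness

log = logging.getLogger("transcortex")

__all__ = ["RunConfig", "PipelineResult", "map_expression", "run_pipeline"]


@dataclass
class RunConfig:
    densities: tuple[float, ...] = (0.05, 0.10, 0.15)
    gammas: tuple[float, ...] = (1.0, 2.0)
    density_main: float = 0.10
    n_rewire_nulls: int = 100
    n_spatial_nulls: int = 500
    consensus_runs: int = 100
    swaps_per_edge: int = 10
    n_random_sets: int = 100
    tolerance_mm: float = 2.0
    age_correct: bool = False
    seed: int = 0
    outdir: Path | None = None

    def __post_init__(self) -> None:
        if any(not 0 < d <= 1 for d in self.densities):
            raise ValueError("densities must lie in (0, 1]")


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    regional: mp.RegionalExpression
    scn: WeightedNetwork
    tbn: WeightedNetwork
    hse_net: WeightedNetwork
    edge_table: pd.DataFrame
    report: dict


def map_expression(dataset: SyntheticDataset, tolerance_mm: float = 2.0
                   ) -> tuple[mp.RegionalExpression, dict]:
    """Probe collapsing, reflection, parcel assignment and aggregation."""
    ex = dataset.expression
    gene_probe, n_excluded = mp.select_probe_per_gene(
        ex.probes, ex.expression, ex.samples["cortical"].to_numpy(bool))
    genes = mp.collapse_probes(ex.expression, gene_probe)
    reflected = mp.reflect_right_hemisphere(ex.samples)
    assignment, report = mp.assign_samples_to_parcels(
        reflected, dataset.atlas, tolerance_mm=tolerance_mm)
    regional = mp.aggregate_regional_expression(genes, assignment,
                                                dataset.atlas)
    info = report.as_dict()
    info["n_probes_unannotated"] = n_excluded
    info["n_regions_interpolated"] = int(regional.interpolated.sum())
    return regional, info


def _stage(name):
    t0 = time.time()
    log.info("stage %s", name)
    return t0


def run_pipeline(run: RunConfig,
                 sim: SimulationConfig | None = None) -> PipelineResult:
    """Run the full analysis on a synthetic cortex and return the report."""
    rng = np.random.default_rng(run.seed)
    sim = sim if sim is not None else fullscale_config(seed=run.seed)
    report: dict = {
        "seed": run.seed,
        "run_config": {k: (list(v) if isinstance(v, tuple) else
                           str(v) if isinstance(v, Path) else v)
                       for k, v in dataclasses.asdict(run).items()},
    }

    t0 = _stage("simulate")
    dataset = simulate_dataset(sim)
    left = dataset.atlas.left()
    dist = left.distances()

    _stage("map-expression")
    regional, map_info = map_expression(dataset, run.tolerance_mm)
    report["mapping"] = map_info

    _stage("networks")
    thickness = dataset.thickness
    covariates = thickness.attrs.get("age") if run.age_correct else None
    scn = pearson_network(thickness, kind="SCN", covariates=covariates)
    tbn = coexpression_network(regional.values, kind="TBN")
    hse = hse_gene_set()
    hse_present = [g for g in hse.genes if g in regional.values.columns]
    if len(hse_present) < 2:
        # preset without HSE-named genes: score the planted coupled set
        hse = GeneSet("coupled", tuple(dataset.expression.coupled_genes))
        hse_present = [g for g in hse.genes
                       if g in regional.values.columns]
    hse_net = coexpression_network(regional.values[hse_present],
                                   kind="coexpr_hse")

    _stage("topology")
    topo: dict = {}
    for name, net in (("SCN", scn), ("TBN", tbn)):
        topo[name] = {}
        for density in run.densities:
            graph = binarize_density(net, density)
            nulls = rewire_null(graph, n=run.n_rewire_nulls,
                                swaps_per_edge=run.swaps_per_edge,
                                seed=int(rng.integers(2**31 - 1)))
            gm = global_metrics(graph)
            sigma = small_worldness(graph, nulls)
            rc = rich_club(graph, nulls)
            valid = np.isfinite(rc.rho_norm)
            nodal, _ = degree_and_distance(graph, left)
            deg = nodal["degree"].to_numpy(float)
            mdist = nodal["mean_distance_mm"].to_numpy(float)
            ok = np.isfinite(mdist)
            r_dd = float(np.corrcoef(deg[ok], mdist[ok])[0, 1])
            entry = gm.as_dict()
            entry.update({
                "sigma": float(sigma),
                "rich_club_max_rho": float(np.nanmax(rc.rho_norm[valid]))
                if valid.any() else None,
                "degree_distance_r2": r_dd ** 2,
                "giant_component_fraction": _giant_fraction(graph),
            })
            topo[name][f"{density:g}"] = entry
    report["topology"] = topo

    _stage("communities")
    comm: dict = {}
    partitions: dict = {}
    for name, net in (("SCN", scn), ("TBN", tbn), ("HSE", hse_net)):
        comm[name] = {}
        densities = run.densities if name == "SCN" else (run.density_main,)
        for density in densities:
            graph = binarize_density(net, density)
            comm[name][f"{density:g}"] = {}
            for gamma in run.gammas:
                part = consensus_partition(
                    graph, gamma=gamma, runs=run.consensus_runs,
                    seed=int(rng.integers(2**31 - 1)))
                partitions[(name, density, gamma)] = part
                comm[name][f"{density:g}"][f"gamma{gamma:g}"] = {
                    "n_modules": part.n_modules,
                    "q": part.q,
                    "converged": part.converged,
                }
    report["communities"] = comm

    _stage("spatial-null + intramodule co-expression")
    intram: dict = {}
    for density in run.densities:
        for gamma in run.gammas:
            part = partitions[("SCN", density, gamma)]
            key = f"scn_d{density:g}_gamma{gamma:g}"
            try:
                nulls = permute_modules(part.labels, left,
                                        n=run.n_spatial_nulls,
                                        seed=int(rng.integers(2**31 - 1)))
            except ValueError as err:   # non-contiguous empirical module
                intram[key] = {"error": str(err)}
                continue
            res = cp.intramodule_coexpression_test(tbn, part.labels, nulls)
            intram[key] = {
                "observed": res.observed,
                "null_p95": res.percentile95,
                "p": res.p_value,
                "significant": res.significant,
            }
    ve_nulls = permute_modules(left.ve_class, left,
                               n=run.n_spatial_nulls,
                               seed=int(rng.integers(2**31 - 1)))
    ve_res = cp.intramodule_coexpression_test(tbn, left.ve_class, ve_nulls)
    intram["von_economo"] = {"observed": ve_res.observed,
                             "null_p95": ve_res.percentile95,
                             "p": ve_res.p_value,
                             "significant": ve_res.significant}
    report["intramodule_coexpression"] = intram

    _stage("coupling")
    edge_table = cp.build_edge_table(
        scn, {"genome": tbn, "hse": hse_net}, left, run.density_main)
    d = edge_table["distance_mm"].to_numpy(float)
    logd = np.log(d)
    scn_vals = edge_table["scn"].to_numpy(float)
    gen_vals = edge_table["coexpr_genome"].to_numpy(float)
    hse_vals = edge_table["coexpr_hse"].to_numpy(float)

    decay = {}
    for label, y in (("scn", scn_vals), ("coexpr_genome", gen_vals)):
        lin = cp.distance_decay_fit(y, d, "linear")
        expf = cp.distance_decay_fit(y, d, "exponential")
        decay[label] = {
            "linear_r2": lin.r2, "linear_aic": lin.aic,
            "exponential_r2": expf.r2, "exponential_aic": expf.aic,
            "exponential_better": expf.aic < lin.aic,
            "decay_mm": expf.coefficients["decay_mm"],
        }

    r_edge = float(np.corrcoef(gen_vals, scn_vals)[0, 1])
    r_hse = float(np.corrcoef(hse_vals, scn_vals)[0, 1])
    partial = cp.partial_edge_correlation(gen_vals, scn_vals, logd)
    fstat, df1, df2, fp = cp.nested_coupling_F(scn_vals, hse_vals, gen_vals, d)

    hse_index, missing = cp.gene_set_index(regional.values, hse)
    graph_main = binarize_density(scn, run.density_main)
    deg = graph_main.degree().astype(float)
    part_main = partitions[("SCN", run.density_main, run.gammas[0])]
    pcoef = participation_coefficient(graph_main, part_main.labels)
    r_deg = float(np.corrcoef(hse_index.to_numpy(float), deg)[0, 1])
    r_pc = float(np.corrcoef(hse_index.to_numpy(float), pcoef)[0, 1])
    classes = cp.class_expression_test(hse_index, left.ve_class)

    contrast_gen = cp.edge_nonedge_contrast(edge_table, "coexpr_genome")
    contrast_hse = cp.edge_nonedge_contrast(edge_table, "coexpr_hse")

    # Screen the planted/HSE set against size-matched random sets.
    gene_pool = [g for g in regional.values.columns if g not in hse_present]
    sets = [GeneSet("hse", tuple(hse_present))]
    for i in range(run.n_random_sets):
        pick = rng.choice(len(gene_pool), size=len(hse_present),
                          replace=False)
        sets.append(GeneSet(f"random_{i + 1:03d}",
                            tuple(gene_pool[j] for j in pick)))
    screen = cp.set_coexpression_screen(regional.values, sets, scn, dist)
    hse_rank = int(screen.loc[screen["set"] == "hse", "rank"].iloc[0])

    same_class = (left.ve_class[:, None] == left.ve_class[None, :])
    iu = np.triu_indices(left.n_regions, 1)
    varpart = cp.variance_partition(scn_vals, logd, hse_vals,
                                    same_class[iu].astype(float))

    report["coupling"] = {
        "edge_coupling_r2": r_edge ** 2,
        "edge_coupling_r2_distance_corrected": partial.r2,
        "hse_coupling_r2": r_hse ** 2,
        "distance_decay": decay,
        "nested_F": {"F": fstat, "df1": df1, "df2": df2, "p": fp},
        "hse_index": {
            "missing_genes": missing,
            "degree_r2": r_deg ** 2,
            "participation_r2": r_pc ** 2,
            "class_test": classes.to_dict(orient="records"),
        },
        "edge_nonedge": {
            "genome": dataclasses.asdict(contrast_gen),
            "hse": dataclasses.asdict(contrast_hse),
        },
        "set_screen": {
            "hse_rank": hse_rank,
            "n_sets": len(sets),
            "hse_r2": float(screen.loc[screen["set"] == "hse",
                                       "r2"].iloc[0]),
        },
        "variance_partition": varpart,
    }

    if run.outdir is not None:
        outdir = Path(run.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dataset.write(outdir / "data")
        regional.values.to_csv(outdir / "regional_expression.tsv", sep="\t")
        edge_table.to_csv(outdir / "edge_table.tsv", sep="\t", index=False)
        screen.to_csv(outdir / "set_screen.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=1,
                                                       default=_json_default))
    log.info("pipeline done in %.1f s", time.time() - t0)
    return PipelineResult(dataset=dataset, regional=regional, scn=scn,
                          tbn=tbn, hse_net=hse_net, edge_table=edge_table,
                          report=report)


def _giant_fraction(graph: BinaryGraph) -> float:
    import networkx as nx
    g = nx.from_numpy_array(graph.adjacency)
    return max(len(c) for c in nx.connected_components(g)) / graph.n


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
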