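"""Couple the two networks edge-wise: distance decay of both (linear vs
exponential by AIC), co-expression vs structural covariance (raw and
distance-corrected), the HSE gene-set analyses (regional index vs degree
and cytoarchitectonic class, screen against random sets, nested F), and
the variance partition of structural covariance.
"""

import json

import numpy as np

import transcortex as tx
from common import DENSITY, dataset, networks, outdir, regional
from transcortex import coupling as cp
from transcortex.communities import consensus_partition
from transcortex.topology import participation_coefficient

ds = dataset()
left = ds.atlas.left()
reg, _ = regional()
scn, tbn, hse_net = networks()
out = outdir()

table = cp.build_edge_table(scn, {"genome": tbn, "hse": hse_net}, left,
                            DENSITY)
table.to_csv(out / "edge_table.tsv", sep="\t", index=False)
d = table["distance_mm"].to_numpy()
report = {}

for label, y in (("scn", table["scn"]), ("tbn", table["coexpr_genome"])):
    lin = cp.distance_decay_fit(y, d, "linear")
    exp = cp.distance_decay_fit(y, d, "exponential")
    best = "exponential" if exp.aic < lin.aic else "linear"
    report[f"{label}_decay"] = {"linear_aic": lin.aic,
                                "exponential_aic": exp.aic, "best": best}
    print(f"{label.upper()} vs distance: linear R^2={lin.r2:.2f}, "
          f"exponential R^2={exp.r2:.2f}; AIC prefers {best}")

r = np.corrcoef(table["coexpr_genome"], table["scn"])[0, 1]
partial = cp.partial_edge_correlation(table["coexpr_genome"], table["scn"],
                                      np.log(d))
r_hse = np.corrcoef(table["coexpr_hse"], table["scn"])[0, 1]
print(f"co-expression ~ structural covariance: R^2={r*r:.3f} "
      f"(distance-corrected {partial.r2:.3f}); HSE co-expression "
      f"R^2={r_hse**2:.3f}")

f, df1, df2, p = cp.nested_coupling_F(table["scn"], table["coexpr_hse"],
                                      table["coexpr_genome"], d)
print(f"HSE beyond genome (distance regressed out): "
      f"F({df1},{df2}) = {f:.0f}, p = {p:.2g}")

hse = tx.hse_gene_set()
index, missing = cp.gene_set_index(reg.values, hse)
graph = tx.binarize_density(scn, DENSITY)
part = consensus_partition(graph, gamma=1.0, runs=100, seed=15)
pc = participation_coefficient(graph, part.labels)
deg = graph.degree().astype(float)
r_deg = np.corrcoef(index, deg)[0, 1]
r_pc = np.corrcoef(index, pc)[0, 1]
classes = cp.class_expression_test(index, left.ve_class)
classes.to_csv(out / "hse_class_test.tsv", sep="\t", index=False)
print(f"HSE index ~ degree R^2={r_deg**2:.2f}; ~ participation "
      f"R^2={r_pc**2:.2f}")
sig = classes.loc[classes["p_fdr"] < 0.05, "ve_class"].tolist()
print(f"classes with HSE index different from cortical mean (FDR<.05): "
      f"{sig or 'none'}")

for set_label, col in (("genome", "coexpr_genome"), ("hse", "coexpr_hse")):
    con = cp.edge_nonedge_contrast(table, col)
    print(f"{set_label}: co-expression {con.mean_edges:.3f} on SCN edges "
          f"vs {con.mean_nonedges:.3f} on non-edges")

rng = np.random.default_rng(77)
present = [g for g in hse.genes if g in reg.values.columns]
pool = [g for g in reg.values.columns if g not in present]
sets = [tx.GeneSet("hse", tuple(present))]
for i in range(100):
    pick = rng.choice(len(pool), len(present), replace=False)
    sets.append(tx.GeneSet(f"random_{i:03d}", tuple(pool[j] for j in pick)))
screen = cp.set_coexpression_screen(reg.values, sets, scn, left.distances())
screen.to_csv(out / "set_screen.tsv", sep="\t", index=False)
rank = int(screen.loc[screen["set"] == "hse", "rank"].iloc[0])
print(f"HSE set ranks {rank} of {len(sets)} in SCN coupling")

same_class = left.ve_class[:, None] == left.ve_class[None, :]
iu = np.triu_indices(left.n_regions, 1)
vp = cp.variance_partition(table["scn"], np.log(d), table["coexpr_hse"],
                           same_class[iu].astype(float))
report["variance_partition"] = vp
print("variance of structural covariance explained: "
      f"log distance {vp['log_distance']:.0%}, HSE co-expression "
      f"{vp['set_coexpression']:.0%}, class co-membership "
      f"{vp['class_comembership']:.0%}, distance+HSE combined "
      f"{vp['distance_plus_coexpression']:.0%}")
(out / "coupling_report.json").write_text(json.dumps(report, indent=1))
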