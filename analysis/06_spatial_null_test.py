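"""Is whole-genome co-expression elevated within SCN modules?  Compare the
mean within-module co-expression against 1000 pseudo-random partitions
that preserve module number, sizes and spatial contiguity; repeat for the
cytoarchitectonic (von Economo) classes.
"""

import json

import transcortex as tx
from common import DENSITY, dataset, networks, outdir
from transcortex import coupling as cp
from transcortex.communities import consensus_partition
from transcortex.spatial import permute_modules

ds = dataset()
left = ds.atlas.left()
scn, tbn, _ = networks()
graph = tx.binarize_density(scn, DENSITY)
part = consensus_partition(graph, gamma=1.0, runs=100, seed=15)

results = {}
for label, labels in (("scn_modules", part.labels),
                      ("von_economo", left.ve_class)):
    nulls = permute_modules(labels, left, n=1000, seed=6)
    res = cp.intramodule_coexpression_test(tbn, labels, nulls)
    results[label] = {"observed": res.observed,
                      "null_p95": res.percentile95,
                      "p": res.p_value}
    verdict = "exceeds" if res.significant else "does not exceed"
    print(f"{label}: within-group co-expression {res.observed:.3f} "
          f"{verdict} the null 95th percentile {res.percentile95:.3f} "
          f"(p = {res.p_value:.4f})")
(outdir() / "spatial_null_test.json").write_text(
    json.dumps(results, indent=1))
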