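"""Consensus Louvain communities of the SCN and TBN at resolutions 1 and 2
(100 runs per consensus iteration), compared with the planted partition.
"""

from sklearn.metrics import adjusted_rand_score

import transcortex as tx
from common import DENSITY, dataset, networks, outdir
from transcortex.communities import consensus_partition

ds = dataset()
left = ds.atlas.left()
scn, tbn, hse_net = networks()
out = outdir()
for name, net in (("SCN", scn), ("TBN", tbn), ("HSE", hse_net)):
    for gamma in (1.0, 2.0):
        graph = tx.binarize_density(net, DENSITY)
        part = consensus_partition(graph, gamma=gamma, runs=100,
                                   seed=int(gamma * 10) + 5)
        part.to_frame(left.region_id).to_csv(
            out / f"partition_{name.lower()}_gamma{gamma:g}.tsv",
            sep="\t", index=False)
        ari = adjusted_rand_score(ds.planted_partition, part.labels)
        print(f"{name} gamma={gamma:g}: {part.n_modules} modules, "
              f"Q={part.q:.3f}, ARI vs planted modules {ari:.2f}")
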