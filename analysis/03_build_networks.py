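"""Build the structural covariance network (inter-regional Pearson
correlation of thickness) and the transcriptional brain network
(inter-regional correlation of expression profiles), then binarize both at
5/10/15% connection density, keeping only the strongest positive weights.
"""

import networkx as nx
import numpy as np

import transcortex as tx
from common import networks, outdir

scn, tbn, hse_net = networks()
out = outdir()
scn.write(out / "scn_weights.tsv")
tbn.write(out / "tbn_weights.tsv")

for name, net in (("scn", scn), ("tbn", tbn)):
    for density in (0.05, 0.10, 0.15):
        graph = tx.binarize_density(net, density)
        graph.write_edgelist(out / f"{name}_edges_d{int(density*100)}.tsv",
                             weights=net.weights)
        g = nx.from_numpy_array(graph.adjacency)
        giant = max(len(c) for c in nx.connected_components(g)) / graph.n
        print(f"{name.upper()} at {density:.0%}: {graph.edge_count} edges, "
              f"giant component {giant:.0%}")

iu = np.triu_indices(scn.n, 1)
r = np.corrcoef(scn.weights[iu], tbn.weights[iu])[0, 1]
print(f"edge-wise SCN~TBN correlation: r = {r:.3f} (R^2 = {r*r:.3f})")
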