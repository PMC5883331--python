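"""Generate the synthetic cortex: a 152-parcel hemisphere (mirrored), a
296-subject cortical-thickness table with 9 planted contiguous covariance
modules, and 6 donors' worth of expression samples with a 19-gene coupled
set carrying the HSE gene symbols.

Writes the data tables and planted truth under results/analysis/data/.
"""

import numpy as np

from common import dataset, outdir

ds = dataset()
out = outdir() / "data"
ds.write(out)

left = ds.atlas.left()
mods, sizes = np.unique(ds.planted_partition, return_counts=True)
samples = ds.expression.samples
print(f"atlas: {left.n_regions} left parcels "
      f"(+{left.n_regions} mirrored), 7 cytoarchitectonic classes")
print(f"thickness: {ds.thickness.shape[0]} subjects x "
      f"{ds.thickness.shape[1]} parcels")
print(f"planted modules: {len(mods)} with sizes "
      f"{sorted(int(s) for s in sizes)}")
print(f"expression: {len(samples)} samples "
      f"({(samples['hemisphere'] == 'R').sum()} right-hemisphere, "
      f"{(~samples['cortical'].astype(bool)).sum()} non-cortical), "
      f"{ds.expression.expression.shape[1]} probes, "
      f"{len(ds.expression.gene_names)} genes")
print(f"coupled set ({len(ds.expression.coupled_genes)} genes): "
      f"{', '.join(sorted(ds.expression.coupled_genes)[:6])}, ...")
print(f"deliberately empty parcel: {ds.expression.empty_region}")
print(f"wrote tables to {out}")
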