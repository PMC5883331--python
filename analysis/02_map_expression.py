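"""Map donor samples to parcels and build the regions x genes matrix:
probes collapse to their highest-expressing gene probe, right-hemisphere
samples reflect across the midline, samples land in the parcel whose
surface is within 2 mm, and per-region values are medians of within-donor
z-normalized expression (empty parcels interpolated from neighbors).
"""

import json

from common import outdir, regional

reg, info = regional()
out = outdir()
reg.values.to_csv(out / "regional_expression.tsv", sep="\t")
reg.n_samples.to_frame("n_samples").to_csv(out / "samples_per_region.tsv",
                                           sep="\t")
(out / "mapping_report.json").write_text(json.dumps(info, indent=1))

frac = info["n_assigned"] / (info["n_input"] - info["n_noncortical"])
print(f"samples: {info['n_input']} in, {info['n_noncortical']} non-cortical "
      f"excluded, {info['n_assigned']} assigned ({frac:.0%} of cortical), "
      f"{info['n_dropped_tolerance']} beyond the 2 mm tolerance")
print(f"regional matrix: {reg.values.shape[0]} regions x "
      f"{reg.values.shape[1]} genes; "
      f"{info['n_regions_interpolated']} region(s) interpolated")
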