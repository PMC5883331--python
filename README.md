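# transcortex

Coupling a **structural covariance network** (SCN) of the human cortex to a
**transcriptional brain network** (TBN), end to end, on a fully synthetic
cortex.

Structural covariance networks link cortical regions whose thickness
co-varies across subjects; transcriptional brain networks link regions
whose gene-expression profiles correlate across genes. Both are spatially
embedded graphs, both decay with distance, and the open question this
pipeline quantifies is how far their edge weights and community structures
are coupled — and how much of that coupling is carried by a small set of
genes enriched in the supragranular layers of human cortex (the 19-gene
HSE set: *BEND5, C1QL2, CACNA1E, COL24A1, COL6A1, CRYM, KCNC3, KCNH4,
LGALS1, MFGE8, NEFH, PRSS12, SCN3B, SCN4B, SNCG, SV2C, SYT2, TPBG,
VAMP1*), versus the shared constraint of physical distance.

Because the source datasets (a cohort MRI thickness table and the donor
microarray atlas) cannot be redistributed, the package ships a
first-class synthetic-cortex generator with planted, recoverable
structure, so that every stage of the analysis is testable: the generator
defines the truth, the pipeline has to find it.

## What the pipeline computes

1. **Synthetic cortex** (`transcortex.simulate`) — a half-ellipsoid
   hemisphere parcellated into 152 regions (mirrored to two hemispheres),
   thickness for 296 subjects drawn from a correlation matrix
   `C = b·exp(−d/λ) + m·1[same module] + low-rank non-spatial term`,
   and six donors' expression samples (multiple probes per gene,
   right-hemisphere samples, samples displaced into white matter, one
   deliberately empty parcel) with a planted 19-gene set whose regional
   profile tracks the covariance-graph degree.
2. **Expression mapping** (`transcortex.mapping`) — probe→gene collapsing
   (highest mean expression), midline reflection, sample→parcel assignment
   with a 2 mm white-matter tolerance, within-donor z-normalization,
   per-region medians, neighbor interpolation of empty parcels.
3. **Networks** (`transcortex.networks`) — Pearson correlation matrices
   and density thresholding: keep exactly ⌊ρ·N(N−1)/2⌋ most strongly
   positive weights (ρ ∈ {5, 10, 15}%).
4. **Topology** (`transcortex.topology`) — Cp, Lp, E_loc, E_glob,
   assortativity, small-worldness σ = (Cp/⟨Cp_rand⟩)/(Lp/⟨Lp_rand⟩),
   normalized rich club Φ(k)/⟨Φ_rand(k)⟩ against degree-preserving rewired
   nulls, degree vs connection distance, participation coefficient
   P_i = 1 − Σ_s (k_is/k_i)².
5. **Communities** (`transcortex.communities`) — Louvain maximizing
   Q = (1/2m) Σ_ij (A_ij − γ k_i k_j / 2m) δ(s_i, s_j), with consensus
   clustering of the co-assignment matrix at γ = 1 and 2.
6. **Spatial null** (`transcortex.spatial`) — pseudo-random partitions
   preserving module number, sizes and spatial contiguity, for
   permutation tests of within-module statistics.
7. **Coupling statistics** (`transcortex.coupling`) — distance-decay model
   selection by AIC (linear vs `a·exp(−d/λ)`), edge-wise coupling R²,
   distance-corrected partial correlations, within-module co-expression
   vs the spatial null, the HSE regional index (mean of per-gene
   z-profiles), a screen of the HSE set against size-matched random sets,
   a nested F for HSE-beyond-genome coupling, and a variance partition of
   structural covariance.

## Worked example

The numbered drivers under `analysis/` run the full study on the
`fullscale` preset (seed 0) and write tables under `results/analysis/`:

```bash
cd analysis
python 01_simulate_cortex.py
python 06_spatial_null_test.py
python 07_coupling_statistics.py
```

prints, among other lines:

```
planted modules: 9 with sizes [9, 12, 12, 13, 13, 22, 23, 24, 24]
scn_modules: within-group co-expression 0.384 exceeds the null 95th
  percentile 0.327 (p = 0.0010)
SCN vs distance: linear R^2=0.15, exponential R^2=0.21; AIC prefers exponential
co-expression ~ structural covariance: R^2=0.272 (distance-corrected 0.120);
  HSE co-expression R^2=0.445
HSE set ranks 1 of 101 in SCN coupling
genome: co-expression 0.382 on SCN edges vs -0.050 on non-edges
```

Reading: the consensus communities of the thickness-covariance graph
recover the 9 planted modules exactly; whole-genome co-expression is
significantly elevated inside those modules relative to 1000 size- and
contiguity-preserving random placements; structural covariance decays
exponentially with distance (recovered decay length ≈ 28 mm vs 30 mm
planted); the planted HSE-like set couples to structural covariance more
strongly than the whole genome and than every size-matched random set;
and unconnected region pairs have co-expression near zero. The same
qualitative pattern holds at 5% and 15% density and at γ = 2 (see the
pipeline report).

The same run is available as one command:

```bash
transcortex run --preset fullscale --seed 0 --out results/run0
```

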