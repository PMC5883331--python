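# Methods

## The synthetic cortex

The analysis consumes only parcel centroids, Euclidean distances, spatial
adjacency, class labels, and per-sample coordinates, so the geometric
substrate is an idealized half-ellipsoid shell (semi-axes 65 × 90 × 60 mm)
rather than a folded surface. Points sampled on the left half are
clustered by k-means into parcels (default 152, matching a high-resolution
subdivision of a standard atlas at ~500 mm² per parcel); parcel adjacency
comes from the Delaunay triangulation of parcel centers in surface
coordinates, which guarantees a connected spatial graph; the right
hemisphere is an exact mirror. Seven cytoarchitectonic ("von Economo")
classes are grown as contiguous patches by seeded region growth. The
minimum atlas size is 14 parcels so that each of the 7 classes has at
least two regions.

### Thickness and the planted covariance

Subject thickness rows are i.i.d. draws from a multivariate normal whose
correlation matrix is

    C = b·exp(−d_ij/λ) + m·1[same planted module] + E,   diag(C) = 1,

with defaults b = 0.25 (`base_corr`), λ = 30 mm (`decay_length`), m = 0.5
(`module_effect`) on 9 contiguous planted modules, and E a rank-5
non-spatial component (`nonspatial_effect` = 0.6 amplitude, row-normalized
loadings, so E is PSD by construction). E models the large fraction of
structural covariance that physical geometry does not explain; with it the
synthetic SCN–distance R² lands near 0.16, the regime reported for real
cortical thickness covariance, instead of the ~0.35 a purely geometric
target produces. C is projected to the nearest PSD correlation matrix by
eigenvalue clipping; for the shipped presets the projection changes C by
~2.4% in Frobenius norm (tolerance 10%, enforced). Mean regional thickness
is ~2.5 mm (sd 0.25 mm across subjects). An optional linear age covariate
(−0.02 mm/yr, subjects 14–25 y) supports the age-correction robustness
check; it is off by default.

### Expression

Gene regional profiles combine three components:

* a spatial Gaussian process with covariance exp(−d/λ_expr), λ_expr =
  60 mm (`expression_decay_length`) — co-expression decays more slowly
  with distance than structural covariance does;
* a weak module-aligned component shared by all genes
  (`genome_module_strength` = 0.3): regions of the same planted
  architectonic unit express more similarly, which is what makes
  whole-genome co-expression detectably elevated within covariance
  modules;
* for the planted coupled set (default 19 genes, named with the HSE
  symbols in the `fullscale` preset): profile_g = c·(w_g·z(degree) + t_g)
  + (1−c)·spatial_g + σ·ε, where z(degree) is the z-scored degree of the
  planted covariance graph at 10% density, w_g ~ N(1, 0.2), and t_g are
  draws from the planted covariance C centered across the set. The
  centering makes the noiseless c = 1 limit exact (the set's mean
  expression correlates 1.0 with planted degree) while the t_g give the
  set's co-expression the full covariance structure — expression-level
  coupling alone cancels out of across-gene correlations and produces no
  co-expression coupling. Default c = 0.9 (`coupling_strength`), σ = 0.3.

Per donor (6 by default, the last 2 also sampling the right hemisphere at
mirrored coordinates), samples are placed at parcel surface points:
80% on the surface, 12% displaced 0.3–1.6 mm outward ("into white
matter", inside the 2 mm tolerance), 8% displaced 4–8 mm (dropped by
assignment); a few non-cortical samples per donor carry unrelated values.
Per-region sampling rates are heterogeneous (Gamma-distributed, floored
so unplanned empty parcels stay rare); one designated parcel receives no
samples at all, exercising interpolation. Donor scale and offset are
random affine transforms (removed exactly by within-donor
z-normalization). Each gene emits 1..k probes (k = 3) with distinct
offsets; a handful of probes carry no gene annotation. Sampling density
per parcel is a parameter (`samples_per_region`, default 1.5 per donor)
because real donor atlases vary widely in per-region sample counts.

All randomness descends from one master seed through per-operation child
streams, so outputs are bitwise reproducible and adding an operation does
not perturb the others.

## Mapping

Probes without a gene symbol are excluded; for multi-probe genes the
probe with the highest mean expression across cortical samples is kept
(ties: lexicographically smaller probe id). Right-hemisphere samples are
reflected by negating the left–right coordinate. A sample is assigned to
the parcel with the nearest surface point if that distance is ≤ 2 mm
(standing in for a volumetric parcellation dilated 2 mm into white
matter); ties break by distance then region id. "Median normalized
expression" is realized as: z-normalize each gene within donor across
that donor's assigned samples, pool donors, take the per-region median.
Within-donor z is the minimal normalization making donors with different
raw scales commensurable, and makes aggregation exactly invariant to any
within-donor affine rescaling. Parcels with zero samples receive the
unweighted mean of their spatially adjacent sampled parcels and are
flagged; a parcel with no sampled neighbor is an error.

## Networks

The SCN is the subjects×regions Pearson correlation matrix (optionally
after residualizing covariates such as age from every column).
Region–region co-expression is computed after z-scoring each gene across
regions; without this, gene-baseline differences dominate and every
region pair correlates near 1. Binarization keeps exactly
⌊ρ·N(N−1)/2⌋ strongest strictly positive weights (ties: larger weight,
then smaller pair index); negative correlations are never admitted even
if ρ demands more edges.

## Topology

Metrics follow the standard binary-graph conventions: Cp is the mean
nodal clustering; Lp averages shortest paths over reachable pairs only;
E_glob counts unreachable pairs as zero contribution; E_loc is the mean
over nodes of E_glob of the neighbor-induced subgraph; assortativity is
the Pearson correlation of degrees over edge endpoints. σ uses the
clustering/path-length ratio form, normalized by degree-preserving
rewired graphs (double-edge swaps, 10 accepted swaps per edge,
connectedness not enforced). Rich club: Φ(k) = 2E_{>k}/(N_{>k}(N_{>k}−1))
for N_{>k} ≥ 2, normalized by the null ensemble mean where positive.
Graph metrics are delegated to networkx where it implements the exact
convention; rich club, participation coefficient, rewiring and Q are
implemented here, and everything is verified against brute-force oracles
in the test suite.

## Communities

Louvain maximizes the Newman–Girvan modularity with the resolution γ
multiplying the degree-based null term. Q is reported on the standard
1/(2m) normalization — the printed 1/(4m) variant of the same quantity
has an identical argmax, and the widely used Louvain implementation this
analysis follows reports 1/(2m). Consensus: R runs (R = 1000 canonical;
the pipeline presets use 60–100) build the co-assignment fraction matrix,
which is reclustered as a weighted graph, iterating until every run of an
iteration returns the identical partition (at most 10 iterations; the
result carries a convergence flag). Labels are canonicalized by
descending module size. Louvain is a greedy local-move heuristic: on
structureless graphs it (and every other local-move method, including
single-node hill climbing and Leiden) can terminate in a basin strictly
below the global modularity optimum; the oracle tests therefore enumerate
partitions exhaustively on small *structured* graphs, where the optimum
is reachable.

## Spatial null

Within-module statistics are biased by the number, sizes and compactness
of modules, so chance is modeled by pseudo-random partitions preserving
module number, size multiset, and per-module spatial contiguity.
Realization (grow-then-repair): modules are seeded at random parcels with
their source sizes as quotas and grown in rounds, each unfilled module
claiming its unclaimed spatial neighbor nearest to its running centroid;
once the cortex is covered, quota imbalances are repaired by transferring
boundary parcels from over-quota to adjacent under-quota modules, only
when the donor remains connected; unrepairable draws are rejected and
resampled (acceptance ≈ 0.16 on a 9-module, 152-parcel partition). A
sequential largest-first growth was tried first and accepts < 1% of
draws — leftover space fragments — which is infeasible at n = 1000.
Accepted draws satisfy the constraints exactly (oracle-verified in
tests). The permutation p-value is (1 + #{null ≥ observed})/(1 + n) and
the 95th percentile of the null is the retention threshold.

Calibration: the test is exchangeable — hence exact — when the observed
partition is itself a draw from the same contiguous ensemble; the
calibration experiment therefore redraws both decoupled expression and a
source partition per replicate (measured type-I rate ≈ 4–5% at the 95th
percentile). When the observed partition comes from consensus Louvain its
compactness profile can differ from the null ensemble's, which makes the
test conservative (measured ≈ 1% under the null), never anti-conservative
in our conditions.

## Coupling statistics

Distance enters regressions as log distance. Model selection between
y = β₀ + β₁d and y = α·exp(−d/λ) uses least squares (the exponential by
multistart nonlinear least squares over λ ∈ {5…160} mm) and the Gaussian
AIC n·ln(RSS/n) + 2k; only the ordering between forms is meaningful. The
offset-free exponential cannot go negative, so on synthetic data — where
normalized co-expression is slightly negative at long range — the TBN
decay can prefer the linear form; the SCN ordering (exponential) is the
robust one. Partial correlations residualize both variables on log
distance (p from t, n−3 df). The HSE-beyond-genome test is a nested OLS F
on distance-residualized variables: scn ~ genome vs scn ~ genome + HSE,
df = (1, n_pairs − 3). The per-set screen correlates each set's
co-expression (≥ 2 genes present) with SCN weights across all pairs, raw
and distance-corrected; whether the source study distance-corrected its
screen is unknowable from the text, so both are emitted. Gene-set
regional indices average per-gene z-profiles. Class tests are one-sample
t tests of the index against 0 per cytoarchitectonic class with
Benjamini–Hochberg correction across the 7 classes. The variance
partition reports single-predictor OLS R² for log distance, set
co-expression and same-class membership, plus the two-predictor
distance + co-expression model.

## Problem sizes and defaults

The `fullscale` preset: 152 parcels, 296 subjects, 600 genes, 6 donors,
9 planted modules, 19-gene coupled set. Pipeline ensembles default to
100 rewired nulls, 500 spatial-null draws and 100 consensus runs per
iteration (the canonical per-operation defaults remain 1000); the
acceptance script uses 50/300/60. These sizes are the package's
desk-scale choices; every ensemble statistic reported was stable to
re-seeding at these sizes (null-ensemble means stable to ~2%).

## What passing tests do and do not show

The generator plants exactly the structures the analysis is designed to
detect: modular covariance with distance decay, spatially autocorrelated
expression with a module-aligned component, and one degree-coupled gene
set. Passing recovery tests therefore demonstrates that the machinery
detects planted effects at realistic sizes and calibrates correctly under
the null — not that real cortex has these effects at these magnitudes.
Real data differ in ways the generator does not emulate: folded geometry
(geodesic vs Euclidean distance), non-Gaussian thickness noise, donor
batch structure beyond affine scale, probe-level cross-hybridization, and
expression gradients that are neither modular nor exponential. Headline
effect sizes measured here (e.g., coupling R²) are properties of the
preset, not predictions for any cohort.

## Known limitations

* The spatial null redraws compact contiguous modules; against
  empirically less-compact partitions the permutation test is
  conservative.
* The exponential decay model has no offset term, by design parity with
  the linear alternative; co-expression with a negative long-range tail
  can prefer the linear form.
* Consensus clustering returns the stable partition, which on ambiguous
  graphs is not the maximum-modularity partition.
* Sample→parcel assignment uses point-cloud distances to an idealized
  shell; parcel "containment" is distance-0 membership, and parcel
  centroids of very coarse atlases can sit deeper than the 2 mm
  tolerance.
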