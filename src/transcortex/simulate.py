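"""Synthetic cortex generator.

Emulates the statistical structure the downstream analysis assumes:

* a subjects x regions cortical-thickness table whose inter-regional
  correlation has a distance-decay component plus a planted modular
  increment (the substrate of the structural covariance network);
* a donor expression-sample table (multiple donors, multiple probes per
  gene, under- and over-sampled parcels, right-hemisphere samples, samples
  displaced into "white matter", one deliberately empty parcel) whose
  regional gene profiles follow an exponential spatial autocorrelation,
  with one planted gene set whose regional profile is a noisy affine
  function of the planted covariance-graph degree.

All randomness flows from a master seed through per-operation child
streams, so adding an operation does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas, grow_contiguous_patches, make_atlas
from .genesets import hse_gene_set

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "planted_correlation",
    "nearest_psd_correlation",
    "simulate_thickness",
    "simulate_expression",
    "simulate_dataset",
    "fullscale_config",
    "reduced_config",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cortex.

    Correlation-scale parameters (`base_corr`, `module_effect`,
    `coupling_strength`) are unitless; `decay_length` is in mm.
    """

    n_regions: int = 152          # per hemisphere
    n_subjects: int = 296
    n_genes: int = 600
    n_probes_per_gene: int = 3    # per-gene probe count drawn uniformly 1..k
    n_donors: int = 6
    n_modules: int = 9            # planted contiguous modules (if no partition given)
    planted_partition: np.ndarray | None = None
    base_corr: float = 0.25       # amplitude of the distance-decay correlation
    module_effect: float = 0.5    # within-module correlation increment
    decay_length: float = 30.0    # mm; thickness-covariance decay; <=0 disables
    expression_decay_length: float = 60.0  # mm; expression autocorrelation
    #   (gene co-expression decays more slowly with distance than structural
    #   covariance does)
    nonspatial_effect: float = 0.6  # amplitude of low-rank non-geometric
    #   structural covariance (the part of the SCN that distance cannot
    #   explain and that the coupled gene set tracks)
    nonspatial_rank: int = 5
    coupled_set_size: int = 19
    coupling_strength: float = 0.9  # in [0,1]; degree-coupling of the planted set
    genome_module_strength: float = 0.3  # in [0,1); module-aligned component
    #   shared by all genes (transcriptional similarity within planted
    #   architectonic units); 0 decouples expression from the partition
    noise_sd: float = 0.3         # residual noise on coupled-gene profiles
    samples_per_region: float = 1.5  # mean samples per region per donor
    sample_noise_sd: float = 0.25
    probe_noise_sd: float = 0.1
    n_unannotated_probes: int = 5
    n_noncortical_samples: int = 4  # per donor
    n_right_donors: int = 2       # donors that also sample the right hemisphere
    coupled_set_symbols: tuple[str, ...] | None = None  # names for coupled genes
    age_effect: bool = False
    age_slope: float = -0.02      # mm per year, applied uniformly when age_effect
    psd_tolerance: float = 0.10   # max relative Frobenius change of PSD projection
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_regions", "n_subjects", "n_genes", "n_probes_per_gene",
                     "n_donors", "n_modules", "coupled_set_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")
        if self.coupled_set_size > self.n_genes:
            raise ValueError("coupled_set_size exceeds n_genes")

    def child_rng(self, stream: int) -> np.random.Generator:
        """Per-operation random stream derived from the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(16)[stream]
        )


def fullscale_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The full-scale preset: 152 parcels, 296 subjects, 6 donors, 9 planted
    modules, and a 19-gene coupled set carrying the HSE gene symbols."""
    kw = dict(coupled_set_symbols=hse_gene_set().genes, seed=seed)
    kw.update(overrides)
    return SimulationConfig(**kw)


def reduced_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A down-scaled preset (60 parcels, 4 modules) for fast experiments."""
    kw = dict(n_regions=60, n_subjects=300, n_genes=200, n_modules=4,
              coupled_set_size=10, seed=seed)
    kw.update(overrides)
    return SimulationConfig(**kw)


# --------------------------------------------------------------- correlation


def nearest_psd_correlation(
    c: np.ndarray, tolerance: float | None = None
) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix
    (eigenvalue clipping followed by diagonal renormalization).

    If `tolerance` is given, reject when the relative Frobenius change
    exceeds it.
    """
    c = (c + c.T) / 2
    w, v = np.linalg.eigh(c)
    if w.min() >= 0:
        out = c
    else:
        w = np.clip(w, 1e-10, None)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2
    np.fill_diagonal(out, 1.0)
    if tolerance is not None:
        rel = np.linalg.norm(out - c) / np.linalg.norm(c)
        if rel > tolerance:
            raise ValueError(
                f"PSD projection changed the matrix by {rel:.1%} "
                f"(tolerance {tolerance:.0%})"
            )
    return out


def _planted_labels(atlas_left: ParcelAtlas, config: SimulationConfig,
                    ) -> np.ndarray:
    if config.planted_partition is not None:
        labels = np.asarray(config.planted_partition)
        if len(labels) != atlas_left.n_regions:
            raise ValueError("planted_partition does not cover all left regions")
        return labels
    return grow_contiguous_patches(
        atlas_left.adjacency, atlas_left.centroids, config.n_modules,
        config.child_rng(1),
    )


def planted_correlation(
    atlas_left: ParcelAtlas, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Target inter-regional correlation: base*exp(-d/lambda) plus the
    within-module increment plus a low-rank non-geometric component,
    projected to the nearest PSD correlation.

    The non-geometric component (outer product of random regional loadings)
    models structural covariance that physical distance cannot explain;
    being PSD by construction it costs the projection nothing.

    Returns (correlation matrix, planted module labels).
    """
    d = atlas_left.distances()
    labels = _planted_labels(atlas_left, config)
    if config.decay_length > 0:
        c = config.base_corr * np.exp(-d / config.decay_length)
    else:
        c = np.zeros_like(d)
    c = c + config.module_effect * (labels[:, None] == labels[None, :])
    if config.nonspatial_effect > 0:
        v = config.child_rng(4).standard_normal(
            (len(d), config.nonspatial_rank))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        c = c + config.nonspatial_effect ** 2 * (v @ v.T)
    np.fill_diagonal(c, 1.0)
    return nearest_psd_correlation(c, config.psd_tolerance), labels


def planted_degree(atlas_left: ParcelAtlas, config: SimulationConfig,
                   density: float = 0.10) -> np.ndarray:
    """Z-scored degree of the planted covariance graph thresholded at
    `density` — the regional profile the coupled gene set tracks."""
    from .networks import binarize_density  # local import avoids cycle at doc build

    c, _ = planted_correlation(atlas_left, config)
    graph = binarize_density(c, density)
    k = graph.adjacency.sum(0).astype(float)
    return (k - k.mean()) / k.std()


# ----------------------------------------------------------------- thickness


def simulate_thickness(atlas: ParcelAtlas, config: SimulationConfig
                       ) -> pd.DataFrame:
    """Subjects x regions cortical-thickness table for the left hemisphere.

    Rows are independent draws from a multivariate normal whose correlation
    is the planted matrix; regional means ~2.5 mm.  When `age_effect` is on,
    a linear age term is added uniformly and subject ages are stored in
    ``df.attrs['age']``.
    """
    left = atlas.left()
    c, _ = planted_correlation(left, config)
    rng = config.child_rng(2)
    mu = rng.normal(2.5, 0.1, left.n_regions)
    sd = 0.25
    chol = np.linalg.cholesky(c + 1e-9 * np.eye(len(c)))
    z = rng.standard_normal((config.n_subjects, left.n_regions))
    x = mu + sd * (z @ chol.T)
    ages = rng.uniform(14, 25, config.n_subjects)
    if config.age_effect:
        x = x + config.age_slope * (ages - ages.mean())[:, None]
    df = pd.DataFrame(x, columns=left.region_id)
    df.attrs["age"] = ages
    return df


# ---------------------------------------------------------------- expression


@dataclass
class SyntheticExpression:
    """Donor samples, per-probe expression, probe annotation and truth."""

    samples: pd.DataFrame      # sample metadata incl. truth columns
    expression: pd.DataFrame   # samples x probes
    probes: pd.DataFrame       # probe_id, gene_symbol
    gene_names: list[str]
    coupled_genes: list[str]
    empty_region: int
    degree_profile: np.ndarray  # z-scored planted degree per left region


def simulate_expression(atlas: ParcelAtlas, config: SimulationConfig
                        ) -> SyntheticExpression:
    rng = config.child_rng(3)
    left = atlas.left()
    n = left.n_regions

    # Regional gene profiles: spatial process + planted degree coupling.
    d = left.distances()
    lam = (config.expression_decay_length
           if config.expression_decay_length > 0 else 1e-6)
    s_cov = nearest_psd_correlation(np.exp(-d / lam))
    chol = np.linalg.cholesky(s_cov + 1e-9 * np.eye(n))
    spatial = chol @ rng.standard_normal((n, config.n_genes))
    # weak module-aligned component in every gene (regions of the same
    # planted architectonic unit express more similarly)
    a = config.genome_module_strength
    if a > 0:
        labels_exp = _planted_labels(left, config)
        uniq = np.unique(labels_exp)
        module_field = rng.standard_normal((len(uniq), config.n_genes))
        idx = np.searchsorted(uniq, labels_exp)
        spatial = np.sqrt(1 - a * a) * spatial + a * module_field[idx, :]

    gene_names = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    coupled_idx = np.sort(rng.choice(config.n_genes, config.coupled_set_size,
                                     replace=False))
    if config.coupled_set_symbols is not None:
        symbols = list(config.coupled_set_symbols)
        if len(symbols) != config.coupled_set_size:
            raise ValueError("coupled_set_symbols length != coupled_set_size")
        for i, sym in zip(coupled_idx, symbols):
            gene_names[i] = sym
    coupled_genes = [gene_names[i] for i in coupled_idx]

    zdeg = planted_degree(left, config)
    c = config.coupling_strength
    baseline = rng.normal(6.0, 1.0, config.n_genes)
    profiles = spatial.copy()
    gene_weight = rng.normal(1.0, 0.2, config.coupled_set_size)
    # Coupled genes: a noisy affine function of the planted covariance-graph
    # degree, with residual profiles drawn from the planted covariance and
    # centered across the set (so at coupling 1 / noise 0 the set's mean
    # expression tracks degree exactly, while the set's co-expression tracks
    # the planted covariance network).
    c_target, _ = planted_correlation(left, config)
    chol_c = np.linalg.cholesky(c_target + 1e-9 * np.eye(n))
    resid = chol_c @ rng.standard_normal((n, config.coupled_set_size))
    resid = resid - resid.mean(axis=1, keepdims=True)
    for j, (i, w) in enumerate(zip(coupled_idx, gene_weight)):
        profiles[:, i] = (
            c * (w * zdeg + resid[:, j])
            + (1 - c) * spatial[:, i]
            + config.noise_sd * rng.standard_normal(n)
        )
    profiles = profiles + baseline

    # Probe annotation: 1..k probes per gene, distinct offsets, plus a few
    # probes with no gene symbol (excluded by probe selection downstream).
    probe_rows, offsets = [], []
    for gi, g in enumerate(gene_names):
        k = int(rng.integers(1, config.n_probes_per_gene + 1))
        offs = np.concatenate([[0.0], rng.uniform(-1.0, 1.0, k - 1)])
        for pi, off in enumerate(offs):
            probe_rows.append((f"P{gi + 1:05d}_{pi + 1}", g))
            offsets.append((gi, off))
    for u in range(config.n_unannotated_probes):
        probe_rows.append((f"PNA_{u + 1:03d}", None))
        offsets.append((-1, 0.0))
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "gene_symbol"])
    probe_gene = np.array([g for g, _ in offsets])
    probe_off = np.array([o for _, o in offsets])

    # Sampling design: heterogeneous per-region rates; one region left empty.
    empty_region = int(rng.choice(left.region_id))
    # heterogeneous sampling density, floored so that unplanned empty
    # parcels stay rare (the one designated empty parcel is guaranteed)
    rates = config.samples_per_region * np.clip(rng.gamma(1.5, 1 / 1.5, n),
                                                0.5, None)
    right_donors = set(range(config.n_donors - config.n_right_donors,
                             config.n_donors))

    meta_rows, expr_rows = [], []
    sid = 0
    for donor in range(config.n_donors):
        donor_scale = rng.uniform(0.8, 1.2)
        donor_shift = rng.normal(0.0, 0.5)
        for ri, region in enumerate(left.region_id):
            if region == empty_region:
                continue
            for _ in range(rng.poisson(rates[ri])):
                sid += 1
                pts = left.surface_points[int(region)]
                p = pts[rng.integers(len(pts))].astype(float)
                u = rng.random()
                if u < 0.80:
                    displacement, category = 0.0, "inside"
                elif u < 0.92:
                    displacement, category = rng.uniform(0.3, 1.6), "near"
                else:
                    displacement, category = rng.uniform(4.0, 8.0), "far"
                coord = p * (1.0 + displacement / np.linalg.norm(p))
                hemi = "L"
                if donor in right_donors and rng.random() < 0.4:
                    coord = coord * np.array([-1.0, 1.0, 1.0])
                    hemi = "R"
                gvals = (profiles[ri] + config.sample_noise_sd
                         * rng.standard_normal(config.n_genes))
                gvals = donor_scale * gvals + donor_shift
                pvals = np.where(
                    probe_gene >= 0,
                    gvals[np.clip(probe_gene, 0, None)] + probe_off,
                    rng.normal(4.0, 1.0, len(probe_gene)),
                ) + config.probe_noise_sd * rng.standard_normal(len(probe_gene))
                meta_rows.append((f"S{sid:05d}", f"D{donor + 1}", *coord, hemi,
                                  True, int(region), category))
                expr_rows.append(pvals)
        for _ in range(config.n_noncortical_samples):
            sid += 1
            coord = rng.uniform(-20, 20, 3) * np.array([1, 1, 0.5]) \
                - np.array([30.0, 0.0, 0.0])
            meta_rows.append((f"S{sid:05d}", f"D{donor + 1}", *coord, "L",
                              False, -1, "noncortical"))
            expr_rows.append(rng.normal(4.0, 1.0, len(probe_gene)))

    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "donor_id", "x", "y", "z", "hemisphere",
                 "cortical", "true_region", "displacement"],
    )
    expression = pd.DataFrame(
        np.array(expr_rows), index=meta["sample_id"],
        columns=probes["probe_id"],
    )
    return SyntheticExpression(
        samples=meta, expression=expression, probes=probes,
        gene_names=gene_names, coupled_genes=coupled_genes,
        empty_region=empty_region, degree_profile=zdeg,
    )


# ------------------------------------------------------------------- bundle


@dataclass
class SyntheticDataset:
    atlas: ParcelAtlas
    thickness: pd.DataFrame
    expression: SyntheticExpression
    planted_partition: np.ndarray
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.atlas.write(outdir)
        self.thickness.to_csv(outdir / "thickness.tsv", sep="\t", index=False)
        self.expression.samples.to_csv(outdir / "samples.tsv", sep="\t",
                                       index=False)
        self.expression.expression.to_csv(outdir / "sample_expression.tsv",
                                          sep="\t")
        self.expression.probes.to_csv(outdir / "probes.tsv", sep="\t",
                                      index=False)
        truth = {
            "planted_partition": self.planted_partition.tolist(),
            "coupled_genes": self.expression.coupled_genes,
            "empty_region": self.expression.empty_region,
            "config": {
                k: (v.tolist() if isinstance(v, np.ndarray)
                    else list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.config).items()
            },
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate atlas, thickness and donor expression under one config."""
    atlas = make_atlas(config.n_regions,
                       int(config.child_rng(0).integers(2**31 - 1)))
    left = atlas.left()
    _, labels = planted_correlation(left, config)
    cfg = dataclasses.replace(config, planted_partition=labels)
    thickness = simulate_thickness(atlas, cfg)
    expression = simulate_expression(atlas, cfg)
    return SyntheticDataset(atlas=atlas, thickness=thickness,
                            expression=expression, planted_partition=labels,
                            config=cfg)
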