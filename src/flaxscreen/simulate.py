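"""Synthetic two-group flax cohorts with ground truth.

The generator emulates the statistical structure the screen assumes: a
fiber-flax group and a linseed group (79 + 112 varieties by default),
per-gene variants whose population alt-allele frequencies either coincide
between groups (null variants) or differ by a fixed ``delta``
(associated variants, concentrated in designated genes), near-homozygous
genotypes (flax varieties are inbred lines; the inbreeding coefficient
defaults to 1), and low-coverage read support with Poisson site depths
around 7x and binomial allele sampling with a small per-read error.

A companion routine generates negative-binomial expression counts with
tissue-specific marker genes for the expression-preprocessing module.
All outputs are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .genomic_io import (
    GenePanel,
    GeneRegion,
    Sample,
    SampleManifest,
    VariantRecord,
    VariantTable,
)

_BASES = np.array(list("ACGT"))


@dataclass
class CohortSimConfig:
    """Study-design parameters for the synthetic cohort.

    delta is the alt-allele frequency difference between groups at
    associated variants; base_freq_* parametrize the Beta distribution of
    null allele frequencies; diversity scales null frequencies per group
    (fiber, linseed), letting one group be less polymorphic; inbreeding
    F=1 makes genotypes effectively homozygous, as expected for inbred
    flax lines.
    """

    n_fiber: int = 79
    n_linseed: int = 112
    panel: GenePanel | None = None
    n_genes: int = 40
    gene_length_bp: int = 2000
    genes_per_chrom: int = 30
    flank_bp: int = 500
    variants_per_gene_mean: float = 8.0
    frac_associated_genes: float = 0.15
    delta: float = 0.6
    base_freq_alpha: float = 0.8
    base_freq_beta: float = 0.8
    diversity: tuple[float, float] = (1.0, 1.0)  # (fiber, linseed)
    inbreeding: float = 1.0
    mean_depth: float = 7.0
    base_error: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fiber < 2 or self.n_linseed < 2:
            raise ValueError("each group needs at least two samples")
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must lie in [0, 1]")
        if not 0 <= self.frac_associated_genes <= 1:
            raise ValueError("frac_associated_genes must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.inbreeding <= 1:
            raise ValueError("inbreeding must lie in [0, 1]")
        if not 0 <= self.base_error < 0.5:
            raise ValueError("base_error must lie in [0, 0.5)")


@dataclass
class TruthSet:
    """Simulation ground truth: per-variant frequencies and latent genotypes."""

    variants: pd.DataFrame  # gene_id, chrom, pos, ref, alt, is_associated, p_fiber, p_linseed
    genotypes: np.ndarray  # variants x samples, alt-allele copies in {0,1,2}
    sample_ids: list[str]
    labels: np.ndarray  # 1 = fiber, 0 = linseed, per sample

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def n_associated(self) -> int:
        return int(self.variants["is_associated"].sum())


def _build_panel(config: CohortSimConfig) -> GenePanel:
    if config.panel is not None:
        return config.panel
    regions = []
    width = config.gene_length_bp + 2 * config.flank_bp
    for i in range(config.n_genes):
        chrom = f"chr{i // config.genes_per_chrom + 1}"
        offset = i % config.genes_per_chrom
        start = config.flank_bp + offset * (width + 1000)
        regions.append(GeneRegion(f"gene_{i + 1:04d}", "simulated", chrom,
                                  start, start + config.gene_length_bp,
                                  "unknown", config.flank_bp))
    return GenePanel(regions)


def _sample_genotypes(rng, p: np.ndarray, n: int, inbreeding: float) -> np.ndarray:
    """Per-sample alt copies under HWE with inbreeding coefficient F."""
    p = p[:, None]
    u = rng.random((len(p), n))
    p_hom_alt = p**2 + inbreeding * p * (1 - p)
    p_het = 2 * p * (1 - p) * (1 - inbreeding)
    g = np.where(u < p_hom_alt, 2, np.where(u < p_hom_alt + p_het, 1, 0))
    return g.astype(np.int8)


def simulate_cohort(config: CohortSimConfig) -> tuple[SampleManifest, GenePanel, TruthSet]:
    """Draw the cohort: manifest, panel and ground-truth genotypes.

    ``ceil(frac_associated_genes * n_genes)`` genes are designated
    associated; every variant placed in them has group frequencies
    differing by exactly ``delta`` (direction random per variant).  Null
    variants share one Beta-distributed frequency, scaled by the per-group
    diversity factors.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    panel = _build_panel(config)
    if len(panel) == 0:
        raise ValueError("empty panel")
    if config.delta > 1:
        raise ValueError("infeasible delta")

    samples = [Sample(f"fiber_{i + 1:03d}", "fiber", "simulated")
               for i in range(config.n_fiber)]
    samples += [Sample(f"linseed_{i + 1:03d}", "linseed", "simulated")
                for i in range(config.n_linseed)]
    manifest = SampleManifest(samples)
    labels = manifest.labels()

    n_assoc_genes = ceil(config.frac_associated_genes * len(panel))
    assoc_genes = set(
        np.array(panel.gene_ids)[rng.choice(len(panel), size=n_assoc_genes, replace=False)]
    ) if n_assoc_genes else set()

    rows = []
    for region in panel.regions:
        n_var = rng.poisson(config.variants_per_gene_mean)
        lo, hi = region.region_start, region.region_end
        n_var = min(n_var, hi - lo)
        positions = np.sort(rng.choice(hi - lo, size=n_var, replace=False)) + lo
        for pos in positions:
            ref_i = rng.integers(4)
            alt_i = (ref_i + 1 + rng.integers(3)) % 4
            is_assoc = region.gene_id in assoc_genes
            if is_assoc:
                p_low = rng.uniform(0, 1 - config.delta)
                if rng.random() < 0.5:
                    p_f, p_l = p_low + config.delta, p_low
                else:
                    p_f, p_l = p_low, p_low + config.delta
            else:
                p = rng.beta(config.base_freq_alpha, config.base_freq_beta)
                p_f = np.clip(p * config.diversity[0], 0, 1)
                p_l = np.clip(p * config.diversity[1], 0, 1)
            rows.append((region.gene_id, region.chrom, int(pos),
                         _BASES[ref_i], _BASES[alt_i], is_assoc, p_f, p_l))
    variants = pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "pos", "ref", "alt", "is_associated", "p_fiber", "p_linseed"])
    variants = variants.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    g_f = _sample_genotypes(rng, variants["p_fiber"].to_numpy(), config.n_fiber,
                            config.inbreeding)
    g_l = _sample_genotypes(rng, variants["p_linseed"].to_numpy(), config.n_linseed,
                            config.inbreeding)
    genotypes = np.concatenate([g_f, g_l], axis=1)
    truth = TruthSet(variants, genotypes, manifest.sample_ids, labels)
    return manifest, panel, truth


def simulate_read_support(truth: TruthSet, config: CohortSimConfig) -> VariantTable:
    """Low-coverage read support for the latent genotypes.

    Site depth is Poisson(mean_depth) per sample per variant; alt reads
    are Binomial(depth, q) with q = (g/2)(1 - e) + (1 - g/2) e for
    genotype g and per-read error e.  Deterministic given the config seed
    (an independent stream from the cohort draw).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_var, n_samp = truth.genotypes.shape
    depth = rng.poisson(config.mean_depth, size=(n_var, n_samp))
    frac = truth.genotypes / 2.0
    q = frac * (1 - config.base_error) + (1 - frac) * config.base_error
    alt = rng.binomial(depth, q)
    records = [
        VariantRecord(row.chrom, int(row.pos), row.ref, row.alt,
                      alt[i].astype(int), depth[i].astype(int))
        for i, row in enumerate(truth.variants.itertuples(index=False))
    ]
    table = VariantTable(records, list(truth.sample_ids))
    table.sort()
    return table


@dataclass
class ExpressionSimConfig:
    """Negative-binomial expression model with tissue markers.

    Marker genes get ``marker_fold`` times the baseline mean in their
    designated tissue; a fraction of genes is silent
    (zero mean) so the low-expression flag has something to find.  Counts are NB
    (gamma-Poisson) with dispersion ``nb_dispersion``; per-sample library
    scale factors are log-normal.
    """

    baseline_mean: float = 200.0
    marker_fold: float = 50.0
    frac_marker_genes: float = 0.3
    frac_silent_genes: float = 0.1
    silent_mean: float = 0.0
    nb_dispersion: float = 0.3
    library_sigma: float = 0.3
    seed: int = 0


def simulate_expression(
    n_genes: int,
    tissues: list[str],
    samples_per_tissue: int,
    config: ExpressionSimConfig | None = None,
):
    """Counts matrix with tissue structure, plus the marker ground truth.

    Returns ``(ExpressionMatrix, truth)`` where truth maps each gene to
    its marker tissue (or none).  Requires at least two tissues.
    """
    from .expression import ExpressionMatrix

    config = config or ExpressionSimConfig()
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    rng = np.random.default_rng(config.seed)
    genes = [f"gene_{i + 1:04d}" for i in range(n_genes)]
    n_marker = int(round(config.frac_marker_genes * n_genes))
    n_silent = int(round(config.frac_silent_genes * n_genes))
    marker_tissue = {genes[i]: tissues[i % len(tissues)] for i in range(n_marker)}
    silent = set(genes[n_marker:n_marker + n_silent])

    sample_ids, tissue_labels = [], []
    for t in tissues:
        for r in range(samples_per_tissue):
            sample_ids.append(f"{t}_{r + 1}")
            tissue_labels.append(t)

    mu = np.zeros((n_genes, len(sample_ids)))
    for i, g in enumerate(genes):
        if g in silent:
            base = config.silent_mean  # 0 by default: gene not expressed
        else:
            base = config.baseline_mean * rng.lognormal(0, 0.5)
        row = np.full(len(sample_ids), base)
        if g in marker_tissue:
            row[np.array(tissue_labels) == marker_tissue[g]] *= config.marker_fold
        mu[i] = row
    scale = rng.lognormal(0, config.library_sigma, size=len(sample_ids))
    mu = mu * scale[None, :]
    # gamma-Poisson mixture => NB with var = mu + dispersion * mu^2
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        sample_meta=pd.DataFrame({
            "sample_id": sample_ids,
            "tissue": tissue_labels,
            "variety": ["simulated"] * len(sample_ids),
        }),
    )
    truth = pd.DataFrame({
        "gene_id": genes,
        "marker_tissue": [marker_tissue.get(g, "") for g in genes],
        "is_silent": [g in silent for g in genes],
    })
    return matrix, truth
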