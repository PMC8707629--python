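# Methods notes

## The screen

The association target is the binary flax plant type: fiber flax vs.
linseed. For each variant the per-variety variant allele frequency
(VAF = alt reads / site reads) is treated as a quantitative genotype
proxy and tested against the label four ways: Spearman rank correlation
(the classifying statistic), Pearson correlation, Kendall tau-b, and a
two-sided Mann–Whitney U test between the two groups. With a binary
label, Spearman's coefficient is a monotone function of the rank
separation between groups, so the Spearman and Mann–Whitney orderings
agree on tie-free data; all four are reported because they weight ties
and outliers differently at low coverage.

Classification uses the correlation coefficient alone — flax-type-
associated (FTA) at |r_s| ≥ 0.4, very strong at |r_s| ≥ 0.6, both
inclusive — with Benjamini–Hochberg-adjusted p-values reported alongside
rather than folded into the call. Since |r_s| is symmetric, the calls are
invariant to which group is coded 1. Under the null, r_s for ~191
independent samples has standard deviation ≈ 1/√190 ≈ 0.073, so the 0.4
cutoff sits at ≈ 5.5 null SDs; the per-variant false-positive rate is
negligible even over a few thousand panel variants, which is why the
screen can classify on r_s without a significance gate.

Decisions where the design was genuinely open:

- **Missing VAF** (zero site depth) is handled pairwise-complete: the
  sample is dropped for that variant's tests. A `min_informative_samples`
  guard (default 10) marks variants with too few covered samples as
  untestable instead of producing unstable coefficients.
- **Zero-variance VAF rows** are untestable: no coefficient, excluded
  from FTA and from the BH input (no test was performed, so they must not
  count toward m).
- **BH scope** defaults to the whole panel, separately per statistic; a
  per-gene scope is available (`bh_scope="gene"`).
- **Exact vs. approximate Mann–Whitney**: exact enumeration when both
  groups have ≤ 25 samples and the pooled values are tie-free, else the
  normal approximation with tie correction — exactness where enumeration
  is cheap, the standard correction elsewhere.

## Variant handling

Internal coordinates are 0-based half-open; VCF positions are converted
on read/write and BED intervals taken as-is. Multi-allelic sites are
decomposed into one record per alternative allele; the site depth (AD
sum) is shared across the decomposed records, so each alt's VAF is its
fraction of all reads at the site. Depths come from `AD` when present,
else `AO`/`RO`; genotype calls are never used. The support filter keeps a
variant when its maximum per-sample alt depth is ≥ 4 — at ~7× effective
coverage a hard genotype-quality filter would discard most of the signal,
whereas four reads in at least one sample suffices to establish that the
allele exists. Variants falling in the flanked regions of two overlapping
genes count toward both, since per-gene analyses are independent. The
per-kb density denominator is the unclipped analysis region, gene length
+ 1000 bp (500 bp per flank), so densities are comparable across genes
even when a flank is clipped at a contig start.

The packaged panel records the 424 candidate gene names and family
memberships only; genome coordinates depend on the assembly and come from
the user's BED file (`default_panel()` fabricates an evenly spaced
synthetic layout for simulation and demonstration).

## Clustering

Varieties are compared by Euclidean distance between VAF profiles. For
pairs with missing entries the summed squared difference over mutually
observed variants is rescaled, d = sqrt(D / m_used · m_total), which
keeps sparsely covered pairs on the same scale as fully observed ones; a
zero-imputation mode is provided for comparison. Agglomeration is Ward's
minimum-variance method in the ward.D2 form (scipy's `linkage(...,
"ward")` on the distance matrix, matching R's `hclust(method =
"ward.D2")`); the test suite checks it against a naive oracle that
recomputes cluster centroids at every merge. The genetic-similarity
matrix is defined as the max-normalized complement of the clustering
distance, s = 1 − d/max(d), so the similarity heatmap and the dendrogram
share one geometry. Cluster-composition reports require an explicit k;
purity is the majority-type fraction per cluster.

## Expression preprocessing

Counts are normalized to counts per million (CPM). Library sizes default
to column sums over the panel counts; when genome-wide mapped-read totals
are available they should be supplied, since panel-restricted totals make
the absolute CPM scale panel-relative (the low-expression threshold of
10 CPM then refers to the panel library, not the transcriptome — a known
limitation). Genes with CPM < 10 in every sample are flagged
low-expressed. Heatmap values are log2(CPM + 1), mean-centered per gene;
the pseudocount of 1 keeps zeros at zero and is negligible for
well-expressed genes (row-scaling invariance holds within 0.02 for rows
with CPM ≥ 100). Aggregation to tissue means, when requested, precedes
the log transform; a per-sample mode is the default. Gene and tissue
dendrograms use the same Euclidean + Ward machinery as the variety
clustering.

## The synthetic cohort generator

The generator emulates the study design the screen assumes, not flax
biology in detail:

- **Cohort**: 79 fiber + 112 linseed varieties (defaults).
- **Panel**: either a user panel or n_genes = 40 synthetic 2-kb genes
  with 500-bp flanks; variants per gene ~ Poisson(8), placed uniformly in
  the flanked region.
- **Association**: ⌈frac_associated_genes · n_genes⌉ genes are designated
  associated; every variant there has group frequencies differing by
  exactly delta (direction random), defaults frac = 0.15, delta = 0.6.
  Null variants draw one shared frequency from Beta(0.8, 0.8), optionally
  scaled per group by a diversity factor so one group can be made less
  polymorphic.
- **Genotypes**: Hardy–Weinberg draws with an inbreeding coefficient
  defaulting to 1 — flax is predominantly self-pollinating and the
  varieties are inbred lines, so VAF concentrates near {0, 1}. No linkage
  between variants is modelled; real FTA variants travel in linked blocks
  within a gene, so per-gene FTA counts on synthetic data are not
  calibrated against real per-gene counts.
- **Reads**: site depth ~ Poisson(7) per sample (the effective coverage
  of the design after duplicate marking), alt reads ~ Binomial(depth, q)
  with q = (g/2)(1−e) + (1−g/2)e and per-read error e = 0.001.
- **Expression**: negative-binomial (gamma-Poisson, dispersion 0.3)
  counts, log-normal library scale factors, 30 % marker genes with a
  50-fold mean boost in a designated tissue, 10 % silent genes (zero
  mean) for the low-expression flag.

What passing tests on these cohorts shows: the statistics, thresholds,
multiple-testing machinery, and clustering behave correctly and recover
planted structure at the study's sample sizes and depth. What they do not
show: performance under linkage, population stratification, shared
ancestry between groups, mapping artefacts, or indel-calling noise — none
of which the generator models.

## Numerical choices and problem sizes

Statistical routines delegate to scipy/statsmodels (Spearman via average
ranks, tau-b with tie correction, BH step-up); the test suite pins each
one to an independent brute-force oracle (rank-Pearson, pair counting,
full enumeration of group assignments, step-up by hand) at 1e-12 on small
instances. Ties in Ward merges are resolved by scipy's deterministic
nearest-neighbor chain. Simulation-based checks use fixed seeds and
moderate sizes — ~1000 null variants for the null-calibration rate,
full-scale 191-variety cohorts for recovery and clustering, 200 genes ×
15 samples for expression — chosen so the entire suite runs in well under
a minute while leaving the binomial error of estimated rates far below
the asserted margins.

## Known limitations

- The screen is marginal per variant: no LD pruning, kinship correction
  or population-structure adjustment (deliberately, matching the
  candidate-panel design).
- FTA classification ignores q-values by design; users wanting an
  FDR-gated call can filter the per-variant table on `q_s`.
- The packaged panel has no genome coordinates; real-data runs need a
  user BED.
- CPM over panel counts is panel-relative (see above).
- Variety clustering reports composition at a user-chosen k rather than
  inferring the number of clusters.
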