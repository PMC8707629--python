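"""Expression preprocessing for heatmap-style tissue profiling.

Counts over the candidate-gene panel are normalized to counts per million
mapped reads (CPM), optionally averaged per tissue, log2-transformed with
a pseudocount, mean-centered per gene, and clustered (genes and/or
samples) with Euclidean + Ward (ward.D2) so the matrices are ready for
heatmap rendering.  Genes whose CPM stays below a threshold in every
sample are flagged as low-expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterTree, ward_cluster

#: Tissue codes used throughout: seedling roots and shoots, leaves,
#: flowers, stems and capsules, plus stem-section samples -- cPAR
#: (cortical parenchyma), iFIB (intrusively growing fibers), tFIB (fibers
#: depositing tertiary cell wall), sXYL (stem xylem) -- and embryo.
KNOWN_TISSUES = (
    "root", "shoot", "leaf", "flower", "stem", "capsule",
    "cPAR", "iFIB", "tFIB", "sXYL", "embryo",
)


@dataclass(frozen=True)
class ExpressionConfig:
    cpm_low_threshold: float = 10.0
    pseudocount: float = 1.0
    aggregate: str = "per_sample"  # or "tissue_mean"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.aggregate not in ("per_sample", "tissue_mean"):
            raise ValueError("aggregate must be 'per_sample' or 'tissue_mean'")


@dataclass
class ExpressionMatrix:
    """Genes x samples raw counts with per-sample tissue metadata.

    ``library_sizes`` defaults to the column sums over the panel when
    genome-wide mapped-read totals are not supplied.
    """

    counts: pd.DataFrame  # genes x samples, non-negative integers
    sample_meta: pd.DataFrame  # columns: sample_id, tissue, variety
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_meta["sample_id"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def tissue_of(self) -> pd.Series:
        return self.sample_meta.set_index("sample_id")["tissue"].reindex(self.counts.columns)


def cpm_normalize(m: ExpressionMatrix) -> pd.DataFrame:
    """CPM = count / library_size * 1e6, per sample.

    Library sizes fall back to column sums; a zero library size with
    nonzero counts is an error (zero with all-zero counts yields zeros).
    """
    lib = m.library_sizes
    if lib is None:
        lib = m.counts.sum(axis=0)
    lib = lib.reindex(m.counts.columns).astype(float)
    bad = lib[(lib <= 0) & (m.counts.sum(axis=0) > 0)]
    if len(bad):
        raise ValueError(f"zero library size with nonzero counts: {list(bad.index)}")
    safe = lib.replace(0, np.nan)
    cpm = m.counts.div(safe, axis=1) * 1e6
    return cpm.fillna(0.0)


def flag_low_expression(cpm: pd.DataFrame, config: ExpressionConfig | None = None) -> pd.Series:
    """True for genes with CPM below the threshold in every sample."""
    config = config or ExpressionConfig()
    if cpm.shape[1] == 0:
        return pd.Series(dtype=bool, index=cpm.index)
    return (cpm < config.cpm_low_threshold).all(axis=1)


def log2_center(cpm: pd.DataFrame, config: ExpressionConfig | None = None) -> pd.DataFrame:
    """log2(CPM + pseudocount), then per-gene mean-centering across samples."""
    config = config or ExpressionConfig()
    v = np.log2(cpm + config.pseudocount)
    return v.sub(v.mean(axis=1), axis=0)


def tissue_aggregate(cpm: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Mean CPM across the samples of each tissue (applied before log2).

    Samples lacking a tissue assignment are an error listing the
    offenders; tissue column order follows first appearance in the
    metadata.
    """
    tissue = sample_meta.set_index("sample_id")["tissue"].reindex(cpm.columns)
    unknown = list(tissue[tissue.isna()].index)
    if unknown:
        raise ValueError(f"samples without a tissue label: {unknown}")
    order = list(dict.fromkeys(tissue))
    agg = cpm.T.groupby(tissue.values).mean().T
    return agg[order]


def cluster_heatmap(
    matrix: pd.DataFrame, axis: str = "genes"
) -> tuple[dict[str, ClusterTree], pd.DataFrame]:
    """Ward-cluster a heatmap matrix on genes, samples or both.

    Returns the tree(s) and the matrix reordered to dendrogram leaf order
    on the clustered axes.  Euclidean distances; requires at least two
    rows/columns on each clustered axis.
    """
    if axis not in ("genes", "samples", "both"):
        raise ValueError("axis must be 'genes', 'samples' or 'both'")
    trees: dict[str, ClusterTree] = {}
    ordered = matrix
    if axis in ("genes", "both"):
        if matrix.shape[0] < 2:
            raise ValueError("need at least two genes to cluster the gene axis")
        d = _euclidean(matrix.values)
        trees["genes"] = ward_cluster(d, list(matrix.index))
        ordered = ordered.iloc[trees["genes"].leaf_order]
    if axis in ("samples", "both"):
        if matrix.shape[1] < 2:
            raise ValueError("need at least two samples to cluster the sample axis")
        d = _euclidean(matrix.values.T)
        trees["samples"] = ward_cluster(d, list(matrix.columns))
        ordered = ordered.iloc[:, trees["samples"].leaf_order]
    return trees, ordered


def _euclidean(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X ** 2, axis=1)
    D = sq[:, None] + sq[None, :] - 2 * X @ X.T
    return np.sqrt(np.clip(D, 0, None))


def heatmap_matrix(
    m: ExpressionMatrix, config: ExpressionConfig | None = None
) -> pd.DataFrame:
    """CPM -> (optional tissue means) -> log2 -> per-gene centering."""
    config = config or ExpressionConfig()
    cpm = cpm_normalize(m)
    if config.aggregate == "tissue_mean":
        cpm = tissue_aggregate(cpm, m.sample_meta)
    return log2_center(cpm, config)
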