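"""Flax-type association screen on variant-allele-frequency profiles.

Each variant's per-sample VAF (alt reads / site reads) is correlated with
the binary plant type (linseed=0, fiber=1 by default).  Spearman, Pearson
and Kendall tau-b coefficients are computed together with a two-sided
Mann-Whitney U test comparing the two groups; p-values are adjusted with
the Benjamini-Hochberg step-up procedure, separately per statistic.

A variant is called flax-type-associated (FTA) from the Spearman
coefficient alone: |r_s| >= 0.4 is "strong", |r_s| >= 0.6 "very strong"
(inclusive thresholds).  Adjusted p-values are reported alongside but do
not enter the classification.

Working on VAF rather than genotype calls keeps the screen usable at low
coverage (~7x effective depth), where hard genotype calls are unreliable
but the read-fraction signal across 191 varieties is still informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import GenePanel, SampleManifest, VariantTable, assign_variants

FTA_NONE = "none"
FTA_STRONG = "strong"
FTA_VERY_STRONG = "very_strong"


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and options for the association screen.

    strong_threshold / very_strong_threshold
        Inclusive cutoffs on |Spearman r_s| for the FTA classes.
    type_coding
        Label -> {0,1} coding; FTA classes are invariant to swapping it.
    min_informative_samples
        Minimum samples with non-missing VAF for a variant to be tested.
    mwu_exact_max_n
        Exact Mann-Whitney enumeration is used when both groups are at most
        this large and the data are tie-free; otherwise the normal
        approximation with tie correction.
    bh_scope
        "panel" adjusts across all tested variants; "gene" adjusts within
        each gene separately.
    """

    strong_threshold: float = 0.4
    very_strong_threshold: float = 0.6
    type_coding: dict = field(default_factory=lambda: {"linseed": 0, "fiber": 1})
    min_informative_samples: int = 10
    mwu_exact_max_n: int = 25
    bh_scope: str = "panel"

    def __post_init__(self) -> None:
        if not (0 < self.strong_threshold <= self.very_strong_threshold <= 1):
            raise ValueError("require 0 < strong <= very_strong <= 1")
        if self.bh_scope not in ("panel", "gene"):
            raise ValueError("bh_scope must be 'panel' or 'gene'")


@dataclass
class VafMatrix:
    """Variants x samples VAF values; NaN marks missing (zero site depth)."""

    values: np.ndarray
    variant_ids: list[str]
    sample_order: list[str]

    def __post_init__(self) -> None:
        present = self.values[~np.isnan(self.values)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError("VAF values must lie in [0, 1]")


def compute_vaf(table: VariantTable) -> VafMatrix:
    """Per-sample VAF = alt_depth / total_depth; missing where depth is 0."""
    n = len(table.records)
    m = len(table.sample_order)
    values = np.full((n, m), np.nan)
    for i, r in enumerate(table.records):
        total = r.total_depth.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            row = np.where(total > 0, r.alt_depth / total, np.nan)
        values[i] = row
    return VafMatrix(values, table.variant_ids, list(table.sample_order))


@dataclass
class AssociationRecord:
    variant_id: str
    gene_ids: tuple[str, ...] = ()
    r_s: float = np.nan
    r_p: float = np.nan
    tau: float = np.nan
    p_s: float = np.nan
    p_p: float = np.nan
    p_tau: float = np.nan
    p_mwu: float = np.nan
    q_s: float = np.nan
    q_p: float = np.nan
    q_tau: float = np.nan
    q_mwu: float = np.nan
    n_used: int = 0
    testable: bool = True
    fta_class: str = FTA_NONE


def classify_fta(r_s: float, config: ScreenConfig | None = None) -> str:
    """FTA class from the Spearman coefficient (inclusive |r_s| thresholds)."""
    config = config or ScreenConfig()
    if r_s is None or np.isnan(r_s):
        return FTA_NONE
    a = abs(r_s)
    if a >= config.very_strong_threshold:
        return FTA_VERY_STRONG
    if a >= config.strong_threshold:
        return FTA_STRONG
    return FTA_NONE


def _mannwhitney(x0: np.ndarray, x1: np.ndarray, config: ScreenConfig) -> float:
    pooled = np.concatenate([x0, x1])
    tie_free = len(np.unique(pooled)) == len(pooled)
    small = len(x0) <= config.mwu_exact_max_n and len(x1) <= config.mwu_exact_max_n
    method = "exact" if (small and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x0, x1, alternative="two-sided", method=method)
    return float(res.pvalue)


def correlate_variant(
    vaf_row: Sequence[float],
    labels: Sequence[int],
    config: ScreenConfig | None = None,
    variant_id: str = "",
) -> AssociationRecord:
    """Correlate one variant's VAF profile with the binary type label.

    Samples with missing VAF are dropped pairwise.  Degenerate inputs
    (too few informative samples, a single class among them, or
    zero-variance VAF) yield an untestable record or undefined
    coefficients rather than an exception, and are excluded from FTA.
    """
    config = config or ScreenConfig()
    v = np.asarray(vaf_row, dtype=float)
    y = np.asarray(labels, dtype=float)
    mask = ~np.isnan(v)
    v, y = v[mask], y[mask]
    rec = AssociationRecord(variant_id=variant_id, n_used=int(mask.sum()))
    if rec.n_used < config.min_informative_samples or len(np.unique(y)) < 2:
        rec.testable = False
        return rec
    if np.all(v == v[0]):
        # zero-variance VAF: correlation undefined, no test performed
        rec.testable = False
        return rec
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rs, ps = stats.spearmanr(v, y)
        rp, pp = stats.pearsonr(v, y)
        tau, ptau = stats.kendalltau(v, y, variant="b")
    rec.r_s, rec.p_s = float(rs), float(ps)
    rec.r_p, rec.p_p = float(rp), float(pp)
    rec.tau, rec.p_tau = float(tau), float(ptau)
    rec.p_mwu = _mannwhitney(v[y == 0], v[y == 1], config)
    rec.fta_class = classify_fta(rec.r_s, config)
    return rec


def adjust_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, mapped to input order.

    NaN entries (untested variants) are passed through as NaN and do not
    count toward the number of tests.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if not mask.any():
        return out
    if p[mask].min() < 0 or p[mask].max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def screen_variants(
    table: VariantTable,
    manifest: SampleManifest,
    panel: GenePanel | None = None,
    config: ScreenConfig | None = None,
) -> list[AssociationRecord]:
    """Run the full screen over a variant table.

    Computes VAF, correlates every variant with the type label, applies BH
    adjustment per statistic over all tested variants (or within genes when
    ``bh_scope="gene"``), and attaches gene memberships from the panel.
    """
    config = config or ScreenConfig()
    if manifest.count("fiber") == 0 or manifest.count("linseed") == 0:
        raise ValueError("association requires samples of both types")
    vaf = compute_vaf(table)
    labels = manifest.labels(config.type_coding)
    records = [
        correlate_variant(vaf.values[i], labels, config, variant_id=vid)
        for i, vid in enumerate(vaf.variant_ids)
    ]
    if panel is not None:
        assignment = assign_variants(table, panel)
        gene_map: dict[int, list[str]] = {}
        for gene, idx in assignment.items():
            for i in idx:
                gene_map.setdefault(int(i), []).append(gene)
        for i, rec in enumerate(records):
            rec.gene_ids = tuple(sorted(gene_map.get(i, [])))
    _apply_bh(records, config)
    return records


def _apply_bh(records: list[AssociationRecord], config: ScreenConfig) -> None:
    if config.bh_scope == "gene":
        groups: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            for g in r.gene_ids or ("",):
                groups.setdefault(g, []).append(i)
    else:
        groups = {"": list(range(len(records)))}
    # per-gene scope may visit a variant several times; last write wins,
    # which is deterministic given sorted gene ids
    for idx in groups.values():
        for p_attr, q_attr in (("p_s", "q_s"), ("p_p", "q_p"),
                               ("p_tau", "q_tau"), ("p_mwu", "q_mwu")):
            q = adjust_bh([getattr(records[i], p_attr) for i in idx])
            for j, i in enumerate(idx):
                setattr(records[i], q_attr, float(q[j]))


def records_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append((r.variant_id, ";".join(r.gene_ids), r.r_s, r.r_p, r.tau,
                     r.p_s, r.p_p, r.p_tau, r.p_mwu,
                     r.q_s, r.q_p, r.q_tau, r.q_mwu,
                     r.n_used, r.testable, r.fta_class))
    return pd.DataFrame(rows, columns=[
        "variant_id", "gene_ids", "r_s", "r_p", "tau",
        "p_s", "p_p", "p_tau", "p_mwu", "q_s", "q_p", "q_tau", "q_mwu",
        "n_used", "testable", "fta_class"])


@dataclass(frozen=True)
class FtaGeneSummary:
    gene_id: str
    family: str
    n_fta_strong: int
    n_fta_very_strong: int
    max_abs_rs: float


def summarize_genes(records: list[AssociationRecord], panel: GenePanel) -> list[FtaGeneSummary]:
    """Per-gene counts of FTA variants at both thresholds.

    Every panel gene is summarised, including genes with zero FTA variants
    (use :func:`gene_report` for the report view that drops them).
    """
    per_gene: dict[str, list[AssociationRecord]] = {g: [] for g in panel.gene_ids}
    for r in records:
        for g in r.gene_ids:
            if g in per_gene:
                per_gene[g].append(r)
    out = []
    for region in panel.regions:
        recs = per_gene[region.gene_id]
        strong = sum(r.fta_class in (FTA_STRONG, FTA_VERY_STRONG) for r in recs)
        very = sum(r.fta_class == FTA_VERY_STRONG for r in recs)
        defined = [abs(r.r_s) for r in recs if not np.isnan(r.r_s)]
        out.append(FtaGeneSummary(region.gene_id, region.family, strong, very,
                                  max(defined) if defined else 0.0))
    return out


def summaries_frame(summaries: list[FtaGeneSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.gene_id, s.family, s.n_fta_strong, s.n_fta_very_strong, s.max_abs_rs)
         for s in summaries],
        columns=["gene_id", "family", "n_fta_strong", "n_fta_very_strong", "max_abs_rs"])


def gene_report(summaries: list[FtaGeneSummary]) -> pd.DataFrame:
    """Report table listing only genes with at least one FTA variant."""
    df = summaries_frame(summaries)
    return df[df.n_fta_strong >= 1].reset_index(drop=True)


def summarize_families(
    summaries: list[FtaGeneSummary], panel: GenePanel
) -> dict[str, tuple[int, float]]:
    """family -> (genes with >=1 strong FTA variant, fraction of family)."""
    fam_sizes = {f: len(g) for f, g in panel.family_index.items()}
    hits: dict[str, int] = {f: 0 for f in fam_sizes}
    for s in summaries:
        if s.n_fta_strong >= 1:
            hits[s.family] = hits.get(s.family, 0) + 1
    return {
        f: (hits[f], hits[f] / fam_sizes[f] if fam_sizes[f] else float("nan"))
        for f in fam_sizes
    }
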