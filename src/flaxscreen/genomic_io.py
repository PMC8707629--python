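"""Cohort I/O: sample manifests, gene panels, and per-sample variant depths.

The pipeline starts from a joint-called VCF with per-sample allelic depths,
a BED-like gene panel (gene body coordinates plus a flank applied at
analysis time), and a manifest labelling every variety as fiber flax or
linseed.  Internally all coordinates are 0-based half-open; VCF positions
are converted on read/write and BED intervals are taken as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

TYPE_LABELS = ("fiber", "linseed")

#: Gene-family tags used by the packaged candidate panel.
FAMILIES = (
    "lignin", "CTL", "BGAL", "ABC_HMA", "lignan",
    "TUB", "CESA", "RGL", "FA", "ACT",
)

DEFAULT_FLANK_BP = 500


class PanelError(ValueError):
    """Raised for malformed gene-panel inputs."""


class VcfFormatError(ValueError):
    """Raised when a VCF lacks the per-sample depth information we need."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    type_label: str  # "fiber" or "linseed"
    source: str = ""

    def __post_init__(self) -> None:
        if self.type_label not in TYPE_LABELS:
            raise ValueError(
                f"unknown type label {self.type_label!r} for sample "
                f"{self.sample_id!r}; expected one of {TYPE_LABELS}"
            )


@dataclass
class SampleManifest:
    """Varieties of the cohort with their binary plant-type labels."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def labels(self, coding: Mapping[str, int] | None = None) -> np.ndarray:
        """Binary label vector in manifest order (default linseed=0, fiber=1)."""
        coding = coding or {"linseed": 0, "fiber": 1}
        return np.array([coding[s.type_label] for s in self.samples], dtype=int)

    def count(self, type_label: str) -> int:
        return sum(s.type_label == type_label for s in self.samples)


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "type_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    samples = [
        Sample(r.sample_id, r.type_label, getattr(r, "source", ""))
        for r in df.itertuples(index=False)
    ]
    return SampleManifest(samples)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.type_label, s.source) for s in manifest.samples],
        columns=["sample_id", "type_label", "source"],
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneRegion:
    """A candidate gene with its analysis flank.

    ``start``/``end`` delimit the gene body (0-based half-open).  Variants
    are assigned over the flanked interval ``[start - flank_bp,
    end + flank_bp)``, clipped at zero.  ``region_length_bp`` deliberately
    uses the unclipped length (gene length + 2*flank) so that per-kb
    densities are comparable across genes.
    """

    gene_id: str
    family: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"
    flank_bp: int = DEFAULT_FLANK_BP

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PanelError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.flank_bp < 0:
            raise PanelError(f"gene {self.gene_id}: negative flank")

    @property
    def region_start(self) -> int:
        return max(0, self.start - self.flank_bp)

    @property
    def region_end(self) -> int:
        return self.end + self.flank_bp

    @property
    def region_length_bp(self) -> int:
        return (self.end - self.start) + 2 * self.flank_bp

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.region_start <= pos < self.region_end


@dataclass
class GenePanel:
    regions: list[GeneRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate gene ids in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.regions]

    @property
    def family_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for r in self.regions:
            idx.setdefault(r.family, []).append(r.gene_id)
        return idx

    def region(self, gene_id: str) -> GeneRegion:
        for r in self.regions:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    def with_flank(self, flank_bp: int) -> "GenePanel":
        return GenePanel([replace(r, flank_bp=flank_bp) for r in self.regions])


def read_panel(path: str | Path, flank_bp: int = DEFAULT_FLANK_BP) -> GenePanel:
    """Read a BED6+1 gene panel (chrom, start, end, gene_id, family, strand).

    BED coordinates are 0-based half-open and are taken as-is.  An empty
    file yields an empty panel with a warning.
    """
    names = ["chrom", "start", "end", "gene_id", "family", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#",
                         dtype={"chrom": str, "gene_id": str, "family": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=names)
    if df.empty:
        warnings.warn(f"gene panel {path} is empty", stacklevel=2)
        return GenePanel([])
    regions = [
        GeneRegion(r.gene_id, r.family, r.chrom, int(r.start), int(r.end),
                   r.strand if r.strand in ("+", "-") else "unknown", flank_bp)
        for r in df.itertuples(index=False)
    ]
    return GenePanel(regions)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in panel.regions:
            strand = r.strand if r.strand in ("+", "-") else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t{r.family}\t{strand}\n")


def load_panel_genes() -> pd.DataFrame:
    """The packaged 424-gene flax candidate panel (gene_id, family).

    The panel covers lignin biosynthesis, chitinase-like (CTL),
    beta-galactosidase (BGAL), ABC-transporter/heavy-metal-associated
    (ABC_HMA), lignan biosynthesis, tubulin (TUB), cellulose synthase
    (CESA), rhamnogalacturonan lyase (RGL), fatty-acid biosynthesis (FA)
    and actin (ACT) families.  Genome coordinates are not part of the
    packaged listing; see :func:`default_panel` for a synthetic layout.
    """
    ref = resources.files("flaxscreen.data").joinpath("panel_genes.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def default_panel(
    gene_length_bp: int = 2000,
    spacing_bp: int = 2000,
    genes_per_chrom: int = 30,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> GenePanel:
    """Packaged 424-gene panel laid out on synthetic chromosome coordinates.

    Real genome coordinates for the candidate genes must be supplied by the
    user as a BED panel; this constructor places the panel's genes on
    evenly spaced synthetic intervals so simulations and end-to-end runs
    can use the full family structure.
    """
    genes = load_panel_genes()
    regions = []
    for i, row in enumerate(genes.itertuples(index=False)):
        chrom = f"chr{i // genes_per_chrom + 1}"
        offset = i % genes_per_chrom
        start = flank_bp + offset * (gene_length_bp + 2 * flank_bp + spacing_bp)
        regions.append(GeneRegion(row.gene_id, row.family, chrom,
                                  start, start + gene_length_bp, "unknown", flank_bp))
    return GenePanel(regions)


@dataclass
class VariantRecord:
    """One bi-allelic variant with per-sample read support.

    Multi-allelic VCF sites are decomposed into one record per alternative
    allele; ``total_depth`` is the site depth (sum over alleles), shared
    between the decomposed records.
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    alt_depth: np.ndarray  # int, per sample
    total_depth: np.ndarray  # int, per sample

    @property
    def kind(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos + 1}:{self.ref}>{self.alt}"


@dataclass
class VariantTable:
    records: list[VariantRecord]
    sample_order: list[str]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def sort(self) -> None:
        self.records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))

    def subset(self, indices: Iterable[int]) -> "VariantTable":
        idx = list(indices)
        return VariantTable([self.records[i] for i in idx], list(self.sample_order))


def _depths_from_variant(v, n_samples: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-sample (alt depths over alts, site depth) from AD or AO/RO."""
    try:
        ad = v.format("AD")
    except KeyError:
        ad = None
    if ad is not None:
        ad = np.asarray(ad, dtype=float)
        ad[ad < 0] = 0  # cyvcf2 encodes missing as negative
        ad = ad.astype(int)
        if ad.ndim == 1:
            ad = ad.reshape(n_samples, -1)
        total = ad.sum(axis=1)
        return ad[:, 1:], total
    try:
        ao = v.format("AO")
        ro = v.format("RO")
    except KeyError:
        return None
    if ao is None or ro is None:
        return None
    ao = np.asarray(ao, dtype=float)
    ro = np.asarray(ro, dtype=float).reshape(n_samples)
    ao[ao < 0] = 0
    ro[ro < 0] = 0
    if ao.ndim == 1:
        ao = ao.reshape(n_samples, -1)
    total = ao.sum(axis=1) + ro
    return ao.astype(int), total.astype(int)


def read_vcf(path: str | Path, manifest: SampleManifest) -> VariantTable:
    """Read per-sample allelic depths from a VCF into a VariantTable.

    Depths come from the ``AD`` FORMAT field when present, else from
    ``AO``/``RO`` pairs; genotype calls are ignored.  Multi-allelic sites
    are decomposed into one record per alternative allele.  Samples are
    reordered to manifest order; VCF 1-based positions become internal
    0-based positions.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    unknown = [s for s in vcf_samples if s not in set(manifest.sample_ids)]
    if unknown:
        raise ValueError(f"VCF samples absent from manifest: {unknown}")
    missing = [s for s in manifest.sample_ids if s not in set(vcf_samples)]
    if missing:
        raise ValueError(f"manifest samples absent from VCF: {missing}")
    order = np.array([vcf_samples.index(s) for s in manifest.sample_ids])

    records: list[VariantRecord] = []
    for v in vcf:
        depths = _depths_from_variant(v, len(vcf_samples))
        if depths is None:
            raise VcfFormatError(
                f"no AD or AO/RO depth fields at {v.CHROM}:{v.POS}"
            )
        alt_depths, total = depths
        for k, alt in enumerate(v.ALT):
            ad_k = alt_depths[:, k] if k < alt_depths.shape[1] else np.zeros(len(vcf_samples), int)
            records.append(VariantRecord(
                chrom=v.CHROM,
                pos=v.POS - 1,
                ref=v.REF,
                alt=alt,
                alt_depth=ad_k[order].astype(int),
                total_depth=total[order].astype(int),
            ))
    table = VariantTable(records, list(manifest.sample_ids))
    table.sort()
    return table


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a VariantTable as an uncompressed VCF with AD/DP fields.

    Decomposed records are written one per line; AD carries
    (site_depth - alt_depth, alt_depth) so that reading the file back
    reconstructs the same per-record depths.
    """
    chroms = sorted({r.chrom for r in table.records})
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                          "FILTER", "INFO", "FORMAT"] + list(table.sample_order))
        fh.write(cols + "\n")
        for r in table.records:
            fields = [
                r.chrom, str(r.pos + 1), ".", r.ref, r.alt, ".", ".", ".", "AD:DP",
            ]
            for a, t in zip(r.alt_depth, r.total_depth):
                fields.append(f"{int(t - a)},{int(a)}:{int(t)}")
            fh.write("\t".join(fields) + "\n")


def assign_variants(table: VariantTable, panel: GenePanel) -> dict[str, np.ndarray]:
    """Map gene_id -> indices of variants inside the gene's flanked region.

    Containment uses the half-open flanked interval; a variant overlapping
    several genes' regions is assigned to each of them, and variants in no
    region are omitted.
    """
    trees: dict[str, IntervalTree] = {}
    for r in panel.regions:
        trees.setdefault(r.chrom, IntervalTree())[r.region_start:r.region_end] = r.gene_id
    hits: dict[str, list[int]] = {g: [] for g in panel.gene_ids}
    for i, rec in enumerate(table.records):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for iv in tree[rec.pos]:
            hits[iv.data].append(i)
    return {g: np.array(sorted(ix), dtype=int) for g, ix in hits.items()}
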