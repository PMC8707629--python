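"""Polymorphism census over the gene panel.

Low-coverage joint calling motivates a read-support filter rather than a
genotype-quality filter: a variant is retained when at least one sample
supports the alternative allele with a minimum number of reads,
irrespective of its variant allele frequency.  Retained variants are then
tallied per gene over the flanked region, with densities expressed per kb
of analysis region (gene length + both flanks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GenePanel, VariantTable, assign_variants

DEFAULT_MIN_ALT_READS = 4


def filter_supported(table: VariantTable, min_alt_reads: int = DEFAULT_MIN_ALT_READS) -> VariantTable:
    """Keep variants whose maximum per-sample alt depth reaches the cutoff.

    "Supported in at least one sample" is evaluated as the maximum alt
    depth across samples; VAF plays no role.  ``min_alt_reads=0`` is the
    identity filter.
    """
    keep = [i for i, r in enumerate(table.records)
            if len(r.alt_depth) and int(np.max(r.alt_depth)) >= min_alt_reads]
    if min_alt_reads <= 0:
        keep = list(range(len(table.records)))
    return table.subset(keep)


@dataclass(frozen=True)
class CensusRecord:
    gene_id: str
    family: str
    n_polymorphisms: int
    region_length_bp: int

    @property
    def density_per_kb(self) -> float:
        return self.n_polymorphisms / (self.region_length_bp / 1000.0)


def census(table: VariantTable, panel: GenePanel) -> list[CensusRecord]:
    """Per-gene polymorphism counts and per-kb densities.

    The table is expected to be support-filtered already.  A variant in the
    flanked regions of several genes increments each of them.
    """
    assignment = assign_variants(table, panel)
    return [
        CensusRecord(r.gene_id, r.family, len(assignment[r.gene_id]), r.region_length_bp)
        for r in panel.regions
    ]


def census_frame(records: list[CensusRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.family, r.n_polymorphisms, r.region_length_bp, r.density_per_kb)
         for r in records],
        columns=["gene_id", "family", "n_polymorphisms", "region_length_bp", "density_per_kb"],
    )


def family_totals(records: list[CensusRecord]) -> dict[str, int]:
    """Total polymorphism count per gene family."""
    totals: dict[str, int] = {}
    for r in records:
        totals[r.family] = totals.get(r.family, 0) + r.n_polymorphisms
    return totals
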