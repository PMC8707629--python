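import numpy as np
import pytest

from flaxscreen import (
    CohortSimConfig,
    Sample,
    SampleManifest,
    VariantRecord,
    VariantTable,
    simulate_cohort,
    simulate_read_support,
)


@pytest.fixture
def small_manifest() -> SampleManifest:
    samples = [Sample(f"f{i}", "fiber", "test") for i in range(3)]
    samples += [Sample(f"l{i}", "linseed", "test") for i in range(3)]
    return SampleManifest(samples)


def make_table(depths, sample_ids, chrom="chr1", start_pos=100) -> VariantTable:
    """Variant table from a list of (alt_depth_list, total_depth_list)."""
    records = [
        VariantRecord(chrom, start_pos + i, "A", "T",
                      np.array(alt, dtype=int), np.array(tot, dtype=int))
        for i, (alt, tot) in enumerate(depths)
    ]
    return VariantTable(records, list(sample_ids))


@pytest.fixture
def small_cohort():
    """Simulated 12 + 14 cohort with a handful of genes, fixed seed."""
    cfg = CohortSimConfig(n_fiber=12, n_linseed=14, n_genes=6,
                          variants_per_gene_mean=5.0, frac_associated_genes=0.5,
                          delta=0.9, seed=7)
    manifest, panel, truth = simulate_cohort(cfg)
    table = simulate_read_support(truth, cfg)
    return cfg, manifest, panel, truth, table
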