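"""End-to-end orchestration: simulate/load -> census -> screen -> cluster.

One run takes a cohort (either simulated or read from VCF + BED + manifest
files), applies the read-support filter, runs the VAF association screen,
clusters the varieties, optionally preprocesses an expression matrix, and
writes every result as TSV next to a machine-readable JSON summary and
the resolved configuration.  Identical configurations (including seeds)
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clustering, expression, genomic_io, screen, simulate
from .census import DEFAULT_MIN_ALT_READS, census, census_frame, family_totals, filter_supported

log = logging.getLogger("flaxscreen")


@dataclass
class RunConfig:
    outdir: Path
    vcf: Path | None = None
    panel_bed: Path | None = None
    manifest: Path | None = None
    counts: Path | None = None
    sample_meta: Path | None = None
    simulate: bool = False
    sim: simulate.CohortSimConfig | None = None
    screen: screen.ScreenConfig = field(default_factory=screen.ScreenConfig)
    expr: expression.ExpressionConfig = field(default_factory=expression.ExpressionConfig)
    min_alt_reads: int = DEFAULT_MIN_ALT_READS
    cluster_k: int = 3
    use_packaged_panel: bool = False
    seed: int = 0


def validate_panel(panel: genomic_io.GenePanel) -> pd.DataFrame:
    """Per-family gene counts plus a total row for a panel."""
    rows = [(fam, len(genes)) for fam, genes in sorted(panel.family_index.items())]
    rows.append(("total", len(panel)))
    return pd.DataFrame(rows, columns=["family", "n_genes"])


def _load_inputs(config: RunConfig):
    if config.simulate:
        sim_cfg = config.sim or simulate.CohortSimConfig(seed=config.seed)
        if config.use_packaged_panel and sim_cfg.panel is None:
            sim_cfg = dataclasses.replace(sim_cfg, panel=genomic_io.default_panel())
        manifest, panel, truth = simulate.simulate_cohort(sim_cfg)
        table = simulate.simulate_read_support(truth, sim_cfg)
        return manifest, panel, table, truth
    if not (config.vcf and config.panel_bed and config.manifest):
        raise ValueError("need --vcf, --panel and --manifest unless simulating")
    manifest = genomic_io.read_manifest(config.manifest)
    panel = genomic_io.read_panel(config.panel_bed)
    table = genomic_io.read_vcf(config.vcf, manifest)
    return manifest, panel, table, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screen and write the report bundle.

    Returns the run summary (also written as ``summary.json``).  Any stage
    failure is re-raised with the stage name attached.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    stage = "setup"
    t0 = time.time()
    try:
        stage = "load"
        manifest, panel, table, truth = _load_inputs(config)
        genomic_io.write_manifest(manifest, out / "manifest.tsv")
        genomic_io.write_panel(panel, out / "panel.bed")
        genomic_io.write_vcf(table, out / "variants.vcf")
        validate_panel(panel).to_csv(out / "panel_families.tsv", sep="\t", index=False)
        summary["n_samples"] = len(manifest)
        summary["n_fiber"] = manifest.count("fiber")
        summary["n_linseed"] = manifest.count("linseed")
        summary["n_genes"] = len(panel)
        summary["n_variants_raw"] = len(table)

        stage = "census"
        supported = filter_supported(table, config.min_alt_reads)
        census_records = census(supported, panel)
        census_frame(census_records).to_csv(out / "census.tsv", sep="\t", index=False)
        summary["n_variants_supported"] = len(supported)
        summary["family_polymorphism_totals"] = family_totals(census_records)

        stage = "screen"
        records = screen.screen_variants(supported, manifest, panel, config.screen)
        screen.records_frame(records).to_csv(
            out / "associations.tsv", sep="\t", index=False, float_format="%.6g")
        summaries = screen.summarize_genes(records, panel)
        screen.summaries_frame(summaries).to_csv(
            out / "fta_genes_full.tsv", sep="\t", index=False, float_format="%.6g")
        screen.gene_report(summaries).to_csv(
            out / "fta_genes_report.tsv", sep="\t", index=False, float_format="%.6g")
        fams = screen.summarize_families(summaries, panel)
        pd.DataFrame(
            [(f, n, frac) for f, (n, frac) in sorted(fams.items())],
            columns=["family", "n_genes_with_fta", "fraction"],
        ).to_csv(out / "fta_families.tsv", sep="\t", index=False, float_format="%.6g")
        summary["n_fta_genes_strong"] = sum(s.n_fta_strong >= 1 for s in summaries)
        summary["n_fta_genes_very_strong"] = sum(s.n_fta_very_strong >= 1 for s in summaries)
        summary["fta_family_fractions"] = {
            f: (None if frac != frac else round(frac, 6)) for f, (n, frac) in sorted(fams.items())
        }

        stage = "cluster"
        vaf = screen.compute_vaf(supported)
        dist = clustering.vaf_distance(vaf)
        pd.DataFrame(dist, index=manifest.sample_ids, columns=manifest.sample_ids).to_csv(
            out / "distances.tsv", sep="\t", float_format="%.6g")
        sim_mat = clustering.similarity_from_distance(dist, manifest.sample_ids)
        sim_mat.frame().to_csv(out / "similarity.tsv", sep="\t", float_format="%.6g")
        tree = clustering.ward_cluster(dist, manifest.sample_ids)
        (out / "varieties.nwk").write_text(tree.to_newick() + "\n")
        comp = clustering.cluster_composition(tree, config.cluster_k, manifest)
        comp.to_csv(out / "cluster_composition.tsv", sep="\t", index=False,
                    float_format="%.6g")
        summary["cluster_purities"] = [round(p, 6) for p in comp["purity"]]

        if config.counts is not None:
            stage = "expression"
            counts = pd.read_csv(config.counts, sep="\t", index_col=0)
            meta = pd.read_csv(config.sample_meta, sep="\t", dtype=str)
            em = expression.ExpressionMatrix(counts, meta)
            cpm = expression.cpm_normalize(em)
            flags = expression.flag_low_expression(cpm, config.expr)
            mat = expression.heatmap_matrix(em, config.expr)
            trees, ordered = expression.cluster_heatmap(mat, axis="both")
            ordered.to_csv(out / "expression_heatmap.tsv", sep="\t", float_format="%.6g")
            flags.rename("low_expression").to_csv(out / "expression_low_flags.tsv", sep="\t")
            (out / "expression_genes.nwk").write_text(trees["genes"].to_newick() + "\n")
            (out / "expression_samples.nwk").write_text(trees["samples"].to_newick() + "\n")
            summary["n_expression_genes"] = int(counts.shape[0])
            summary["n_low_expressed"] = int(flags.sum())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["runtime_s"] = round(time.time() - t0, 3)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "run_config.json").write_text(_config_json(config))
    log.info("pipeline finished in %.2fs; outputs in %s", summary["runtime_s"], out)
    return summary


def _config_json(config: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, genomic_io.GenePanel):
            return f"<panel with {len(o)} genes>"
        return str(o)

    d = dataclasses.asdict(config, dict_factory=dict)
    return json.dumps(d, indent=2, sort_keys=True, default=enc) + "\n"
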