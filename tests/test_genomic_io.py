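import numpy as np
import pytest

from flaxscreen import (
    GenePanel,
    GeneRegion,
    assign_variants,
    default_panel,
    load_panel_genes,
    read_manifest,
    read_panel,
    read_vcf,
    write_manifest,
    write_panel,
    write_vcf,
)
from flaxscreen.genomic_io import PanelError, Sample, SampleManifest, VcfFormatError

from conftest import make_table
from oracles import assign_by_scan

VCF_AD = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t1001\t.\tG\tA\t.\t.\t.\tGT:AD\t0/1:6,4\t0/0:8,0
chr1\t2000\t.\tC\tA,T\t.\t.\t.\tGT:AD\t1/2:2,3,4\t0/0:5,0,1
"""

VCF_AORO = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alt obs">
##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Ref obs">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t501\t.\tA\tC\t.\t.\t.\tAO:RO\t5:2\t0:9
"""

VCF_NO_DEPTH = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tC\t.\t.\t.\tGT\t0/1\t0/0
"""


@pytest.fixture
def two_sample_manifest():
    return SampleManifest([Sample("s1", "fiber"), Sample("s2", "linseed")])


class TestReadVcf:
    def test_ad_depths_and_coordinates(self, tmp_path, two_sample_manifest):
        """AD 6,4 gives alt 4 / site depth 10; VCF POS 1001 becomes 0-based 1000."""
        path = tmp_path / "a.vcf"
        path.write_text(VCF_AD)
        table = read_vcf(path, two_sample_manifest)
        rec = table.records[0]
        assert (rec.pos, rec.ref, rec.alt) == (1000, "G", "A")
        assert rec.alt_depth.tolist() == [4, 0]
        assert rec.total_depth.tolist() == [10, 8]
        assert rec.kind == "SNV"

    def test_multiallelic_decomposition_shares_site_depth(self, tmp_path, two_sample_manifest):
        path = tmp_path / "a.vcf"
        path.write_text(VCF_AD)
        table = read_vcf(path, two_sample_manifest)
        decomposed = [r for r in table.records if r.pos == 1999]
        assert [r.alt for r in decomposed] == ["A", "T"]
        assert [int(r.alt_depth[0]) for r in decomposed] == [3, 4]
        # site depth (AD sum) is shared across the decomposed records
        assert all(int(r.total_depth[0]) == 9 for r in decomposed)
        assert all(int(r.total_depth[1]) == 6 for r in decomposed)

    def test_ao_ro_fallback(self, tmp_path, two_sample_manifest):
        path = tmp_path / "a.vcf"
        path.write_text(VCF_AORO)
        table = read_vcf(path, two_sample_manifest)
        rec = table.records[0]
        assert rec.alt_depth.tolist() == [5, 0]
        assert rec.total_depth.tolist() == [7, 9]

    def test_missing_depth_fields_error_names_site(self, tmp_path, two_sample_manifest):
        path = tmp_path / "a.vcf"
        path.write_text(VCF_NO_DEPTH)
        with pytest.raises(VcfFormatError, match="chr1:100"):
            read_vcf(path, two_sample_manifest)

    def test_vcf_sample_not_in_manifest_errors(self, tmp_path):
        path = tmp_path / "a.vcf"
        path.write_text(VCF_AD)
        manifest = SampleManifest([Sample("s1", "fiber"), Sample("other", "linseed")])
        with pytest.raises(ValueError, match="s2"):
            read_vcf(path, manifest)

    def test_samples_reordered_to_manifest(self, tmp_path):
        path = tmp_path / "a.vcf"
        path.write_text(VCF_AD)
        manifest = SampleManifest([Sample("s2", "linseed"), Sample("s1", "fiber")])
        table = read_vcf(path, manifest)
        assert table.sample_order == ["s2", "s1"]
        assert table.records[0].alt_depth.tolist() == [0, 4]


def test_vcf_round_trip_preserves_records(tmp_path, small_cohort):
    """write_vcf(read_vcf(f)) keeps chrom/pos/ref/alt and all depths."""
    _, manifest, _, _, table = small_cohort
    p1 = tmp_path / "out.vcf"
    write_vcf(table, p1)
    back = read_vcf(p1, manifest)
    assert len(back) == len(table)
    for a, b in zip(table.records, back.records):
        assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)
        assert a.alt_depth.tolist() == b.alt_depth.tolist()
        assert a.total_depth.tolist() == b.total_depth.tolist()


class TestPanel:
    def test_read_write_round_trip(self, tmp_path):
        panel = GenePanel([GeneRegion("g1", "lignin", "chr1", 100, 600, "+"),
                           GeneRegion("g2", "CTL", "chr2", 0, 50, "-")])
        path = tmp_path / "p.bed"
        write_panel(panel, path)
        back = read_panel(path)
        assert back.gene_ids == ["g1", "g2"]
        assert back.region("g2").strand == "-"
        assert back.region("g1").start == 100 and back.region("g1").end == 600

    def test_duplicate_gene_id_errors(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t0\t10\tg1\tlignin\t+\nchr2\t0\t10\tg1\tCTL\t+\n")
        with pytest.raises(PanelError, match="g1"):
            read_panel(path)

    def test_end_not_after_start_errors(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t10\t10\tg1\tlignin\t+\n")
        with pytest.raises(PanelError, match="g1"):
            read_panel(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            panel = read_panel(path)
        assert len(panel) == 0

    def test_flanked_region_clips_at_zero(self):
        r = GeneRegion("g", "ACT", "chr1", 200, 700, flank_bp=500)
        assert (r.region_start, r.region_end) == (0, 1200)
        assert r.region_length_bp == 1500  # unclipped definition


def test_packaged_panel_families():
    """The packaged candidate panel has 424 genes in the expected families."""
    genes = load_panel_genes()
    assert len(genes) == 424
    counts = genes["family"].value_counts().to_dict()
    assert counts == {"ABC_HMA": 206, "lignin": 66, "BGAL": 40, "CTL": 35,
                      "TUB": 21, "CESA": 16, "ACT": 15, "RGL": 10,
                      "lignan": 9, "FA": 6}
    panel = default_panel()
    assert len(panel.family_index["lignin"]) == 66
    assert len(panel) == 424


def test_manifest_round_trip_and_duplicates(tmp_path):
    m = SampleManifest([Sample("a", "fiber", "x"), Sample("b", "linseed", "y")])
    path = tmp_path / "m.tsv"
    write_manifest(m, path)
    back = read_manifest(path)
    assert back.sample_ids == ["a", "b"]
    assert back.labels().tolist() == [1, 0]
    with pytest.raises(ValueError, match="duplicate"):
        SampleManifest([Sample("a", "fiber"), Sample("a", "linseed")])


class TestAssignVariants:
    def test_half_open_boundaries(self):
        panel = GenePanel([GeneRegion("g", "ACT", "chr1", 1000, 2000, flank_bp=500)])
        table = make_table([([0, 0], [1, 1])] * 3, ["s1", "s2"])
        table.records[0].pos = 600    # inside [500, 2500)
        table.records[1].pos = 2500   # excluded right edge
        table.records[2].pos = 500    # included left edge
        table.sort()
        got = assign_variants(table, panel)["g"]
        positions = [table.records[i].pos for i in got]
        assert sorted(positions) == [500, 600]

    def test_overlapping_genes_both_assigned(self):
        panel = GenePanel([GeneRegion("g1", "ACT", "chr1", 1000, 2000, flank_bp=500),
                           GeneRegion("g2", "TUB", "chr1", 1800, 3000, flank_bp=500)])
        table = make_table([([0], [1])], ["s1"])
        table.records[0].pos = 1900
        got = assign_variants(table, panel)
        assert got["g1"].tolist() == [0] and got["g2"].tolist() == [0]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        regions = []
        for i in range(25):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 5000))
            regions.append(GeneRegion(f"g{i}", "ACT", chrom, start,
                                      start + int(rng.integers(100, 1500)),
                                      flank_bp=int(rng.integers(0, 600))))
        panel = GenePanel(regions)
        n_var = 300
        chroms = [f"chr{c}" for c in rng.integers(1, 4, size=n_var)]
        positions = rng.integers(0, 8000, size=n_var)
        table = make_table([([0], [1])] * n_var, ["s1"])
        for rec, c, p in zip(table.records, chroms, positions):
            rec.chrom, rec.pos = c, int(p)
        got = assign_variants(table, panel)
        expected = assign_by_scan(
            [(r.chrom, r.pos) for r in table.records],
            [(r.gene_id, r.chrom, r.region_start, r.region_end) for r in regions])
        assert {g: v.tolist() for g, v in got.items()} == expected
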