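"""Gene-context statistics: feature classes, TSS distance, metagene, enrichment."""

import numpy as np
import pytest

from ripscan.genomic_context import (
    GeneContext,
    GeneModel,
    classify_feature,
    distance_to_tss,
    feature_class_percentages,
    load_genes,
    megabase_density_correlation,
    metagene_profile,
    upstream_depth_by_gene,
    upstream_enrichment,
    write_gff3,
)


@pytest.fixture
def plus_gene():
    return GeneModel("g1", "chr1", "+", 10_000, 13_000,
                     exons=[(10_000, 10_600), (11_200, 11_800), (12_400, 13_000)])


@pytest.fixture
def minus_gene():
    return GeneModel("g2", "chr1", "-", 30_000, 33_000,
                     exons=[(30_000, 30_600), (31_200, 31_800), (32_400, 33_000)])


class TestGeneModel:
    def test_overlapping_exons_merged(self):
        g = GeneModel("g", "chr1", "+", 0, 100, exons=[(0, 50), (40, 80)])
        assert g.exons == [(0, 80)]

    def test_no_exons_falls_back_to_gene_span(self):
        g = GeneModel("g", "chr1", "+", 5, 50)
        assert g.exons == [(5, 50)]

    def test_exon_outside_gene_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", "+", 10, 20, exons=[(0, 30)])

    def test_missing_strand_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", ".", 0, 10)

    def test_gff3_coordinate_conversion(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
            "chr1\tx\texon\t1001\t1200\t.\t+\t.\tID=g1.e1;Parent=g1\n"
        )
        (g,) = load_genes(p)
        assert (g.start, g.end) == (1000, 2000)
        assert g.exons == [(1000, 1200)]


class TestClassify:
    def test_precedence_exon_over_flank(self, plus_gene, minus_gene):
        # 10_500 is exonic in g1 even though genes could neighbour it
        assert classify_feature(10_500, "chr1", [plus_gene, minus_gene]) == "exon"

    def test_intron(self, plus_gene):
        assert classify_feature(11_000, "chr1", [plus_gene]) == "intron"

    def test_up2kb_plus_strand(self, plus_gene):
        assert classify_feature(8_500, "chr1", [plus_gene]) == "up2kb"

    def test_up2kb_minus_strand_is_right_of_gene(self, minus_gene):
        assert classify_feature(34_000, "chr1", [minus_gene]) == "up2kb"
        assert classify_feature(29_000, "chr1", [minus_gene]) == "down2kb"

    def test_intergenic(self, plus_gene):
        assert classify_feature(20_000, "chr1", [plus_gene]) == "intergenic"

    def test_percentages_sum_to_100(self, plus_gene, minus_gene, rng):
        pts = [("chr1", int(p)) for p in rng.integers(0, 40_000, 500)]
        pct = feature_class_percentages(pts, [plus_gene, minus_gene])
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.1)


class TestTSSDistance:
    def test_upstream_point(self, plus_gene):
        assert distance_to_tss(9_900, "chr1", [plus_gene]) == 100

    def test_at_tss(self, plus_gene):
        assert distance_to_tss(10_000, "chr1", [plus_gene]) == 0

    def test_minus_strand_tss_is_right_end(self, minus_gene):
        assert distance_to_tss(32_999, "chr1", [minus_gene]) == 0

    def test_nearest_wins(self):
        genes = [GeneModel("a", "chr1", "+", 0, 100),
                 GeneModel("b", "chr1", "+", 10_000, 10_100)]
        assert distance_to_tss(4_000, "chr1", genes) == 4_000

    def test_no_genes_on_chrom_warns(self, plus_gene):
        with pytest.warns(UserWarning):
            assert distance_to_tss(5, "chrX", [plus_gene]) is None


class TestDensityCorrelation:
    def test_perfect_anticorrelation(self):
        genes = []
        gid = 0
        for b, n in enumerate([3, 2, 1]):
            for _ in range(n):
                genes.append(GeneModel(f"g{gid}", "chr1", "+", b * 100 + 1, b * 100 + 50))
                gid += 1
        pts = [("chr1", b * 100 + 10) for b, n in enumerate([1, 2, 3]) for _ in range(n)]
        r = megabase_density_correlation(pts, genes, {"chr1": 300}, bin_size=100)
        assert r == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        genes = [GeneModel(f"g{i}", "chr1", "+", b * 100 + 1, b * 100 + 50)
                 for b in range(3) for i in range(b + 1)]
        pts = [("chr1", b * 100 + 10) for b in range(3) for _ in range(b + 1)]
        r = megabase_density_correlation(pts, genes, {"chr1": 300}, bin_size=100)
        assert r == pytest.approx(1.0)

    def test_constant_vector_returns_none(self):
        genes = [GeneModel(f"g{b}", "chr1", "+", b * 100 + 1, b * 100 + 50) for b in range(3)]
        pts = [("chr1", 10), ("chr1", 110), ("chr1", 210)]
        with pytest.warns(UserWarning):
            assert megabase_density_correlation(pts, genes, {"chr1": 300}, 100) is None

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            megabase_density_correlation([], [], {"chr1": 100}, bin_size=100)


class TestMetagene:
    def test_tss_anchors_spike_at_body_start(self, plus_gene):
        prof = metagene_profile([("chr1", 10_000)] * 10, [plus_gene])
        n_flank = 2000 // 50
        assert prof[n_flank] == pytest.approx(1.0)
        assert prof.sum() == pytest.approx(1.0)

    def test_profile_sums_to_one(self, plus_gene, minus_gene, rng):
        pts = [("chr1", int(p)) for p in rng.integers(7_000, 36_000, 2_000)]
        prof = metagene_profile(pts, [plus_gene, minus_gene])
        assert prof.sum() == pytest.approx(1.0)

    def test_strand_flip_reverses_profile_exactly(self, rng):
        genes = [GeneModel(f"g{i}", "chr1", "+", 10_000 + 8_000 * i, 13_000 + 8_000 * i)
                 for i in range(4)]
        flipped = [GeneModel(g.gene_id, g.chrom, "-", g.start, g.end) for g in genes]
        pts = [("chr1", int(p)) for p in rng.integers(7_000, 40_000, 3_000)]
        a = metagene_profile(pts, genes)
        b = metagene_profile(pts, flipped)
        assert np.array_equal(a, b[::-1])

    def test_empty_anchors_warns_zero_vector(self, plus_gene):
        with pytest.warns(UserWarning):
            prof = metagene_profile([], [plus_gene])
        assert prof.sum() == 0

    def test_approximately_flat_for_uniform_anchors(self, rng):
        """Uniform anchors over one gene +- flank give a flat profile
        (chi-square goodness of fit against uniform)."""
        from scipy import stats

        g = GeneModel("g", "chr1", "+", 2_000, 12_000)  # body 10 kb = 100 bins x 100 bp
        pts = [("chr1", int(p)) for p in rng.integers(0, 14_000, 10_000)]
        prof = metagene_profile(pts, [g], flank=2000, body_bins=100, flank_bin=50)
        counts = prof * 10_000
        # flank bins cover 50 bp, body bins 100 bp: expected proportional to width
        widths = np.array([50] * 40 + [100] * 100 + [50] * 40)
        expected = widths / widths.sum() * counts.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=len(counts) - 1) > 0.001


class TestUpstreamEnrichment:
    def test_ratio_boundary_inclusive(self):
        depth = {"landrace": {"g": 40}, "teosinte": {"g": 7}}
        sizes = {"landrace": 4, "teosinte": 4}
        # normalized: 10 vs (1.75 + 0.25) = ratio exactly 5 -> included
        assert upstream_enrichment(depth, sizes) == ["g"]

    def test_zero_numerator_excluded(self):
        depth = {"landrace": {"g": 0}, "teosinte": {"g": 0}}
        assert upstream_enrichment(depth, {"landrace": 4, "teosinte": 4}) == []

    def test_zero_denominator_included_via_pseudocount(self):
        depth = {"landrace": {"g": 100}, "teosinte": {"g": 0}}
        assert upstream_enrichment(depth, {"landrace": 4, "teosinte": 4}) == ["g"]

    def test_missing_group_rejected(self):
        with pytest.raises(KeyError):
            upstream_enrichment({"landrace": {}}, {"landrace": 4, "teosinte": 4})

    def test_depth_counting_is_strand_aware(self, plus_gene, minus_gene):
        anchors = [("chr1", 9_000), ("chr1", 34_000), ("chr1", 29_000)]
        counts = upstream_depth_by_gene(anchors, [plus_gene, minus_gene])
        assert counts == {"g1": 1, "g2": 1}
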