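import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mbsub.peaks import (
    AnnotationParams,
    GeneModel,
    GenomicInterval,
    annotate_peak,
    genomic_distribution,
    merge_union,
    read_bed,
    region_enrichment,
    write_bed,
)
from mbsub.synthetic import plant_peaks, simulate_genome

from conftest import union_oracle


class TestMergeUnion:
    def test_overlapping_merged(self):
        out = merge_union([GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 20)])
        assert [(iv.start, iv.end) for iv in out] == [(0, 20)]

    def test_touching_merged(self):
        out = merge_union([GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 15)])
        assert [(iv.start, iv.end) for iv in out] == [(0, 15)]

    def test_disjoint_untouched(self):
        ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]
        out = merge_union(ivs)
        assert [(iv.start, iv.end) for iv in out] == [(0, 10), (20, 30)]

    def test_chromosomes_kept_separate(self):
        out = merge_union(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 5, 15)]
        )
        assert {iv.chrom for iv in out} == {"chr1", "chr2"}

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="invalid interval"):
            GenomicInterval("chr1", 10, 10)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spans = []
        for _ in range(200):
            s = int(rng.integers(0, 900))
            spans.append((s, s + int(rng.integers(1, 60))))
        merged = merge_union([GenomicInterval("c", s, e) for s, e in spans])
        assert [(iv.start, iv.end) for iv in merged] == union_oracle(spans)


def _gene(start, end, strand, exons=(), chrom="chr1", gene_id="g"):
    return GeneModel(gene_id, chrom, start, end, strand, tuple(exons))


class TestAnnotatePeak:
    params = AnnotationParams()

    def test_peak_spanning_plus_tss_is_promoter(self):
        gene = _gene(10_000, 20_000, "+", [(10_000, 10_400)])
        peak = GenomicInterval("chr1", 9_900, 10_100)
        assert annotate_peak(peak, [gene], self.params) == "promoter"

    def test_minus_strand_tss_convention(self):
        gene = _gene(10_000, 20_000, "-")
        assert gene.tss == 19_999
        peak = GenomicInterval("chr1", 20_500, 20_700)  # upstream of the minus TSS
        assert annotate_peak(peak, [gene], self.params) == "promoter"

    def test_exon_beats_intron(self):
        gene = _gene(10_000, 40_000, "+", [(10_000, 10_400), (24_800, 25_200)])
        peak = GenomicInterval("chr1", 24_900, 25_000)
        assert annotate_peak(peak, [gene], self.params) == "exon"

    def test_intron_far_from_tss(self):
        gene = _gene(10_000, 40_000, "+", [(10_000, 10_400), (39_600, 40_000)])
        peak = GenomicInterval("chr1", 20_000, 20_200)
        assert annotate_peak(peak, [gene], self.params) == "intron"

    def test_downstream_window(self):
        gene = _gene(10_000, 20_000, "+")
        peak = GenomicInterval("chr1", 21_000, 21_200)
        # 3 kb past the plus-strand gene end but outside any promoter
        assert annotate_peak(peak, [gene], self.params) == "downstream"

    def test_no_genes_anywhere_is_distal(self):
        peak = GenomicInterval("chrX", 100, 200)
        assert annotate_peak(peak, [], self.params) == "distal intergenic"

    def test_planted_round_trip_all_categories(self):
        genes, chrom_sizes = simulate_genome(n_chroms=2, n_genes=20, seed=6)
        for category in ("promoter", "exon", "intron", "downstream", "distal intergenic"):
            peaks = plant_peaks(genes, chrom_sizes, category, 8, seed=3)
            assert all(annotate_peak(p, genes) == category for p in peaks)


class TestGenomicDistribution:
    def test_planted_promoters_give_fraction_one(self):
        genes, chrom_sizes = simulate_genome(n_chroms=1, n_genes=10, seed=1)
        peaks = plant_peaks(genes, chrom_sizes, "promoter", 12, seed=2)
        dist = genomic_distribution(peaks, genes)
        assert dist["promoter"] == pytest.approx(1.0)

    def test_fractions_sum_to_one_and_order_invariant(self):
        genes, chrom_sizes = simulate_genome(n_chroms=2, n_genes=16, seed=9)
        peaks = []
        for i, cat in enumerate(("promoter", "intron", "distal intergenic")):
            peaks += plant_peaks(genes, chrom_sizes, cat, 5, seed=10 + i)
        dist = genomic_distribution(peaks, genes)
        assert sum(dist.values()) == pytest.approx(1.0)
        assert genomic_distribution(list(reversed(peaks)), genes) == dist

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            genomic_distribution([], [])


class TestRegionEnrichment:
    def test_self_overlap_is_extreme(self):
        genes, chrom_sizes = simulate_genome(n_chroms=1, n_genes=8, seed=5)
        query = plant_peaks(genes, chrom_sizes, "distal intergenic", 30, seed=4)
        (res,) = region_enrichment(
            query, {"self": query}, chrom_sizes, n_shuffles=200, seed=0
        )
        assert res.observed == len(query)
        assert res.p <= 1 / 201 + 1e-12
        assert res.z is not None and res.z > 5

    def test_genome_wide_catalog_degenerate(self):
        chrom_sizes = {"chr1": 10_000}
        query = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 5_000, 5_100)]
        catalog = {"all": [GenomicInterval("chr1", 0, 10_000)]}
        (res,) = region_enrichment(query, catalog, chrom_sizes, n_shuffles=100, seed=1)
        assert res.z is None  # null has zero spread
        assert res.p == pytest.approx(1.0)

    def test_empirical_p_never_zero_and_seeded(self):
        rng = np.random.default_rng(11)
        chrom_sizes = {"chr1": 1_000_000}
        query = [
            GenomicInterval("chr1", int(s), int(s) + 300)
            for s in rng.integers(0, 999_000, 20)
        ]
        catalog = {
            "c": [
                GenomicInterval("chr1", int(s), int(s) + 500)
                for s in rng.integers(0, 999_000, 40)
            ]
        }
        r1 = region_enrichment(query, catalog, chrom_sizes, n_shuffles=99, seed=5)
        r2 = region_enrichment(query, catalog, chrom_sizes, n_shuffles=99, seed=5)
        assert r1[0].p > 0
        assert (r1[0].p, r1[0].null_mean, r1[0].null_sd) == (
            r2[0].p, r2[0].null_mean, r2[0].null_sd,
        )

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            region_enrichment(
                [GenomicInterval("chr1", 0, 2_000)],
                {"c": []},
                {"chr1": 1_000},
                n_shuffles=10,
                seed=0,
            )

    def test_bh_correction_across_labels(self):
        genes, chrom_sizes = simulate_genome(n_chroms=1, n_genes=6, seed=3)
        query = plant_peaks(genes, chrom_sizes, "distal intergenic", 25, seed=1)
        rng = np.random.default_rng(2)
        random_cat = [
            GenomicInterval("chr1", int(s), int(s) + 400)
            for s in rng.integers(0, chrom_sizes["chr1"] - 400, 30)
        ]
        results = region_enrichment(
            query, {"self": query, "random": random_cat}, chrom_sizes,
            n_shuffles=200, seed=9,
        )
        by_label = {r.label: r for r in results}
        assert by_label["self"].q <= by_label["random"].q
        assert all(0 < r.q <= 1 for r in results)


class TestBedIO:
    def test_roundtrip(self, tmp_path):
        ivs = [
            GenomicInterval("chr1", 0, 100, "a", 5.0),
            GenomicInterval("chr2", 50, 80, None, None),
        ]
        path = tmp_path / "x.bed"
        write_bed(ivs, path)
        back = read_bed(path)
        assert [(i.chrom, i.start, i.end, i.name) for i in back] == [
            ("chr1", 0, 100, "a"), ("chr2", 50, 80, None),
        ]
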