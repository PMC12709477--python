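import numpy as np
import pandas as pd
import pytest

from mbsub.synthetic import (
    CohortSpec,
    PlatformDistortion,
    XenograftSpec,
    simulate_cohort,
    simulate_de_tables,
    simulate_genome,
    simulate_xenograft_alignments,
)

from conftest import SMALL_SPEC


class TestCohort:
    def test_fixed_seed_bit_identical(self):
        a = simulate_cohort(SMALL_SPEC)
        b = simulate_cohort(SMALL_SPEC)
        assert a.expression.equals(b.expression)
        assert a.labels.equals(b.labels)
        assert a.marker_map == b.marker_map

    def test_zero_delta_null_case(self):
        spec = CohortSpec(
            n_subgroups=2, samples_per_subgroup=30, n_genes=300,
            marker_sets_per_subgroup=2, n_gene_sets=10, genes_per_set=10,
            effect_size_delta=0.0, noise_sd=0.5, seed=3,
        )
        cohort = simulate_cohort(spec)
        genes = sorted(cohort.gene_sets[cohort.marker_map["SG1"][0]].genes)
        sg1 = cohort.labels[cohort.labels == "SG1"].index
        sg2 = cohort.labels[cohort.labels == "SG2"].index
        diff = (
            cohort.undistorted.loc[genes, sg1].mean(axis=1)
            - cohort.undistorted.loc[genes, sg2].mean(axis=1)
        )
        # sampling error of a mean difference at sd 0.5, n 30/group
        assert abs(diff.mean()) < 3 * 0.5 * np.sqrt(2 / 30)

    def test_planted_shift_recovered(self):
        spec = CohortSpec(
            n_subgroups=2, samples_per_subgroup=40, n_genes=300,
            marker_sets_per_subgroup=2, n_gene_sets=10, genes_per_set=10,
            effect_size_delta=2.0, noise_sd=0.5, seed=4,
        )
        cohort = simulate_cohort(spec)
        marker_genes = sorted(
            g
            for name in cohort.marker_map["SG1"]
            for g in cohort.gene_sets[name].genes
        )
        sg1 = cohort.labels[cohort.labels == "SG1"].index
        sg2 = cohort.labels[cohort.labels == "SG2"].index
        diff = (
            cohort.undistorted.loc[marker_genes, sg1].mean(axis=1)
            - cohort.undistorted.loc[marker_genes, sg2].mean(axis=1)
        ).mean()
        assert diff == pytest.approx(2.0, abs=0.15)

    def test_labels_balanced_and_platforms_assigned(self, small_cohort):
        counts = small_cohort.labels.value_counts()
        assert (counts == SMALL_SPEC.samples_per_subgroup).all()
        assert set(small_cohort.sample_platform) == {
            p.name for p in SMALL_SPEC.platforms
        }

    def test_platform_distortion_preserves_ranks(self, small_cohort):
        for s in small_cohort.expression.columns[:8]:
            raw = small_cohort.undistorted[s].rank()
            warped = small_cohort.expression[s].rank()
            assert raw.equals(warped)

    def test_distortion_strictly_increasing(self):
        d = PlatformDistortion("p", slope=1.4, intercept=2.0, power=1.15)
        x = np.linspace(-5, 15, 500)
        assert (np.diff(d.apply(x)) > 0).all()
        with pytest.raises(ValueError, match="strictly increasing"):
            PlatformDistortion("bad", slope=-1.0)

    def test_marker_sets_exceeding_genes_rejected(self):
        with pytest.raises(ValueError, match="exceed n_genes"):
            CohortSpec(n_genes=50, n_gene_sets=20, marker_sets_per_subgroup=2,
                       genes_per_set=10, n_subgroups=4)


class TestXenograft:
    def test_pure_graft(self):
        pairs, origins = simulate_xenograft_alignments(
            XenograftSpec(n_pairs=100, graft_fraction=1.0, ambiguous_fraction=0.0, seed=1)
        )
        assert all(o == "graft" for o in origins)
        assert all(p.human_score > p.mouse_score for p in pairs)

    def test_all_ambiguous_tied(self):
        pairs, _ = simulate_xenograft_alignments(
            XenograftSpec(n_pairs=50, graft_fraction=0.0, ambiguous_fraction=1.0, seed=2)
        )
        assert all(p.human_score == p.mouse_score for p in pairs)

    def test_graft_fraction_matches(self):
        pairs, origins = simulate_xenograft_alignments(
            XenograftSpec(n_pairs=1000, graft_fraction=0.6, ambiguous_fraction=0.0, seed=3)
        )
        frac = np.mean([p.human_score > p.mouse_score for p in pairs])
        assert frac == pytest.approx(0.6, abs=0.01)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="<= 1"):
            XenograftSpec(graft_fraction=0.8, ambiguous_fraction=0.4)


class TestDeTables:
    def test_planted_flags_and_reproducibility(self):
        a = simulate_de_tables(n_genes=300, seed=9)
        b = simulate_de_tables(n_genes=300, seed=9)
        for ta, tb in zip(a.foreground + a.background, b.foreground + b.background):
            pd.testing.assert_frame_equal(ta, tb)
        for table in a.foreground:
            sub = table[table["gene"].isin(a.truth["exclusive_up"])]
            assert (sub["log2FoldChange"] > 1).all()
            assert (sub["padj"] < 0.05).all()

    def test_nothing_planted_means_nothing_significant(self):
        sim = simulate_de_tables(
            n_genes=400, n_exclusive_up=0, n_exclusive_down=0, n_shared_mixed=0,
            n_shared_with_background=0, n_low_count=0, seed=5,
        )
        for table in sim.foreground + sim.background:
            sig = (table["padj"] < 0.05) & (table["log2FoldChange"].abs() > 1)
            assert not sig.any()

    def test_overpacked_roles_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            simulate_de_tables(n_genes=50, n_exclusive_up=60)


class TestGenome:
    def test_genes_disjoint_and_within_bounds(self):
        genes, chrom_sizes = simulate_genome(n_chroms=3, n_genes=30, seed=8)
        by_chrom: dict = {}
        for g in genes:
            assert 0 <= g.start < g.end <= chrom_sizes[g.chrom]
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))

    def test_minus_strand_tss_is_end_minus_one(self):
        genes, _ = simulate_genome(n_chroms=1, n_genes=4, seed=2)
        minus = [g for g in genes if g.strand == "-"]
        assert minus and all(g.tss == g.end - 1 for g in minus)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genome(n_chroms=1, chrom_length=100_000, n_genes=50, seed=0)

    def test_zero_genes_allowed(self):
        genes, chrom_sizes = simulate_genome(n_chroms=1, n_genes=0, seed=0)
        assert genes == [] and chrom_sizes
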