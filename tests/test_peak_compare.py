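import numpy as np
import pytest

from peakbench.core_io import ChromSizes, GeneModel, GenomicInterval, ReadSet
from peakbench.peak_compare import (annotate_peaks, coverage_summary,
                                    fdr_quantile_recovery, find_overlaps,
                                    merge_replicates, partition_unique_common,
                                    random_matched_regions,
                                    region_read_coverage, saturation_recall)
from .conftest import (make_peak, overlap_oracle, random_intervals,
                       region_coverage_oracle)


class TestFindOverlaps:
    def test_direct_overlap(self):
        rep = find_overlaps([make_peak("chr1", 100, 200)],
                            [make_peak("chr1", 150, 250)], 0)
        assert rep.nA_hit == 1 and rep.components_both == 1
        assert rep.pctA == 1.0

    def test_gap_within_maxgap(self):
        rep = find_overlaps([make_peak("chr1", 100, 200)],
                            [make_peak("chr1", 250, 300)], 100)
        assert rep.nA_hit == 1  # gap is 50

    def test_gap_beyond_maxgap(self):
        rep = find_overlaps([make_peak("chr1", 100, 200)],
                            [make_peak("chr1", 350, 400)], 100)
        assert rep.nA_hit == 0  # gap is 150
        assert rep.components_onlyA == 1 and rep.components_onlyB == 1

    def test_negative_maxgap_rejected(self):
        with pytest.raises(ValueError):
            find_overlaps([], [], -1)

    def test_matches_brute_force_oracle(self, small_sizes):
        rng = np.random.default_rng(40)
        A = [make_peak(iv.chrom, iv.start, iv.end)
             for iv in random_intervals(rng, 250, small_sizes)]
        B = [make_peak(iv.chrom, iv.start, iv.end)
             for iv in random_intervals(rng, 250, small_sizes)]
        rep = find_overlaps(A, B, 0)
        a_hit, b_hit = overlap_oracle([p.interval for p in A],
                                      [p.interval for p in B], 0)
        assert rep.nA_hit == sum(a_hit) and rep.nB_hit == sum(b_hit)

    def test_monotone_in_maxgap(self, small_sizes):
        rng = np.random.default_rng(41)
        A = [make_peak(iv.chrom, iv.start, iv.end)
             for iv in random_intervals(rng, 100, small_sizes)]
        B = [make_peak(iv.chrom, iv.start, iv.end)
             for iv in random_intervals(rng, 100, small_sizes)]
        prev_a, prev_b = -1, -1
        for maxgap in (0, 100, 200, 4000):  # the published maxgap grid
            rep = find_overlaps(A, B, maxgap)
            # hit counts grow with maxgap; merged-component counts need not
            # (two "both" components can fuse into one), so only bound them
            assert rep.nA_hit >= prev_a and rep.nB_hit >= prev_b
            assert rep.components_both <= min(rep.nA_hit, rep.nB_hit)
            prev_a, prev_b = rep.nA_hit, rep.nB_hit

    def test_chained_component_counted_once(self):
        # a1 - b - a2 chain merges into a single "both" component
        A = [make_peak("chr1", 0, 100), make_peak("chr1", 220, 300)]
        B = [make_peak("chr1", 110, 210)]
        rep = find_overlaps(A, B, 20)
        assert rep.components_both == 1
        assert rep.components_onlyA == rep.components_onlyB == 0


class TestMergeReplicates:
    def test_union_coordinates(self):
        merged = merge_replicates([make_peak("chr1", 100, 200, q=3.0)],
                                  [make_peak("chr1", 150, 250, q=5.0)])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 250)

    def test_unreplicated_dropped(self):
        merged = merge_replicates(
            [make_peak("chr1", 100, 200, q=3.0),
             make_peak("chr1", 5000, 5100, q=9.0)],
            [make_peak("chr1", 150, 250, q=5.0)])
        assert len(merged) == 1

    def test_best_significance_kept(self):
        merged = merge_replicates([make_peak("chr1", 0, 100, q=3.0, p=2.0)],
                                  [make_peak("chr1", 50, 150, q=5.0, p=7.0)])
        assert merged[0].q == 5.0 and merged[0].p == 7.0

    def test_fdr_cutoff_applied_before_matching(self):
        merged = merge_replicates([make_peak("chr1", 0, 100, q=0.5)],
                                  [make_peak("chr1", 50, 150, q=5.0)],
                                  fdr_cutoff=0.05)
        assert merged == []

    def test_cutoff_without_q_rejected(self):
        with pytest.raises(ValueError, match="q values"):
            merge_replicates([make_peak("chr1", 0, 100)],
                             [make_peak("chr1", 50, 150)], fdr_cutoff=0.05)

    def test_output_self_merged(self, small_sizes):
        rng = np.random.default_rng(42)
        A = [make_peak(iv.chrom, iv.start, iv.end, q=5.0)
             for iv in random_intervals(rng, 80, small_sizes)]
        B = [make_peak(iv.chrom, iv.start, iv.end, q=5.0)
             for iv in random_intervals(rng, 80, small_sizes)]
        merged = merge_replicates(A, B, maxgap=50)
        from peakbench.core_io import gap
        for i, a in enumerate(merged):
            for b in merged[i + 1:]:
                assert gap(a.interval, b.interval) > 50


class TestQuantileRecovery:
    def test_all_recovered(self):
        cands = [make_peak("chr1", i * 1000, i * 1000 + 100, q=float(i + 1))
                 for i in range(10)]
        qr = fdr_quantile_recovery(cands, cands, maxgap=0, n_quantiles=10)
        assert qr.fractions == [1.0] * 10

    def test_hand_partition_20_candidates(self):
        # 10 low-FDR candidates overlap the reference, 10 high-FDR don't
        ref = [make_peak("chr1", i * 1000, i * 1000 + 100) for i in range(10)]
        low = [make_peak("chr1", i * 1000, i * 1000 + 100, q=10.0 + i)
               for i in range(10)]
        high = [make_peak("chr2", i * 1000, i * 1000 + 100, q=0.1 * i)
                for i in range(10)]
        qr = fdr_quantile_recovery(low + high, ref, maxgap=0, n_quantiles=10)
        assert qr.fractions == [1.0] * 5 + [0.0] * 5
        assert qr.counts == [2] * 10

    def test_remainder_to_lowest_fdr_blocks(self):
        cands = [make_peak("chr1", i * 1000, i * 1000 + 100, q=float(i))
                 for i in range(23)]
        qr = fdr_quantile_recovery(cands, cands, maxgap=0, n_quantiles=10)
        assert qr.counts == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]
        assert sum(qr.counts) == 23

    def test_missing_q_rejected(self):
        with pytest.raises(ValueError, match="q value"):
            fdr_quantile_recovery([make_peak("chr1", 0, 100)],
                                  [make_peak("chr1", 0, 100)], 0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            fdr_quantile_recovery([make_peak("chr1", 0, 100, q=1.0)], [], 0)

    def test_bad_quantile_count(self):
        with pytest.raises(ValueError):
            fdr_quantile_recovery([make_peak("chr1", 0, 100, q=1.0)],
                                  [make_peak("chr1", 0, 100)], 0, n_quantiles=0)


class TestSaturation:
    def test_full_set_gives_one(self):
        full = [make_peak("chr1", i * 1000, i * 1000 + 100) for i in range(5)]
        curve = saturation_recall(full, {"100%": full}, maxgap=0)
        assert curve.fractions == [1.0]

    def test_empty_depth_gives_zero(self):
        full = [make_peak("chr1", 0, 100)]
        curve = saturation_recall(full, {"10%": []}, maxgap=0)
        assert curve.fractions == [0.0]

    def test_nested_sets_non_decreasing(self):
        full = [make_peak("chr1", i * 1000, i * 1000 + 100) for i in range(10)]
        depths = {f"{k}0%": full[:k] for k in range(1, 11)}
        curve = saturation_recall(full, depths, maxgap=0)
        assert curve.fractions == sorted(curve.fractions)

    def test_empty_full_rejected(self):
        with pytest.raises(ValueError):
            saturation_recall([], {"d": []}, 0)


class TestPartitionUniqueCommon:
    def test_disjoint_all_unique(self):
        A = [make_peak("chr1", 0, 100)]
        B = [make_peak("chr2", 0, 100)]
        parts = partition_unique_common(A, B, 0)
        assert len(parts["A_only"]) == 1 and len(parts["B_only"]) == 1
        assert parts["A_common"] == [] and parts["B_common"] == []

    def test_identical_all_common(self):
        A = [make_peak("chr1", 0, 100)]
        parts = partition_unique_common(A, list(A), 0)
        assert parts["A_only"] == [] and len(parts["A_common"]) == 1

    def test_one_pair_among_three(self):
        A = [make_peak("chr1", 0, 100), make_peak("chr1", 5000, 5100),
             make_peak("chr2", 0, 100)]
        B = [make_peak("chr1", 50, 150), make_peak("chr1", 8000, 8100),
             make_peak("chr2", 5000, 5100)]
        parts = partition_unique_common(A, B, 0)
        assert len(parts["A_common"]) == len(parts["B_common"]) == 1
        assert len(parts["A_only"]) == len(parts["B_only"]) == 2

    def test_sizes_partition_exactly(self, small_sizes):
        rng = np.random.default_rng(43)
        A = [make_peak(iv.chrom, iv.start, iv.end)
             for iv in random_intervals(rng, 60, small_sizes)]
        B = [make_peak(iv.chrom, iv.start, iv.end)
             for iv in random_intervals(rng, 60, small_sizes)]
        parts = partition_unique_common(A, B, 100)
        assert len(parts["A_only"]) + len(parts["A_common"]) == len(A)
        assert len(parts["B_only"]) + len(parts["B_common"]) == len(B)


class TestRandomMatchedRegions:
    def test_lengths_match_elementwise(self, small_sizes):
        rng = np.random.default_rng(44)
        template = [make_peak(iv.chrom, iv.start, iv.end)
                    for iv in random_intervals(rng, 30, small_sizes)]
        regions = random_matched_regions(template, small_sizes, seed=1)
        assert [len(r) for r in regions] == \
               [len(p.interval) for p in template]
        assert [r.chrom for r in regions] == [p.chrom for p in template]

    def test_deterministic(self, small_sizes):
        template = [make_peak("chr1", 100, 600)]
        r1 = random_matched_regions(template, small_sizes, seed=7)
        r2 = random_matched_regions(template, small_sizes, seed=7)
        assert r1 == r2

    def test_exclusions_respected(self):
        sizes = ChromSizes([("chr1", 10_000)])
        exclusions = [GenomicInterval("chr1", 0, 5000)]
        template = [make_peak("chr1", 0, 200) for _ in range(50)]
        regions = random_matched_regions(template, sizes, exclusions, seed=3)
        for r in regions:
            assert r.start >= 5000  # gap-0 rule also bars abutting? no: start>=5000 ok

    def test_template_longer_than_chrom_rejected(self):
        sizes = ChromSizes([("chr1", 100)])
        with pytest.raises(ValueError, match="chromosome"):
            random_matched_regions([make_peak("chr1", 0, 100)], sizes)

    def test_saturated_exclusions_warns_and_accepts(self, caplog):
        sizes = ChromSizes([("chr1", 1000)])
        exclusions = [GenomicInterval("chr1", 0, 1000)]
        with caplog.at_level("WARNING"):
            regions = random_matched_regions([make_peak("chr1", 0, 100)],
                                             sizes, exclusions, seed=5,
                                             max_tries=10)
        assert len(regions) == 1
        assert "tries" in caplog.text


class TestRegionReadCoverage:
    def test_no_fragments(self):
        counts = region_read_coverage(ReadSet([]),
                                      [GenomicInterval("chr1", 0, 100)])
        assert list(counts) == [0]

    def test_single_containment(self):
        reads = ReadSet([GenomicInterval("chr1", 10, 20)])
        regions = [GenomicInterval("chr1", 0, 100),
                   GenomicInterval("chr1", 200, 300),
                   GenomicInterval("chr2", 0, 100)]
        assert list(region_read_coverage(reads, regions)) == [1, 0, 0]

    def test_matches_oracle(self, small_sizes):
        rng = np.random.default_rng(45)
        reads = ReadSet(random_intervals(rng, 1000, small_sizes))
        regions = random_intervals(rng, 40, small_sizes)
        counts = region_read_coverage(reads, regions)
        assert list(counts) == region_coverage_oracle(reads.fragments, regions)

    def test_summary_fields(self):
        s = coverage_summary(np.array([1, 2, 3, 4]))
        assert s["median"] == 2.5 and s["n"] == 4


class TestAnnotatePeaks:
    @pytest.fixture
    def genes(self):
        return [
            GeneModel(GenomicInterval("chr1", 5000, 15_000), "+", "geneA"),
            GeneModel(GenomicInterval("chr1", 50_000, 60_000), "-", "geneB"),
        ]

    def test_promoter_upstream_plus(self, genes):
        pk = make_peak("chr1", 4400, 4600, summit=100)  # 500 bp before TSS
        ann = annotate_peaks([pk], genes)
        assert ann.categories == ["Promoter"]
        assert ann.nearest_gene == ["geneA"]
        assert ann.distance_to_tss == [-500]

    def test_gene_body(self, genes):
        pk = make_peak("chr1", 9900, 10_100, summit=100)  # 5 kb into geneA
        ann = annotate_peaks([pk], genes)
        assert ann.categories == ["GeneBody"]

    def test_distal_intergenic(self, genes):
        pk = make_peak("chr1", 30_000, 30_200, summit=100)
        ann = annotate_peaks([pk], genes)
        assert ann.categories == ["DistalIntergenic"]

    def test_minus_strand_promoter(self, genes):
        # geneB TSS is at its right end; 500 bp to the right is upstream
        pk = make_peak("chr1", 60_399, 60_599, summit=100)
        ann = annotate_peaks([pk], genes)
        assert ann.categories == ["Promoter"]
        assert ann.nearest_gene == ["geneB"]
        assert ann.distance_to_tss == [-500]

    def test_midpoint_anchor_when_no_summit(self, genes):
        pk = make_peak("chr1", 9000, 11_000)  # midpoint 10,000 inside geneA
        assert annotate_peaks([pk], genes).categories == ["GeneBody"]

    def test_empty_genes_rejected(self):
        with pytest.raises(ValueError, match="empty gene"):
            annotate_peaks([make_peak("chr1", 0, 100)], [])
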