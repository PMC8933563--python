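"""CRE candidate calling, peak-to-gene assignment, Th0-novelty detection."""

import numpy as np
import pytest

from crelicense.cre_annotation import (
    assign_peak,
    cre_candidates,
    gene_index,
    genes_with_dev_cre,
    genes_with_novel_peaks,
    novel_th0_peaks,
)
from crelicense.intervals import overlap_length
from crelicense.io_formats import GeneModel, GenomicInterval, PeakSet


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def gene(gene_id, start, end, strand="+", chrom="chr1"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand=strand))


class TestCreCandidates:
    def test_overlap_retained_adjacency_dropped(self):
        atac = PeakSet("ATAC", "DP", [iv("chr1", 100, 300), iv("chr1", 100, 200)])
        k27 = PeakSet("H3K27Ac", "DP", [iv("chr1", 250, 400), iv("chr1", 200, 300)])
        out = cre_candidates(atac, k27)
        # (100,300) overlaps both marks; (100,200) only touches at 200 (half-open)
        assert list(out) == [iv("chr1", 100, 300)]
        assert out.assay == "ATAC" and out.state == "DP"

    def test_assay_and_state_validation(self):
        a = PeakSet("ATAC", "DP", [])
        k = PeakSet("H3K27Ac", "CD4SP", [])
        with pytest.raises(ValueError, match="states differ"):
            cre_candidates(a, k)
        with pytest.raises(ValueError, match="ATAC"):
            cre_candidates(k, k)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)

        def random_peaks(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 20_000))
                out.append(iv("chr1", s, s + int(rng.integers(50, 800))))
            return out

        atac = PeakSet("ATAC", "DP", random_peaks(80))
        k27 = PeakSet("H3K27Ac", "DP", random_peaks(80))
        got = set((p.start, p.end) for p in cre_candidates(atac, k27, min_bp=100))
        expected = {
            (a.start, a.end)
            for a in atac
            if any(overlap_length(a, k) >= 100 for k in k27)
        }
        assert got == expected

    def test_result_subset_of_atac(self):
        atac = PeakSet("ATAC", "DP", [iv("chr1", 0, 100)])
        k27 = PeakSet("H3K27Ac", "DP", [iv("chr1", 500, 600)])
        assert len(cre_candidates(atac, k27)) == 0


class TestAssignPeak:
    @pytest.fixture
    def idx(self):
        # gA: + strand, body 10000-20000, tss 10000
        return gene_index([gene("gA", 10_000, 20_000, "+")])

    def test_gene_body_link(self, idx):
        link = assign_peak(iv("chr1", 12_000, 12_500), idx)
        assert link.gene_id == "gA" and link.category == "gene_body"
        assert link.tss_distance == 2_000

    def test_upstream_link_by_edge_distance(self, idx):
        link = assign_peak(iv("chr1", 500, 700), idx)
        # |10000 - 699| = 9301 < 10000
        assert link is not None
        assert link.tss_distance == 9_301 and link.category == "upstream"

    @pytest.mark.parametrize(
        "peak,linked",
        [((0, 100), True), ((0, 5), True)],  # 9901 and 9996, both < 10000
    )
    def test_near_threshold(self, idx, peak, linked):
        assert (assign_peak(iv("chr1", *peak), idx) is not None) == linked

    def test_exact_threshold_excluded(self):
        idx = gene_index([gene("gA", 30_000, 40_000, "+")])
        # peak end 20001 -> distance |30000 - 20000| = 10000, strict < fails
        assert assign_peak(iv("chr1", 19_000, 20_001), idx) is None
        # one base closer links
        assert assign_peak(iv("chr1", 19_000, 20_002), idx) is not None

    def test_far_peak_unlinked(self):
        idx = gene_index([gene("gA", 30_000, 40_000, "+")])
        assert assign_peak(iv("chr1", 0, 100), idx) is None

    def test_downstream_category_plus_strand(self):
        # short gene so that a peak past the 3' end is still < 10 kb from the TSS
        idx = gene_index([gene("gA", 10_000, 12_000, "+")])
        link = assign_peak(iv("chr1", 13_000, 13_200), idx)
        assert link is not None and link.category == "downstream"

    def test_strand_aware_upstream_minus(self):
        # minus strand: tss = body.end; upstream = larger coordinates
        idx = gene_index([gene("gA", 18_000, 20_000, "-")])
        up = assign_peak(iv("chr1", 21_000, 21_200), idx)
        down = assign_peak(iv("chr1", 15_000, 15_200), idx)
        assert up.category == "upstream" and down.category == "downstream"

    def test_tie_breaks_lexicographic(self):
        # two genes with TSS equidistant from the peak
        idx = gene_index([gene("gB", 20_000, 30_000, "+"), gene("gA", 2_000, 9_000, "-")])
        peak = iv("chr1", 14_000, 15_001)  # edge distances: gA tss 9000 -> 5000; gB tss 20000 -> 5000
        link = assign_peak(peak, idx)
        assert link.gene_id == "gA"

    def test_multi_body_overlap_prefers_nearest_tss(self):
        idx = gene_index(
            [gene("gFar", 0, 50_000, "+"), gene("gNear", 29_000, 31_000, "+")]
        )
        link = assign_peak(iv("chr1", 29_500, 29_600), idx)
        assert link.gene_id == "gNear" and link.category == "gene_body"

    def test_empty_index_raises(self):
        with pytest.raises(ValueError, match="empty"):
            assign_peak(iv("chr1", 0, 10), gene_index([]))

    def test_midpoint_anchor(self):
        idx = gene_index([gene("gA", 30_000, 40_000, "+")])
        peak = iv("chr1", 19_000, 21_000)  # midpoint 20000 -> distance 10000 (excluded)
        assert assign_peak(peak, idx, anchor="midpoint") is None
        assert assign_peak(peak, idx, anchor="edge") is not None  # edge distance 9001


class TestDevCre:
    def test_either_state_semantics(self):
        genes = gene_index([gene("gA", 1_000, 9_000, "+")])
        dp = PeakSet("ATAC", "DP", [iv("chr1", 2_000, 2_400)])
        empty = PeakSet("ATAC", "CD4SP", [])
        assert genes_with_dev_cre(dp, empty, genes) == {"gA"}
        assert genes_with_dev_cre(empty, dp, genes) == {"gA"}

    def test_no_peaks_empty_set(self):
        genes = gene_index([gene("gA", 1_000, 9_000, "+")])
        empty_dp = PeakSet("ATAC", "DP", [])
        empty_cd = PeakSet("ATAC", "CD4SP", [])
        assert genes_with_dev_cre(empty_dp, empty_cd, genes) == set()

    def test_union_of_per_state_assignments(self):
        genes = gene_index([gene("gA", 1_000, 9_000, "+"), gene("gB", 50_000, 60_000, "+")])
        dp = PeakSet("ATAC", "DP", [iv("chr1", 2_000, 2_400)])
        cd = PeakSet("ATAC", "CD4SP", [iv("chr1", 51_000, 51_400)])
        both = genes_with_dev_cre(dp, cd, genes)
        empty_cd = PeakSet("ATAC", "CD4SP", [])
        empty_dp = PeakSet("ATAC", "DP", [])
        assert both == genes_with_dev_cre(dp, empty_cd, genes) | genes_with_dev_cre(
            empty_dp, cd, genes
        )


class TestNovelTh0:
    def test_unopposed_peak_is_novel(self):
        th0 = PeakSet("ATAC", "Th0", [iv("chr1", 500, 700)])
        empty_dp = PeakSet("ATAC", "DP", [])
        empty_cd = PeakSet("ATAC", "CD4SP", [])
        assert list(novel_th0_peaks(th0, empty_dp, empty_cd)) == [iv("chr1", 500, 700)]

    def test_developmental_overlap_disqualifies(self):
        th0 = PeakSet("ATAC", "Th0", [iv("chr1", 100, 300)])
        dp = PeakSet("ATAC", "DP", [iv("chr1", 250, 400)])
        empty_cd = PeakSet("ATAC", "CD4SP", [])
        assert len(novel_th0_peaks(th0, dp, empty_cd)) == 0

    def test_non_atac_input_raises(self):
        th0 = PeakSet("ATAC", "Th0", [])
        k27 = PeakSet("H3K27Ac", "DP", [])
        with pytest.raises(ValueError, match="ATAC"):
            novel_th0_peaks(th0, k27, th0)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_brute_force_complement(self, seed):
        rng = np.random.default_rng(seed)

        def random_peaks(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 30_000))
                out.append(iv("chr1", s, s + int(rng.integers(50, 600))))
            return out

        th0 = PeakSet("ATAC", "Th0", random_peaks(60))
        dp = PeakSet("ATAC", "DP", random_peaks(40))
        cd = PeakSet("ATAC", "CD4SP", random_peaks(40))
        novel = novel_th0_peaks(th0, dp, cd)
        dev = list(dp) + list(cd)
        expected = [p for p in th0 if all(overlap_length(p, d) < 1 for d in dev)]
        assert list(novel) == expected
        # post-hoc: zero qualifying overlap against developmental sets
        for p in novel:
            assert all(overlap_length(p, d) == 0 for d in dev)

    def test_overlap_fraction_mode(self):
        th0 = PeakSet("ATAC", "Th0", [iv("chr1", 0, 1000)])
        dp = PeakSet("ATAC", "DP", [iv("chr1", 990, 1500)])  # 10 bp = 1% of Th0 peak
        empty = PeakSet("ATAC", "CD4SP", [])
        assert len(novel_th0_peaks(th0, dp, empty, min_overlap_fraction=0.05)) == 1
        assert len(novel_th0_peaks(th0, dp, empty)) == 0


class TestGenesWithNovelPeaks:
    def test_body_and_threshold(self):
        genes = gene_index([gene("gA", 20_000, 30_000, "+")])
        inside = PeakSet("ATAC", "Th0", [iv("chr1", 21_000, 21_300)])
        far = PeakSet("ATAC", "Th0", [iv("chr1", 0, 100)])  # ~19.9 kb from TSS
        assert genes_with_novel_peaks(inside, genes) == {"gA"}
        assert genes_with_novel_peaks(far, genes) == set()

    def test_order_invariance(self):
        genes = gene_index([gene("gA", 20_000, 30_000, "+"), gene("gB", 60_000, 70_000, "-")])
        peaks = [iv("chr1", 21_000, 21_300), iv("chr1", 65_000, 65_300)]
        a = genes_with_novel_peaks(PeakSet("ATAC", "Th0", peaks), genes)
        b = genes_with_novel_peaks(PeakSet("ATAC", "Th0", peaks[::-1]), genes)
        assert a == b == {"gA", "gB"}
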