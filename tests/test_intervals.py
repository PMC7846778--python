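import numpy as np
import pytest
from scipy.stats import hypergeom

from cgimeth.intervals import (
    AnnotationResult,
    GeneModel,
    GenomicInterval,
    annotate_cgis,
    count_overlaps,
    filter_intervals,
    make_windows,
    map_cgis_to_genes,
    merge_intervals,
    overlap_enrichment,
)
from conftest import random_intervals


def iv(chrom, start, end, name=None):
    return GenomicInterval(chrom, start, end, name=name)


def base_set(intervals):
    """Brute-force union of covered bases (oracle for merge)."""
    return {(i.chrom, b) for i in intervals for b in range(i.start, i.end)}


class TestMergeIntervals:
    @pytest.mark.parametrize(
        "intervals,expected",
        [
            ([iv("chr1", 100, 200), iv("chr1", 150, 250)], [iv("chr1", 100, 250)]),
            ([iv("chr1", 100, 200), iv("chr1", 200, 300)], [iv("chr1", 100, 300)]),
            ([], []),
            ([iv("chr1", 5, 10), iv("chr2", 5, 10)],
             [iv("chr1", 5, 10), iv("chr2", 5, 10)]),
        ],
    )
    def test_examples(self, intervals, expected):
        assert merge_intervals(intervals) == expected

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="start >= end"):
            iv("chr1", 10, 10)

    def test_matches_base_set_union_and_idempotent(self, rng):
        for _ in range(50):
            ivs = random_intervals(rng, int(rng.integers(1, 15)))
            merged = merge_intervals(ivs)
            assert base_set(merged) == base_set(ivs)
            starts_ends = [(m.chrom, m.start, m.end) for m in merged]
            assert starts_ends == sorted(starts_ends)
            # disjoint and not book-ended within a chromosome
            for a, b in zip(merged, merged[1:]):
                if a.chrom == b.chrom:
                    assert a.end < b.start
            assert merge_intervals(merged) == merged


class TestFilterIntervals:
    def test_non_autosomal_removed(self):
        cgis = [iv("chr1", 0, 100), iv("chrX", 0, 100)]
        kept = filter_intervals(cgis, allowed_chroms={f"chr{i}" for i in range(1, 23)})
        assert kept == [iv("chr1", 0, 100)]

    def test_single_bp_blacklist_overlap_removed(self):
        cgi = iv("chr1", 100, 200)
        assert filter_intervals([cgi], blacklist=[iv("chr1", 199, 300)]) == []
        assert filter_intervals([cgi], blacklist=[iv("chr1", 200, 300)]) == [cgi]

    def test_empty_blacklist_identity(self):
        cgis = [iv("chr1", 0, 50), iv("chr2", 10, 60)]
        assert filter_intervals(cgis) == cgis

    def test_brute_force_overlap_agreement(self, rng):
        cgis = random_intervals(rng, 30)
        bl = random_intervals(rng, 5)
        kept = filter_intervals(cgis, blacklist=bl)
        expect = [c for c in cgis if not any(c.overlaps(b) for b in bl)]
        assert kept == expect


@pytest.fixture
def two_genes():
    g1 = GeneModel(
        "GENE1",
        tss=(iv("chr1", 1000, 1001),),
        transcripts=(iv("chr1", 1000, 5000),),
    )
    g2 = GeneModel(
        "GENE2",
        tss=(iv("chr1", 8000, 8001),),
        transcripts=(iv("chr1", 3000, 9000),),
    )
    return [g1, g2]


class TestAnnotateCgis:
    def test_tss_beats_gene_body(self, two_genes):
        # overlaps GENE1's TSS and GENE2's body: TSS wins
        cgi = iv("chr1", 900, 3500)
        (res,) = annotate_cgis([cgi], two_genes)
        assert res.category == "TSS"
        assert res.assigned_genes == ("GENE1",)

    def test_transcript_only_is_gene_body(self, two_genes):
        (res,) = annotate_cgis([iv("chr1", 2000, 2500)], two_genes)
        assert res.category == "gene_body"

    def test_no_overlap_is_intergenic(self, two_genes):
        (res,) = annotate_cgis([iv("chr1", 20000, 21000)], two_genes)
        assert res.category == "intergenic"
        assert res.assigned_genes == ()

    def test_category_counts_order_invariant(self, rng, two_genes):
        cgis = random_intervals(rng, 40, chroms=("chr1",), span=25000)
        fwd = annotate_cgis(cgis, two_genes)
        rev = annotate_cgis(list(reversed(cgis)), two_genes)
        count = lambda rs: sorted(r.category for r in rs)
        assert count(fwd) == count(rev)

    def test_empty_genes_rejected(self):
        with pytest.raises(ValueError):
            annotate_cgis([iv("chr1", 0, 10)], [])

    def test_tss_outside_transcript_rejected(self):
        with pytest.raises(ValueError, match="outside all transcripts"):
            GeneModel("BAD", tss=(iv("chr1", 99, 100),),
                      transcripts=(iv("chr1", 1000, 2000),))


class TestMapCgisToGenes:
    def test_dual_tss_overlap_assigns_both(self):
        genes = [
            GeneModel("A", (iv("chr1", 100, 101),), (iv("chr1", 100, 500),)),
            GeneModel("B", (iv("chr1", 150, 151),), (iv("chr1", 150, 600),)),
        ]
        cgi = iv("chr1", 90, 200)
        assert map_cgis_to_genes([cgi], genes)[cgi] == {"A", "B"}

    def test_equidistant_tss_tie_keeps_both(self):
        genes = [
            GeneModel("L", (iv("chr1", 100, 101),), (iv("chr1", 100, 200),)),
            GeneModel("R", (iv("chr1", 900, 901),), (iv("chr1", 900, 1000),)),
        ]
        # edges at 400/600: distance 300 to TSS 100, distance 300 to TSS 900
        cgi = iv("chr1", 400, 601)
        assert map_cgis_to_genes([cgi], genes)[cgi] == {"L", "R"}
        # brute-force distance scan agrees for a nearer left gene
        cgi2 = iv("chr1", 300, 500)
        assert map_cgis_to_genes([cgi2], genes)[cgi2] == {"L"}

    def test_inside_transcript_maps_to_that_gene(self, two_genes):
        cgi = iv("chr1", 1500, 1600)
        mapping = map_cgis_to_genes([cgi], two_genes)
        assert mapping[cgi] == {"GENE1"}

    def test_chromosome_without_genes_unmapped(self, two_genes):
        cgi = iv("chr9", 0, 100)
        assert map_cgis_to_genes([cgi], two_genes)[cgi] == frozenset()


class TestCountOverlaps:
    def test_fragment_spanning_two_regions_increments_both(self):
        regions = [iv("chr1", 0, 100), iv("chr1", 100, 200)]
        counts = count_overlaps([iv("chr1", 90, 110)], regions)
        assert counts.tolist() == [1, 1]

    def test_no_fragments_all_zero(self):
        assert count_overlaps([], [iv("chr1", 0, 10)]).tolist() == [0]

    def test_exact_match_counts_once(self):
        assert count_overlaps([iv("chr1", 5, 15)], [iv("chr1", 5, 15)]).tolist() == [1]

    def test_brute_force_all_pairs(self, rng):
        frags = random_intervals(rng, 60)
        regions = random_intervals(rng, 20)
        counts = count_overlaps(frags, regions)
        expect = [sum(f.overlaps(r) for f in frags) for r in regions]
        assert counts.tolist() == expect


def hypergeom_tail_p(k, n_target, k_bg, n_bg, sided="greater"):
    """Exact tail-sum oracle on the 2x2 table (independent of fisher_exact)."""
    rv = hypergeom(n_bg, k_bg, n_target)
    support = np.arange(max(0, n_target + k_bg - n_bg), min(n_target, k_bg) + 1)
    pmf = rv.pmf(support)
    if sided == "greater":
        return float(pmf[support >= k].sum())
    return float(pmf[pmf <= rv.pmf(k) * (1 + 1e-9)].sum())


class TestOverlapEnrichment:
    def test_equal_rates_fold_one(self):
        peaks = [iv("chr1", i * 100, i * 100 + 10) for i in range(5)]
        bg = [iv("chr1", i * 100, i * 100 + 50) for i in range(10)]
        # bg overlap rate is 5/10; target of one overlapping + one clean CGI
        # has the same rate 0.5
        target = [bg[0], bg[6]]
        fold, _, _ = overlap_enrichment(target, peaks, bg)
        assert fold == pytest.approx(1.0)

    def test_matches_exact_tail_oracle(self):
        # target: 8 of 10 overlap; rest: 10 of 90
        peaks = [iv("chr1", i * 1000, i * 1000 + 10) for i in range(18)]
        overlapping = [iv("chr1", i * 1000, i * 1000 + 50) for i in range(18)]
        clean = [iv("chr2", i * 1000, i * 1000 + 50) for i in range(82)]
        target = overlapping[:8] + clean[:2]
        bg = target + overlapping[8:] + clean[2:]
        fold, odds, p = overlap_enrichment(target, peaks, bg, sided="greater")
        assert p == pytest.approx(hypergeom_tail_p(8, 10, 18, 100), rel=1e-9)
        assert fold == pytest.approx((8 / 10) / (18 / 100))

    def test_degenerate_target_equals_background(self):
        bg = [iv("chr1", i * 100, i * 100 + 50) for i in range(6)]
        peaks = [iv("chr1", 0, 10)]
        fold, _, p = overlap_enrichment(bg, peaks, bg)
        assert fold == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment([], [], [])


class TestMakeWindows:
    def test_even_count_splits_at_midpoint(self):
        region = iv("chr1", 900, 1100)  # midpoint 1000
        wins = make_windows(region, 250, 2)
        assert [(w.start, w.end) for w in wins] == [(750, 1000), (1000, 1250)]

    def test_odd_count_centres_middle_window(self):
        region = iv("chr1", 900, 1100)
        (w,) = make_windows(region, 250, 1)
        assert (w.start, w.end) == (875, 1125)
        wins3 = make_windows(region, 250, 3)
        assert [(w.start, w.end) for w in wins3] == [(625, 875), (875, 1125), (1125, 1375)]

    def test_left_truncation_at_zero(self):
        region = iv("chr1", 0, 100)  # midpoint 50
        (w,) = make_windows(region, 250, 1)
        assert (w.start, w.end) == (0, 175)

    def test_contiguous_and_total_span(self):
        region = iv("chr1", 5000, 6000)
        wins = make_windows(region, 100, 8)
        for a, b in zip(wins, wins[1:]):
            assert a.end == b.start
        assert wins[-1].end - wins[0].start == 800
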