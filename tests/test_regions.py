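import numpy as np
import pytest

from ernakit.intervals import AnnotationSet, GeneRecord, GenomicInterval
from ernakit.regions import (
    ERNARegion,
    build_exclusion_mask,
    consensus_enhancers,
    define_regions,
    filter_regions,
)

from _oracles import perbase_consensus, perbase_mask


def enh_set(source, pairs, chrom="chr1"):
    return AnnotationSet(role="enhancer", source=source, intervals=[
        GenomicInterval(chrom, s, e) for s, e in pairs])


def gene(chrom, start, end, strand="+", gid="g", exons=None, tss=None, tes=None):
    if tss is None:
        tss = start if strand == "+" else end - 1
    if tes is None:
        tes = end - 1 if strand == "+" else start
    exons = exons or ((start, end),)
    return GeneRecord(chrom=chrom, start=start, end=end, strand=strand,
                      id=gid, tss=tss, tes=tes, exons=exons)


def gene_set(records, role="gene"):
    return AnnotationSet(role=role, source="x", intervals=records)


EMPTY_GENES = gene_set([], role="gene")
EMPTY_LNC = gene_set([], role="lncRNA")
EMPTY_BL = AnnotationSet(role="blacklist", source="x", intervals=[])


class TestConsensus:
    def test_single_source_interval_excluded(self):
        out = consensus_enhancers(
            [enh_set("a", [(100, 200)]), enh_set("b", [])], min_sources=2)
        assert len(out) == 0

    def test_partial_overlap_merges_to_union_span(self):
        out = consensus_enhancers(
            [enh_set("a", [(100, 300)]), enh_set("b", [(250, 400)])],
            min_sources=2)
        assert [(iv.start, iv.end) for iv in out] == [(100, 400)]

    def test_identical_in_three_sources_appears_once(self):
        out = consensus_enhancers(
            [enh_set(s, [(100, 200)]) for s in "abc"], min_sources=2)
        assert [(iv.start, iv.end) for iv in out] == [(100, 200)]

    def test_too_few_sources_error(self):
        with pytest.raises(ValueError, match="min_sources"):
            consensus_enhancers([enh_set("a", [(0, 10)])], min_sources=2)

    def test_within_source_duplicates_count_once(self):
        # two overlapping intervals from the same source must not fake
        # two-source support
        out = consensus_enhancers(
            [enh_set("a", [(100, 200), (150, 250)]), enh_set("b", [])],
            min_sources=2)
        assert len(out) == 0

    def test_raising_min_sources_never_increases_count(self):
        rng = np.random.default_rng(3)
        sources = [
            enh_set(f"s{k}", [(int(s), int(s) + int(l)) for s, l in zip(
                rng.integers(0, 9000, 15), rng.integers(50, 500, 15))])
            for k in range(3)
        ]
        counts = [len(consensus_enhancers(sources, m)) for m in (1, 2, 3)]
        assert counts[0] >= counts[1] >= counts[2]


class TestDefineRegions:
    LENGTHS = {"chr1": 1_000_000}

    def test_midpoint_and_flank(self):
        out = define_regions(enh_set("c", [(4000, 6000)]), 3000, self.LENGTHS)
        (r,) = out
        assert (r.midpoint, r.start, r.end) == (5000, 2000, 8000)

    def test_clamped_at_chromosome_start(self):
        (r,) = define_regions(enh_set("c", [(0, 2000)]), 3000, self.LENGTHS)
        assert (r.midpoint, r.start, r.end) == (1000, 0, 4000)

    def test_one_bp_enhancer_clamps(self):
        (r,) = define_regions(enh_set("c", [(100, 101)]), 3000, self.LENGTHS)
        assert (r.start, r.end) == (0, 3100)

    def test_unknown_chromosome_error(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            define_regions(enh_set("c", [(0, 10)], chrom="chrX"), 3000,
                           self.LENGTHS)

    def test_id_deterministic_from_coordinates(self):
        a = define_regions(enh_set("c", [(4000, 6000)]), 3000, self.LENGTHS)
        b = define_regions(enh_set("c", [(4000, 6000)]), 3000, self.LENGTHS)
        assert a[0].id == b[0].id


class TestExclusionMask:
    def test_gene_extension_plus_uarna_merge(self):
        g = gene("chr1", 10000, 20000, "+")
        mask = build_exclusion_mask(gene_set([g]), EMPTY_LNC, EMPTY_BL,
                                    gene_extension_bp=1000, uaRNA_window_bp=500)
        assert mask.merged["chr1"] == [(8500, 21000)]

    def test_minus_strand_uarna_is_downstream_in_coordinates(self):
        g = gene("chr1", 10000, 20000, "-")
        mask = build_exclusion_mask(gene_set([g]), EMPTY_LNC, EMPTY_BL,
                                    gene_extension_bp=1000, uaRNA_window_bp=500)
        assert mask.merged["chr1"] == [(9000, 21500)]

    def test_no_inputs_empty_mask(self):
        mask = build_exclusion_mask(EMPTY_GENES, EMPTY_LNC, EMPTY_BL, 1000, 500)
        assert mask.merged == {}

    def test_adjacent_extensions_merge(self):
        g1 = gene("chr1", 10000, 20000, "+", gid="g1")
        g2 = gene("chr1", 21500, 30000, "+", gid="g2")
        mask = build_exclusion_mask(gene_set([g1, g2]), EMPTY_LNC, EMPTY_BL,
                                    gene_extension_bp=1000, uaRNA_window_bp=500)
        # g1 ext ends 21000; g2 uaRNA starts 20000 -> one merged run
        assert mask.merged["chr1"] == [(8500, 31000)]


class TestFilterRegions:
    def region(self, start, end, chrom="chr1"):
        return ERNARegion(id=f"e_{start}",
                          interval=GenomicInterval(chrom, start, end),
                          midpoint=(start + end) // 2)

    def mask_of(self, pairs, chrom="chr1"):
        bl = AnnotationSet(role="blacklist", source="x", intervals=[
            GenomicInterval(chrom, s, e) for s, e in pairs])
        return build_exclusion_mask(EMPTY_GENES, EMPTY_LNC, bl, 1000, 500)

    def test_single_bp_overlap_drops(self):
        kept, audit = filter_regions([self.region(2000, 8000)],
                                     self.mask_of([(7999, 9000)]))
        assert kept == [] and list(audit["reason"]) == ["blacklist"]

    def test_half_open_touching_kept(self):
        kept, _ = filter_regions([self.region(2000, 8000)],
                                 self.mask_of([(8000, 9000)]))
        assert len(kept) == 1

    def test_idempotent(self):
        regions = [self.region(0, 100), self.region(500, 600),
                   self.region(5000, 5600)]
        mask = self.mask_of([(550, 560)])
        once, _ = filter_regions(regions, mask)
        twice, _ = filter_regions(once, mask)
        assert once == twice

    def test_enlarging_mask_never_rescues_regions(self):
        rng = np.random.default_rng(5)
        regions = [self.region(int(s), int(s) + 300)
                   for s in rng.integers(0, 50_000, 30)]
        small = self.mask_of([(1000, 1500), (9000, 9100)])
        big = self.mask_of([(1000, 1500), (9000, 9100), (20000, 30000)])
        kept_small, _ = filter_regions(regions, small)
        kept_big, _ = filter_regions(regions, big)
        assert set(r.id for r in kept_big) <= set(r.id for r in kept_small)


class TestPerBaseOracle:
    """Engine vs per-base brute force on random toy genomes (a small sample;
    the full 50-genome sweep runs in the acceptance suite)."""

    @pytest.mark.parametrize("seed", range(5))
    def test_consensus_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chrom_len = 20_000
        source_pairs = []
        for _ in range(3):
            n = int(rng.integers(3, 12))
            starts = rng.integers(0, chrom_len - 600, n)
            lens = rng.integers(50, 600, n)
            source_pairs.append(
                [(int(s), int(s + l)) for s, l in zip(starts, lens)])
        got = consensus_enhancers(
            [enh_set(f"s{k}", p) for k, p in enumerate(source_pairs)], 2)
        expected = perbase_consensus(source_pairs, 2, chrom_len)
        assert [(iv.start, iv.end) for iv in got] == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_filter_matches_perbase_overlap(self, seed):
        rng = np.random.default_rng(100 + seed)
        chrom_len = 50_000
        regions = []
        for i, s in enumerate(rng.integers(0, chrom_len - 800, 25)):
            s = int(s)
            regions.append(ERNARegion(
                id=f"e{i}", interval=GenomicInterval("chr1", s, s + 800),
                midpoint=s + 400))
        bl_pairs = [(int(s), int(s) + int(l)) for s, l in zip(
            rng.integers(0, chrom_len - 2000, 10), rng.integers(100, 2000, 10))]
        mask = build_exclusion_mask(
            EMPTY_GENES, EMPTY_LNC,
            AnnotationSet(role="blacklist", source="x", intervals=[
                GenomicInterval("chr1", s, e) for s, e in bl_pairs]),
            1000, 500)
        kept, _ = filter_regions(regions, mask)
        cov = perbase_mask(bl_pairs, chrom_len)
        expected = [r.id for r in sorted(regions, key=lambda r: r.start)
                    if not cov[r.start:r.end].any()]
        assert [r.id for r in kept] == expected


class TestMergeOverlappingRegions:
    def test_overlapping_regions_collapse_to_union(self):
        from ernakit.regions import merge_overlapping_regions
        r1 = ERNARegion(id="a", interval=GenomicInterval("chr1", 100, 700),
                        midpoint=400)
        r2 = ERNARegion(id="b", interval=GenomicInterval("chr1", 600, 1200),
                        midpoint=900)
        r3 = ERNARegion(id="c", interval=GenomicInterval("chr2", 0, 100),
                        midpoint=50)
        out = merge_overlapping_regions([r1, r2, r3])
        spans = [(r.chrom, r.start, r.end) for r in out]
        assert spans == [("chr1", 100, 1200), ("chr2", 0, 100)]

    def test_disjoint_regions_unchanged(self):
        from ernakit.regions import merge_overlapping_regions
        r1 = ERNARegion(id="a", interval=GenomicInterval("chr1", 0, 100),
                        midpoint=50)
        r2 = ERNARegion(id="b", interval=GenomicInterval("chr1", 200, 300),
                        midpoint=250)
        out = merge_overlapping_regions([r1, r2])
        assert [(r.start, r.end) for r in out] == [(0, 100), (200, 300)]
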