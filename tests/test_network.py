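import numpy as np
import pandas as pd
import pytest

from ernakit.config import PipelineConfig
from ernakit.intervals import AnnotationSet, GeneRecord, GenomicInterval
from ernakit.network import (
    HiCIndex,
    annotate_pathways,
    candidate_pairs,
    correlate_links,
    hic_support,
    permutation_enrichment,
)
from ernakit.regions import ERNARegion


def region(rid, mid, chrom="chr1", half=3000):
    return ERNARegion(id=rid,
                      interval=GenomicInterval(chrom, max(0, mid - half),
                                               mid + half),
                      midpoint=mid)


def gene(gid, tss, chrom="chr1", length=5000, exons=None):
    start, end = tss, tss + length
    return GeneRecord(chrom=chrom, start=start, end=end, strand="+", id=gid,
                      tss=tss, tes=end - 1, exons=exons or ((start, end),))


def gene_set(gs):
    return AnnotationSet(role="gene", source="x", intervals=gs)


class TestCandidatePairs:
    def test_distance_boundary_inclusive(self):
        pairs = candidate_pairs([region("r", 5000)],
                                gene_set([gene("g", 1_005_000)]), 1_000_000)
        assert len(pairs) == 1 and pairs["distance_bp"].iloc[0] == 1_000_000

    def test_distance_above_limit_excluded(self):
        pairs = candidate_pairs([region("r", 5000)],
                                gene_set([gene("g", 1_005_001)]), 1_000_000)
        assert len(pairs) == 0

    def test_cross_chromosome_excluded(self):
        pairs = candidate_pairs([region("r", 5000)],
                                gene_set([gene("g", 6000, chrom="chr2")]),
                                1_000_000)
        assert len(pairs) == 0

    def test_intronic_region_removed(self):
        g = gene("g", 10_000, length=40_000,
                 exons=((10_000, 12_000), (38_000, 50_000)))
        # region [17000, 23000) sits wholly inside intron (12000, 38000)
        pairs = candidate_pairs([region("r", 20_000)], gene_set([g]), 1_000_000)
        assert len(pairs) == 0
        # a region overlapping an exon stays
        pairs2 = candidate_pairs([region("r2", 11_500)], gene_set([g]),
                                 1_000_000)
        assert len(pairs2) == 1

    def test_missing_tss_error(self):
        bad = AnnotationSet(role="enhancer", source="x", intervals=[
            GenomicInterval("chr1", 0, 10, id="g")])
        with pytest.raises(ValueError, match="TSS"):
            candidate_pairs([region("r", 5000)], bad, 1_000_000)


class TestCorrelateLinks:
    def test_duplicated_rows_link_with_rs_one(self, config):
        rng = np.random.default_rng(0)
        x = rng.random(40)
        e = pd.DataFrame([x], index=["r"])
        g = pd.DataFrame([x], index=["g"])
        e.columns = g.columns = [f"s{i}" for i in range(40)]
        pairs = pd.DataFrame({"erna_id": ["r"], "gene_id": ["g"],
                              "distance_bp": [100]})
        links = correlate_links(pairs, e, g, "C", config)
        assert len(links) == 1
        assert links["rs"].iloc[0] == pytest.approx(1.0)

    def test_bh_scope_is_all_candidates(self, config):
        """q of a strong pair grows when many null candidates join the
        same cohort-wide correction."""
        rng = np.random.default_rng(1)
        n = 40
        x = rng.standard_normal(n)
        e = pd.DataFrame({"r0": x + 0.3 * rng.standard_normal(n)}).T
        genes = {"g0": x + 0.9 * rng.standard_normal(n)}
        for i in range(1, 60):
            genes[f"g{i}"] = rng.standard_normal(n)
        g = pd.DataFrame(genes).T
        e.columns = g.columns = [f"s{i}" for i in range(n)]
        one = pd.DataFrame({"erna_id": ["r0"], "gene_id": ["g0"],
                            "distance_bp": [1]})
        many = pd.DataFrame({"erna_id": "r0", "gene_id": list(genes),
                             "distance_bp": 1})
        q_alone = correlate_links(one, e, g, "C", config)["q"].iloc[0]
        out_many = correlate_links(many, e, g, "C", config)
        row = out_many[out_many["gene_id"] == "g0"]
        if len(row):
            assert row["q"].iloc[0] >= q_alone


def hic_from_rows(rows, bin_bp=10_000):
    for r in rows:
        r.setdefault("chrom", "chr1")
    return HiCIndex(pd.DataFrame(rows, columns=["tissue", "chrom", "bin_a",
                                                "bin_b", "oe"]), bin_bp)


class TestHiCSupport:
    def test_supported_tissue_count(self):
        rows = [{"tissue": f"t{i}", "bin_a": 0, "bin_b": 50_000,
                 "oe": 2.0 if i < 12 else 0.5} for i in range(20)]
        hic = hic_from_rows(rows)
        links = pd.DataFrame({"erna_id": ["r"], "gene_id": ["g"]})
        sup = hic_support(links, hic, {"r": ("chr1", 5_000)},
                          {"g": ("chr1", 55_000)}, hic_oe_min=1.0)
        assert sup["supported_tissues"].iloc[0] == 12
        assert bool(sup["supported_any"].iloc[0])

    def test_all_missing_counts_zero(self):
        hic = hic_from_rows([{"tissue": "t0", "bin_a": 900_000,
                              "bin_b": 910_000, "oe": 5.0}])
        links = pd.DataFrame({"erna_id": ["r"], "gene_id": ["g"]})
        sup = hic_support(links, hic, {"r": ("chr1", 5_000)},
                          {"g": ("chr1", 55_000)}, hic_oe_min=1.0)
        assert sup["supported_tissues"].iloc[0] == 0
        assert not bool(sup["supported_any"].iloc[0])

    def test_key_is_unordered(self):
        hic = hic_from_rows([{"tissue": "t0", "bin_a": 50_000, "bin_b": 0,
                              "oe": 3.0}])
        assert hic.oe("t0", "chr1", 5_000, 55_000) == 3.0
        assert hic.oe("t0", "chr1", 55_000, 5_000) == 3.0

    def test_support_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        rows = [{"tissue": f"t{i}", "bin_a": 0, "bin_b": 50_000,
                 "oe": float(np.exp(rng.normal(0, 1)))} for i in range(20)]
        hic = hic_from_rows(rows)
        links = pd.DataFrame({"erna_id": ["r"], "gene_id": ["g"]})
        mids, tss = {"r": ("chr1", 5_000)}, {"g": ("chr1", 55_000)}
        counts = [hic_support(links, hic, mids, tss, thr)
                  ["supported_tissues"].iloc[0] for thr in (0.5, 1.0, 2.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_planted_enrichment_supported_in_all_tissues(self, bundle, config):
        hic = HiCIndex(bundle.hic, config.hic_bin_bp)
        truth = bundle.truth.tables["planted_hic"]
        mids = {r.id: (r.chrom, r.midpoint) for r in bundle.regions}
        tss = {g.id: (g.chrom, g.tss) for g in bundle.genes}
        sup = hic_support(truth[["erna_id", "gene_id"]], hic, mids, tss,
                          config.hic_oe_min)
        assert (sup["supported_tissues"] == bundle.design.n_tissues).all()


class TestPermutation:
    def setup_universe(self, seed=0, n_regions=15, n_genes=25):
        rng = np.random.default_rng(seed)
        regions = [region(f"r{i}", int(m))
                   for i, m in enumerate(rng.integers(5_000, 2_000_000,
                                                      n_regions))]
        genes = gene_set([gene(f"g{j}", int(t))
                          for j, t in enumerate(rng.integers(0, 2_000_000,
                                                             n_genes))])
        rows = []
        for r in regions:
            a = r.midpoint // 10_000 * 10_000
            for g in genes:
                b = g.tss // 10_000 * 10_000
                if rng.random() < 0.5:
                    rows.append({"tissue": "t0", "bin_a": min(a, b),
                                 "bin_b": max(a, b),
                                 "oe": float(np.exp(rng.normal(0, 0.5)))})
        return regions, genes, hic_from_rows(rows)

    def test_p_formula_and_determinism(self):
        regions, genes, hic = self.setup_universe()
        links = pd.DataFrame({"erna_id": ["r0", "r1"],
                              "gene_id": ["g0", "g1"]})
        a = permutation_enrichment(links, regions, genes, hic, 200, seed=42)
        b = permutation_enrichment(links, regions, genes, hic, 200, seed=42)
        assert a.p_empirical == (a.exceedances + 1) / 201
        assert (a.p_empirical, a.observed_fraction) == \
               (b.p_empirical, b.observed_fraction)

    def test_zero_links_error(self):
        regions, genes, hic = self.setup_universe()
        with pytest.raises(ValueError, match="no links"):
            permutation_enrichment(pd.DataFrame({"erna_id": [],
                                                 "gene_id": []}),
                                   regions, genes, hic, 200, seed=0)

    def test_too_few_permutations_error(self):
        regions, genes, hic = self.setup_universe()
        links = pd.DataFrame({"erna_id": ["r0"], "gene_id": ["g0"]})
        with pytest.raises(ValueError, match="100"):
            permutation_enrichment(links, regions, genes, hic, 50, seed=0)

    def test_planted_enrichment_minimal_p(self, bundle, config):
        hic = HiCIndex(bundle.hic, config.hic_bin_bp)
        links = bundle.truth.tables["planted_links"][["erna_id", "gene_id"]]
        res = permutation_enrichment(links, bundle.regions, bundle.genes,
                                     hic, 999, seed=5)
        assert res.observed_fraction == 1.0
        assert res.p_empirical == pytest.approx(1 / 1000)


class TestAnnotatePathways:
    SETS = pd.DataFrame({"set": ["p53", "p53", "notch"],
                         "member": ["gA", "gB", "gB"]})

    def links(self, genes):
        return pd.DataFrame({"erna_id": [f"r{i}" for i, _ in enumerate(genes)],
                             "gene_id": genes, "cohort": "C",
                             "distance_bp": 1, "n": 60, "rs": 0.5,
                             "p": 1e-5, "q": 1e-3})

    def test_single_membership(self):
        labelled, per_erna = annotate_pathways(self.links(["gA"]), self.SETS)
        assert list(labelled["pathway"]) == ["p53"]
        assert per_erna["pathways"].iloc[0] == ["p53"]

    def test_gene_in_two_sets_two_labels(self):
        labelled, _ = annotate_pathways(self.links(["gB"]), self.SETS)
        assert sorted(labelled["pathway"]) == ["notch", "p53"]

    def test_empty_sets_no_labels(self):
        labelled, per_erna = annotate_pathways(
            self.links(["gA"]), pd.DataFrame({"set": [], "member": []}))
        assert labelled.empty and per_erna.empty
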