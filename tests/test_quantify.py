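import numpy as np
import pandas as pd
import pytest

from ernakit.intervals import AnnotationSet, GenomicInterval
from ernakit.quantify import (
    ExpressionMatrix,
    classify_specificity,
    count_overlaps,
    detectability,
    rpm,
    sample_similarity,
)
from ernakit.regions import ERNARegion

from _oracles import bruteforce_counts


def region(rid, chrom, start, end):
    return ERNARegion(id=rid, interval=GenomicInterval(chrom, start, end),
                      midpoint=(start + end) // 2)


def reads_set(rows):
    return AnnotationSet(role="read", source="reads", intervals=[
        GenomicInterval(c, s, e, id=smp) for c, s, e, smp in rows])


class TestCountOverlaps:
    REGIONS = [region("r1", "chr1", 2000, 8000)]

    def test_overlapping_read_counts(self):
        c = count_overlaps(reads_set([("chr1", 2500, 2600, "s1")]), self.REGIONS)
        assert c.loc["r1", "s1"] == 1

    def test_half_open_touching_read_does_not_count(self):
        c = count_overlaps(reads_set([("chr1", 8000, 8100, "s1")]), self.REGIONS)
        assert c.loc["r1", "s1"] == 0

    def test_read_spanning_two_regions_counts_in_both(self):
        regions = [region("a", "chr1", 0, 100), region("b", "chr1", 50, 150)]
        c = count_overlaps(reads_set([("chr1", 40, 60, "s1")]), regions)
        assert c.loc["a", "s1"] == 1 and c.loc["b", "s1"] == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        regions = [region(f"r{i}", f"chr{1 + i % 2}", int(s), int(s) + 500)
                   for i, s in enumerate(rng.integers(0, 50_000, 20))]
        samples = ["s1", "s2", "s3"]
        rows = [(f"chr{1 + int(rng.integers(2))}", int(s), int(s) + 75,
                 samples[int(rng.integers(3))])
                for s in rng.integers(0, 50_000, 1000)]
        got = count_overlaps(reads_set(rows), regions)
        expected = bruteforce_counts(
            rows, [(r.id, r.chrom, r.start, r.end) for r in regions], samples)
        for (rid, smp), v in expected.items():
            assert got.loc[rid, smp] == v


class TestRPM:
    def test_arithmetic(self):
        counts = pd.DataFrame({"s1": [50, 0]}, index=["a", "b"])
        lib = pd.Series({"s1": 5e6})
        em = rpm(counts, lib)
        assert em.values.loc["a", "s1"] == 10.0
        assert em.values.loc["b", "s1"] == 0.0

    def test_joint_scaling_invariance_exact(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 1000, (20, 5)).astype(float),
                              index=[f"f{i}" for i in range(20)],
                              columns=[f"s{j}" for j in range(5)])
        lib = pd.Series(rng.integers(int(1e6), int(5e6), 5).astype(float),
                        index=counts.columns)
        a = rpm(counts, lib).values
        b = rpm(counts * 7, lib * 7).values
        assert (a.to_numpy() == b.to_numpy()).all()

    def test_zero_library_size_error(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(ValueError, match="positive"):
            rpm(counts, pd.Series({"s1": 0.0}))


def expr_matrix(values, metadata_rows):
    md = pd.DataFrame(metadata_rows).set_index("sample")
    return ExpressionMatrix(values=values, metadata=md)


class TestDetectability:
    def make(self, means):
        """One eRNA with the given per-cohort mean RPM (2 tumor samples
        each, equal values)."""
        cols, rows, md = [], [], []
        for ci, m in enumerate(means):
            for j in range(2):
                s = f"c{ci}_t{j}"
                cols.append(s)
                rows.append(m)
                md.append({"sample": s, "cohort": f"c{ci}",
                           "condition": "tumor"})
        values = pd.DataFrame([rows], index=["e1"], columns=cols)
        return expr_matrix(values, md)

    def test_inclusive_boundary(self):
        table = detectability(self.make([1.0, 0.99]), threshold=1.0)
        det = table.per_cohort.set_index("cohort")["detectable"]
        assert det["c0"] and not det["c1"]

    def test_strict_threshold_is_subset(self, bundle, config):
        expr = rpm(bundle.counts, bundle.library_sizes, bundle.metadata)
        erna = ExpressionMatrix(
            expr.values.loc[[r.id for r in bundle.regions]],
            expr.library_sizes, expr.metadata)
        loose = detectability(erna, config.rpm_detect).per_cohort
        strict = detectability(erna, config.rpm_strict).per_cohort
        loose_set = set(map(tuple, loose[loose.detectable][["erna_id", "cohort"]].values))
        strict_set = set(map(tuple, strict[strict.detectable][["erna_id", "cohort"]].values))
        assert strict_set <= loose_set

    def test_normals_excluded_from_cohort_means(self):
        md = [{"sample": "t", "cohort": "c", "condition": "tumor"},
              {"sample": "n", "cohort": "c", "condition": "normal"}]
        values = pd.DataFrame([[2.0, 100.0]], index=["e1"], columns=["t", "n"])
        table = detectability(expr_matrix(values, md), threshold=1.0)
        assert table.per_cohort["mean_rpm"].iloc[0] == 2.0

    def test_cohort_without_tumor_samples_error(self):
        md = [{"sample": "n", "cohort": "c", "condition": "normal"}]
        values = pd.DataFrame([[1.0]], index=["e1"], columns=["n"])
        with pytest.raises(ValueError, match="no tumor samples"):
            detectability(expr_matrix(values, md), threshold=1.0)


class TestClassify:
    @pytest.mark.parametrize("n,expected", [
        (0, "undetected"), (1, "specific"), (2, "intermediate"),
        (9, "intermediate"), (10, "ubiquitous"), (15, "ubiquitous"),
    ])
    def test_boundaries(self, n, expected):
        out = classify_specificity(pd.Series({"e": n}))
        assert out["e"] == expected

    def test_classes_partition_detectable(self, bundle, config):
        expr = rpm(bundle.counts, bundle.library_sizes, bundle.metadata)
        erna = ExpressionMatrix(
            expr.values.loc[[r.id for r in bundle.regions]],
            expr.library_sizes, expr.metadata)
        per_erna = detectability(erna, config.rpm_detect).per_erna
        detected = per_erna[per_erna["n_cohorts_detected"] > 0]
        counts = detected["erna_class"].value_counts()
        assert counts.sum() == len(detected)
        assert "undetected" not in counts.index


class TestSampleSimilarity:
    def test_duplicated_sample_similarity_one(self):
        rng = np.random.default_rng(0)
        x = rng.random(30)
        values = pd.DataFrame({"s1": x, "s2": x, "s3": rng.random(30)})
        sim = sample_similarity(ExpressionMatrix(values))
        assert sim.loc["s1", "s2"] == pytest.approx(1.0)

    def test_constant_sample_recorded_missing(self):
        values = pd.DataFrame({"s1": np.arange(20.0),
                               "s2": np.ones(20)})
        sim = sample_similarity(ExpressionMatrix(values))
        assert np.isnan(sim.loc["s1", "s2"])
        assert sim.loc["s2", "s2"] == 1.0

    def test_within_cohort_exceeds_between(self, bundle, config):
        """Cohort-specific expression programs make tumor samples of the
        same cohort more rank-similar than samples of different cohorts."""
        expr = rpm(bundle.counts, bundle.library_sizes, bundle.metadata)
        erna = ExpressionMatrix(
            expr.values.loc[[r.id for r in bundle.regions]],
            expr.library_sizes, expr.metadata)
        table = detectability(erna, config.rpm_detect)
        det_any = sorted(table.per_erna.index[
            table.per_erna["n_cohorts_detected"] > 0])
        tumor = [s for s in erna.samples
                 if bundle.metadata.loc[s, "condition"] == "tumor"]
        sim = sample_similarity(erna.subset_samples(tumor), det_any)
        cohorts = bundle.metadata.loc[tumor, "cohort"]
        arr = sim.to_numpy()
        same = cohorts.to_numpy()[:, None] == cohorts.to_numpy()[None, :]
        off_diag = ~np.eye(len(tumor), dtype=bool)
        within = arr[same & off_diag].mean()
        between = arr[~same].mean()
        assert within > between
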