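import numpy as np
import pandas as pd
import pytest

from atacqc.differential import (CountMatrix, DARResult, annotate_distribution,
                                 assign_nearest_gene, call_dars, count_matrix,
                                 differential_test)
from atacqc.formats_io import AlignedPair, ChromSizes, Interval
from atacqc.qc_metrics import merge_peaks
from atacqc.read_processing import deduplicate, useful_ends

from conftest import endset_from_centers, make_pair


class TestCountMatrix:
    def test_one_pair_dual_mode(self, small_sizes):
        # pair inside a peak: both insertion centres and the midpoint contained
        pair = make_pair(start_plus=10_000, end_plus=10_050,
                         start_minus=10_100, end_minus=10_150)
        peaks = merge_peaks([Interval("chr1", 9_900, 10_300)])
        se = useful_ends([pair], "pseudoSE", small_sizes)
        pe = useful_ends([pair], "noShift", small_sizes)
        m_se = count_matrix(peaks, {"s": se}, "pseudoSE")
        m_pe = count_matrix(peaks, {"s": pe}, "noShift")
        assert m_se.counts.iloc[0, 0] == 2
        assert m_pe.counts.iloc[0, 0] == 1

    def test_straddling_pair_with_centres_outside(self, small_sizes):
        pair = make_pair(start_plus=10_000, end_plus=10_050,
                         start_minus=10_100, end_minus=10_150)
        # peak covers only [10010, 10070): centres 10004 and 10145 outside
        peaks = merge_peaks([Interval("chr1", 10_010, 10_070)])
        se = useful_ends([pair], "pseudoSE", small_sizes)
        m = count_matrix(peaks, {"s": se}, "pseudoSE")
        assert m.counts.iloc[0, 0] == 0

    def test_mode_mismatch_rejected(self, small_sizes):
        se = useful_ends([make_pair()], "pseudoSE", small_sizes)
        with pytest.raises(ValueError):
            count_matrix(merge_peaks([Interval("chr1", 0, 100)]),
                         {"s": se}, "noShift")

    def test_column_sums_bounded_by_library_sizes(self, sim_library):
        pairs, _ = deduplicate(sim_library["pairs"])
        sizes = sim_library["sizes"]
        ends = useful_ends(pairs, "pseudoSE", sizes)
        m = count_matrix(sim_library["peaks"], {"s": ends}, "pseudoSE")
        assert m.counts["s"].sum() <= m.library_sizes["s"]

    def test_pseudo_se_counts_double_noshift_on_contained_pairs(self, small_sizes):
        pairs = [make_pair(start_plus=10_000 + i, end_plus=10_050 + i,
                           start_minus=10_100 + i, end_minus=10_150 + i)
                 for i in range(20)]
        peaks = merge_peaks([Interval("chr1", 9_000, 11_000)])
        se = count_matrix(peaks, {"s": useful_ends(pairs, "pseudoSE", small_sizes)},
                          "pseudoSE")
        pe = count_matrix(peaks, {"s": useful_ends(pairs, "noShift", small_sizes)},
                          "noShift")
        assert int(se.counts.values.sum()) == 2 * int(pe.counts.values.sum())


def matrix_from_counts(counts: dict, lib_sizes: dict, mode="pseudoSE"):
    frame = pd.DataFrame(counts)
    frame.index = [f"chr1:{i * 1000}-{i * 1000 + 500}" for i in range(len(frame))]
    return CountMatrix(counts=frame, mode=mode, library_sizes=lib_sizes)


class TestDifferentialTest:
    def test_identical_groups_all_ns(self):
        m = matrix_from_counts({"a": [10, 20, 30], "b": [10, 20, 30]},
                               {"a": 1000, "b": 1000})
        results = differential_test(m, {"a": "g1", "b": "g2"})
        assert all(r.log2fc == 0.0 for r in results)
        dars = call_dars(results)
        assert not dars["group1"] and not dars["group2"]

    def test_hand_computed_log2fc(self):
        # normalized means 100 vs 25 -> log2(26/101)
        m = matrix_from_counts({"a": [100], "b": [25]},
                               {"a": 10_000_000, "b": 10_000_000})
        results = differential_test(m, {"a": "g1", "b": "g2"})
        assert results[0].log2fc == pytest.approx(np.log2(26 / 101), abs=1e-6)

    def test_padj_at_least_pvalue(self):
        rng = np.random.default_rng(1)
        m = matrix_from_counts({"a": rng.poisson(30, 200),
                                "b": rng.poisson(30, 200)},
                               {"a": 100_000, "b": 100_000})
        results = differential_test(m, {"a": "g1", "b": "g2"})
        assert all(r.padj >= r.pvalue - 1e-12 for r in results)

    def test_single_group_rejected(self):
        m = matrix_from_counts({"a": [1], "b": [1]}, {"a": 10, "b": 10})
        with pytest.raises(ValueError):
            differential_test(m, {"a": "g1", "b": "g1"})

    def test_pluggable_pvalues(self):
        m = matrix_from_counts({"a": [5, 5], "b": [5, 5]}, {"a": 10, "b": 10})
        results = differential_test(m, {"a": "g1", "b": "g2"},
                                    pvalues=np.asarray([0.001, 1.0]))
        assert results[0].pvalue == 0.001 and results[1].pvalue == 1.0

    def test_planted_fourfold_recall(self):
        rng = np.random.default_rng(42)
        n_peaks, n_planted = 2000, 100
        base = 30
        counts = {}
        for s, group in (("a1", 1), ("a2", 1), ("b1", 2), ("b2", 2)):
            lam = np.full(n_peaks, base, dtype=float)
            if group == 2:
                lam[:n_planted] *= 4.0
            counts[s] = rng.poisson(lam)
        m = matrix_from_counts(counts, {s: 10_000_000 for s in counts})
        results = differential_test(
            m, {"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"})
        dars = call_dars(results)
        planted_ids = set(m.counts.index[:n_planted])
        called = {r.peak_id for r in dars["group2"]}
        recall = len(called & planted_ids) / n_planted
        assert recall >= 0.8


class TestCallDars:
    def make(self, padj, fc):
        return DARResult(peak_id="chr1:0-100", log2fc=fc, pvalue=padj, padj=padj)

    def test_strict_boundaries(self):
        dars = call_dars([self.make(0.01, 5.0),    # padj == 0.01 -> excluded
                          self.make(0.001, 1.0),   # |fc| == 1 -> excluded
                          self.make(0.001, -2.0)])
        assert len(dars["ns"]) == 2
        assert len(dars["group1"]) == 1
        assert dars["group1"][0].direction == "group1-specific"

    def test_partition(self):
        rng = np.random.default_rng(0)
        results = [self.make(float(p), float(f))
                   for p, f in zip(rng.random(100), rng.normal(0, 2, 100))]
        dars = call_dars(results)
        assert sum(len(v) for v in dars.values()) == 100


class TestAnnotation:
    def test_precedence_and_partition(self):
        dars = [DARResult("chr1:1000-1200", 0, 1, 1),
                DARResult("chr1:5000-5200", 0, 1, 1),
                DARResult("chr1:9000-9200", 0, 1, 1)]
        annotation = {
            "promoter": [Interval("chr1", 1000, 1200)],
            "exon": [Interval("chr1", 1000, 1200), Interval("chr1", 5000, 5200)],
            "intron": [],
        }
        fr = annotate_distribution(dars, annotation)
        assert fr["promoter"] == pytest.approx(1 / 3)   # beats exon
        assert fr["exon"] == pytest.approx(1 / 3)
        assert fr["intergenic"] == pytest.approx(1 / 3)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_empty_annotation_all_intergenic(self):
        dars = [DARResult("chr1:0-100", 0, 1, 1)]
        fr = annotate_distribution(dars, {})
        assert fr["intergenic"] == 1.0


class TestNearestGene:
    tss = [Interval("chr1", 10_000, 10_001, name="geneA"),
           Interval("chr1", 50_000, 50_001, name="geneB")]

    @pytest.mark.parametrize("start,end,expect_class,expect_gene", [
        (9_950, 10_050, "proximal", "geneA"),    # distance 0
        (11_900, 12_100, "proximal", "geneA"),   # distance 2000 exactly
        (20_000, 20_200, "distal", "geneA"),
        (34_900, 35_100, "unassigned", "geneB"),  # 15 km from nothing < 20kb? 15000->distal
    ])
    def test_classes(self, start, end, expect_class, expect_gene):
        mid = (start + end) // 2
        dist_a = abs(mid - 10_000)
        dist_b = abs(mid - 50_000)
        best = min(dist_a, dist_b)
        expect_class = ("proximal" if best <= 2000
                        else "distal" if best <= 20_000 else "unassigned")
        dar = DARResult(f"chr1:{start}-{end}", 0, 1, 1)
        gene, dist, klass = assign_nearest_gene([dar], self.tss)[dar.peak_id]
        assert klass == expect_class and dist == best

    def test_far_dar_unassigned(self):
        dar = DARResult("chr2:400000-400200", 0, 1, 1)
        gene, dist, klass = assign_nearest_gene(
            [dar], self.tss)[dar.peak_id]
        assert klass == "unassigned" and gene is None

    def test_no_tss_rejected(self):
        with pytest.raises(ValueError):
            assign_nearest_gene([], [])
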