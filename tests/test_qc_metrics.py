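import numpy as np
import pytest
from scipy import stats

from atacqc.formats_io import ChromSizes, Interval
from atacqc.qc_metrics import (MetricUndefinedError, PeakSet, ReferenceTable,
                               background_metric, end_under_peak,
                               grade_metrics, merge_peaks, promoter_enrichment,
                               promoter_peak_fraction, region_rpkm, rupr,
                               sample_background_regions, saturation_curve,
                               signal_ranking, subsampling_enrichment,
                               validate_peaks)
from atacqc.read_processing import Fragment

from conftest import endset_from_centers


def bp_oracle_total_length(intervals, genome_len=100_000):
    covered = np.zeros(genome_len, dtype=bool)
    for iv in intervals:
        covered[iv.start:iv.end] = True
    return int(covered.sum())


class TestMergePeaks:
    def test_overlapping_merge(self):
        ps = merge_peaks([Interval("chr1", 10, 20), Interval("chr1", 15, 30)])
        assert len(ps) == 1 and ps.peaks[0].start == 10 and ps.peaks[0].end == 30
        assert ps.total_length == 20

    def test_disjoint_lengths_add(self):
        ps = merge_peaks([Interval("chr1", 0, 10), Interval("chr1", 20, 30)])
        assert len(ps) == 2 and ps.total_length == 20

    def test_touching_intervals_merge(self):
        ps = merge_peaks([Interval("chr1", 0, 10), Interval("chr1", 10, 20)])
        assert len(ps) == 1 and ps.total_length == 20

    def test_total_length_matches_bp_oracle(self):
        rng = np.random.default_rng(17)
        starts = rng.integers(0, 99_000, size=1000)
        widths = rng.integers(1, 800, size=1000)
        ivs = [Interval("chr1", int(s), int(min(s + w, 100_000)))
               for s, w in zip(starts, widths)]
        assert merge_peaks(ivs).total_length == bp_oracle_total_length(ivs)


class TestOverlapRule:
    def setup_method(self):
        self.peaks = merge_peaks([Interval("chr1", 1000, 2000)])

    def test_exactly_half_overlap_counts(self):
        # fragment [925, 1075): 75 of 150 bp inside -> boundary inclusive
        frag = Fragment("chr1", 925, 1075, "pseudoSE", center=1000)
        assert end_under_peak(frag, self.peaks)

    def test_just_under_half_does_not(self):
        frag = Fragment("chr1", 926, 1074 + 2, "pseudoSE", center=1001)
        # [926, 1076): 76 inside of 150 -> counts; shift left instead:
        frag = Fragment("chr1", 924, 1074, "pseudoSE", center=999)
        assert not end_under_peak(frag, self.peaks)  # 74 of 150 inside

    def test_fully_inside(self):
        frag = Fragment("chr1", 1100, 1250, "pseudoSE", center=1175)
        assert end_under_peak(frag, self.peaks)


class TestRupr:
    def test_half_under(self, small_sizes):
        ends = endset_from_centers([1500] * 5 + [500_000] * 5, small_sizes)
        peaks = merge_peaks([Interval("chr1", 1000, 2000)])
        assert rupr(ends, peaks) == pytest.approx(0.5)

    def test_empty_peakset_gives_zero(self, small_sizes):
        ends = endset_from_centers([1500], small_sizes)
        assert rupr(ends, merge_peaks([])) == 0.0

    def test_no_ends_is_undefined(self, small_sizes):
        ends = endset_from_centers([], small_sizes)
        with pytest.raises(MetricUndefinedError):
            rupr(ends, merge_peaks([Interval("chr1", 0, 100)]))

    def test_invariant_under_end_duplication(self, small_sizes):
        rng = np.random.default_rng(4)
        centers = rng.integers(100, 900_000, size=2000)
        ends = endset_from_centers(centers, small_sizes)
        doubled = endset_from_centers(np.concatenate([centers, centers]),
                                      small_sizes)
        peaks = merge_peaks([Interval("chr1", i * 10_000, i * 10_000 + 500)
                             for i in range(50)])
        assert rupr(ends, peaks) == pytest.approx(rupr(doubled, peaks))


class TestBackgroundRegions:
    def test_peak_free_genome(self):
        sizes = ChromSizes({"chr1": 1_000_000, "chrM": 20_000})
        regions = sample_background_regions(sizes, merge_peaks([]), n=100, seed=1)
        assert len(regions) == 100
        assert all(r.length == 500 and r.chrom != "chrM" for r in regions)

    def test_fully_covered_genome_errors(self):
        sizes = ChromSizes({"chr1": 10_000, "chrM": 1_000})
        peaks = merge_peaks([Interval("chr1", 0, 10_000)])
        with pytest.raises(MetricUndefinedError):
            sample_background_regions(sizes, peaks, n=10)

    def test_seed_determinism(self, small_sizes):
        peaks = merge_peaks([Interval("chr1", 1000, 2000)])
        a = sample_background_regions(small_sizes, peaks, n=50, seed=9)
        b = sample_background_regions(small_sizes, peaks, n=50, seed=9)
        assert a == b

    def test_regions_avoid_peaks(self, small_sizes):
        peaks = merge_peaks([Interval("chr1", i * 2000, i * 2000 + 1500)
                             for i in range(400)])
        regions = sample_background_regions(small_sizes, peaks, n=500, seed=2)
        from atacqc._intervals import union_overlap
        ov = union_overlap(peaks.index,
                           np.asarray([r.chrom for r in regions], dtype=object),
                           np.asarray([r.start for r in regions]),
                           np.asarray([r.end for r in regions]))
        assert (ov == 0).all()


class TestRegionRpkm:
    def test_hand_arithmetic(self, small_sizes):
        ends = endset_from_centers([1100, 1200] + list(range(10_000, 10_008)),
                                   small_sizes)
        region = Interval("chr1", 1000, 1500)
        # 2 ends / (0.5 kb * 10 ends / 1e6) = 400,000
        assert region_rpkm(region, ends) == pytest.approx(2 / (0.5 * 10 / 1e6))

    def test_empty_region_zero(self, small_sizes):
        ends = endset_from_centers([500_000], small_sizes)
        assert region_rpkm(Interval("chr1", 0, 1000), ends) == 0.0


class TestBackgroundMetric:
    def test_no_reads_outside_peaks_gives_zero(self, small_sizes):
        peaks = merge_peaks([Interval("chr1", 1000, 2000)])
        ends = endset_from_centers([1500] * 20, small_sizes)
        bg = background_metric(ends, peaks, small_sizes, n=200, seed=1)
        assert bg.background == 0.0 and bg.n_high == 0

    def test_threshold_zero_with_dense_reads_gives_one(self, small_sizes):
        centers = np.arange(100, 999_900, 100)
        ends = endset_from_centers(centers, small_sizes)
        # drop chr2 from eligibility by covering it with a peak
        peaks = merge_peaks([Interval("chr2", 0, 500_000)])
        bg = background_metric(ends, peaks, small_sizes, n=200,
                               threshold=0.0, seed=1)
        assert bg.background == 1.0

    def test_matches_poisson_tail_on_homogeneous_library(self):
        sizes = ChromSizes({"chr1": 10_000_000, "chrM": 20_000})
        rng = np.random.default_rng(8)
        n_ends = 20_000
        centers = rng.integers(0, 10_000_000, size=n_ends)
        ends = endset_from_centers(centers, sizes)
        n_regions = 5000
        bg = background_metric(ends, merge_peaks([]), sizes,
                               n=n_regions, seed=3)
        lam = n_ends * 500 / 10_000_000
        k_star = int(np.floor(0.377 * 0.5 * n_ends / 1e6)) + 1
        expect = stats.poisson.sf(k_star - 1, lam)
        sigma = np.sqrt(expect * (1 - expect) / n_regions)
        assert abs(bg.background - expect) < 5 * sigma

    def test_fixed_seed_bit_reproducible(self, small_sizes):
        ends = endset_from_centers(
            np.random.default_rng(0).integers(0, 900_000, 3000), small_sizes)
        a = background_metric(ends, merge_peaks([]), small_sizes, n=500, seed=5)
        b = background_metric(ends, merge_peaks([]), small_sizes, n=500, seed=5)
        assert a == b


class TestPromoterEnrichment:
    def test_all_ends_in_promoter_peaks_covering_one_percent(self):
        sizes = ChromSizes({"chr1": 100_000, "chrM": 1_000})
        peaks = merge_peaks([Interval("chr1", 2000, 3000)])  # 1% of 100 kb
        promoters = [Interval("chr1", 2400, 2600)]
        ends = endset_from_centers(np.full(50, 2500), sizes)
        proen = promoter_enrichment(ends, peaks, promoters, sizes)
        assert proen == pytest.approx(100.0)

    def test_no_promoter_peaks_not_applicable(self, small_sizes):
        ends = endset_from_centers([1000], small_sizes)
        peaks = merge_peaks([Interval("chr1", 500, 1500)])
        with pytest.raises(MetricUndefinedError):
            promoter_enrichment(ends, peaks, [Interval("chr2", 0, 100)],
                                small_sizes)

    def test_no_ends_is_error(self, small_sizes):
        ends = endset_from_centers([], small_sizes)
        with pytest.raises(MetricUndefinedError):
            promoter_enrichment(ends, merge_peaks([Interval("chr1", 0, 100)]),
                                [Interval("chr1", 0, 100)], small_sizes)


class TestSubEn:
    def planted(self, sizes, frac_ends_in_peak=0.6):
        rng = np.random.default_rng(21)
        n = 20_000
        n_in = int(frac_ends_in_peak * n)
        peak = Interval("chr1", 100_000, 150_000)  # 50 kb of ~1.48 Mb eff
        inside = rng.integers(peak.start, peak.end, size=n_in)
        outside = rng.integers(200_000, 900_000, size=n - n_in)
        ends = endset_from_centers(np.concatenate([inside, outside]), sizes)
        return ends, merge_peaks([peak])

    def test_bounded_by_no_pseudo_enrichment(self, small_sizes):
        ends, peaks = self.planted(small_sizes)
        l_g = small_sizes.effective_length(False)
        f = peaks.total_length / l_g
        g = 0.6
        upper = (g / f) / ((1 - g) / (1 - f))
        res = subsampling_enrichment(ends, small_sizes, peaks, seed=2)
        assert res.suben is not None and 1.0 < res.suben < upper

    def test_small_pseudo_approaches_raw_enrichment(self, small_sizes):
        ends, peaks = self.planted(small_sizes)
        l_g = small_sizes.effective_length(False)
        f = peaks.total_length / l_g
        res = subsampling_enrichment(ends, small_sizes, peaks, pseudo=1, seed=2)
        g_hat = res.e_under_peaks / res.e_sampled
        raw = (g_hat / f) / ((1 - g_hat) / (1 - f))
        assert res.suben == pytest.approx(raw, rel=1e-3)

    def test_huge_pseudo_shrinks_to_one(self, small_sizes):
        ends, peaks = self.planted(small_sizes)
        res = subsampling_enrichment(ends, small_sizes, peaks,
                                     pseudo=10**12, seed=2)
        assert res.suben == pytest.approx(1.0, abs=1e-3)

    def test_no_peaks_not_applicable(self, small_sizes):
        ends = endset_from_centers([100, 200], small_sizes)
        res = subsampling_enrichment(ends, small_sizes, merge_peaks([]), seed=1)
        assert res.suben is None

    def test_invariant_to_end_order_and_repeatable(self, small_sizes):
        ends, peaks = self.planted(small_sizes)
        res1 = subsampling_enrichment(ends, small_sizes, peaks,
                                      depth=5000, seed=7)
        shuffled = ends.subset(np.random.default_rng(0).permutation(ends.e_total))
        res2 = subsampling_enrichment(shuffled, small_sizes, peaks,
                                      depth=5000, seed=7)
        res3 = subsampling_enrichment(ends, small_sizes, peaks,
                                      depth=5000, seed=7)
        assert res1 == res2 == res3


class TestSaturation:
    def test_full_depth_recovery_is_one_and_monotone(self, small_sizes):
        rng = np.random.default_rng(31)
        peaks = [Interval("chr1", i * 20_000, i * 20_000 + 600)
                 for i in range(1, 40)]
        in_peak = np.concatenate([
            rng.integers(p.start, p.end, size=150) for p in peaks])
        bg = rng.integers(0, 1_000_000, size=3000)
        ends = endset_from_centers(np.concatenate([in_peak, bg]), small_sizes)

        from atacqc.signal_and_peaks import calls_to_peakset, naive_call_peaks
        caller = lambda e: calls_to_peakset(naive_call_peaks(e, small_sizes))
        curve = saturation_curve(ends, small_sizes, caller, seed=6)
        fractions = [f for f, _ in curve]
        recoveries = [r for _, r in curve]
        assert fractions == pytest.approx([0.1 * i for i in range(1, 11)])
        assert recoveries[-1] == pytest.approx(1.0)
        for a, b in zip(recoveries, recoveries[1:]):
            assert b >= a - 0.02  # nested subsamples, caller noise only

    def test_bad_step_rejected(self, small_sizes):
        ends = endset_from_centers([100], small_sizes)
        with pytest.raises(ValueError):
            saturation_curve(ends, small_sizes, lambda e: merge_peaks([]),
                             step_fraction=0.0)


class TestSignalRanking:
    def make_peaks(self, n=20):
        return merge_peaks([Interval("chr1", i * 10_000, i * 10_000 + 1000)
                            for i in range(1, n + 1)])

    def test_separable_promoter_top_half(self, small_sizes):
        peaks = self.make_peaks(20)
        # top-10 peaks (by signal) are the promoter peaks
        centers = []
        for rank, p in enumerate(peaks.peaks):
            count = 100 - rank  # descending signal with peak order
            centers.extend([p.midpoint] * count)
        ends = endset_from_centers(centers, small_sizes)
        promoters = [Interval("chr1", p.start, p.end)
                     for p in peaks.peaks[:10]]
        deciles = signal_ranking(ends, peaks, promoters, n_quantiles=10)
        assert deciles == [1.0] * 5 + [0.0] * 5

    def test_all_promoter_or_none(self, small_sizes):
        peaks = self.make_peaks(10)
        ends = endset_from_centers([p.midpoint for p in peaks.peaks],
                                   small_sizes)
        everywhere = [Interval("chr1", 0, 1_000_000)]
        assert signal_ranking(ends, peaks, everywhere) == [1.0] * 10
        assert signal_ranking(ends, peaks, []) == [0.0] * 10

    def test_too_few_peaks_rejected(self, small_sizes):
        peaks = self.make_peaks(5)
        ends = endset_from_centers([100], small_sizes)
        with pytest.raises(ValueError, match="n_quantiles"):
            signal_ranking(ends, peaks, [], n_quantiles=10)


class TestPromoterPeakFraction:
    def test_fraction(self):
        peaks = merge_peaks([Interval("chr1", i * 1000, i * 1000 + 500)
                             for i in range(10)])
        promoters = [Interval("chr1", i * 1000, i * 1000 + 100)
                     for i in range(4)]
        assert promoter_peak_fraction(peaks, promoters) == pytest.approx(0.4)

    def test_empty_promoters_and_identity(self):
        peaks = merge_peaks([Interval("chr1", 0, 100)])
        assert promoter_peak_fraction(peaks, []) == 0.0
        assert promoter_peak_fraction(peaks, peaks.peaks) == 1.0
        with pytest.raises(MetricUndefinedError):
            promoter_peak_fraction(merge_peaks([]), [])


class TestValidatePeaks:
    def test_identical_sets(self):
        peaks = merge_peaks([Interval("chr1", 0, 100), Interval("chr1", 200, 300)])
        res = validate_peaks(peaks, peaks)
        assert res.fdr_like == 0.0 and res.fnr_like == 0.0

    def test_empty_reference_rejected(self):
        peaks = merge_peaks([Interval("chr1", 0, 100)])
        with pytest.raises(MetricUndefinedError):
            validate_peaks(peaks, merge_peaks([]))


class TestGrading:
    table = ReferenceTable({
        "rupr": (0.25, 0.10, "higher-better"),
        "background": (0.12, 0.05, "lower-better"),
    })

    @pytest.mark.parametrize("value,grade", [
        (0.25, "good"),        # == mean, boundary inclusive
        (0.15, "acceptable"),  # == mean - sd exactly
        (0.1499, "fail"),
        (0.40, "good"),
    ])
    def test_higher_better_boundaries(self, value, grade):
        assert grade_metrics({"rupr": value}, self.table)["rupr"] == grade

    @pytest.mark.parametrize("value,grade", [
        (0.12, "good"),
        (0.12 + 0.05, "acceptable"),  # mean + sd exactly
        (0.22, "fail"),        # mean + 2 sd
    ])
    def test_lower_better_mirrored(self, value, grade):
        assert grade_metrics({"background": value}, self.table)["background"] == grade

    def test_unknown_metric_flagged(self):
        assert grade_metrics({"mystery": 1.0}, self.table)["mystery"] == "ungraded"

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            ReferenceTable({"rupr": (0.2, -0.1, "higher-better")})
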