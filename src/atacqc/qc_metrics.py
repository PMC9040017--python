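"""Peak-calling QC statistics for ATAC-seq libraries.

The four ratio metrics:

* RUPr  — fraction of useful ends with >= 50% overlap with called peaks.
* Background — fraction of 50,000 random non-peak 500-bp regions whose
  signal exceeds RPKM 0.377.
* ProEn — useful-end density inside promoter-overlapping peaks relative
  to the genome-wide density.
* SubEn — in-peak vs out-of-peak end density on a 10-million-end
  subsample, shrunk toward 1 by 10 million uniform pseudo-counts.

Plus saturation analysis, signal-ranking analysis, promoter peak
distribution, reference-set (DHS) validation and mean/SD grading.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from . import _intervals
from .formats_io import ChromSizes, Interval
from .read_processing import EndSet, Fragment

DEFAULT_N_BACKGROUND_REGIONS = 50_000
DEFAULT_BACKGROUND_WIDTH = 500
DEFAULT_RPKM_THRESHOLD = 0.377
DEFAULT_SUBEN_DEPTH = 10_000_000
DEFAULT_SUBEN_PSEUDO = 10_000_000
DEFAULT_SATURATION_STEP = 0.10
DEFAULT_PROMOTER_HALF_WINDOW = 1_000
DEFAULT_MIN_OVERLAP_FRAC = 0.5


class MetricUndefinedError(ValueError):
    """A metric's preconditions do not hold (exit code 4 in the CLI)."""


@dataclass
class PeakSet:
    """Merged, sorted, pairwise-disjoint peaks with total covered bp."""

    peaks: List[Interval]
    total_length: int
    source: str = ""
    _index: Optional[_intervals.ChromIndex] = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def index(self) -> _intervals.ChromIndex:
        if self._index is None:
            self._index = _intervals.build_index(
                (p.chrom, p.start, p.end) for p in self.peaks)
        return self._index


@dataclass
class BackgroundResult:
    n_regions: int
    region_width: int
    rpkm_threshold: float
    n_high: int
    background: float
    seed: int


@dataclass
class SubEnResult:
    sample_depth: int
    pseudo: int
    e_sampled: int
    e_under_peaks: int
    peak_length: int
    suben: Optional[float]  # None = not applicable (no peaks)
    shortfall: int = 0      # ends short of the requested depth
    form: str = "canonical-form"


@dataclass
class ValidationResult:
    n_peaks: int
    n_reference: int
    n_validated: int
    n_unvalidated: int
    fdr_like: float
    n_missed: int
    fnr_like: float


@dataclass
class ReferenceTable:
    """Per-metric (mean, sd, direction) grading reference.

    direction is ``higher-better`` or ``lower-better``.
    """

    entries: Dict[str, Tuple[float, float, str]]

    def __post_init__(self) -> None:
        for metric, (mean, sd, direction) in self.entries.items():
            if sd < 0:
                raise ValueError(f"{metric}: sd must be >= 0, got {sd}")
            if direction not in ("higher-better", "lower-better"):
                raise ValueError(f"{metric}: bad direction {direction!r}")

    @classmethod
    def from_file(cls, path: str) -> "ReferenceTable":
        entries: Dict[str, Tuple[float, float, str]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 4:
                    raise ValueError(f"{path}:{lineno}: expected "
                                     "'metric mean sd direction'")
                entries[fields[0]] = (float(fields[1]), float(fields[2]), fields[3])
        return cls(entries)


def merge_peaks(intervals: Sequence[Interval], source: str = "") -> PeakSet:
    """Merge overlapping/touching intervals into a PeakSet."""
    if not intervals:
        return PeakSet(peaks=[], total_length=0, source=source)
    merged = _intervals.merge_triples((iv.chrom, iv.start, iv.end) for iv in intervals)
    peaks = [Interval(c, s, e) for c, s, e in merged]
    total = sum(e - s for _, s, e in merged)
    return PeakSet(peaks=peaks, total_length=total, source=source)


def ends_under_peaks(ends: EndSet, peaks: PeakSet,
                     min_frac: float = DEFAULT_MIN_OVERLAP_FRAC) -> np.ndarray:
    """Boolean per fragment: does >= min_frac of it overlap the peak union?"""
    if len(peaks) == 0 or ends.e_total == 0:
        return np.zeros(ends.e_total, dtype=bool)
    overlap = _intervals.union_overlap(peaks.index, ends.chroms, ends.starts, ends.ends)
    lengths = ends.ends - ends.starts
    return overlap >= min_frac * lengths


def end_under_peak(fragment: Fragment, peaks: PeakSet,
                   min_frac: float = DEFAULT_MIN_OVERLAP_FRAC) -> bool:
    """50%-overlap rule for a single fragment."""
    if len(peaks) == 0:
        return False
    overlap = _intervals.union_overlap(
        peaks.index, np.asarray([fragment.chrom], dtype=object),
        np.asarray([fragment.start]), np.asarray([fragment.end]))[0]
    return bool(overlap >= min_frac * fragment.length)


def rupr(ends: EndSet, peaks: PeakSet,
         min_frac: float = DEFAULT_MIN_OVERLAP_FRAC) -> float:
    """Reads-under-peak ratio: E_under_peaks / E_total."""
    if ends.e_total == 0:
        raise MetricUndefinedError("RUPr undefined: no useful ends")
    return float(ends_under_peaks(ends, peaks, min_frac).sum()) / ends.e_total


def sample_background_regions(sizes: ChromSizes, peaks: PeakSet,
                              n: int = DEFAULT_N_BACKGROUND_REGIONS,
                              width: int = DEFAULT_BACKGROUND_WIDTH,
                              seed: int = 0) -> List[Interval]:
    """n random width-bp regions outside the peaks, off the mitochondrion.

    Sampling is uniform over all eligible start positions; regions may
    overlap one another.  Deterministic for a fixed seed.
    """
    gaps = _intervals.complement(peaks.index, sizes.non_mito())
    eligible = [(c, s, e) for c, s, e in gaps if e - s >= width]
    counts = np.asarray([e - width - s + 1 for _, s, e in eligible], dtype=np.int64)
    total = int(counts.sum()) if len(counts) else 0
    if total <= 0:
        avail = sum(e - s for _, s, e in gaps)
        raise MetricUndefinedError(
            f"cannot sample {width}-bp background regions: only {avail} bp "
            "outside peaks")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, total, size=n)
    cum = np.concatenate([[0], np.cumsum(counts)])
    gap_idx = np.searchsorted(cum, draws, side="right") - 1
    out: List[Interval] = []
    for d, g in zip(draws.tolist(), gap_idx.tolist()):
        chrom, gs, _ = eligible[g]
        start = gs + (d - int(cum[g]))
        out.append(Interval(chrom, start, start + width))
    return out


def _counts_in_regions(ends: EndSet, regions: Sequence[Interval]) -> np.ndarray:
    """Ends whose assignment centre lies in each region (centre-in-region rule)."""
    by_chrom: Dict[str, np.ndarray] = {}
    chrom_arr = ends.chroms.astype(str)
    for chrom in set(chrom_arr.tolist()):
        by_chrom[chrom] = np.sort(ends.centers[chrom_arr == chrom])
    counts = np.zeros(len(regions), dtype=np.int64)
    for i, region in enumerate(regions):
        centers = by_chrom.get(region.chrom)
        if centers is None:
            continue
        counts[i] = (np.searchsorted(centers, region.end)
                     - np.searchsorted(centers, region.start))
    return counts


def region_rpkm(region: Interval, ends: EndSet) -> float:
    """RPKM of one region, counting ends by their insertion centre."""
    if ends.e_total == 0:
        raise MetricUndefinedError("RPKM undefined: no useful ends")
    count = int(_counts_in_regions(ends, [region])[0])
    kb = region.length / 1000.0
    millions = ends.e_total / 1e6
    return count / (kb * millions)


def background_metric(ends: EndSet, peaks: PeakSet, sizes: ChromSizes,
                      n: int = DEFAULT_N_BACKGROUND_REGIONS,
                      width: int = DEFAULT_BACKGROUND_WIDTH,
                      threshold: float = DEFAULT_RPKM_THRESHOLD,
                      seed: int = 0) -> BackgroundResult:
    """Fraction of random non-peak regions with RPKM strictly over threshold."""
    if ends.e_total == 0:
        raise MetricUndefinedError("Background undefined: no useful ends")
    regions = sample_background_regions(sizes, peaks, n=n, width=width, seed=seed)
    counts = _counts_in_regions(ends, regions)
    rpkm = counts / ((width / 1000.0) * (ends.e_total / 1e6))
    n_high = int((rpkm > threshold).sum())
    return BackgroundResult(n_regions=n, region_width=width,
                            rpkm_threshold=threshold, n_high=n_high,
                            background=n_high / n, seed=seed)


def promoter_peaks(peaks: PeakSet, promoters: Sequence[Interval]) -> PeakSet:
    """Sub-PeakSet of peaks with >= 1 bp overlap with any promoter interval."""
    if len(peaks) == 0 or not promoters:
        return PeakSet(peaks=[], total_length=0, source="promoter-peaks")
    prom_index = _intervals.build_index(
        _intervals.merge_triples((p.chrom, p.start, p.end) for p in promoters))
    chroms = np.asarray([p.chrom for p in peaks.peaks], dtype=object)
    starts = np.asarray([p.start for p in peaks.peaks])
    ends_ = np.asarray([p.end for p in peaks.peaks])
    overlap = _intervals.union_overlap(prom_index, chroms, starts, ends_)
    chosen = [p for p, ov in zip(peaks.peaks, overlap) if ov >= 1]
    return merge_peaks(chosen, source="promoter-peaks")


def promoters_from_tss(tss: Sequence[Interval], sizes: ChromSizes,
                       half_window: int = DEFAULT_PROMOTER_HALF_WINDOW) -> List[Interval]:
    """Expand TSS point records to [tss - half_window, tss + half_window)."""
    out: List[Interval] = []
    for rec in tss:
        pos = rec.start
        start = max(0, pos - half_window)
        end = min(sizes[rec.chrom], pos + half_window) if rec.chrom in sizes \
            else pos + half_window
        out.append(Interval(rec.chrom, start, end, name=rec.name, strand=rec.strand))
    return out


def promoter_enrichment(ends: EndSet, peaks: PeakSet,
                        promoters: Sequence[Interval], sizes: ChromSizes,
                        min_frac: float = DEFAULT_MIN_OVERLAP_FRAC) -> float:
    """ProEn = (E_under_promoter_peaks / L_promoter_peaks) / (E_total / L_genome)."""
    if ends.e_total == 0:
        raise MetricUndefinedError("ProEn undefined: no useful ends")
    pp = promoter_peaks(peaks, promoters)
    if pp.total_length == 0:
        raise MetricUndefinedError("ProEn not applicable: no promoter-overlapping peaks")
    e_under = int(ends_under_peaks(ends, pp, min_frac).sum())
    l_genome = sizes.effective_length(ends.include_mito)
    return (e_under / pp.total_length) / (ends.e_total / l_genome)


PeakCaller = Callable[[EndSet], PeakSet]


def subsampling_enrichment(ends: EndSet, sizes: ChromSizes,
                           peak_caller: Union[PeakCaller, PeakSet],
                           depth: int = DEFAULT_SUBEN_DEPTH,
                           pseudo: int = DEFAULT_SUBEN_PSEUDO,
                           seed: int = 0,
                           min_frac: float = DEFAULT_MIN_OVERLAP_FRAC) -> SubEnResult:
    """SubEn: in-peak vs out-of-peak density on a fixed-depth subsample.

    With sampled in-peak ends E_in, sampled total E_s, peak bp L_p,
    genome bp L_g and ``pseudo`` uniform pseudo-ends:

        SubEn = [(E_in + p*L_p/L_g) / L_p]
              / [((E_s - E_in) + p*(1 - L_p/L_g)) / (L_g - L_p)]

    The pseudo-counts shrink the ratio toward 1, avoiding blow-ups at
    low sequencing depth.
    """
    if ends.e_total == 0:
        raise MetricUndefinedError("SubEn undefined: no useful ends")
    canon = ends.canonical_order()
    k = min(depth, canon.e_total)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(canon.e_total)[:k]
    sample = canon.subset(np.sort(idx))
    peaks = peak_caller if isinstance(peak_caller, PeakSet) else peak_caller(sample)
    if peaks.total_length == 0:
        return SubEnResult(depth, pseudo, k, 0, 0, suben=None,
                           shortfall=depth - k)
    e_in = int(ends_under_peaks(sample, peaks, min_frac).sum())
    l_p = peaks.total_length
    l_g = sizes.effective_length(ends.include_mito)
    if l_p >= l_g:
        raise MetricUndefinedError("SubEn undefined: peaks cover the whole genome")
    num = (e_in + pseudo * l_p / l_g) / l_p
    den = ((k - e_in) + pseudo * (1 - l_p / l_g)) / (l_g - l_p)
    return SubEnResult(depth, pseudo, k, e_in, l_p, suben=num / den,
                       shortfall=depth - k)


def _peakset_overlap_bp(a: PeakSet, b: PeakSet) -> int:
    if len(a) == 0 or len(b) == 0:
        return 0
    chroms = np.asarray([p.chrom for p in a.peaks], dtype=object)
    starts = np.asarray([p.start for p in a.peaks])
    ends_ = np.asarray([p.end for p in a.peaks])
    return int(_intervals.union_overlap(b.index, chroms, starts, ends_).sum())


def saturation_curve(ends: EndSet, sizes: ChromSizes, peak_caller: PeakCaller,
                     step_fraction: float = DEFAULT_SATURATION_STEP,
                     seed: int = 0) -> List[Tuple[float, float]]:
    """Peak-bp recovery along nested subsamples at 10% depth steps.

    recovery(f) = bp(peaks_f intersect peaks_full) / bp(peaks_full); the
    subsamples are nested so recovery is monotone up to caller noise,
    and recovery(1.0) == 1 by construction.
    """
    if ends.e_total == 0:
        raise MetricUndefinedError("saturation undefined: no useful ends")
    if not (0 < step_fraction <= 1):
        raise ValueError(f"step_fraction must be in (0, 1], got {step_fraction}")
    canon = ends.canonical_order()
    full_peaks = peak_caller(canon)
    if full_peaks.total_length == 0:
        raise MetricUndefinedError("saturation undefined: no peaks at full depth")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(canon.e_total)
    n_steps = round(1.0 / step_fraction)
    curve: List[Tuple[float, float]] = []
    for i in range(1, n_steps + 1):
        f = i * step_fraction
        k = min(canon.e_total, round(f * canon.e_total))
        sub = canon.subset(np.sort(perm[:k]))
        peaks_f = peak_caller(sub)
        rec = _peakset_overlap_bp(peaks_f, full_peaks) / full_peaks.total_length
        curve.append((round(f, 10), rec))
    return curve


def _per_peak_counts(ends: EndSet, peaks: PeakSet) -> np.ndarray:
    """Assigned-end count per merged peak (centre containment)."""
    counts = np.zeros(len(peaks), dtype=np.int64)
    if len(peaks) == 0 or ends.e_total == 0:
        return counts
    offsets: Dict[str, int] = {}
    per_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    run_chrom, run_start = None, 0
    for i, p in enumerate(peaks.peaks):
        if p.chrom != run_chrom:
            run_chrom, run_start = p.chrom, i
            offsets[p.chrom] = i
    for chrom, (starts, ends_, _) in peaks.index.items():
        per_chrom[chrom] = (starts, ends_)
    chrom_arr = ends.chroms.astype(str)
    for chrom in set(chrom_arr.tolist()):
        entry = per_chrom.get(chrom)
        if entry is None:
            continue
        starts, ends_ = entry
        pts = ends.centers[chrom_arr == chrom]
        member = _intervals.interval_member_index(starts, ends_, pts)
        hit = member[member >= 0]
        if len(hit):
            local = np.bincount(hit, minlength=len(starts))
            counts[offsets[chrom]:offsets[chrom] + len(starts)] += local
    return counts


def signal_ranking(ends: EndSet, peaks: PeakSet, promoters: Sequence[Interval],
                   n_quantiles: int = 10) -> List[float]:
    """Fraction of promoter peaks per signal quantile (descending signal).

    Signal is assigned-end count per peak kb, so the ranking does not
    depend on any caller's score.  Bin sizes differ by at most one, the
    remainder going to the top bins.
    """
    n = len(peaks)
    if n < n_quantiles:
        raise ValueError(f"{n} peaks < {n_quantiles} quantiles; "
                         "use a smaller n_quantiles")
    counts = _per_peak_counts(ends, peaks)
    lengths = np.asarray([p.length for p in peaks.peaks], dtype=float)
    signal = counts / (lengths / 1000.0)
    order = np.lexsort((np.arange(n), -signal))  # descending, stable
    is_prom = np.zeros(n, dtype=bool)
    if promoters:
        prom_index = _intervals.build_index(
            _intervals.merge_triples((p.chrom, p.start, p.end) for p in promoters))
        chroms = np.asarray([p.chrom for p in peaks.peaks], dtype=object)
        starts = np.asarray([p.start for p in peaks.peaks])
        ends_ = np.asarray([p.end for p in peaks.peaks])
        is_prom = _intervals.union_overlap(prom_index, chroms, starts, ends_) >= 1
    base, rem = divmod(n, n_quantiles)
    fractions: List[float] = []
    pos = 0
    for b in range(n_quantiles):
        size = base + (1 if b < rem else 0)
        members = order[pos:pos + size]
        fractions.append(float(is_prom[members].mean()))
        pos += size
    return fractions


def promoter_peak_fraction(peaks: PeakSet, promoters: Sequence[Interval]) -> float:
    """Fraction of peaks with >= 1 bp promoter overlap."""
    if len(peaks) == 0:
        raise MetricUndefinedError("promoter peak fraction undefined: no peaks")
    if not promoters:
        return 0.0
    prom_index = _intervals.build_index(
        _intervals.merge_triples((p.chrom, p.start, p.end) for p in promoters))
    chroms = np.asarray([p.chrom for p in peaks.peaks], dtype=object)
    starts = np.asarray([p.start for p in peaks.peaks])
    ends_ = np.asarray([p.end for p in peaks.peaks])
    overlap = _intervals.union_overlap(prom_index, chroms, starts, ends_)
    return float((overlap >= 1).mean())


def validate_peaks(peaks: PeakSet, reference: PeakSet) -> ValidationResult:
    """Validate peaks against a reference open-chromatin set (e.g. DHSs).

    A peak is validated by >= 1 bp of reference overlap; unvalidated
    peaks give an FDR-like rate, and reference elements missed by every
    peak give an FNR-like rate.
    """
    if len(peaks) == 0:
        raise MetricUndefinedError("validation undefined: empty peak set")
    if len(reference) == 0:
        raise MetricUndefinedError("validation undefined: empty reference set")
    chroms = np.asarray([p.chrom for p in peaks.peaks], dtype=object)
    starts = np.asarray([p.start for p in peaks.peaks])
    ends_ = np.asarray([p.end for p in peaks.peaks])
    validated = _intervals.union_overlap(reference.index, chroms, starts, ends_) >= 1
    n_validated = int(validated.sum())
    n_unvalidated = len(peaks) - n_validated
    r_chroms = np.asarray([p.chrom for p in reference.peaks], dtype=object)
    r_starts = np.asarray([p.start for p in reference.peaks])
    r_ends = np.asarray([p.end for p in reference.peaks])
    found = _intervals.union_overlap(peaks.index, r_chroms, r_starts, r_ends) >= 1
    n_missed = len(reference) - int(found.sum())
    return ValidationResult(
        n_peaks=len(peaks), n_reference=len(reference),
        n_validated=n_validated, n_unvalidated=n_unvalidated,
        fdr_like=n_unvalidated / len(peaks),
        n_missed=n_missed, fnr_like=n_missed / len(reference))


def grade_metrics(values: Mapping[str, float],
                  table: ReferenceTable) -> Dict[str, str]:
    """Grade metrics against a reference table (Good = Mean; Acceptable = Mean - SD).

    For a higher-better metric m: good if m >= mean, acceptable if
    mean - sd <= m < mean, else fail.  Lower-better metrics mirror this
    (good if m <= mean, acceptable up to mean + sd).  Metrics absent
    from the table are flagged ``ungraded``.
    """
    grades: Dict[str, str] = {}
    for metric, value in values.items():
        entry = table.entries.get(metric)
        if entry is None or value is None:
            grades[metric] = "ungraded"
            continue
        mean, sd, direction = entry
        if direction == "higher-better":
            if value >= mean:
                grades[metric] = "good"
            elif value >= mean - sd:
                grades[metric] = "acceptable"
            else:
                grades[metric] = "fail"
        else:
            if value <= mean:
                grades[metric] = "good"
            elif value <= mean + sd:
                grades[metric] = "acceptable"
            else:
                grades[metric] = "fail"
    return grades
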