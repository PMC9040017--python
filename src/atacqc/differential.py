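"""Dual-mode per-peak counting and differential accessibility calling.

Counting assigns each useful end to at most one merged peak by point
containment (the insertion centre in pseudo-SE mode, the fragment
midpoint in noShift mode), so pseudo-SE counts two events per read
pair and noShift counts one.  The bundled significance test is an exact
conditional binomial (Poisson rate) test on summed counts with
library-size exposures — an explicit stand-in for a negative-binomial
model such as DESeq2, which can be injected through the pluggable test
interface.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _intervals
from .formats_io import ChromSizes, Interval
from .qc_metrics import PeakSet
from .read_processing import EndSet

DEFAULT_PADJ_MAX = 0.01
DEFAULT_MIN_ABS_LOG2FC = 1.0
DEFAULT_NORMALIZE_TO = 10_000_000
PROXIMAL_MAX = 2_000
DISTAL_MAX = 20_000


@dataclass
class CountMatrix:
    """Peaks x samples integer counts, tagged with the counting mode."""

    counts: pd.DataFrame  # index: "chrom:start-end", columns: sample names
    mode: str
    library_sizes: Dict[str, int]


@dataclass
class DARResult:
    peak_id: str
    log2fc: float    # group2 over group1, pseudo-count 1 on normalized means
    pvalue: float
    padj: float
    direction: str = "ns"


def peak_id(peak: Interval) -> str:
    return f"{peak.chrom}:{peak.start}-{peak.end}"


def count_matrix(peaks: PeakSet, samples: Mapping[str, EndSet],
                 mode: str) -> CountMatrix:
    """Count assigned ends per merged peak for every sample.

    Each end lands in at most one peak (peaks are merged and disjoint),
    so column sums never exceed library sizes.
    """
    ids = [peak_id(p) for p in peaks.peaks]
    data: Dict[str, np.ndarray] = {}
    library_sizes: Dict[str, int] = {}
    from .qc_metrics import _per_peak_counts
    for name, ends in samples.items():
        if ends.mode != mode:
            raise ValueError(f"sample {name!r} has mode {ends.mode!r}, "
                             f"requested {mode!r}")
        data[name] = _per_peak_counts(ends, peaks)
        library_sizes[name] = ends.e_total
    frame = pd.DataFrame(data, index=ids, dtype=np.int64)
    return CountMatrix(counts=frame, mode=mode, library_sizes=library_sizes)


def poisson_rate_test(c1: np.ndarray, c2: np.ndarray,
                      exposure1: float, exposure2: float) -> np.ndarray:
    """Exact conditional test of equal Poisson rates, two-sided.

    Conditional on c1 + c2, c1 ~ Binomial(c1 + c2, exposure1 / total);
    the two-sided p-value doubles the smaller tail (capped at 1).
    """
    c1 = np.asarray(c1, dtype=np.int64)
    c2 = np.asarray(c2, dtype=np.int64)
    n = c1 + c2
    r = exposure1 / (exposure1 + exposure2)
    lower = stats.binom.cdf(c1, n, r)
    upper = stats.binom.sf(c1 - 1, n, r)
    p = 2 * np.minimum(lower, upper)
    p = np.where(n == 0, 1.0, p)
    return np.minimum(p, 1.0)


TestFunc = Callable[[np.ndarray, np.ndarray, float, float], np.ndarray]


def differential_test(matrix: CountMatrix, design: Mapping[str, str],
                      test: Optional[TestFunc] = None,
                      pvalues: Optional[np.ndarray] = None,
                      normalize_to: int = DEFAULT_NORMALIZE_TO) -> List[DARResult]:
    """Per-peak two-group comparison with BH correction.

    Counts are normalized to counts-per-10-million by library size;
    log2FC uses a pseudo-count of 1 on the normalized group means
    (group2 over group1, groups ordered alphabetically).  P-values come
    from the pluggable ``test`` (default: exact Poisson rate test on
    summed raw counts with library-size exposures) or may be supplied
    directly via ``pvalues``.
    """
    groups = sorted(set(design.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if matrix.counts.empty:
        raise ValueError("empty count matrix")
    missing = [s for s in design if s not in matrix.counts.columns]
    if missing:
        raise ValueError(f"design samples missing from matrix: {missing}")
    g1 = [s for s, g in design.items() if g == groups[0]]
    g2 = [s for s, g in design.items() if g == groups[1]]
    if not g1 or not g2:
        raise ValueError("each group needs >= 1 sample")
    libs = matrix.library_sizes
    norm = matrix.counts.astype(float).copy()
    for s in design:
        norm[s] = norm[s] * (normalize_to / libs[s])
    mean1 = norm[g1].mean(axis=1).to_numpy()
    mean2 = norm[g2].mean(axis=1).to_numpy()
    log2fc = np.log2((mean2 + 1.0) / (mean1 + 1.0))
    if pvalues is not None:
        pv = np.asarray(pvalues, dtype=float)
        if len(pv) != len(matrix.counts):
            raise ValueError("pvalues length does not match peak count")
    else:
        c1 = matrix.counts[g1].sum(axis=1).to_numpy()
        c2 = matrix.counts[g2].sum(axis=1).to_numpy()
        t1 = float(sum(libs[s] for s in g1))
        t2 = float(sum(libs[s] for s in g2))
        fn = test if test is not None else poisson_rate_test
        pv = np.asarray(fn(c1, c2, t1, t2), dtype=float)
    _, padj, _, _ = multipletests(pv, method="fdr_bh")
    return [DARResult(pid, float(fc), float(p), float(q))
            for pid, fc, p, q in zip(matrix.counts.index, log2fc, pv, padj)]


def call_dars(results: Sequence[DARResult],
              padj_max: float = DEFAULT_PADJ_MAX,
              min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC
              ) -> Dict[str, List[DARResult]]:
    """Split results by strict thresholds: padj < padj_max and |log2FC| > min.

    ``group1`` holds peaks more accessible in group1 (negative log2FC),
    ``group2`` the mirror set, ``ns`` everything else.  The three sets
    partition the input.
    """
    out: Dict[str, List[DARResult]] = {"group1": [], "group2": [], "ns": []}
    for r in results:
        if r.padj < padj_max and abs(r.log2fc) > min_abs_log2fc:
            if r.log2fc < 0:
                r.direction = "group1-specific"
                out["group1"].append(r)
            else:
                r.direction = "group2-specific"
                out["group2"].append(r)
        else:
            r.direction = "ns"
            out["ns"].append(r)
    return out


def _parse_peak_id(pid: str) -> Tuple[str, int, int]:
    chrom, span = pid.rsplit(":", 1)
    s, e = span.split("-")
    return chrom, int(s), int(e)


def annotate_distribution(dars: Sequence[DARResult],
                          annotation: Mapping[str, Sequence[Interval]]
                          ) -> Dict[str, float]:
    """Fraction of DARs per genomic category by midpoint containment.

    Precedence: promoter > exon > intron > intergenic; the fractions
    partition the input (sum to 1 for non-empty input).
    """
    categories = ["promoter", "exon", "intron"]
    indices = {}
    for cat in categories:
        ivs = annotation.get(cat, [])
        indices[cat] = _intervals.build_index(
            _intervals.merge_triples((p.chrom, p.start, p.end) for p in ivs)) \
            if ivs else {}
    tallies = {cat: 0 for cat in categories + ["intergenic"]}
    for r in dars:
        chrom, s, e = _parse_peak_id(r.peak_id)
        mid = np.asarray([(s + e) // 2])
        carr = np.asarray([chrom], dtype=object)
        for cat in categories:
            if indices[cat] and bool(
                    _intervals.points_in_union(indices[cat], carr, mid)[0]):
                tallies[cat] += 1
                break
        else:
            tallies["intergenic"] += 1
    n = len(dars)
    return {cat: (count / n if n else 0.0) for cat, count in tallies.items()}


def assign_nearest_gene(dars: Sequence[DARResult], tss: Sequence[Interval]
                        ) -> Dict[str, Tuple[Optional[str], Optional[int], str]]:
    """Nearest-TSS assignment: proximal <= 2 kb, distal (2 kb, 20 kb].

    TSS records are points (interval start); distance is measured from
    the DAR midpoint.  DARs beyond 20 kb of any TSS, or on chromosomes
    without one, are ``unassigned``.
    """
    if not tss:
        raise ValueError("no TSS records supplied")
    by_chrom: Dict[str, Tuple[np.ndarray, List[Optional[str]]]] = {}
    tmp: Dict[str, List[Tuple[int, Optional[str]]]] = {}
    for rec in tss:
        tmp.setdefault(rec.chrom, []).append((rec.start, rec.name))
    for chrom, entries in tmp.items():
        entries.sort()
        by_chrom[chrom] = (np.asarray([p for p, _ in entries]),
                           [n for _, n in entries])
    out: Dict[str, Tuple[Optional[str], Optional[int], str]] = {}
    for r in dars:
        chrom, s, e = _parse_peak_id(r.peak_id)
        mid = (s + e) // 2
        entry = by_chrom.get(chrom)
        if entry is None:
            out[r.peak_id] = (None, None, "unassigned")
            continue
        positions, names = entry
        j = int(np.searchsorted(positions, mid))
        candidates = [k for k in (j - 1, j) if 0 <= k < len(positions)]
        best = min(candidates, key=lambda k: abs(int(positions[k]) - mid))
        dist = abs(int(positions[best]) - mid)
        if dist <= PROXIMAL_MAX:
            klass = "proximal"
        elif dist <= DISTAL_MAX:
            klass = "distal"
        else:
            klass = "unassigned"
        out[r.peak_id] = (names[best], dist, klass)
    return out


def write_dar_bed(dars: Sequence[DARResult], path: str) -> None:
    """BED6 with peak ID + log2FC in the name field."""
    with open(path, "w") as fh:
        for r in dars:
            chrom, s, e = _parse_peak_id(r.peak_id)
            fh.write(f"{chrom}\t{s}\t{e}\t{r.peak_id}|log2fc={r.log2fc:.4f}"
                     f"\t0\t.\n")


def read_design_table(path: str) -> Dict[str, str]:
    """Two-column (sample, group) TSV."""
    design: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>group'")
            design[fields[0]] = fields[1]
    return design
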