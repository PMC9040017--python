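"""Normalized signal tracks, a Poisson-tile peak caller and meta-profiles.

The bundled caller is a deliberately simple, deterministic stand-in for
a full model-based caller: it tiles the genome in fixed windows, scores
each window against a genome-wide Poisson rate and keeps windows that
survive Benjamini-Hochberg at the q-value cutoff.  It exists so the
saturation/SubEn machinery and the test-suite can run end-to-end with no
external caller; real analyses can supply MACS2 peaks as BED instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import ChromSizes, Interval
from .qc_metrics import PeakSet, merge_peaks
from .read_processing import EndSet, InsertionSite

DEFAULT_NORMALIZE_TO = 10_000_000
DEFAULT_CALLER_WINDOW = 150
DEFAULT_CALLER_Q = 0.01


@dataclass
class Track:
    """Run-length encoded per-bp signal: chrom -> (starts, ends, values).

    Within a chromosome the spans are sorted and disjoint; values are
    reads-per-10-million after normalization.
    """

    data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]
    normalization_factor: float = 1.0
    units: str = "reads-per-10-million"

    def total_signal(self) -> float:
        """Sum over the genome of value * span width."""
        return float(sum(((e - s) * v).sum() for s, e, v in self.data.values()))

    def spans(self) -> Iterable[Tuple[str, int, int, float]]:
        for chrom in sorted(self.data):
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts.tolist(), ends.tolist(), values.tolist()):
                yield chrom, s, e, v

    def integral(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Cumulative signal in [0, x) for each position x (vectorised)."""
        entry = self.data.get(chrom)
        out = np.zeros(len(positions), dtype=float)
        if entry is None:
            return out
        starts, ends, values = entry
        seg = values * (ends - starts)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        j = np.searchsorted(starts, positions, side="right")
        out = cum[j].copy()
        has_prev = j > 0
        jp = np.clip(j - 1, 0, None)
        overhang = np.maximum(ends[jp] - positions, 0)
        inside = np.minimum(overhang, ends[jp] - starts[jp])
        out -= np.where(has_prev, inside * values[jp], 0.0)
        return out


@dataclass
class PeakCall:
    """One called peak with a -log10 q-value score and a summit offset."""

    chrom: str
    start: int
    end: int
    score: float
    summit_offset: int

    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end,
                        name=None, score=self.score)


def _rle_from_events(starts: np.ndarray, ends: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pileup depth of [start, end) events, run-length encoded, zero runs dropped."""
    pos = np.concatenate([starts, ends])
    delta = np.concatenate([np.ones(len(starts)), -np.ones(len(ends))])
    uniq, inv = np.unique(pos, return_inverse=True)
    net = np.zeros(len(uniq))
    np.add.at(net, inv, delta)
    depth = np.cumsum(net)[:-1]
    seg_starts, seg_ends = uniq[:-1], uniq[1:]
    keep = depth > 0
    return seg_starts[keep], seg_ends[keep], depth[keep]


def coverage_track(ends: EndSet, sizes: ChromSizes,
                   normalize_to: int = DEFAULT_NORMALIZE_TO) -> Track:
    """Fragment pileup scaled to ``normalize_to`` total reads."""
    if ends.e_total == 0:
        raise ValueError("coverage track undefined: no useful ends")
    factor = normalize_to / ends.e_total
    data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    chrom_arr = ends.chroms.astype(str)
    for chrom in sorted(set(chrom_arr.tolist())):
        mask = chrom_arr == chrom
        s, e, depth = _rle_from_events(ends.starts[mask], ends.ends[mask])
        data[chrom] = (s, e, depth * factor)
    return Track(data=data, normalization_factor=factor)


def insertion_track(sites: Sequence[InsertionSite], sizes: ChromSizes) -> Track:
    """Per-bp count of Tn5 insertion centres."""
    data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    by_chrom: Dict[str, List[int]] = {}
    for site in sites:
        by_chrom.setdefault(site.chrom, []).append(site.pos)
    for chrom in sorted(by_chrom):
        pos, counts = np.unique(np.asarray(by_chrom[chrom], dtype=np.int64),
                                return_counts=True)
        data[chrom] = (pos, pos + 1, counts.astype(float))
    return Track(data=data, normalization_factor=1.0, units="insertions")


def naive_call_peaks(ends: EndSet, sizes: ChromSizes,
                     window: int = DEFAULT_CALLER_WINDOW,
                     q_cutoff: float = DEFAULT_CALLER_Q) -> List[PeakCall]:
    """Poisson-tile peak calling with BH correction.

    Non-overlapping ``window``-bp tiles are scored by the count of
    insertion centres against a genome-wide rate lambda =
    e_total * window / genome_length; tiles with BH q <= q_cutoff merge
    into peaks when adjacent.  Fully deterministic.
    """
    if ends.e_total == 0:
        return []
    chrom_names: List[str] = []
    tile_counts: List[np.ndarray] = []
    chrom_arr = ends.chroms.astype(str)
    chrom_lengths = (sizes.sizes if ends.include_mito else sizes.non_mito())
    for chrom, length in chrom_lengths.items():
        n_tiles = -(-length // window)  # ceil
        mask = chrom_arr == chrom
        counts = np.zeros(n_tiles, dtype=np.int64)
        if mask.any():
            tiles = ends.centers[mask] // window
            counts = np.bincount(tiles, minlength=n_tiles)
        chrom_names.append(chrom)
        tile_counts.append(counts)
    genome = sizes.effective_length(ends.include_mito)
    lam = ends.e_total * window / genome
    all_counts = np.concatenate(tile_counts)
    pvals = stats.poisson.sf(all_counts - 1, lam)  # P(X >= count)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    calls: List[PeakCall] = []
    offset = 0
    for chrom, counts in zip(chrom_names, tile_counts):
        n_tiles = len(counts)
        sig = qvals[offset:offset + n_tiles] <= q_cutoff
        qs = qvals[offset:offset + n_tiles]
        offset += n_tiles
        idx = np.flatnonzero(sig)
        if len(idx) == 0:
            continue
        length = chrom_lengths[chrom]
        run_start = idx[0]
        prev = idx[0]
        runs: List[Tuple[int, int]] = []
        for t in idx[1:]:
            if t == prev + 1:
                prev = t
            else:
                runs.append((run_start, prev))
                run_start = prev = t
        runs.append((run_start, prev))
        for t0, t1 in runs:
            start = t0 * window
            end = min((t1 + 1) * window, length)
            tile_slice = slice(t0, t1 + 1)
            best_q = max(float(qs[tile_slice].min()), 1e-300)
            peak_counts = counts[tile_slice]
            best_tile = t0 + int(np.argmax(peak_counts))
            summit = min(best_tile * window + window // 2, end - 1) - start
            calls.append(PeakCall(chrom, int(start), int(end),
                                  score=-np.log10(best_q),
                                  summit_offset=int(summit)))
    return calls


def calls_to_peakset(calls: Sequence[PeakCall], source: str = "naive-caller") -> PeakSet:
    """Merge PeakCalls into a PeakSet for the QC metrics."""
    return merge_peaks([c.interval() for c in calls], source=source)


def write_peak_bed(calls: Sequence[PeakCall], path: str) -> None:
    """BED6 peaks: name peak_N, score min(1000, int(10 * -log10 q))."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls, start=1):
            score = min(1000, int(10 * c.score))
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tpeak_{i}\t{score}\t.\n")


def aggregate_profile(regions: Sequence[Interval], track: Track,
                      span: int = 5000, bin: int = 100) -> np.ndarray:
    """Mean track signal in ``bin``-bp windows across +/- span of region centres.

    Output has 2*span/bin entries; positions off the chromosome
    contribute zero signal.  Order of regions does not matter.
    """
    if not regions:
        raise ValueError("aggregate profile undefined: no regions")
    if span % bin != 0:
        raise ValueError("span must be a multiple of bin")
    n_bins = 2 * span // bin
    total = np.zeros(n_bins, dtype=float)
    edges_rel = np.arange(-span, span + bin, bin)
    for region in regions:
        center = region.midpoint
        edges = np.maximum(center + edges_rel, 0)
        integ = track.integral(region.chrom, edges)
        total += np.diff(integ) / bin
    return total / len(regions)
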