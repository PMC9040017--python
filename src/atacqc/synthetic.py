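"""Seeded generator of ATAC-like synthetic libraries with known truth.

The generator emulates the structure the QC metrics respond to: a small
multi-chromosome genome with a planted open-chromatin peak landscape, a
tri-modal insert-size mixture (sub-nucleosomal / mono- / di-nucleosomal),
a configurable in-peak read probability, PCR duplicates, mitochondrial
contamination and a mapping-quality mixture.  It does not model sequence
content, GC bias or Tn5 sequence preference — fragments are placed, not
sequenced.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .formats_io import AlignedPair, ChromSizes, Interval
from .qc_metrics import PeakSet, merge_peaks
from .read_processing import MINUS_SHIFT, PLUS_SHIFT


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic library.

    Defaults describe a decent-quality ATAC-seq library at desk scale:
    a 1.8 Mb two-chromosome genome plus a 20 kb mitochondrion, 60 planted
    peaks of ~500 bp, 30% of read pairs inside peaks, 10% PCR duplicates
    and 5% chrM contamination.
    """

    chrom_sizes: Dict[str, int] = field(default_factory=lambda: {
        "chr1": 1_000_000, "chr2": 800_000, "chrM": 20_000})
    mito_name: str = "chrM"
    n_peaks: int = 60
    peak_width_mean: float = 500.0
    peak_width_sd: float = 100.0
    peak_width_min: int = 150
    promoter_fraction: float = 0.4
    p_peak: float = 0.30
    n_pairs: int = 20_000
    frag_weights: Tuple[float, float, float] = (0.45, 0.40, 0.15)
    frag_means: Tuple[float, float, float] = (70.0, 200.0, 400.0)
    frag_sds: Tuple[float, float, float] = (15.0, 40.0, 60.0)
    frag_min: int = 50
    duplicate_fraction: float = 0.10
    mito_fraction: float = 0.05
    low_mapq_fraction: float = 0.05
    mapq_high: int = 60
    read_length: int = 50
    n_unmapped: int = 0
    n_improper: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (("p_peak", self.p_peak),
                           ("duplicate_fraction", self.duplicate_fraction),
                           ("mito_fraction", self.mito_fraction),
                           ("low_mapq_fraction", self.low_mapq_fraction),
                           ("promoter_fraction", self.promoter_fraction)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if abs(sum(self.frag_weights) - 1.0) > 1e-9:
            raise ValueError("frag_weights must sum to 1")
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated library."""

    planted_peaks: PeakSet
    promoter_tss: List[Interval]
    realized_in_peak_fraction: float
    realized_duplicate_fraction: float
    realized_mito_fraction: float
    expected: Dict[str, float]


def simulate_genome(config: SimulationConfig,
                    ) -> Tuple[ChromSizes, PeakSet, List[Interval]]:
    """Plant non-overlapping peaks and promoter TSSs on a synthetic genome.

    Peaks are allocated to non-mito chromosomes in proportion to length
    and placed uniformly without overlap (margin kept clear of the
    chromosome ends so read pairs always fit).  A ``promoter_fraction``
    subset is flagged promoter-proximal; its TSSs sit at peak midpoints.
    Deterministic per seed.
    """
    rng = np.random.default_rng([config.seed, 101])
    sizes = ChromSizes(dict(config.chrom_sizes), mito_name=config.mito_name)
    non_mito = sizes.non_mito()
    total_len = sum(non_mito.values())
    margin = 1000
    alloc: Dict[str, int] = {}
    remaining = config.n_peaks
    chroms = list(non_mito)
    for i, chrom in enumerate(chroms):
        if i == len(chroms) - 1:
            alloc[chrom] = remaining
        else:
            k = round(config.n_peaks * non_mito[chrom] / total_len)
            k = min(k, remaining)
            alloc[chrom] = k
            remaining -= k
    peaks: List[Interval] = []
    for chrom, k in alloc.items():
        length = non_mito[chrom]
        widths = np.maximum(
            rng.normal(config.peak_width_mean, config.peak_width_sd, size=k),
            config.peak_width_min).astype(np.int64)
        if widths.sum() + 2 * margin > length:
            raise ValueError(f"cannot pack {widths.sum()} bp of peaks into "
                             f"{chrom} ({length} bp)")
        placed: List[Tuple[int, int]] = []
        for w in widths.tolist():
            for _ in range(1000):
                start = int(rng.integers(margin, length - margin - w))
                if all(start + w + 50 <= s or start >= e + 50 for s, e in placed):
                    placed.append((start, start + w))
                    break
            else:
                raise ValueError(f"failed to place a {w}-bp peak on {chrom}")
        placed.sort()
        peaks.extend(Interval(chrom, s, e) for s, e in placed)
    peakset = merge_peaks(peaks, source="planted")
    n_prom = round(config.promoter_fraction * len(peakset.peaks))
    prom_idx = rng.choice(len(peakset.peaks), size=n_prom, replace=False)
    tss = [Interval(p.chrom, p.midpoint, p.midpoint + 1, name=f"gene{i}")
           for i, p in enumerate(peakset.peaks) if i in set(prom_idx.tolist())]
    return sizes, peakset, tss


def _draw_fragment_sizes(rng: np.random.Generator, config: SimulationConfig,
                         n: int) -> np.ndarray:
    comp = rng.choice(len(config.frag_weights), size=n, p=config.frag_weights)
    means = np.asarray(config.frag_means)[comp]
    sds = np.asarray(config.frag_sds)[comp]
    sizes = rng.normal(means, sds)
    return np.maximum(sizes, config.frag_min).astype(np.int64)


def simulate_pairs(config: SimulationConfig, sizes: ChromSizes,
                   peaks: PeakSet) -> Tuple[List[AlignedPair], SimulationTruth]:
    """Draw aligned read pairs from the planted landscape.

    Each original (non-duplicate) pair is mitochondrial with probability
    ``mito_fraction``; otherwise, with probability ``p_peak`` both Tn5
    insertion centres fall inside one uniformly chosen planted peak, and
    with probability 1 - p_peak the pair is uniform background.
    Duplicates are exact coordinate copies of earlier pairs.
    """
    rng = np.random.default_rng([config.seed, 202])
    n_total = config.n_pairs
    n_dup = round(config.duplicate_fraction * n_total)
    n_orig = n_total - n_dup
    rl = config.read_length
    non_mito = sizes.non_mito()
    bg_chroms = list(non_mito)
    bg_weights = np.asarray([non_mito[c] for c in bg_chroms], dtype=float)
    bg_weights /= bg_weights.sum()
    frag = _draw_fragment_sizes(rng, config, n_orig)
    is_mito = rng.random(n_orig) < config.mito_fraction
    is_peak = (~is_mito) & (rng.random(n_orig) < config.p_peak)
    peak_choice = rng.integers(0, len(peaks.peaks), size=n_orig)
    bg_choice = rng.choice(len(bg_chroms), size=n_orig, p=bg_weights)
    uniforms = rng.random(n_orig)
    low_mapq = rng.random(n_orig) < config.low_mapq_fraction
    mapq_low_vals = rng.integers(0, 10, size=n_orig)

    originals: List[AlignedPair] = []
    n_in_peak = 0
    shift_span = PLUS_SHIFT + MINUS_SHIFT  # insert = site span + 9
    for i in range(n_orig):
        f = int(frag[i])
        if is_mito[i]:
            chrom = sizes.mito_name
            length = sizes[chrom]
            f = min(f, length)
            start_plus = int(uniforms[i] * (length - f + 1))
        elif is_peak[i]:
            p = peaks.peaks[int(peak_choice[i])]
            chrom = p.chrom
            span = f - shift_span  # distance between the two insertion sites
            max_site = p.end - 1 - span
            if max_site < p.start:
                span = p.length - 1
                f = span + shift_span
                max_site = p.start
            site = p.start + int(uniforms[i] * (max_site - p.start + 1))
            start_plus = site - PLUS_SHIFT
            n_in_peak += 1
        else:
            chrom = bg_chroms[int(bg_choice[i])]
            length = non_mito[chrom]
            f = min(f, length)
            start_plus = int(uniforms[i] * (length - f + 1))
        end_minus = start_plus + f
        mapq = int(mapq_low_vals[i]) if low_mapq[i] else config.mapq_high
        originals.append(AlignedPair(
            chrom=chrom, start_plus=start_plus, end_plus=start_plus + rl,
            start_minus=end_minus - rl, end_minus=end_minus, mapq=mapq))
    dup_src = rng.integers(0, n_orig, size=n_dup)
    pairs = originals + [originals[int(j)] for j in dup_src]
    order = rng.permutation(len(pairs))
    pairs = [pairs[int(j)] for j in order]

    n_unique = len({p.key() for p in pairs})
    n_non_mito = int((~is_mito).sum())
    truth = SimulationTruth(
        planted_peaks=peaks,
        promoter_tss=[],
        realized_in_peak_fraction=(n_in_peak / n_non_mito if n_non_mito else 0.0),
        realized_duplicate_fraction=1.0 - n_unique / len(pairs),
        realized_mito_fraction=float(is_mito.mean()),
        expected=expected_metrics(config, sizes, peaks),
    )
    return pairs, truth


def expected_metrics(config: SimulationConfig, sizes: ChromSizes,
                     peaks: PeakSet,
                     promoter_peak_length: Optional[int] = None,
                     promoter_peak_count: Optional[int] = None
                     ) -> Dict[str, float]:
    """Closed-form metric expectations under the configured conditions.

    * RUPr ~= p_peak + (1 - p_peak) * q, with q the chance a uniform
      150-bp pseudo-SE fragment meets the 50% rule: q = sum(w_i + 1)/L
      for peaks of width w_i >= 75 (the qualifying-centre measure of a
      width-w peak is w + 1 positions).
    * Background = Poisson upper tail beyond the count that pushes a
      500-bp region's RPKM over 0.377, at the uniform background rate.
    * ProEn ~= p_peak * f_pp * L / L_pp + (1 - p_peak), where f_pp is
      the fraction of peaks that are promoter peaks.
    """
    from scipy import stats
    l_eff = sizes.effective_length(False)
    q = sum(p.length + 1 for p in peaks.peaks if p.length >= 75) / l_eff
    p = config.p_peak
    expected_rupr = p + (1 - p) * q

    # Background: E_total ~= 2 * unique non-mito pairs (pseudo-SE mode)
    n_unique = round(config.n_pairs * (1 - config.duplicate_fraction))
    e_total = 2 * round(n_unique * (1 - config.mito_fraction))
    width = 500
    bg_density = (1 - p) * e_total / l_eff  # ends per bp outside peaks
    lam = bg_density * width
    k_threshold = 0.377 * (width / 1000.0) * (e_total / 1e6)
    k_star = int(np.floor(k_threshold)) + 1  # smallest count with RPKM > 0.377
    expected_background = float(stats.poisson.sf(k_star - 1, lam))

    expected = {
        "rupr": float(expected_rupr),
        "background": expected_background,
        "rupr_tolerance": 5.0 * float(np.sqrt(
            expected_rupr * (1 - expected_rupr) / max(e_total, 1))) + q,
    }
    if promoter_peak_length and promoter_peak_count is not None and len(peaks):
        f_pp = promoter_peak_count / len(peaks.peaks)
        expected["proen"] = float(
            p * f_pp * l_eff / promoter_peak_length + (1 - p))
    return expected


def write_sam(pairs: Sequence[AlignedPair], sizes: ChromSizes, path: str,
              config: Optional[SimulationConfig] = None,
              read_length: int = 50) -> None:
    """Write pairs as a coordinate-agnostic SAM file (plain text).

    Optionally appends ``config.n_unmapped`` unmapped and
    ``config.n_improper`` cross-chromosome record pairs so parsers'
    tally bookkeeping can be exercised.
    """
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": name, "LN": length}
                     for name, length in sizes.sizes.items()]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        hdr = out.header
        for i, pair in enumerate(pairs):
            qname = f"pair{i:08d}"
            rl_plus = pair.end_plus - pair.start_plus
            rl_minus = pair.end_minus - pair.start_minus
            a = pysam.AlignedSegment(hdr)
            a.query_name = qname
            a.flag = 0x1 | 0x2 | 0x40 | 0x20  # paired, proper, read1, mate rev
            a.reference_name = pair.chrom
            a.reference_start = pair.start_plus
            a.mapping_quality = pair.mapq
            a.cigarstring = f"{rl_plus}M"
            a.query_sequence = "A" * rl_plus
            a.next_reference_name = pair.chrom
            a.next_reference_start = pair.start_minus
            a.template_length = pair.insert_size
            b = pysam.AlignedSegment(hdr)
            b.query_name = qname
            b.flag = 0x1 | 0x2 | 0x80 | 0x10  # paired, proper, read2, reverse
            b.reference_name = pair.chrom
            b.reference_start = pair.start_minus
            b.mapping_quality = pair.mapq
            b.cigarstring = f"{rl_minus}M"
            b.query_sequence = "A" * rl_minus
            b.next_reference_name = pair.chrom
            b.next_reference_start = pair.start_plus
            b.template_length = -pair.insert_size
            out.write(a)
            out.write(b)
        n_unmapped = config.n_unmapped if config else 0
        n_improper = config.n_improper if config else 0
        first_chrom = next(iter(sizes.sizes))
        chrom_list = list(sizes.sizes)
        for i in range(n_unmapped):
            a = pysam.AlignedSegment(hdr)
            a.query_name = f"unmapped{i:06d}"
            a.flag = 0x1 | 0x4 | 0x8 | 0x40  # both mates unmapped
            a.query_sequence = "A" * read_length
            b = pysam.AlignedSegment(hdr)
            b.query_name = f"unmapped{i:06d}"
            b.flag = 0x1 | 0x4 | 0x8 | 0x80
            b.query_sequence = "A" * read_length
            out.write(a)
            out.write(b)
        for i in range(n_improper):
            c2 = chrom_list[1] if len(chrom_list) > 1 else first_chrom
            a = pysam.AlignedSegment(hdr)
            a.query_name = f"improper{i:06d}"
            a.flag = 0x1 | 0x40 | 0x20
            a.reference_name = first_chrom
            a.reference_start = 100 + i
            a.mapping_quality = 60
            a.cigarstring = f"{read_length}M"
            a.query_sequence = "A" * read_length
            a.next_reference_name = c2
            a.next_reference_start = 100 + i
            b = pysam.AlignedSegment(hdr)
            b.query_name = f"improper{i:06d}"
            b.flag = 0x1 | 0x80 | 0x10
            b.reference_name = c2
            b.reference_start = 100 + i
            b.mapping_quality = 60
            b.cigarstring = f"{read_length}M"
            b.query_sequence = "A" * read_length
            b.next_reference_name = first_chrom
            b.next_reference_start = 100 + i
            out.write(a)
            out.write(b)


def write_chrom_sizes(sizes: ChromSizes, path: str) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.sizes.items():
            fh.write(f"{name}\t{length}\n")
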