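"""Tn5 insertion-site transforms and alignment-level QC.

ATAC-seq reads start 9 bp outside the actual transposition centre, so
each mate is shifted +4 bp (plus strand) / -5 bp (minus strand) onto the
insertion point.  From the two insertion sites of a pair this module
derives either two 150-bp pseudo single-end fragments (PE-asSE mode,
doubling the usable event count) or one fragment spanning the whole
insert (PE-noShift mode).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .formats_io import AlignedPair, ChromSizes, Interval

PLUS_SHIFT = 4     # bp added to the plus-strand 5' end
MINUS_SHIFT = 5    # bp subtracted from the minus-strand 3' end
DEFAULT_EXT = 75   # bp extension either side of an insertion site
DEFAULT_MAPQ_MIN = 10

MODE_PSEUDO_SE = "pseudoSE"
MODE_NOSHIFT = "noShift"


@dataclass(frozen=True)
class InsertionSite:
    """A single Tn5 insertion centre."""

    chrom: str
    pos: int
    source_strand: str  # strand of the mate the site came from


@dataclass
class Fragment:
    """A useful-end interval in one of the two processing modes.

    ``center`` is the event's assignment point: the insertion site for a
    pseudo-SE fragment (midpoint of the unclipped 150-bp window) or the
    fragment midpoint in noShift mode.
    """

    chrom: str
    start: int
    end: int
    mode: str
    center: int
    strand: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class EndSet:
    """Column-oriented container of useful ends (one mode only).

    Arrays are aligned: ``chroms[i]``, ``starts[i]``, ``ends[i]``,
    ``centers[i]``, ``strands[i]`` describe fragment i.  ``e_total`` is
    the denominator of every ratio metric.
    """

    mode: str
    sizes: ChromSizes
    include_mito: bool
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    centers: np.ndarray
    strands: np.ndarray

    @property
    def e_total(self) -> int:
        return len(self.starts)

    @classmethod
    def from_fragments(cls, fragments: Sequence[Fragment], mode: str,
                       sizes: ChromSizes, include_mito: bool = False) -> "EndSet":
        return cls(
            mode=mode, sizes=sizes, include_mito=include_mito,
            chroms=np.asarray([f.chrom for f in fragments], dtype=object),
            starts=np.asarray([f.start for f in fragments], dtype=np.int64),
            ends=np.asarray([f.end for f in fragments], dtype=np.int64),
            centers=np.asarray([f.center for f in fragments], dtype=np.int64),
            strands=np.asarray([f.strand for f in fragments], dtype=object),
        )

    def subset(self, idx: np.ndarray) -> "EndSet":
        return EndSet(self.mode, self.sizes, self.include_mito,
                      self.chroms[idx], self.starts[idx], self.ends[idx],
                      self.centers[idx], self.strands[idx])

    def canonical_order(self) -> "EndSet":
        """Sort by (chrom, center, start, end, strand); makes downstream
        seeded subsampling independent of input order."""
        order = np.lexsort((self.strands.astype(str), self.ends, self.starts,
                            self.centers, self.chroms.astype(str)))
        return self.subset(order)

    def fragments(self) -> List[Fragment]:
        return [Fragment(c, int(s), int(e), self.mode, int(m), str(t))
                for c, s, e, m, t in zip(self.chroms, self.starts, self.ends,
                                         self.centers, self.strands)]


@dataclass
class AlignmentQC:
    """Alignment-level QC numbers for one library."""

    n_unique_nonredundant: int
    duplication_rate: float
    per_chrom_counts: Dict[str, int]
    mito_rate: float
    insert_size_histogram: Dict[int, int]


def filter_pairs(pairs: Iterable[AlignedPair], mapq_min: int = DEFAULT_MAPQ_MIN,
                 tally=None) -> Tuple[List[AlignedPair], int]:
    """Keep pairs with mapq >= mapq_min (inclusive); return kept + filtered count."""
    kept: List[AlignedPair] = []
    n_filtered = 0
    for pair in pairs:
        if pair.mapq >= mapq_min:
            kept.append(pair)
        else:
            n_filtered += 1
    if tally is not None:
        tally.low_quality_pairs += n_filtered
        tally.yielded_pairs -= n_filtered
    return kept, n_filtered


def deduplicate(pairs: Sequence[AlignedPair]) -> Tuple[List[AlignedPair], float]:
    """Collapse pairs with identical mate coordinates; duplication rate = 1 - unique/total."""
    seen = set()
    unique: List[AlignedPair] = []
    for pair in pairs:
        k = pair.key()
        if k not in seen:
            seen.add(k)
            unique.append(pair)
    total = len(pairs)
    rate = 0.0 if total == 0 else 1.0 - len(unique) / total
    return unique, rate


def tn5_insertions(pair: AlignedPair) -> Tuple[InsertionSite, InsertionSite]:
    """The two Tn5 insertion centres of a pair (+4 / -5 shift).

    The minus-strand shift applies to the half-open end of the mate:
    ``end_minus - 5`` is 4 bp interior to the rightmost aligned base,
    symmetric with the plus side under the half-open convention.
    """
    plus = InsertionSite(pair.chrom, pair.start_plus + PLUS_SHIFT, "+")
    minus = InsertionSite(pair.chrom, pair.end_minus - MINUS_SHIFT, "-")
    return plus, minus


def pe_as_se(pair: AlignedPair, sizes: ChromSizes,
             ext: int = DEFAULT_EXT) -> Tuple[Fragment, Fragment]:
    """Two pseudo single-end fragments, ``[site - ext, site + ext)`` each.

    Fragments are clipped at chromosome bounds (keeping weight 1) so a
    pair always yields exactly two events.
    """
    length = sizes[pair.chrom]
    out = []
    for site in tn5_insertions(pair):
        start = max(0, site.pos - ext)
        end = min(length, site.pos + ext)
        out.append(Fragment(pair.chrom, start, end, MODE_PSEUDO_SE,
                            center=site.pos, strand=site.source_strand))
    return out[0], out[1]


def pe_noshift(pair: AlignedPair) -> Fragment:
    """One fragment spanning the two shifted insertion positions.

    Coincident insertions give a length-1 fragment rather than being
    dropped, conserving the pair count.
    """
    plus, minus = tn5_insertions(pair)
    lo, hi = min(plus.pos, minus.pos), max(plus.pos, minus.pos)
    start, end = lo, hi + 1
    return Fragment(pair.chrom, start, end, MODE_NOSHIFT,
                    center=(start + end) // 2, strand=".")


def useful_ends(pairs: Sequence[AlignedPair], mode: str, sizes: ChromSizes,
                include_mito: bool = False, ext: int = DEFAULT_EXT) -> EndSet:
    """All useful ends of a deduplicated pair stream in one mode.

    Mitochondrial fragments are dropped by default (chrM is treated as
    contamination and reported in AlignmentQC instead).
    """
    if mode not in (MODE_PSEUDO_SE, MODE_NOSHIFT):
        raise ValueError(f"unknown mode {mode!r}")
    fragments: List[Fragment] = []
    mito = sizes.mito_name
    for pair in pairs:
        if not include_mito and pair.chrom == mito:
            continue
        if mode == MODE_PSEUDO_SE:
            fragments.extend(pe_as_se(pair, sizes, ext=ext))
        else:
            fragments.append(pe_noshift(pair))
    return EndSet.from_fragments(fragments, mode, sizes, include_mito)


def alignment_qc(pairs: Sequence[AlignedPair], sizes: ChromSizes,
                 duplication_rate: float = 0.0) -> AlignmentQC:
    """Chromosome distribution, chrM contamination and insert-size histogram.

    Insert size is the outer span of the pair, ``end_minus - start_plus``.
    """
    per_chrom: Dict[str, int] = {}
    hist: Dict[int, int] = {}
    for pair in pairs:
        per_chrom[pair.chrom] = per_chrom.get(pair.chrom, 0) + 1
        size = pair.insert_size
        hist[size] = hist.get(size, 0) + 1
    total = sum(per_chrom.values())
    mito = per_chrom.get(sizes.mito_name, 0)
    mito_rate = 0.0 if total == 0 else mito / total
    return AlignmentQC(
        n_unique_nonredundant=len(pairs),
        duplication_rate=duplication_rate,
        per_chrom_counts=per_chrom,
        mito_rate=mito_rate,
        insert_size_histogram=dict(sorted(hist.items())),
    )
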