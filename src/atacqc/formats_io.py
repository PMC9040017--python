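"""Readers and writers for the genomic text formats the pipeline touches.

Every coordinate inside the package is 0-based half-open (the BED
convention).  SAM input, which is 1-based, is converted here at the
boundary and never leaks into the rest of the code.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam


class ParseError(ValueError):
    """Malformed input file (exit code 3 in the CLI)."""


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome-name -> length (bp) mapping for one assembly.

    The mitochondrial chromosome is carried by name (default ``chrM``) so
    the contamination metrics and the mito-exclusion rules know which
    sequence to treat as contamination.
    """

    sizes: Dict[str, int]
    mito_name: str = "chrM"

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if length <= 0:
                raise ParseError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def genome_length(self) -> int:
        return sum(self.sizes.values())

    def effective_length(self, include_mito: bool = False) -> int:
        """Genome length matching an EndSet's mito policy."""
        total = self.genome_length
        if not include_mito and self.mito_name in self.sizes:
            total -= self.sizes[self.mito_name]
        return total

    def non_mito(self) -> Dict[str, int]:
        return {c: l for c, l in self.sizes.items() if c != self.mito_name}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]


@dataclass
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class AlignedPair:
    """One properly paired, uniquely mapped read pair (FR orientation).

    The plus-strand mate spans ``[start_plus, end_plus)`` and the
    minus-strand mate ``[start_minus, end_minus)``; ``mapq`` is the
    minimum of the two mates' mapping qualities.
    """

    chrom: str
    start_plus: int
    end_plus: int
    start_minus: int
    end_minus: int
    mapq: int
    duplicate_flag: bool = False

    @property
    def insert_size(self) -> int:
        """Outer span of the pair (library insert length)."""
        return self.end_minus - self.start_plus

    def key(self) -> Tuple[str, int, int, int, int]:
        return (self.chrom, self.start_plus, self.end_plus,
                self.start_minus, self.end_minus)


@dataclass
class PairTally:
    """Record-level bookkeeping from alignment parsing.

    ``unmapped`` counts records belonging to a pair with >=1 unmapped
    mate; ``improper`` counts records of pairs failing same-chromosome or
    FR-orientation checks; ``orphan`` counts records whose mate never
    appeared.  ``low_quality_pairs`` is filled later by
    :func:`atacqc.read_processing.filter_pairs`.
    """

    total_records: int = 0
    yielded_pairs: int = 0
    unmapped: int = 0
    improper: int = 0
    orphan: int = 0
    low_quality_pairs: int = 0

    def partition_ok(self) -> bool:
        return self.total_records == (2 * self.yielded_pairs + self.unmapped
                                      + self.improper + self.orphan
                                      + 2 * self.low_quality_pairs)


def read_chrom_sizes(path: str, mito_name: str = "chrM") -> ChromSizes:
    """Parse a two-column (name, length) chrom.sizes file."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        n_lines = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            n_lines += 1
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: length {fields[1]!r} is not an integer")
            if length <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive length {length}")
            if name in sizes:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    if n_lines == 0:
        raise ParseError(f"{path}: empty chrom.sizes file")
    return ChromSizes(sizes=sizes, mito_name=mito_name)


def read_bed(path: str, sizes: Optional[ChromSizes] = None) -> List[Interval]:
    """Parse BED3+ into Intervals (file order preserved).

    If ``sizes`` is given, records on unknown chromosomes or out of
    bounds are rejected.
    """
    out: List[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates")
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start {start}")
            if sizes is not None:
                if chrom not in sizes:
                    raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > sizes[chrom]:
                    raise ParseError(f"{path}:{lineno}: end {end} beyond chromosome "
                                     f"length {sizes[chrom]}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric score {fields[4]!r}")
            strand = fields[5] if len(fields) > 5 and fields[5] != "." else None
            if strand not in (None, "+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            out.append(Interval(chrom, start, end, name=name, score=score, strand=strand))
    return out


def _pair_from_reads(fwd: pysam.AlignedSegment, rev: pysam.AlignedSegment) -> AlignedPair:
    return AlignedPair(
        chrom=fwd.reference_name,
        start_plus=fwd.reference_start,
        end_plus=fwd.reference_end,
        start_minus=rev.reference_start,
        end_minus=rev.reference_end,
        mapq=min(fwd.mapping_quality, rev.mapping_quality),
        duplicate_flag=bool(fwd.is_duplicate or rev.is_duplicate),
    )


def read_alignments(path: str, sizes: ChromSizes) -> Tuple[List[AlignedPair], PairTally]:
    """Extract properly paired FR read pairs from a SAM/BAM file.

    1-based SAM positions become 0-based half-open spans.  Pairs with an
    unmapped mate, cross-chromosome pairs and non-FR pairs are tallied
    and skipped; orphan records (mate never seen) are tallied too.
    """
    tally = PairTally()
    pairs: List[AlignedPair] = []
    pending: Dict[str, pysam.AlignedSegment] = {}
    try:
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for read in fh:
                if read.is_secondary or read.is_supplementary:
                    continue
                tally.total_records += 1
                if read.is_unmapped or read.mate_is_unmapped:
                    tally.unmapped += 1
                    continue
                mate = pending.pop(read.query_name, None)
                if mate is None:
                    pending[read.query_name] = read
                    continue
                a, b = mate, read
                if a.reference_name != b.reference_name or a.is_reverse == b.is_reverse:
                    tally.improper += 2
                    continue
                fwd, rev = (a, b) if not a.is_reverse else (b, a)
                if fwd.reference_name not in sizes:
                    raise ParseError(f"{path}: alignment on unknown chromosome "
                                     f"{fwd.reference_name!r}")
                if not (fwd.reference_start < rev.reference_end):
                    tally.improper += 2
                    continue
                pairs.append(_pair_from_reads(fwd, rev))
                tally.yielded_pairs += 1
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: failed to read alignments: {exc}") from exc
    tally.orphan = len(pending)
    return pairs, tally


def write_bed(intervals: Sequence[Interval], path: str) -> None:
    """Write Intervals as BED; column count is the max any record needs."""
    ncols = 3
    for iv in intervals:
        if iv.strand is not None:
            ncols = max(ncols, 6)
        elif iv.score is not None:
            ncols = max(ncols, 5)
        elif iv.name is not None:
            ncols = max(ncols, 4)
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if ncols >= 4:
                fields.append(iv.name if iv.name is not None else ".")
            if ncols >= 5:
                if iv.score is None:
                    fields.append(".")
                elif float(iv.score).is_integer():
                    fields.append(str(int(iv.score)))
                else:
                    fields.append(repr(float(iv.score)))
            if ncols >= 6:
                fields.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(fields) + "\n")


def write_bedgraph(spans: Iterable[Tuple[str, int, int, float]], path: str,
                   decimals: int = 4) -> None:
    """Write (chrom, start, end, value) spans as bedGraph.

    Spans must be sorted by (chrom, start) and non-overlapping within a
    chromosome; anything else raises.
    """
    last: Dict[str, int] = {}
    prev_chrom: Optional[str] = None
    with open(path, "w") as fh:
        for chrom, start, end, value in spans:
            if start >= end:
                raise ValueError(f"bedGraph span {chrom}:{start}-{end} is empty")
            if chrom in last and start < last[chrom]:
                raise ValueError(f"bedGraph spans unsorted or overlapping at "
                                 f"{chrom}:{start}")
            if prev_chrom is not None and chrom != prev_chrom and chrom in last:
                raise ValueError(f"bedGraph chromosome {chrom} split across blocks")
            last[chrom] = end
            prev_chrom = chrom
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.{decimals}f}\n")


def write_tsv_matrix(frame, path: str, index_label: str = "peak_id") -> None:
    """Write a peaks x samples DataFrame as TSV with peak IDs first."""
    frame.to_csv(path, sep="\t", index_label=index_label)
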