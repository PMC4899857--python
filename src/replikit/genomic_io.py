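"""Genomic interval / sequence data model with BED and FASTA round-trip I/O.

Coordinates are BED-style 0-based half-open everywhere.  Strand is carried
but ignored by all distance primitives; it matters only for motif scanning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "PeakRegion",
    "PeakSet",
    "GenomeSequence",
    "BedParseError",
    "RangeError",
    "DegenerateSequenceError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "gap_distance",
    "center",
    "gc_fraction",
]

_HEADER_PREFIXES = ("#", "track", "browser")


class BedParseError(ValueError):
    """Malformed BED line (bad columns, non-integer or inverted coordinates)."""


class RangeError(ValueError):
    """Interval falls outside its chromosome."""


class DegenerateSequenceError(ValueError):
    """Sequence has no informative (non-N) bases for the requested statistic."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise BedParseError(f"non-integer coordinates: {self.start}, {self.end}")
        if self.start < 0 or self.start >= self.end:
            raise BedParseError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise BedParseError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakRegion:
    """A scored interval as read from a peak-caller BED file."""

    interval: GenomicInterval
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise BedParseError(f"non-finite score on peak {self.name}")

    # convenience pass-throughs used heavily downstream
    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class PeakSet:
    """Ordered collection of peaks; may contain overlapping members."""

    peaks: List[PeakRegion] = field(default_factory=list)
    label: str = ""
    #: number of BED columns seen on input (3..6); used for faithful re-write
    columns: int = 5

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[PeakRegion]:
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    def sorted(self) -> "PeakSet":
        key = lambda p: (p.chrom, p.start, p.end)
        return PeakSet(sorted(self.peaks, key=key), label=self.label, columns=self.columns)

    def by_chrom(self) -> Dict[str, List[PeakRegion]]:
        out: Dict[str, List[PeakRegion]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out


class GenomeSequence:
    """Mapping chrom -> nucleotide string over {A, C, G, T, N}."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: Dict[str, str] = {c: str(s).upper() for c, s in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def chroms(self) -> List[str]:
        return list(self._seqs)

    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def items(self):
        return self._seqs.items()

    def fetch(self, interval: GenomicInterval) -> str:
        """Subsequence for an interval, with bounds checking."""
        try:
            seq = self._seqs[interval.chrom]
        except KeyError:
            raise RangeError(f"unknown chromosome {interval.chrom!r}") from None
        if interval.end > len(seq):
            raise RangeError(
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end]


def _parse_bed_line(line: str, lineno: int, score_col: int) -> tuple[PeakRegion, int]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise BedParseError(
            f"line {lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
        ) from None
    name = fields[3] if len(fields) > 3 else "."
    score = 0.0
    if len(fields) >= score_col:
        raw = fields[score_col - 1]
        if raw not in (".", ""):
            try:
                score = float(raw)
            except ValueError:
                raise BedParseError(f"line {lineno}: non-numeric score {raw!r}") from None
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
    try:
        iv = GenomicInterval(chrom, start, end, strand)
        peak = PeakRegion(iv, score=score, name=name)
    except BedParseError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from None
    return peak, min(len(fields), 6)


def read_bed(path: Union[str, Path], score_col: int = 5, label: str = "") -> PeakSet:
    """Read BED3/BED5/BED6 into a PeakSet.

    Parameters
    ----------
    path:
        Tab-separated BED file.  Lines starting with ``#``, ``track`` or
        ``browser`` are skipped.
    score_col:
        1-based column holding the peak score (default 5; some callers emit
        the score in column 7).
    """
    path = Path(path)
    peaks: List[PeakRegion] = []
    ncols = 3
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith(_HEADER_PREFIXES):
                continue
            peak, seen = _parse_bed_line(line, lineno, score_col)
            ncols = max(ncols, seen)
            peaks.append(peak)
    return PeakSet(peaks, label=label or path.stem, columns=ncols)


def _format_score(score: float) -> str:
    if score == int(score):
        return str(int(score))
    return format(score, "g")


def write_bed(peaks: PeakSet, path: Union[str, Path]) -> None:
    """Write a PeakSet back to BED with as many columns as were read."""
    ncols = peaks.columns
    with Path(path).open("w") as fh:
        for p in peaks:
            fields = [p.chrom, str(p.start), str(p.end)]
            if ncols >= 4:
                fields.append(p.name)
            if ncols >= 5:
                fields.append(_format_score(p.score))
            if ncols >= 6:
                fields.append(p.interval.strand)
            fh.write("\t".join(fields) + "\n")


def read_fasta(path: Union[str, Path]) -> GenomeSequence:
    """Read a (possibly multi-record, line-wrapped) FASTA file."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: Union[str, Path], width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Edge-to-edge gap in bp; 0 for overlapping or book-ended intervals.

    Intervals on different chromosomes are infinitely far apart.
    """
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start - b.end, b.start - a.end, 0)


def center(a: GenomicInterval) -> int:
    """Midpoint, floor((start + end) / 2)."""
    return (a.start + a.end) // 2


def gc_fraction(genome: GenomeSequence, interval: GenomicInterval) -> float:
    """(#G + #C) / (#A + #C + #G + #T) over the interval; N bases excluded."""
    seq = genome.fetch(interval)
    return gc_of_sequence(seq)


def gc_of_sequence(seq: str) -> float:
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    informative = gc + seq.count("A") + seq.count("T")
    if informative == 0:
        raise DegenerateSequenceError("interval contains no non-N bases")
    return gc / informative


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
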