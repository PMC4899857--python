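"""Peak-subset selection, GC/length-matched randomized null, motif scanning.

The null model draws, for each template region, a random genomic locus of
identical length whose GC content matches the template region within an
absolute tolerance.  Candidate loci are sampled uniformly (chromosome chosen
proportional to length, start uniform) and rejected when GC deviates, when
more than 10% of bases are N, or when the candidate overlaps any template
region.  Motif matching is exact IUPAC string containment on both strands —
no mismatches, no position-weight scoring.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .colocalization import ProximityConfig, _build_index, min_gap_to_set
from .genomic_io import (
    DegenerateSequenceError,
    GenomeSequence,
    GenomicInterval,
    PeakRegion,
    PeakSet,
    gc_of_sequence,
    reverse_complement,
)

__all__ = [
    "SubsetCriteria",
    "MotifPattern",
    "NullConfig",
    "EnrichmentReport",
    "MatchingFailureError",
    "select_peak_subset",
    "generate_matched_random",
    "contains_motif",
    "motif_fraction",
    "enrichment_table",
]

IUPAC_CODES: Dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "U": "T",
    "R": "AG",
    "Y": "CT",
    "S": "GC",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}


class MatchingFailureError(RuntimeError):
    """A template region's GC could not be matched within the attempt budget."""


@dataclass(frozen=True)
class SubsetCriteria:
    """Filter for motif-discovery input: short, isolated, high-scoring peaks."""

    max_length: int = 400  # exclusive: length must be < max_length
    min_isolation: int = 1000  # exclusive: nearest-other-peak gap must be > this
    min_score: float = 150.0  # inclusive
    score_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.max_length <= 0 or self.min_isolation <= 0 or self.min_score <= 0:
            raise ValueError("subset criteria must all be positive")


@dataclass(frozen=True)
class MotifPattern:
    """Fixed-length IUPAC nucleotide pattern scanned on both strands."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = [c for c in self.pattern.upper() if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in motif: {''.join(sorted(set(bad)))}")

    @property
    def length(self) -> int:
        return len(self.pattern)

    def regex(self) -> re.Pattern:
        # expand to concrete-base classes: N in the scanned sequence never matches
        body = "".join(
            c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]"
            for c in self.pattern.upper()
        )
        return re.compile(body)


@dataclass(frozen=True)
class NullConfig:
    n_files: int = 3
    gc_tolerance: float = 0.02
    max_attempts_per_region: int = 10000
    max_n_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_files < 1:
            raise ValueError("n_files must be >= 1")
        if not (0 < self.gc_tolerance < 0.5):
            raise ValueError("gc_tolerance must be in (0, 0.5)")


def _nearest_other_gap(peaks: Sequence[PeakRegion]) -> List[float]:
    """For each peak, the edge gap to the nearest *other* peak in the set.

    Sorted-neighbor scan per chromosome: the nearest other peak is either
    the next peak in (start, end) order or any earlier-starting peak, whose
    best gap is determined by the running maximum end.
    """
    gaps = [math.inf] * len(peaks)
    by_chrom: Dict[str, List[int]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append(i)
    for idxs in by_chrom.values():
        order = sorted(idxs, key=lambda i: (peaks[i].start, peaks[i].end))
        max_end_before = -1
        for rank, i in enumerate(order):
            p = peaks[i]
            best = math.inf
            if max_end_before >= 0:
                best = max(p.start - max_end_before, 0)
            if rank + 1 < len(order):
                nxt = peaks[order[rank + 1]]
                best = min(best, max(nxt.start - p.end, 0))
            gaps[i] = best
            max_end_before = max(max_end_before, p.end)
    return gaps


def select_peak_subset(peaks: PeakSet, criteria: SubsetCriteria = SubsetCriteria()) -> PeakSet:
    """Peaks shorter than max_length, scoring >= min_score, and more than
    min_isolation bp from every other peak of the *input* set."""
    gaps = _nearest_other_gap(peaks.peaks)
    kept = []
    for p, gap in zip(peaks, gaps):
        if p.length >= criteria.max_length:
            continue
        score_ok = (
            p.score >= criteria.min_score
            if criteria.score_inclusive
            else p.score > criteria.min_score
        )
        if not score_ok:
            continue
        if gap <= criteria.min_isolation:
            continue
        kept.append(p)
    return PeakSet(kept, label=f"{peaks.label}.subset", columns=peaks.columns)


def _n_fraction(seq: str) -> float:
    return seq.count("N") / len(seq) if seq else 1.0


def generate_matched_random(
    template: PeakSet, genome: GenomeSequence, cfg: NullConfig
) -> List[PeakSet]:
    """Draw ``cfg.n_files`` random region sets matched to ``template``.

    Each replicate contains exactly one region per template region, of
    identical length, with GC within ``cfg.gc_tolerance`` (absolute) of its
    template region.  Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = genome.lengths()
    chrom_names = list(lengths)
    chrom_sizes = np.array([lengths[c] for c in chrom_names], dtype=float)
    chrom_probs = chrom_sizes / chrom_sizes.sum()
    template_index = _build_index(template)

    template_gc = []
    for p in template:
        try:
            template_gc.append(gc_of_sequence(genome.fetch(p.interval)))
        except DegenerateSequenceError:
            raise MatchingFailureError(f"template region {p.name} is all-N") from None

    replicates: List[PeakSet] = []
    for rep in range(cfg.n_files):
        regions: List[PeakRegion] = []
        for ti, (p, target_gc) in enumerate(zip(template, template_gc)):
            L = p.length
            placed = None
            for _ in range(cfg.max_attempts_per_region):
                ci = int(rng.choice(len(chrom_names), p=chrom_probs))
                chrom = chrom_names[ci]
                span = lengths[chrom] - L
                if span < 0:
                    continue
                start = int(rng.integers(0, span + 1))
                iv = GenomicInterval(chrom, start, start + L)
                seq = genome.fetch(iv)
                if _n_fraction(seq) > cfg.max_n_fraction:
                    continue
                try:
                    gc = gc_of_sequence(seq)
                except DegenerateSequenceError:
                    continue
                if abs(gc - target_gc) > cfg.gc_tolerance:
                    continue
                dummy = PeakRegion(iv, name=f"rand{rep+1}_{ti+1}")
                if min_gap_to_set(dummy, template_index) <= 0:
                    continue  # overlaps (or touches) a template region
                placed = dummy
                break
            if placed is None:
                raise MatchingFailureError(
                    f"could not match region {p.name} ({p.chrom}:{p.start}-{p.end}, "
                    f"GC {target_gc:.3f}) within {cfg.max_attempts_per_region} attempts"
                )
            regions.append(placed)
        replicates.append(PeakSet(regions, label=f"{template.label}.null{rep+1}", columns=4))
    return replicates


def contains_motif(seq: str, motif: MotifPattern, both_strands: bool = True) -> bool:
    """Exact IUPAC containment; N in the scanned sequence matches nothing."""
    pattern = motif.regex()
    seq = seq.upper()
    if pattern.search(seq):
        return True
    if both_strands and pattern.search(reverse_complement(seq)):
        return True
    return False


def motif_fraction(
    regions: PeakSet,
    genome: GenomeSequence,
    motif: MotifPattern,
    both_strands: bool = True,
) -> Tuple[int, float]:
    """(count, fraction) of regions whose sequence contains the motif."""
    if len(regions) == 0:
        warnings.warn("motif_fraction called on an empty region set", stacklevel=2)
        return 0, 0.0
    count = sum(
        contains_motif(genome.fetch(p.interval), motif, both_strands) for p in regions
    )
    return count, count / len(regions)


@dataclass(frozen=True)
class SetEnrichment:
    """Motif/proximity breakdown for one region set."""

    label: str
    n: int
    n_motif: int
    n_near: int
    n_near_motif: int
    n_far: int
    n_far_motif: int

    @property
    def fraction_motif(self) -> float:
        return self.n_motif / self.n if self.n else 0.0

    @property
    def fraction_near(self) -> float:
        return self.n_near / self.n if self.n else 0.0

    @property
    def fraction_motif_near(self) -> float:
        return self.n_near_motif / self.n_near if self.n_near else 0.0

    @property
    def fraction_motif_far(self) -> float:
        return self.n_far_motif / self.n_far if self.n_far else 0.0


@dataclass
class EnrichmentReport:
    rows: List[SetEnrichment]
    cutoff_d: int
    motif: str

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "set": r.label,
                    "n_regions": r.n,
                    "n_with_motif": r.n_motif,
                    "fraction_with_motif": r.fraction_motif,
                    "n_near_origin": r.n_near,
                    "fraction_near_origin": r.fraction_near,
                    "n_near_with_motif": r.n_near_motif,
                    "fraction_motif_near_origin": r.fraction_motif_near,
                    "n_far": r.n_far,
                    "n_far_with_motif": r.n_far_motif,
                    "fraction_motif_far": r.fraction_motif_far,
                }
            )
        return pd.DataFrame(recs)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _enrich_one(
    label: str,
    regions: PeakSet,
    origins_index,
    genome: GenomeSequence,
    motif: MotifPattern,
    cfg: ProximityConfig,
) -> SetEnrichment:
    n = len(regions)
    n_motif = n_near = n_near_motif = n_far_motif = 0
    for p in regions:
        has = contains_motif(genome.fetch(p.interval), motif, both_strands=True)
        near = min_gap_to_set(p, origins_index, cfg.mode) <= cfg.cutoff_d
        n_motif += has
        if near:
            n_near += 1
            n_near_motif += has
        else:
            n_far_motif += has
    return SetEnrichment(
        label=label,
        n=n,
        n_motif=n_motif,
        n_near=n_near,
        n_near_motif=n_near_motif,
        n_far=n - n_near,
        n_far_motif=n_far_motif,
    )


def enrichment_table(
    regions: PeakSet,
    nulls: Sequence[PeakSet],
    origins: PeakSet,
    genome: GenomeSequence,
    motif: MotifPattern,
    cfg: ProximityConfig = ProximityConfig(),
) -> EnrichmentReport:
    """Observed-vs-null motif containment, stratified by origin proximity."""
    origins_index = _build_index(origins)
    rows = [_enrich_one(regions.label or "observed", regions, origins_index, genome, motif, cfg)]
    for i, null_set in enumerate(nulls, start=1):
        rows.append(
            _enrich_one(null_set.label or f"null{i}", null_set, origins_index, genome, motif, cfg)
        )
    return EnrichmentReport(rows=rows, cutoff_d=cfg.cutoff_d, motif=motif.pattern)
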