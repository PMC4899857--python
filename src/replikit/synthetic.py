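"""Synthetic inputs with known ground truth for every pipeline stage.

Generators are deterministic given their seed: regeneration with the same
spec yields byte-identical FASTA/BED/TSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .fibers import FiberTrack, Segment
from .genomic_io import GenomeSequence, GenomicInterval, PeakRegion, PeakSet
from .motif_null import IUPAC_CODES, MotifPattern, contains_motif

__all__ = [
    "SyntheticGenomeSpec",
    "PeakPairSpec",
    "FiberSimSpec",
    "PlacementError",
    "simulate_genome",
    "plant_motif",
    "simulate_peak_pair",
    "simulate_fibers",
    "place_disjoint_regions",
]

_BASES = np.array(list("ACGT"))
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(RuntimeError):
    """Requested peak density cannot be placed on the given genome."""


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    chrom_lengths: Dict[str, int]
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 1000 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be >= 1000")
        if not (0 <= self.gc <= 1):
            raise ValueError("gc must be in [0, 1]")


def simulate_genome(spec: SyntheticGenomeSpec) -> GenomeSequence:
    """I.i.d. bases with P(G) + P(C) = gc, A/T and G/C symmetric."""
    rng = np.random.default_rng(spec.seed)
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    seqs = {}
    for chrom, length in spec.chrom_lengths.items():
        idx = rng.choice(4, size=length, p=p)
        seqs[chrom] = _BASE_CODES[idx].tobytes().decode("ascii")
    return GenomeSequence(seqs)


def _instantiate_iupac(pattern: str, rng: np.random.Generator) -> str:
    """Concrete ACGT word drawn uniformly from an IUPAC pattern's expansion."""
    return "".join(
        IUPAC_CODES[c][int(rng.integers(len(IUPAC_CODES[c])))] for c in pattern.upper()
    )


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def plant_motif(
    genome: GenomeSequence,
    motif: MotifPattern,
    regions: PeakSet,
    which: Sequence[int],
    seed: int = 0,
    max_attempts: int = 1000,
) -> GenomeSequence:
    """Return a genome where exactly the chosen regions contain the motif.

    Chosen regions (indices into ``regions``) get one concrete motif instance
    planted at a random offset on a random strand; the remaining regions are
    reshuffled (base composition preserved) until motif-free on both strands.
    """
    rng = np.random.default_rng(seed)
    seqs = {c: list(s) for c, s in genome.items()}
    chosen = set(int(i) for i in which)
    for i in chosen:
        region = regions[i]
        if motif.length > region.length:
            raise ValueError(
                f"motif (len {motif.length}) does not fit region {region.name} "
                f"(len {region.length})"
            )
    for i, region in enumerate(regions):
        chrom_seq = seqs[region.chrom]
        if i in chosen:
            word = _instantiate_iupac(motif.pattern, rng)
            if rng.integers(2):
                word = _rc(word)
            offset = int(rng.integers(0, region.length - motif.length + 1))
            pos = region.start + offset
            chrom_seq[pos : pos + motif.length] = list(word)
        else:
            for _ in range(max_attempts):
                sub = "".join(chrom_seq[region.start : region.end])
                if not contains_motif(sub, motif, both_strands=True):
                    break
                shuffled = np.array(list(sub))
                rng.shuffle(shuffled)
                chrom_seq[region.start : region.end] = list(shuffled)
            else:
                raise RuntimeError(f"could not scrub motif from region {region.name}")
    return GenomeSequence({c: "".join(s) for c, s in seqs.items()})


@dataclass(frozen=True)
class PeakPairSpec:
    n_anchors: int = 1000
    n_events: int = 1000
    colocal_fraction: float = 0.8
    cutoff_d: int = 2000
    anchor_length: Tuple[int, int] = (200, 400)
    event_length: Tuple[int, int] = (500, 1000)
    score_range: Tuple[float, float] = (50.0, 500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.colocal_fraction <= 1):
            raise ValueError("colocal_fraction must be in [0, 1]")
        if self.cutoff_d <= 0:
            raise ValueError("cutoff_d must be positive")
        if round(self.colocal_fraction * self.n_anchors) > self.n_events:
            raise ValueError("n_events too small for requested colocal_fraction")


def simulate_peak_pair(
    spec: PeakPairSpec, genome_lengths: Dict[str, int]
) -> Tuple[PeakSet, PeakSet]:
    """Anchor/event BED pair with an exact, recoverable colocalization fraction.

    round(colocal_fraction * n_anchors) anchors get a same-slot event at an
    edge gap uniform in [0, cutoff]; all other anchor/event placements live
    in separate slots whose margins guarantee >= 6x cutoff edge separation,
    so non-colocalized anchors are > 5x cutoff from every event.
    """
    rng = np.random.default_rng(spec.seed)
    n_pair = int(round(spec.colocal_fraction * spec.n_anchors))
    n_lone_anchor = spec.n_anchors - n_pair
    n_lone_event = spec.n_events - n_pair

    margin = 3 * spec.cutoff_d
    usable = spec.anchor_length[1] + spec.cutoff_d + spec.event_length[1]
    slot_w = usable + 2 * margin

    slots: List[Tuple[str, int]] = []
    for chrom, length in genome_lengths.items():
        for k in range(length // slot_w):
            slots.append((chrom, k * slot_w))
    n_slots = n_pair + n_lone_anchor + n_lone_event
    if n_slots > len(slots):
        raise PlacementError(
            f"need {n_slots} placement slots of {slot_w} bp but genome provides "
            f"{len(slots)}"
        )
    order = rng.permutation(len(slots))[:n_slots]
    kinds = ["pair"] * n_pair + ["anchor"] * n_lone_anchor + ["event"] * n_lone_event

    anchors: List[PeakRegion] = []
    events: List[PeakRegion] = []

    def rand_len(bounds: Tuple[int, int]) -> int:
        return int(rng.integers(bounds[0], bounds[1] + 1))

    def rand_score() -> float:
        return float(np.round(rng.uniform(*spec.score_range), 2))

    for kind, slot_i in zip(kinds, order):
        chrom, offset = slots[int(slot_i)]
        base = offset + margin
        if kind == "pair":
            la, le = rand_len(spec.anchor_length), rand_len(spec.event_length)
            gap = int(rng.integers(0, spec.cutoff_d + 1))
            jitter = int(rng.integers(0, usable - (la + gap + le) + 1))
            a0 = base + jitter
            anchors.append(
                PeakRegion(GenomicInterval(chrom, a0, a0 + la), rand_score(),
                           f"anchor{len(anchors)+1}")
            )
            e0 = a0 + la + gap
            events.append(
                PeakRegion(GenomicInterval(chrom, e0, e0 + le), rand_score(),
                           f"event{len(events)+1}")
            )
        elif kind == "anchor":
            la = rand_len(spec.anchor_length)
            jitter = int(rng.integers(0, usable - la + 1))
            a0 = base + jitter
            anchors.append(
                PeakRegion(GenomicInterval(chrom, a0, a0 + la), rand_score(),
                           f"anchor{len(anchors)+1}")
            )
        else:
            le = rand_len(spec.event_length)
            jitter = int(rng.integers(0, usable - le + 1))
            e0 = base + jitter
            events.append(
                PeakRegion(GenomicInterval(chrom, e0, e0 + le), rand_score(),
                           f"event{len(events)+1}")
            )

    key = lambda p: (p.chrom, p.start)
    return (
        PeakSet(sorted(anchors, key=key), label="anchors", columns=5),
        PeakSet(sorted(events, key=key), label="events", columns=5),
    )


def place_disjoint_regions(
    genome_lengths: Dict[str, int],
    lengths: Sequence[int],
    seed: int = 0,
    spacing: int = 100,
) -> PeakSet:
    """Non-overlapping template regions of the given lengths, jittered but
    deterministic — a convenience for null-model tests."""
    rng = np.random.default_rng(seed)
    lengths = list(lengths)
    needed = sum(lengths) + spacing * len(lengths)
    total = sum(genome_lengths.values())
    if needed > total:
        raise PlacementError("genome too small for requested regions")
    regions: List[PeakRegion] = []
    chroms = list(genome_lengths)
    ci, cursor = 0, 0
    for i, L in enumerate(lengths):
        placed = False
        while ci < len(chroms):
            chrom = chroms[ci]
            gap = int(rng.integers(spacing // 2, spacing + 1))
            start = cursor + gap
            if start + L <= genome_lengths[chrom]:
                regions.append(
                    PeakRegion(GenomicInterval(chrom, start, start + L),
                               score=200.0, name=f"tmpl{i+1}")
                )
                cursor = start + L
                placed = True
                break
            ci, cursor = ci + 1, 0
        if not placed:
            raise PlacementError("ran out of genome while placing regions")
    return PeakSet(regions, label="template", columns=5)


@dataclass(frozen=True)
class FiberSimSpec:
    n_fibers: int = 1000
    condition: str = "WT"
    fiber_length_kb: Tuple[float, float] = (300.0, 600.0)  # uniform range
    inter_origin_distribution: str = "exponential"  # or "gamma"
    inter_origin_median_kb: float = 102.6
    gamma_shape: float = 2.0
    fork_speed_mean: float = 1.570
    fork_speed_sd: float = 0.3
    stall_probability: float = 0.0
    stall_factor: float = 0.5
    stall_balanced: bool = False
    pulse1_minutes: float = 30.0
    pulse2_minutes: float = 30.0
    scale_kb_per_um: float = 2.0
    signal_fraction: float = 1.0
    origins_per_fiber: Optional[int] = None  # None -> 1 + Poisson(1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.stall_probability <= 1):
            raise ValueError("stall_probability must be in [0, 1]")
        if not (0 <= self.signal_fraction <= 1):
            raise ValueError("signal_fraction must be in [0, 1]")
        if self.fork_speed_mean <= 0 or self.inter_origin_median_kb <= 0:
            raise ValueError("rates must be positive")
        if self.inter_origin_distribution not in ("exponential", "gamma"):
            raise ValueError("inter_origin_distribution must be exponential or gamma")


def _gap_sampler(spec: FiberSimSpec, rng: np.random.Generator):
    if spec.inter_origin_distribution == "exponential":
        scale = spec.inter_origin_median_kb / math.log(2)
        return lambda n: rng.exponential(scale, size=n)
    unit_median = float(sps.gamma.ppf(0.5, spec.gamma_shape))
    scale = spec.inter_origin_median_kb / unit_median
    return lambda n: rng.gamma(spec.gamma_shape, scale, size=n)


def _truncated_normal(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    while (bad := out <= 0).any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return out


def _stall_patterns(
    n_origins: int, spec: FiberSimSpec, rng: np.random.Generator
) -> np.ndarray:
    """(n_origins, 2) boolean stall flags for (left, right) fork sides.

    Balanced mode allocates the four (left, right) outcome patterns in exact
    proportion to their Bernoulli probabilities (largest-remainder rounding,
    random assignment) — a variance-reduction option that makes the realized
    stall fraction deterministic.
    """
    p = spec.stall_probability
    if not spec.stall_balanced:
        return rng.random((n_origins, 2)) < p
    probs = np.array([(1 - p) ** 2, p * (1 - p), p * (1 - p), p * p])
    raw = probs * n_origins
    counts = np.floor(raw).astype(int)
    rem = n_origins - counts.sum()
    if rem:
        frac_order = np.argsort(-(raw - counts))
        counts[frac_order[:rem]] += 1
    pattern_of = np.repeat(np.arange(4), counts)
    rng.shuffle(pattern_of)
    flags = np.zeros((n_origins, 2), dtype=bool)
    flags[:, 0] = np.isin(pattern_of, (1, 3))  # left stalled
    flags[:, 1] = np.isin(pattern_of, (2, 3))  # right stalled
    return flags


def simulate_fibers(spec: FiberSimSpec) -> List[FiberTrack]:
    """Combed-fiber population with known spacing, speed, and stall truth.

    Each origin emits two forks.  The first-pulse (IdU) tracks extend from
    the origin center; second-pulse (CldU) tracks continue outward and are
    the elongating segments used for speed.  A stalled side has its CldU
    track shortened by ``stall_factor``.  All lengths are emitted in um
    (kb / scale).
    """
    rng = np.random.default_rng(spec.seed)
    sample_gaps = _gap_sampler(spec, rng)

    # pass 1: fiber skeletons (signal flag, origin count, gaps)
    has_signal = rng.random(spec.n_fibers) < spec.signal_fraction
    n_origins_per = np.zeros(spec.n_fibers, dtype=int)
    for i in range(spec.n_fibers):
        if not has_signal[i]:
            continue
        if spec.origins_per_fiber is not None:
            n_origins_per[i] = spec.origins_per_fiber
        else:
            n_origins_per[i] = 1 + int(rng.poisson(1.5))
    gaps_per_fiber = [
        sample_gaps(max(k - 1, 0)) if k else np.empty(0) for k in n_origins_per
    ]
    total_origins = int(n_origins_per.sum())
    speeds = _truncated_normal(
        spec.fork_speed_mean, spec.fork_speed_sd, 2 * total_origins, rng
    ).reshape(-1, 2)
    stalls = _stall_patterns(total_origins, spec, rng)

    fibers: List[FiberTrack] = []
    oi = 0  # global origin cursor
    for i in range(spec.n_fibers):
        fid = f"f{i+1:05d}"
        nominal_len = float(rng.uniform(*spec.fiber_length_kb))
        if not has_signal[i]:
            fibers.append(
                FiberTrack(fid, spec.condition, ssdna_length_um=nominal_len / spec.scale_kb_per_um)
            )
            continue
        k = n_origins_per[i]
        centers = 30.0 + np.concatenate([[0.0], np.cumsum(gaps_per_fiber[i])])
        segments: List[Segment] = []
        span_end = 0.0
        for j in range(k):
            c = float(centers[j])
            vL, vR = speeds[oi]
            sL, sR = stalls[oi]
            oid = f"{fid}o{j+1}"
            idu_l = vL * spec.pulse1_minutes
            idu_r = vR * spec.pulse1_minutes
            cldu_l = vL * spec.pulse2_minutes * (spec.stall_factor if sL else 1.0)
            cldu_r = vR * spec.pulse2_minutes * (spec.stall_factor if sR else 1.0)
            um = lambda kb: kb / spec.scale_kb_per_um
            segments.extend(
                [
                    Segment("CldU", um(cldu_l), "elongating", oid, "left",
                            start_um=um(c - idu_l - cldu_l)),
                    Segment("IdU", um(idu_l), "initiating", oid, "left",
                            start_um=um(c - idu_l)),
                    Segment("IdU", um(idu_r), "initiating", oid, "right",
                            start_um=um(c)),
                    Segment("CldU", um(cldu_r), "elongating", oid, "right",
                            start_um=um(c + idu_r)),
                ]
            )
            span_end = max(span_end, c + idu_r + cldu_r)
            oi += 1
        segments.sort(key=lambda s: s.start_um)
        length_kb = max(nominal_len, span_end + 30.0)
        fibers.append(
            FiberTrack(
                fid,
                spec.condition,
                ssdna_length_um=length_kb / spec.scale_kb_per_um,
                segments=segments,
            )
        )
    return fibers
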