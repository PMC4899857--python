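"""Proximity classification of peak sets against each other.

Implements the three analyses run on anchor/event peak pairs: the fraction
of anchors with an event within a distance cutoff (and the reverse), the
signed distance-to-center profile over a fixed window, and the partition of
origins into binder-bound and unbound subsets.

Distance is measured edge-to-edge by default (overlap counts as 0); a
center-to-center mode is available for sensitivity analysis.  Chromosome
names must match exactly (use the CLI ``--chrom-alias`` map for dialects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Tuple

import numpy as np

from .genomic_io import PeakRegion, PeakSet, center

__all__ = [
    "ProximityConfig",
    "ColocalizationSummary",
    "DistanceProfile",
    "fraction_within",
    "format_percent",
    "distance_profile",
    "stratify_origins",
    "min_gap_to_set",
]


@dataclass(frozen=True)
class ProximityConfig:
    """Cutoff and profile-window parameters for proximity analyses."""

    cutoff_d: int = 2000
    profile_half_window: int = 10000
    profile_bin: int = 500
    mode: str = "gap"  # "gap" (edge-to-edge) or "center"

    def __post_init__(self) -> None:
        if self.cutoff_d < 0:
            # 0 is allowed: it means overlapping-or-book-ended only
            raise ValueError("cutoff_d must be non-negative")
        if self.profile_bin <= 0 or self.profile_half_window <= 0:
            raise ValueError("profile window/bin must be positive")
        if self.profile_half_window % self.profile_bin != 0:
            raise ValueError("profile_half_window must be a multiple of profile_bin")
        if self.mode not in ("gap", "center"):
            raise ValueError(f"unknown distance mode {self.mode!r}")


@dataclass(frozen=True)
class ColocalizationSummary:
    n_anchors: int
    n_anchors_colocal: int
    fraction: float
    n_events: int
    n_events_colocal: int
    fraction_reverse: float
    cutoff_d: int


@dataclass(frozen=True)
class DistanceProfile:
    bin_edges: np.ndarray  # length n_bins + 1, spanning [-half_window, +half_window]
    counts: np.ndarray  # length n_bins, non-negative ints
    n_anchors: int


class _ChromIndex:
    """Sorted-interval index for one chromosome: O(log n) nearest-gap queries."""

    def __init__(self, peaks: List[PeakRegion]):
        order = sorted(range(len(peaks)), key=lambda i: (peaks[i].start, peaks[i].end))
        self.starts = np.array([peaks[i].start for i in order], dtype=np.int64)
        ends = np.array([peaks[i].end for i in order], dtype=np.int64)
        self.prefix_max_end = np.maximum.accumulate(ends)
        self.centers = np.sort(
            np.array([center(p.interval) for p in peaks], dtype=np.int64)
        )

    def min_gap(self, start: int, end: int) -> float:
        """Smallest edge-to-edge gap from [start, end) to any indexed interval."""
        idx = int(np.searchsorted(self.starts, end, side="right"))
        best = math.inf
        if idx > 0:
            # intervals starting before `end`: overlap iff their max end > start
            max_end = int(self.prefix_max_end[idx - 1])
            best = max(start - max_end, 0)
        if idx < len(self.starts):
            best = min(best, int(self.starts[idx]) - end)
        return best

    def min_center_distance(self, c: int) -> float:
        pos = int(np.searchsorted(self.centers, c))
        best = math.inf
        if pos > 0:
            best = c - int(self.centers[pos - 1])
        if pos < len(self.centers):
            best = min(best, int(self.centers[pos]) - c)
        return best


def _build_index(peaks: PeakSet) -> Dict[str, _ChromIndex]:
    return {chrom: _ChromIndex(ps) for chrom, ps in peaks.by_chrom().items()}


def min_gap_to_set(peak: PeakRegion, index: Dict[str, _ChromIndex], mode: str = "gap") -> float:
    """Distance from one peak to the nearest member of an indexed set."""
    ci = index.get(peak.chrom)
    if ci is None:
        return math.inf
    if mode == "center":
        return ci.min_center_distance(center(peak.interval))
    return ci.min_gap(peak.start, peak.end)


def _colocal_flags(anchors: PeakSet, events: PeakSet, cfg: ProximityConfig) -> List[bool]:
    index = _build_index(events)
    return [min_gap_to_set(a, index, cfg.mode) <= cfg.cutoff_d for a in anchors]


def fraction_within(
    anchors: PeakSet, events: PeakSet, cfg: ProximityConfig
) -> ColocalizationSummary:
    """Fraction of anchors with >=1 event within ``cfg.cutoff_d`` bp.

    ``fraction_reverse`` reports the same quantity with the roles swapped.
    An anchor near several events still counts once.  Empty inputs yield
    fraction 0 by convention.
    """
    fwd = _colocal_flags(anchors, events, cfg)
    rev = _colocal_flags(events, anchors, cfg)
    n_a, n_e = len(anchors), len(events)
    n_ac, n_ec = sum(fwd), sum(rev)
    return ColocalizationSummary(
        n_anchors=n_a,
        n_anchors_colocal=n_ac,
        fraction=n_ac / n_a if n_a else 0.0,
        n_events=n_e,
        n_events_colocal=n_ec,
        fraction_reverse=n_ec / n_e if n_e else 0.0,
        cutoff_d=cfg.cutoff_d,
    )


def format_percent(numerator: int, denominator: int, decimals: int = 0) -> str:
    """Round-half-up percentage string, e.g. (20841, 24222, 0) -> '86%'."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return f"{pct.quantize(quantum, rounding=ROUND_HALF_UP)}%"


def distance_profile(
    anchors: PeakSet, events: PeakSet, cfg: ProximityConfig
) -> DistanceProfile:
    """Histogram of signed center-to-center distances, event minus anchor.

    Every (anchor, event) pair on the same chromosome with |distance| <=
    half-window contributes one count; bins are [edge_i, edge_{i+1}) with
    the final right edge inclusive (numpy histogram convention), so the
    invariant sum(counts) == #{pairs with |d| <= half_window} holds.
    """
    hw, width = cfg.profile_half_window, cfg.profile_bin
    edges = np.arange(-hw, hw + width, width, dtype=np.int64)
    event_centers: Dict[str, np.ndarray] = {
        chrom: np.sort(np.array([center(p.interval) for p in ps], dtype=np.int64))
        for chrom, ps in events.by_chrom().items()
    }
    distances: List[np.ndarray] = []
    for a in anchors:
        centers = event_centers.get(a.chrom)
        if centers is None:
            continue
        c = center(a.interval)
        lo = np.searchsorted(centers, c - hw, side="left")
        hi = np.searchsorted(centers, c + hw, side="right")
        if hi > lo:
            distances.append(centers[lo:hi] - c)
    if distances:
        counts, _ = np.histogram(np.concatenate(distances), bins=edges)
    else:
        counts = np.zeros(len(edges) - 1, dtype=np.int64)
    return DistanceProfile(bin_edges=edges, counts=counts.astype(np.int64), n_anchors=len(anchors))


def stratify_origins(
    origins: PeakSet, binder: PeakSet, cfg: ProximityConfig
) -> Tuple[PeakSet, PeakSet]:
    """Partition origins into (bound, unbound) by the fraction_within rule."""
    flags = _colocal_flags(origins, binder, cfg)
    bound = PeakSet(
        [p for p, f in zip(origins, flags) if f],
        label=f"{origins.label}.bound",
        columns=origins.columns,
    )
    unbound = PeakSet(
        [p for p, f in zip(origins, flags) if not f],
        label=f"{origins.label}.unbound",
        columns=origins.columns,
    )
    return bound, unbound
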