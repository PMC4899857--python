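"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately avoid the library's sorted-index implementations: all
distances are computed pairwise, and the rank test is enumerated over all
group assignments.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np


def brute_gap(a, b) -> float:
    """Edge gap between two peaks (objects with chrom/start/end)."""
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start - b.end, b.start - a.end, 0)


def brute_center_distance(a, b) -> float:
    if a.chrom != b.chrom:
        return math.inf
    ca = (a.start + a.end) // 2
    cb = (b.start + b.end) // 2
    return abs(ca - cb)


def brute_min_distance(anchor, events, mode: str = "gap") -> float:
    fn = brute_gap if mode == "gap" else brute_center_distance
    return min((fn(anchor, e) for e in events), default=math.inf)


def brute_colocal_flags(anchors, events, cutoff: int, mode: str = "gap") -> List[bool]:
    return [brute_min_distance(a, events, mode) <= cutoff for a in anchors]


def brute_fraction_within(anchors, events, cutoff: int, mode: str = "gap") -> float:
    if not len(anchors):
        return 0.0
    flags = brute_colocal_flags(anchors, events, cutoff, mode)
    return sum(flags) / len(anchors)


def brute_profile_distances(anchors, events, half_window: int) -> List[int]:
    """All signed center distances (event - anchor) with |d| <= half_window."""
    out = []
    for a in anchors:
        ca = (a.start + a.end) // 2
        for e in events:
            if e.chrom != a.chrom:
                continue
            d = (e.start + e.end) // 2 - ca
            if abs(d) <= half_window:
                out.append(d)
    return out


def brute_nearest_other_gap(peaks) -> List[float]:
    out = []
    for i, p in enumerate(peaks):
        out.append(
            min(
                (brute_gap(p, q) for j, q in enumerate(peaks) if j != i),
                default=math.inf,
            )
        )
    return out


def brute_select_subset(peaks, max_length: int, min_isolation: int, min_score: float):
    gaps = brute_nearest_other_gap(list(peaks))
    return [
        p
        for p, gap in zip(peaks, gaps)
        if p.length < max_length and p.score >= min_score and gap > min_isolation
    ]


def exact_mannwhitney_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact p by full enumeration of rank assignments (no ties)."""
    pooled = sorted(list(a) + list(b))
    if len(set(pooled)) != len(pooled):
        raise ValueError("exact enumeration oracle requires tie-free data")
    n, N = len(a), len(a) + len(b)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - n * (n + 1) / 2
    us = np.array([sum(c) - n * (n + 1) / 2 for c in combinations(range(1, N + 1), n)])
    p = 2 * min(float((us <= u_obs).mean()), float((us >= u_obs).mean()))
    return min(1.0, p)
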