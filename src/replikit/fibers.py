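"""DNA-combing replication statistics.

Consumes measured fiber tables (one row per label segment) and computes
fork speeds from second-pulse elongating tracks, inter-origin distances
from initiation-signal centers, the fork-asymmetry classification, the
fraction of fibers carrying any replication signal, and a two-condition
Mann-Whitney comparison.

Conventions: lengths on disk are in micrometers and converted with a fixed
stretching constant (default 2 kb/um); each pulse lasts 30 min; a fork pair
is asymmetric when the longer side exceeds the shorter by more than the
threshold ratio (strictly greater than 1.33 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Segment",
    "FiberTrack",
    "ForkMeasurement",
    "FiberConfig",
    "ConditionStats",
    "FiberSummary",
    "um_to_kb",
    "fork_speed",
    "classify_fork",
    "inter_origin_distances",
    "fork_measurements",
    "summarize_conditions",
    "read_fiber_table",
    "write_fiber_table",
    "rank_sum_test",
]

LABELS = ("IdU", "CldU")
KINDS = ("elongating", "initiating", "terminating", "unclassified")

FIBER_COLUMNS = [
    "fiber_id",
    "condition",
    "ssdna_length_um",
    "segment_index",
    "label",
    "length_um",
    "kind",
    "origin_id",
    "side",
    "start_um",
]


@dataclass(frozen=True)
class Segment:
    label: str  # IdU | CldU | none
    length_um: float
    kind: str  # elongating | initiating | terminating | unclassified | none
    origin_id: str = ""
    side: str = ""  # left | right | ""
    start_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label != "none" and self.length_um <= 0:
            raise ValueError(f"segment length must be positive, got {self.length_um}")


@dataclass
class FiberTrack:
    fiber_id: str
    condition: str
    ssdna_length_um: float
    segments: List[Segment] = field(default_factory=list)

    @property
    def has_signal(self) -> bool:
        return any(s.label in LABELS for s in self.segments)


@dataclass(frozen=True)
class ForkMeasurement:
    """Outgoing left/right track lengths (kb) of one origin's fork pair."""

    left_kb: float
    right_kb: float

    def __post_init__(self) -> None:
        if self.left_kb < 0 or self.right_kb < 0:
            raise ValueError("fork lengths must be non-negative")


@dataclass(frozen=True)
class FiberConfig:
    scale_kb_per_um: float = 2.0
    pulse_minutes: float = 30.0
    asymmetry_threshold: float = 0.33
    speed_label: str = "CldU"  # CldU | IdU | both

    def __post_init__(self) -> None:
        if self.scale_kb_per_um <= 0 or self.pulse_minutes <= 0:
            raise ValueError("scale and pulse must be positive")
        if not (0 < self.asymmetry_threshold <= 1):
            raise ValueError("asymmetry_threshold must be in (0, 1]")
        if self.speed_label not in ("CldU", "IdU", "both"):
            raise ValueError(f"unknown speed_label {self.speed_label!r}")


def um_to_kb(length_um: float, cfg: FiberConfig = FiberConfig()) -> float:
    """Micrometers to kb via the stretching constant."""
    if length_um < 0:
        raise ValueError("length must be >= 0")
    return length_um * cfg.scale_kb_per_um


def fork_speed(track_um: float, cfg: FiberConfig = FiberConfig()) -> float:
    """Speed (kb/min) of an elongating-fork label track.

    Callers must pass elongating tracks only; initiating forks are excluded
    upstream because their label tracks do not span the full pulse.
    """
    return um_to_kb(track_um, cfg) / cfg.pulse_minutes


def classify_fork(fork: ForkMeasurement, cfg: FiberConfig = FiberConfig()) -> str:
    """'asymmetric' when the longer side is more than threshold longer (strict)."""
    lo, hi = sorted((fork.left_kb, fork.right_kb))
    if hi == 0:
        raise ValueError("both fork sides are zero")
    if lo == 0:
        return "asymmetric"
    return "asymmetric" if hi / lo > 1 + cfg.asymmetry_threshold else "symmetric"


def inter_origin_distances(
    fiber: FiberTrack, cfg: FiberConfig = FiberConfig()
) -> List[float]:
    """Distances (kb) between consecutive origin centers on one fiber.

    Origin centers are the midpoints of initiation-pattern segments, located
    via the segment start positions; fibers with fewer than two positioned
    origins yield an empty list.
    """
    centers: Dict[str, List[Tuple[float, float]]] = {}
    for s in fiber.segments:
        if s.kind == "initiating" and s.origin_id and s.start_um is not None:
            centers.setdefault(s.origin_id, []).append((s.start_um, s.length_um))
    origin_centers = []
    for spans in centers.values():
        lo = min(start for start, _ in spans)
        hi = max(start + length for start, length in spans)
        origin_centers.append((lo + hi) / 2)
    origin_centers.sort()
    return [
        um_to_kb(b - a, cfg) for a, b in zip(origin_centers, origin_centers[1:])
    ]


def fork_measurements(
    fiber: FiberTrack, cfg: FiberConfig = FiberConfig()
) -> List[ForkMeasurement]:
    """Left/right fork-track pairs (kb) for each origin on the fiber."""
    wanted = LABELS if cfg.speed_label == "both" else (cfg.speed_label,)
    sides: Dict[str, Dict[str, float]] = {}
    for s in fiber.segments:
        if s.kind == "elongating" and s.origin_id and s.side in ("left", "right"):
            if s.label in wanted:
                d = sides.setdefault(s.origin_id, {})
                d[s.side] = d.get(s.side, 0.0) + um_to_kb(s.length_um, cfg)
    out = []
    for d in sides.values():
        if "left" in d and "right" in d:
            out.append(ForkMeasurement(d["left"], d["right"]))
    return out


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact when both groups are small (<= 8) and tie-free; otherwise the
    normal approximation with tie correction.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="auto", use_continuity=False
    )
    return float(res.pvalue)


@dataclass(frozen=True)
class ConditionStats:
    condition: str
    n_fibers: int
    n_fibers_with_signal: int
    n_origins: int
    n_forks: int
    n_asymmetric: int
    median_inter_origin_kb: Optional[float]
    median_fork_speed_kb_min: Optional[float]

    @property
    def percent_asymmetric(self) -> Optional[float]:
        return 100.0 * self.n_asymmetric / self.n_forks if self.n_forks else None

    @property
    def percent_fibers_with_signal(self) -> float:
        return 100.0 * self.n_fibers_with_signal / self.n_fibers if self.n_fibers else 0.0


@dataclass
class FiberSummary:
    conditions: Dict[str, ConditionStats]
    p_inter_origin: Optional[float] = None
    p_fork_speed: Optional[float] = None
    compared: Optional[Tuple[str, str]] = None

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for c in self.conditions.values():
            recs.append(
                {
                    "condition": c.condition,
                    "n_fibers": c.n_fibers,
                    "percent_fibers_with_signal": c.percent_fibers_with_signal,
                    "n_origins": c.n_origins,
                    "median_inter_origin_kb": c.median_inter_origin_kb,
                    "median_fork_speed_kb_min": c.median_fork_speed_kb_min,
                    "n_forks": c.n_forks,
                    "percent_asymmetric": c.percent_asymmetric,
                }
            )
        df = pd.DataFrame(recs)
        if self.compared is not None:
            df["p_inter_origin"] = self.p_inter_origin
            df["p_fork_speed"] = self.p_fork_speed
        return df


def _condition_measurements(
    fibers: Sequence[FiberTrack], cfg: FiberConfig
) -> Tuple[List[float], List[float], int, int, int]:
    """(inter-origin distances, fork speeds, n_origins, n_forks, n_asym)."""
    distances: List[float] = []
    speeds: List[float] = []
    n_origins = n_forks = n_asym = 0
    for fiber in fibers:
        distances.extend(inter_origin_distances(fiber, cfg))
        n_origins += len(
            {s.origin_id for s in fiber.segments if s.kind == "initiating" and s.origin_id}
        )
        wanted = LABELS if cfg.speed_label == "both" else (cfg.speed_label,)
        for s in fiber.segments:
            if s.kind == "elongating" and s.label in wanted:
                speeds.append(um_to_kb(s.length_um, cfg) / cfg.pulse_minutes)
        for fork in fork_measurements(fiber, cfg):
            n_forks += 1
            n_asym += classify_fork(fork, cfg) == "asymmetric"
    return distances, speeds, n_origins, n_forks, n_asym


def summarize_conditions(
    fibers: Sequence[FiberTrack],
    cfg: FiberConfig = FiberConfig(),
    condition_a: Optional[str] = None,
    condition_b: Optional[str] = None,
) -> FiberSummary:
    """Per-condition medians and fork statistics, plus an optional two-sided
    rank-sum comparison of inter-origin distance and fork speed between two
    named conditions (each needs >= 3 observations to test)."""
    groups: Dict[str, List[FiberTrack]] = {}
    for f in fibers:
        groups.setdefault(f.condition, []).append(f)
    for name in (condition_a, condition_b):
        if name is not None and name not in groups:
            raise ValueError(f"unknown condition label {name!r}")

    per_cond: Dict[str, ConditionStats] = {}
    measured: Dict[str, Tuple[List[float], List[float]]] = {}
    for cond, flist in groups.items():
        distances, speeds, n_origins, n_forks, n_asym = _condition_measurements(flist, cfg)
        measured[cond] = (distances, speeds)
        per_cond[cond] = ConditionStats(
            condition=cond,
            n_fibers=len(flist),
            n_fibers_with_signal=sum(f.has_signal for f in flist),
            n_origins=n_origins,
            n_forks=n_forks,
            n_asymmetric=n_asym,
            median_inter_origin_kb=float(np.median(distances)) if distances else None,
            median_fork_speed_kb_min=float(np.median(speeds)) if speeds else None,
        )

    summary = FiberSummary(conditions=per_cond)
    if condition_a is not None and condition_b is not None:
        da, sa = measured[condition_a]
        db, sb = measured[condition_b]
        summary.compared = (condition_a, condition_b)
        if len(da) >= 3 and len(db) >= 3:
            summary.p_inter_origin = rank_sum_test(da, db)
        if len(sa) >= 3 and len(sb) >= 3:
            summary.p_fork_speed = rank_sum_test(sa, sb)
    return summary


def _segments_from_rows(rows: pd.DataFrame) -> List[Segment]:
    segs = []
    for _, r in rows.sort_values("segment_index").iterrows():
        if str(r["label"]) == "none":
            continue
        start = r.get("start_um")
        segs.append(
            Segment(
                label=str(r["label"]),
                length_um=float(r["length_um"]),
                kind=str(r["kind"]),
                origin_id="" if pd.isna(r.get("origin_id")) else str(r["origin_id"]),
                side="" if pd.isna(r.get("side")) else str(r["side"]),
                start_um=None if start is None or pd.isna(start) else float(start),
            )
        )
    return segs


def read_fiber_table(path: Union[str, Path]) -> List[FiberTrack]:
    """Read the per-segment fiber TSV dialect into FiberTrack objects.

    Rows with label 'none' mark fibers carrying no replication signal.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"fiber_id": str})
    missing = {"fiber_id", "condition", "label", "length_um", "kind"} - set(df.columns)
    if missing:
        raise ValueError(f"fiber table missing columns: {sorted(missing)}")
    if "segment_index" not in df.columns:
        df["segment_index"] = range(len(df))
    fibers = []
    for (fid, cond), rows in df.groupby(["fiber_id", "condition"], sort=False):
        ss = rows["ssdna_length_um"].iloc[0] if "ssdna_length_um" in rows.columns else 0.0
        fibers.append(
            FiberTrack(
                fiber_id=str(fid),
                condition=str(cond),
                ssdna_length_um=float(ss) if not pd.isna(ss) else 0.0,
                segments=_segments_from_rows(rows),
            )
        )
    return fibers


def write_fiber_table(
    fibers: Sequence[FiberTrack], path: Union[str, Path], header_comments: Sequence[str] = ()
) -> None:
    recs = []
    for f in fibers:
        if not f.segments:
            recs.append(
                dict(
                    fiber_id=f.fiber_id,
                    condition=f.condition,
                    ssdna_length_um=f.ssdna_length_um,
                    segment_index=0,
                    label="none",
                    length_um=0.0,
                    kind="none",
                    origin_id="",
                    side="",
                    start_um="",
                )
            )
            continue
        for i, s in enumerate(f.segments):
            recs.append(
                dict(
                    fiber_id=f.fiber_id,
                    condition=f.condition,
                    ssdna_length_um=f.ssdna_length_um,
                    segment_index=i,
                    label=s.label,
                    length_um=s.length_um,
                    kind=s.kind,
                    origin_id=s.origin_id,
                    side=s.side,
                    start_um="" if s.start_um is None else s.start_um,
                )
            )
    df = pd.DataFrame(recs, columns=FIBER_COLUMNS)
    with Path(path).open("w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
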