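from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pytest

from replikit.genomic_io import GenomicInterval, PeakRegion, PeakSet
from replikit.synthetic import SyntheticGenomeSpec, simulate_genome


def make_peak(chrom: str, start: int, end: int, score: float = 0.0, name: str = ".") -> PeakRegion:
    return PeakRegion(GenomicInterval(chrom, start, end), score=score, name=name)


def random_peakset(
    rng: np.random.Generator,
    n: int,
    chroms: Tuple[str, ...] = ("chr1", "chr2"),
    span: int = 50_000,
    max_len: int = 1_000,
    label: str = "rand",
) -> PeakSet:
    peaks: List[PeakRegion] = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len + 1))
        score = float(np.round(rng.uniform(0, 500), 1))
        peaks.append(make_peak(chrom, start, start + length, score, f"{label}{i+1}"))
    return PeakSet(peaks, label=label)


@pytest.fixture(scope="session")
def small_genome():
    """200 kb two-chromosome uniform genome shared across tests."""
    return simulate_genome(
        SyntheticGenomeSpec({"chr1": 120_000, "chr2": 80_000}, gc=0.5, seed=11)
    )
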