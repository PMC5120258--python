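"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from bivalchrom.intervals import GenomicInterval


# ---------------------------------------------------------------------------
# brute-force per-base oracles (kept independent of the library's sweep-line
# implementations: everything here works on explicit base bit-vectors)

GENOME_LEN = 10_000


def coverage_vector(intervals, chrom: str, length: int = GENOME_LEN) -> np.ndarray:
    v = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            v[iv.start : iv.end] = True
    return v


def chroms_of(*collections) -> set[str]:
    return {iv.chrom for coll in collections for iv in coll}


def brute_overlap_bases(a, b, length: int = GENOME_LEN) -> int:
    total = 0
    for chrom in chroms_of(a, b):
        total += int(
            (coverage_vector(a, chrom, length) & coverage_vector(b, chrom, length)).sum()
        )
    return total


def brute_auc(scores, labels) -> float:
    """Pairwise-concordance AUC with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=GENOME_LEN, max_len=500):
    out = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, max_pos - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
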