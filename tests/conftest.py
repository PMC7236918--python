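"""Shared fixtures: random assemblage generation and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from symdiv.diversity import AssemblageCounts


def make_random_assemblage(
    rng: np.random.Generator, max_p: int = 8, max_count: int = 12
) -> AssemblageCounts:
    p = int(rng.integers(1, max_p + 1))
    counts = rng.integers(1, max_count + 1, size=p)
    labels = tuple(f"phy{i:03d}" for i in range(p))
    return AssemblageCounts(labels, counts)


def enumerate_expected_richness(counts, n: int) -> float:
    """Exhaustive oracle: average distinct-phylotype count over every one
    of the C(N, n) equally likely subsamples of the record multiset."""
    rec = [i for i, c in enumerate(counts) for _ in range(c)]
    total = 0
    count = 0
    for combo in itertools.combinations(range(len(rec)), n):
        total += len({rec[i] for i in combo})
        count += 1
    return total / count


def integer_partitions(n: int):
    """All multisets of positive integers summing to n (nonincreasing)."""

    def gen(remaining: int, cap: int, prefix: tuple[int, ...]):
        if remaining == 0:
            yield prefix
            return
        for first in range(min(cap, remaining), 0, -1):
            yield from gen(remaining - first, first, prefix + (first,))

    yield from gen(n, n, ())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def random_assemblage(rng):
    return make_random_assemblage(rng)
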