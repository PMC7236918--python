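"""Richness and evenness metrics for symbiont assemblages.

An *assemblage* is the multiset of phylotype association records compiled
for one coral host species: ``N_i`` records of phylotype *i*, ``N`` records
in total, ``P`` distinct phylotypes (raw richness). Because sampling effort
``N`` varies over orders of magnitude across host species, raw richness is
not comparable across species; the metrics here standardize it by
individual-based (Hurlbert) rarefaction:

* ``raw_evenness`` -- Pielou's J': Shannon entropy of the relative
  abundances divided by ``ln P``.
* ``expected_richness`` -- E(S; n), the expected number of distinct
  phylotypes in a random subsample of ``n`` records drawn without
  replacement, via the hypergeometric identity
  ``E(S; n) = sum_i [1 - C(N - N_i, n) / C(N, n)]``.
* ``rarefaction_curve`` -- E(S; n) for every n = 1..N, plus the
  slope-at-end diagnostic ``E(S; N) - E(S; N-1)`` (near zero when the
  curve is asymptotic, i.e. the assemblage is sufficiently sampled).
* ``pie`` -- Hurlbert's Probability of Interspecific Encounter, the chance
  that two randomly chosen records are different phylotypes; equal to the
  initial slope ``E(S; 2) - E(S; 1)`` of the rarefaction curve, and hence a
  sample-size-independent evenness metric.
* ``monte_carlo_rarefaction`` -- a resampling estimator of E(S; n) used as
  an internal cross-check of the analytic formula.

Binomial-coefficient ratios are evaluated as telescoping products of
factors in (0, 1], so assemblages with N in the thousands neither
overflow nor lose precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "AssemblageCounts",
    "RarefactionCurve",
    "SpeciesMetrics",
    "raw_evenness",
    "expected_richness",
    "rarefaction_curve",
    "pie",
    "monte_carlo_rarefaction",
    "species_metrics",
]


def _ratio_by_count(big_n: int, n: int, counts: np.ndarray) -> np.ndarray:
    """C(N - c, n) / C(N, n) for each c in ``counts``.

    Uses the telescoping identity
    ``C(N-c, n)/C(N, n) = prod_{j=0}^{c-1} (N - n - j) / (N - j)``;
    every factor lies in [0, 1], the product hits an exact zero at the
    c > N - n boundary, and no large intermediates ever form.
    """
    cmax = int(counts.max())
    j = np.arange(cmax, dtype=float)
    factors = np.maximum(big_n - n - j, 0.0) / (big_n - j)
    return np.cumprod(factors)[counts - 1]


@dataclass(frozen=True)
class AssemblageCounts:
    """Per-phylotype record counts for one host species.

    Counts are stored in canonical order -- descending count, ties broken
    lexicographically by label -- so that outputs are deterministic. All
    metrics are invariant to the input order.
    """

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(lab) for lab in self.labels)
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or len(labels) != counts.size:
            raise ValueError("labels and counts must be 1-D and equal length")
        if counts.size == 0:
            raise ValueError("assemblage must contain at least one phylotype")
        if (counts < 1).any():
            raise ValueError("all phylotype counts must be >= 1")
        if len(set(labels)) != len(labels):
            raise ValueError("phylotype labels must be unique")
        # primary key: descending count; secondary: label ascending
        order = np.lexsort((np.asarray(labels, dtype=object), -counts))
        object.__setattr__(self, "labels", tuple(labels[i] for i in order))
        counts = counts[order]
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_mapping(cls, counts: Mapping[str, int]) -> "AssemblageCounts":
        return cls(tuple(counts.keys()), np.fromiter(counts.values(), dtype=np.int64))

    @property
    def n_records(self) -> int:
        """N, the total number of association records."""
        return int(self.counts.sum())

    @property
    def richness(self) -> int:
        """P, the number of distinct phylotypes (raw richness)."""
        return int(self.counts.size)

    @property
    def proportions(self) -> np.ndarray:
        """Relative abundances p_i = N_i / N."""
        return self.counts / self.counts.sum()


@dataclass(frozen=True)
class RarefactionCurve:
    """E(S; n) for n = 1..N, with the end-slope saturation diagnostic."""

    label: str
    expected: np.ndarray  # expected[k] = E(S; k+1)
    slope_at_end: float

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.expected.size + 1)


@dataclass(frozen=True)
class SpeciesMetrics:
    """Bundle of raw and rarefied diversity metrics for one species."""

    n_records: int
    raw_richness: int
    raw_evenness: float
    pie: float  # NaN when N < 2
    rarefied_richness: dict[int, float | None] = field(default_factory=dict)


def raw_evenness(a: AssemblageCounts) -> float:
    """Pielou's J' = (-sum p_i ln p_i) / ln P, defined as 0 for P = 1.

    A monotypic assemblage has zero entropy and an undefined normalizer;
    it is maximally uneven, so J' is fixed at 0 rather than NaN to keep
    every species on the 0-1 evenness scale.
    """
    p = a.proportions
    if a.richness == 1:
        return 0.0
    shannon = float(-(p * np.log(p)).sum())
    return shannon / math.log(a.richness)


def expected_richness(a: AssemblageCounts, n: int) -> float:
    """E(S; n): expected distinct phylotypes in n records drawn without
    replacement from the N compiled records.

    Interpolation only: ``n`` must satisfy 1 <= n <= N; richness is never
    extrapolated beyond the observed sampling effort.
    """
    n = int(n)
    big_n = a.n_records
    if not 1 <= n <= big_n:
        raise ValueError(f"rarefaction depth n={n} outside [1, N={big_n}]")
    return float(a.richness - _ratio_by_count(big_n, n, a.counts).sum())


def rarefaction_curve(a: AssemblageCounts, label: str = "") -> RarefactionCurve:
    """Smooth rarefaction curve: E(S; n) evaluated at every n in 1..N."""
    big_n = a.n_records
    uniq, mult = np.unique(a.counts, return_counts=True)
    cmax = int(uniq[-1])
    expected = np.empty(big_n)
    j = np.arange(cmax, dtype=float)
    # chunk over subsample sizes to bound the (chunk x cmax) work array
    chunk = max(1, int(5_000_000 // cmax))
    for start in range(0, big_n, chunk):
        ns = np.arange(start + 1, min(start + chunk, big_n) + 1, dtype=float)
        factors = np.maximum(big_n - ns[:, None] - j[None, :], 0.0) / (big_n - j)
        ratios = np.cumprod(factors, axis=1)[:, uniq - 1]
        expected[start : start + ns.size] = a.richness - ratios @ mult
    slope = float(expected[-1] - expected[-2]) if big_n >= 2 else 0.0
    expected.setflags(write=False)
    return RarefactionCurve(label=label, expected=expected, slope_at_end=slope)


def pie(a: AssemblageCounts) -> float:
    """Hurlbert's Probability of Interspecific Encounter.

    PIE = sum_i (N_i / N) * ((N - N_i) / (N - 1)); 0 for a monotypic
    assemblage, -> 1 for many equally abundant phylotypes. Equals the
    rarefaction curve's initial slope E(S; 2) - E(S; 1).
    """
    big_n = a.n_records
    if big_n < 2:
        raise ValueError("PIE requires at least 2 records")
    c = a.counts.astype(float)
    return float(((c / big_n) * ((big_n - c) / (big_n - 1.0))).sum())


def monte_carlo_rarefaction(
    a: AssemblageCounts, n: int, iterations: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Resampling estimate of E(S; n): mean and standard error of the
    distinct-phylotype count over ``iterations`` random subsamples of size
    ``n`` drawn without replacement from the record multiset.

    This is the brute-force counterpart of :func:`expected_richness`, kept
    as an independent check of the analytic formula.
    """
    n = int(n)
    big_n = a.n_records
    if not 1 <= n <= big_n:
        raise ValueError(f"rarefaction depth n={n} outside [1, N={big_n}]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    rec = np.repeat(np.arange(a.richness), a.counts)
    total = 0.0
    total_sq = 0.0
    done = 0
    chunk = max(1, int(2_000_000 // big_n))
    while done < iterations:
        m = min(chunk, iterations - done)
        u = rng.random((m, big_n))
        idx = np.argpartition(u, n - 1, axis=1)[:, :n]
        sel = np.sort(rec[idx], axis=1)
        distinct = (np.diff(sel, axis=1) != 0).sum(axis=1) + 1
        distinct = distinct.astype(float)
        total += distinct.sum()
        total_sq += (distinct**2).sum()
        done += m
    mean = total / iterations
    var = max(total_sq - iterations * mean**2, 0.0) / max(iterations - 1, 1)
    stderr = math.sqrt(var / iterations)
    return mean, stderr


def species_metrics(a: AssemblageCounts, depths: Iterable[int]) -> SpeciesMetrics:
    """Raw and rarefied metrics at the configured standard depths.

    A species is eligible at depth d only when N >= d (strict
    interpolation); ineligible depths are reported as ``None`` and the
    species drops out of cross-species comparisons at that depth.
    """
    depths = sorted({int(d) for d in depths})
    if not depths:
        raise ValueError("at least one rarefaction depth is required")
    big_n = a.n_records
    rarefied: dict[int, float | None] = {
        d: (expected_richness(a, d) if d <= big_n else None) for d in depths
    }
    return SpeciesMetrics(
        n_records=big_n,
        raw_richness=a.richness,
        raw_evenness=raw_evenness(a),
        pie=pie(a) if big_n >= 2 else float("nan"),
        rarefied_richness=rarefied,
    )
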