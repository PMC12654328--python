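"""Shared permutation machinery.

Every resampling test in the pipeline goes through this module: the
group-size-preserving label shuffle, the p-value convention, Holm
step-down adjustment, and the named-stream seeding contract.

Two p-value conventions are offered.  ``proportion_ge`` is the plain
exceedance proportion ``#{null >= observed} / B``; it can return 0 and is
mildly anti-conservative at small B.  ``plus_one`` counts the observed
statistic as one more null draw, ``(1 + #{null >= observed}) / (1 + B)``,
which is never below ``1/(B+1)`` and gives exact level control.  All
statistics in this pipeline are oriented as non-negative departures
(ranges, absolute differences, H), so a one-tailed exceedance on the
statistic is the two-sided test.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PermutationResult",
    "PairwiseResult",
    "make_rng",
    "permute_labels",
    "permutation_null",
    "perm_pvalue",
    "holm_adjust",
    "enumerate_two_group_splits",
]

#: statistic over a grouping: takes one 2-D array (replicates, n_g) per
#: group and returns one statistic value per replicate row.
GroupStatistic = Callable[[list[np.ndarray]], np.ndarray]

CONVENTIONS = ("proportion_ge", "plus_one")


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, its permutation-null summary, and a p-value."""

    statistic_name: str
    observed_stat: float
    n_permutations: int
    p_value: float
    convention: str
    seed: int | None = None
    degenerate: bool = False
    null_stats: np.ndarray | None = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class PairwiseResult:
    """One pairwise contrast with raw and Holm-adjusted p-values.

    ``effect`` keeps the sign of the contrast as reported; the permutation
    statistic itself is the absolute departure.
    """

    pair: tuple[str, str]
    effect: float
    p_raw: float
    p_holm: float
    statistic_name: str = ""
    n_permutations: int = 0


def make_rng(seed: int, stream_label: str) -> np.random.Generator:
    """Independent, reproducible random stream for a named analysis step.

    The stream is keyed on ``(seed, stream_label)`` so adding or reordering
    analysis steps never perturbs another step's draws.
    """
    key = zlib.crc32(stream_label.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def permute_labels(
    values: Sequence[float], group_sizes: Sequence[int], rng: np.random.Generator
) -> list[np.ndarray]:
    """One uniformly random partition of ``values`` into groups of the given sizes."""
    values = np.asarray(values, dtype=float)
    sizes = np.asarray(group_sizes, dtype=int)
    if sizes.sum() != values.size:
        raise ValueError(
            f"group sizes sum to {sizes.sum()} but there are {values.size} values"
        )
    perm = rng.permutation(values)
    return np.split(perm, np.cumsum(sizes)[:-1])


def permutation_null(
    values: Sequence[float],
    group_sizes: Sequence[int],
    statistic: GroupStatistic,
    n_permutations: int,
    rng: np.random.Generator,
    chunk_size: int = 1024,
) -> np.ndarray:
    """Monte-Carlo permutation null of a grouping statistic.

    Label shuffles preserve group sizes exactly; the pooled multiset of
    values is identical in every replicate.  Shuffles are generated in
    chunks and the statistic is evaluated vectorised over rows.
    """
    values = np.asarray(values, dtype=float)
    sizes = np.asarray(group_sizes, dtype=int)
    if sizes.sum() != values.size:
        raise ValueError(
            f"group sizes sum to {sizes.sum()} but there are {values.size} values"
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    bounds = np.cumsum(sizes)[:-1]
    null = np.empty(n_permutations, dtype=float)
    done = 0
    while done < n_permutations:
        k = min(chunk_size, n_permutations - done)
        mat = np.broadcast_to(values, (k, values.size)).copy()
        rng.permuted(mat, axis=1, out=mat)
        null[done : done + k] = statistic(np.hsplit(mat, bounds))
        done += k
    return null


def observed_statistic(groups: Sequence[np.ndarray], statistic: GroupStatistic) -> float:
    """Evaluate a row-vectorised grouping statistic on the observed grouping."""
    return float(statistic([np.asarray(g, dtype=float)[None, :] for g in groups])[0])


def perm_pvalue(
    observed: float,
    null_stats: Sequence[float],
    convention: str = "proportion_ge",
    tie_rtol: float = 1e-9,
) -> float:
    """Permutation p-value of an exceedance-oriented statistic.

    Ties between null replicates and the observed value count as
    exceedances under both conventions.  Equality is judged with a tiny
    relative tolerance (``tie_rtol``): permuted replicates that are
    mathematically tied with the observed statistic can differ from it in
    the last floating-point digits (summation order), and dropping those
    ties would bias p downward on gridded data such as 40-trial
    proportions.
    """
    null = np.asarray(null_stats, dtype=float)
    if null.size == 0:
        raise ValueError("null_stats must be non-empty")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; choose from {CONVENTIONS}")
    tol = tie_rtol * max(1.0, abs(observed))
    n_ge = int(np.count_nonzero(null >= observed - tol))
    if convention == "proportion_ge":
        return n_ge / null.size
    return (1 + n_ge) / (1 + null.size)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Sort ascending; the i-th order statistic is multiplied by (m - i),
    capped at 1, and made monotone by a running maximum.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepdown = np.minimum(1.0, (m - np.arange(m)) * p[order])
    stepdown = np.maximum.accumulate(stepdown)
    adjusted = np.empty_like(p)
    adjusted[order] = stepdown
    return adjusted


def enumerate_two_group_splits(
    values: Sequence[float], n_first: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """All distinct assignments of ``values`` into two groups (first of size n_first).

    Exhaustive reference null for small two-group permutation tests; the
    C(n, n_first) index subsets are enumerated directly.
    """
    from itertools import combinations

    values = np.asarray(values, dtype=float)
    n = values.size
    if not 0 < n_first < n:
        raise ValueError("n_first must be strictly between 0 and len(values)")
    all_idx = frozenset(range(n))
    splits = []
    for first in combinations(range(n), n_first):
        rest = sorted(all_idx.difference(first))
        splits.append((values[list(first)], values[rest]))
    return splits
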