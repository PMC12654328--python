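"""Per-fly location (central tendency) inference on light-choice probability.

The global test is a permutation Kruskal–Wallis: the usual tie-corrected
H statistic on ranks, referred not to its chi-square approximation but to
its own permutation null (labels shuffled across flies, group sizes
preserved).  Pairwise contrasts are permutation tests on the absolute
difference of group means, Holm-adjusted, with the signed difference
reported as the effect size.  With 40 trials per fly the LCP takes only
41 distinct values, so ties are massive and the tie correction matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .resampling import (
    PairwiseResult,
    PermutationResult,
    holm_adjust,
    observed_statistic,
    perm_pvalue,
    permutation_null,
)

__all__ = [
    "GroupSummary",
    "summarize_groups",
    "kruskal_H",
    "perm_kw_test",
    "pairwise_mean_tests",
]


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n_flies: int
    median: float
    q1: float
    q3: float
    mean: float
    sem: float | None  # None for a single fly


def summarize_groups(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Median (IQR, linear-interpolation quartiles) and mean ± SEM per group."""
    out = []
    for g, v in groups.items():
        x = np.asarray(v, dtype=float)
        if x.size == 0:
            raise ValueError(f"group {g!r} is empty")
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else None
        out.append(
            GroupSummary(
                group_label=g, n_flies=x.size, median=float(med),
                q1=float(q1), q3=float(q3), mean=float(x.mean()), sem=sem,
            )
        )
    return out


def _h_from_ranks(rank_parts: list[np.ndarray], n_total: int) -> np.ndarray:
    """Uncorrected H from rank rows: 12/(N(N+1)) Σ Rsum²/n - 3(N+1)."""
    term = sum(r.sum(axis=1) ** 2 / r.shape[1] for r in rank_parts)
    return 12.0 / (n_total * (n_total + 1)) * term - 3.0 * (n_total + 1)


def _tie_factor(pooled: np.ndarray) -> float:
    """1 - Σ(t³-t)/(N³-N) over tie groups; 0 when all values are equal."""
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)


def kruskal_H(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    tie_correction: bool = True,
) -> float:
    """Kruskal–Wallis H with average ranks for ties.

    Tie-corrected by default (divide by 1 - Σ(t³-t)/(N³-N)); the
    uncorrected statistic is available for sensitivity analysis.  When
    every value is identical the tie factor is 0 and H is returned as 0.
    """
    arrays = [np.asarray(v, dtype=float)
              for v in (groups.values() if isinstance(groups, Mapping) else groups)]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("need at least three observations in total")
    ranks = rankdata(pooled)
    bounds = np.cumsum([a.size for a in arrays])[:-1]
    h = float(_h_from_ranks([r[None, :] for r in np.split(ranks, bounds)], pooled.size)[0])
    if not tie_correction:
        return h
    tf = _tie_factor(pooled)
    if tf == 0.0:
        return 0.0
    return h / tf


def perm_kw_test(
    groups: Mapping[str, Sequence[float]],
    n_permutations: int,
    rng: np.random.Generator,
    convention: str = "proportion_ge",
    tie_correction: bool = True,
) -> PermutationResult:
    """Permutation Kruskal–Wallis test.

    The pooled values are ranked once; permuting labels is equivalent to
    permuting the rank vector, and the tie-correction factor is invariant
    under permutation, so the null is built on ranks directly.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    sizes = [a.size for a in arrays]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = rankdata(pooled)
    tf = _tie_factor(pooled) if tie_correction else 1.0
    degenerate = tf == 0.0
    scale = 1.0 if degenerate else 1.0 / tf

    def stat(parts: list[np.ndarray]) -> np.ndarray:
        return scale * _h_from_ranks(parts, n_total)

    bounds = np.cumsum(sizes)[:-1]
    observed = 0.0 if degenerate else float(
        stat([r[None, :] for r in np.split(ranks, bounds)])[0]
    )
    null = permutation_null(ranks, sizes, stat, n_permutations, rng)
    return PermutationResult(
        statistic_name="kruskal_H",
        observed_stat=observed,
        n_permutations=n_permutations,
        p_value=perm_pvalue(observed, null, convention),
        convention=convention,
        degenerate=degenerate,
        null_stats=null,
    )


def _abs_mean_diff(parts: list[np.ndarray]) -> np.ndarray:
    return np.abs(parts[0].mean(axis=1) - parts[1].mean(axis=1))


def pairwise_mean_tests(
    groups: Mapping[str, Sequence[float]],
    n_permutations: int,
    rng: np.random.Generator,
    convention: str = "proportion_ge",
) -> list[PairwiseResult]:
    """Permutation tests on |mean_a - mean_b| per pair, Holm-adjusted.

    The reported effect is the signed difference mean_a - mean_b in the
    pair's label order; the test statistic is its absolute value.
    """
    labels = list(groups.keys())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    raws, effects, pairs = [], [], []
    for a, b in combinations(labels, 2):
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if xa.size == 0 or xb.size == 0:
            raise ValueError(f"pair ({a!r}, {b!r}) has an empty group")
        observed = float(xa.mean() - xb.mean())
        null = permutation_null(
            np.concatenate([xa, xb]), [xa.size, xb.size],
            _abs_mean_diff, n_permutations, rng,
        )
        pairs.append((a, b))
        effects.append(observed)
        raws.append(perm_pvalue(abs(observed), null, convention))
    adj = holm_adjust(raws)
    return [
        PairwiseResult(
            pair=pair, effect=eff, p_raw=praw, p_holm=float(ph),
            statistic_name="abs_mean_diff", n_permutations=n_permutations,
        )
        for pair, eff, praw, ph in zip(pairs, effects, raws, adj)
    ]
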