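"""Pooled-trial descriptives: Wilson intervals, chi-square, MOVER-W contrasts.

Pooling the 40 trials of every fly treats trials as independent, which
the per-fly analyses show they are not (between-fly overdispersion).
Everything in this module is therefore descriptive effect-size reporting,
never confirmatory inference, and reports carry a ``descriptive`` flag.

Intervals for a single proportion are Wilson score intervals; the
difference interval is MOVER-W (method of variance estimates recovery),
which recombines the two Wilson limits in quadrature around the point
difference.  The two-proportion z-test uses the pooled-variance form
without continuity correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy.stats import chi2, norm

from .resampling import holm_adjust
from .trial_io import CohortDataset

__all__ = [
    "PooledProportion",
    "ProportionContrast",
    "TwoPropZ",
    "pool_counts",
    "wilson_ci",
    "chisq_groups_by_choice",
    "two_prop_z",
    "mover_w_ci",
    "pooled_contrasts",
]


@dataclass(frozen=True)
class PooledProportion:
    group_label: str
    n_trials_total: int
    n_toward: int
    p_hat: float
    wilson_lower: float
    wilson_upper: float
    level: float = 0.95
    descriptive: bool = True


@dataclass(frozen=True)
class ProportionContrast:
    pair: tuple[str, str]
    delta: float  # p_a - p_b
    mover_lower: float
    mover_upper: float
    z_stat: float
    p_raw: float
    p_holm: float
    level: float = 0.95
    descriptive: bool = True


class TwoPropZ(NamedTuple):
    z_stat: float
    p_two_sided: float
    degenerate: bool = False


def wilson_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Exact at the boundaries: x = 0 gives lower = 0 and x = n gives
    upper = 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    p = x / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lower = 0.0 if x == 0 else max(0.0, center - half)
    upper = 1.0 if x == n else min(1.0, center + half)
    return float(lower), float(upper)


def pool_counts(cohort: CohortDataset, level: float = 0.95) -> list[PooledProportion]:
    """Pooled toward/total counts and Wilson CI per group (retained flies)."""
    out = []
    for g in cohort.group_labels:
        flies = cohort.group(g)
        if not flies:
            raise ValueError(f"group {g!r} has no retained flies")
        n_tot = sum(f.n_trials for f in flies)
        n_tow = sum(f.n_toward for f in flies)
        lo, hi = wilson_ci(n_tow, n_tot, level)
        out.append(
            PooledProportion(
                group_label=g, n_trials_total=n_tot, n_toward=n_tow,
                p_hat=n_tow / n_tot, wilson_lower=lo, wilson_upper=hi, level=level,
            )
        )
    return out


def chisq_groups_by_choice(
    counts: Sequence[tuple[int, int]] | Mapping[str, tuple[int, int]],
) -> tuple[float, int, float]:
    """Pearson chi-square on the groups × (toward, away) table.

    Returns (statistic, df, p).  No continuity correction.
    """
    if isinstance(counts, Mapping):
        counts = list(counts.values())
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise ValueError("counts must form a G×2 table with G >= 2")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row or column margin; chi-square undefined")
    expected = row * col / table.sum()
    stat = float(np.sum((table - expected) ** 2 / expected))
    df = table.shape[0] - 1
    return stat, df, float(chi2.sf(stat, df))


def two_prop_z(
    x1: int, n1: int, x2: int, n2: int, pooled_variance: bool = True
) -> TwoPropZ:
    """Two-proportion z-test, pooled-variance form, no continuity correction.

    The unpooled (Wald) form is available by switch.  When the pooled
    proportion is 0 or 1 the statistic is undefined; p is reported as 1
    with a degenerate flag.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("invalid counts")
    p1, p2 = x1 / n1, x2 / n2
    if pooled_variance:
        pbar = (x1 + x2) / (n1 + n2)
        var = pbar * (1 - pbar) * (1 / n1 + 1 / n2)
    else:
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var == 0.0:
        return TwoPropZ(z_stat=0.0, p_two_sided=1.0, degenerate=True)
    z = (p1 - p2) / np.sqrt(var)
    return TwoPropZ(z_stat=float(z), p_two_sided=float(2 * norm.sf(abs(z))))


def mover_w_ci(
    x1: int, n1: int, x2: int, n2: int, level: float = 0.95
) -> tuple[float, float]:
    """MOVER-W interval for the difference of proportions p1 - p2.

    Built from the two Wilson intervals (l1,u1), (l2,u2):
    lower = d - sqrt((p1-l1)² + (u2-p2)²), upper = d + sqrt((u1-p1)² + (p2-l2)²).
    """
    p1, p2 = x1 / n1, x2 / n2
    l1, u1 = wilson_ci(x1, n1, level)
    l2, u2 = wilson_ci(x2, n2, level)
    d = p1 - p2
    lower = d - float(np.hypot(p1 - l1, u2 - p2))
    upper = d + float(np.hypot(u1 - p1, p2 - l2))
    return lower, upper


def pooled_contrasts(
    pooled: Sequence[PooledProportion],
    level: float = 0.95,
    pooled_variance: bool = True,
) -> list[ProportionContrast]:
    """All pairwise pooled-trial contrasts with MOVER-W CIs, Holm-adjusted.

    Delta follows the pair's label order: delta = p_a - p_b.
    """
    by_label = {p.group_label: p for p in pooled}
    pairs, deltas, cis, zs, raws = [], [], [], [], []
    for a, b in combinations(by_label.keys(), 2):
        pa, pb = by_label[a], by_label[b]
        z = two_prop_z(pa.n_toward, pa.n_trials_total, pb.n_toward, pb.n_trials_total,
                       pooled_variance=pooled_variance)
        ci = mover_w_ci(pa.n_toward, pa.n_trials_total, pb.n_toward, pb.n_trials_total,
                        level)
        pairs.append((a, b))
        deltas.append(pa.p_hat - pb.p_hat)
        cis.append(ci)
        zs.append(z.z_stat)
        raws.append(z.p_two_sided)
    adj = holm_adjust(raws)
    return [
        ProportionContrast(
            pair=pair, delta=d, mover_lower=ci[0], mover_upper=ci[1],
            z_stat=z, p_raw=praw, p_holm=float(ph), level=level,
        )
        for pair, d, ci, z, praw, ph in zip(pairs, deltas, cis, zs, raws, adj)
    ]
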