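"""Pre-specified robustness screens: 3-MAD outlier check, lane/side balance.

The outlier screen flags flies whose LCP lies more than k (default 3)
median absolute deviations from their group median.  It is applied once
(no iterative re-screening) and is read in raw MAD units by default; the
normalised MADn unit is available by switch and widens the threshold by
1.4826×.  A group with MAD = 0 cannot flag anyone and is reported as
degenerate.

The balance diagnostics are transparent descriptives: a group × lane
contingency chi-square and the pooled toward-rate split by which side
was lit, each with Wilson intervals.  They check the randomisation, not
any causal model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .dispersion import MADN_SCALE, mad
from .pooled import wilson_ci
from .trial_io import CohortDataset, TrialRecord

__all__ = ["OutlierReport", "BalanceReport", "screen_outliers", "lane_side_balance"]


@dataclass(frozen=True)
class OutlierReport:
    group_label: str
    n_checked: int
    flagged_fly_ids: tuple[str, ...]
    threshold_k: float
    scale_used: str  # "raw_mad" or "madn"
    group_median: float
    group_mad: float
    degenerate: bool = False


@dataclass
class BalanceReport:
    group_by_lane: pd.DataFrame | None
    lane_chisq: tuple[float, int, float] | None
    per_side_rates: dict[str, dict] | None
    alpha: float = 0.05
    lane_imbalance_flag: bool | None = None
    notes: list[str] = field(default_factory=list)


def screen_outliers(
    cohort: CohortDataset, k: float = 3.0, scale: str = "raw_mad"
) -> list[OutlierReport]:
    """Flag flies with |LCP - group median| > k × MAD (single pass).

    ``scale='madn'`` uses the normalised MAD instead, widening the
    threshold by the 1.4826 consistency factor.
    """
    if scale not in ("raw_mad", "madn"):
        raise ValueError(f"scale must be 'raw_mad' or 'madn', got {scale!r}")
    if k < 0:
        raise ValueError("k must be non-negative")
    reports = []
    for g in cohort.group_labels:
        flies = cohort.group(g)
        if not flies:
            raise ValueError(f"group {g!r} has no retained flies")
        lcps = np.array([f.lcp for f in flies])
        med = float(np.median(lcps))
        m = float(mad(lcps))
        unit = m * (MADN_SCALE if scale == "madn" else 1.0)
        degenerate = unit == 0.0
        flagged = () if degenerate else tuple(
            f.fly_id for f, v in zip(flies, lcps) if abs(v - med) > k * unit
        )
        reports.append(
            OutlierReport(
                group_label=g, n_checked=len(flies), flagged_fly_ids=flagged,
                threshold_k=k, scale_used=scale, group_median=med, group_mad=m,
                degenerate=degenerate,
            )
        )
    return reports


def lane_side_balance(
    trials: Sequence[TrialRecord],
    cohort: CohortDataset,
    alpha: float = 0.05,
    level: float = 0.95,
) -> BalanceReport:
    """Descriptive lane/side balance diagnostics on retained flies.

    Group × lane table of fly counts with a contingency chi-square, and
    the pooled toward-rate split by lit side.  Missing lane or side
    information skips the corresponding diagnostic with a logged notice.
    """
    report = BalanceReport(group_by_lane=None, lane_chisq=None,
                           per_side_rates=None, alpha=alpha)
    retained = {f.fly_id for f in cohort.flies}

    lanes = {f.fly_id: f.lane_id for f in cohort.flies if f.lane_id is not None}
    if lanes:
        df = pd.DataFrame(
            {"group": [f.group_label for f in cohort.flies if f.fly_id in lanes],
             "lane": [lanes[f.fly_id] for f in cohort.flies if f.fly_id in lanes]}
        )
        table = pd.crosstab(df["group"], df["lane"])
        # drop all-zero margins cannot occur in a crosstab of observed rows
        stat, p, dof, _ = chi2_contingency(table.to_numpy())
        report.group_by_lane = table
        report.lane_chisq = (float(stat), int(dof), float(p))
        report.lane_imbalance_flag = bool(p < alpha)
    else:
        report.notes.append("lane information missing; lane balance skipped")

    sided = [t for t in trials if t.lit_side is not None and t.fly_id in retained]
    if sided:
        rates: dict[str, dict] = {}
        for side in ("left", "right"):
            sub = [t for t in sided if t.lit_side == side]
            n = len(sub)
            x = sum(1 for t in sub if t.score == 1)
            lo, hi = wilson_ci(x, n, level) if n else (float("nan"), float("nan"))
            rates[side] = {
                "n_trials": n, "n_toward": x,
                "toward_rate": x / n if n else float("nan"),
                "wilson_lower": lo, "wilson_upper": hi,
            }
        report.per_side_rates = rates
    else:
        report.notes.append("lit-side information missing; side balance skipped")
    return report
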