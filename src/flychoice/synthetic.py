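"""Synthetic T-maze choice cohorts with tunable between-fly overdispersion.

Each fly carries a latent light-choice probability p_i.  With
intraclass correlation rho > 0, p_i ~ Beta(alpha, beta) with
alpha = mu(1-rho)/rho and beta = (1-mu)(1-rho)/rho, so E[p_i] = mu and
Var[p_i] = rho·mu(1-mu); rho = 0 collapses to a pure binomial (every fly
shares p = mu, the no-individuality null).  Trials are independent coin
flips at p_i, the lit side is a fair coin per trial, and a Bernoulli-
selected fraction of flies stops early at a uniform random trial count,
exercising the completion filter downstream.

The variance of the per-fly choice proportion over m trials is
mu(1-mu)[rho + (1-rho)/m], the beta-binomial identity the moment tests
check.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .resampling import make_rng
from .trial_io import TrialRecord

__all__ = [
    "GroupSpec",
    "SyntheticCohortSpec",
    "sample_fly_counts",
    "sample_cohort",
    "paper_like_spec",
    "PAPER_LIKE_GROUPS",
]

N_LANES = 40  # parallel T-maze modules in the apparatus


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group: size, mean LCP, overdispersion, dropout."""

    label: str
    n_flies: int
    mean_lcp: float
    icc: float = 0.0
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError(f"n_flies must be >= 1, got {self.n_flies}")
        if not 0.0 <= self.mean_lcp <= 1.0:
            raise ValueError(f"mean_lcp must be in [0, 1], got {self.mean_lcp}")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError(f"icc must be in [0, 1), got {self.icc}")
        if self.icc > 0.0 and not 0.0 < self.mean_lcp < 1.0:
            raise ValueError("icc > 0 requires mean_lcp strictly inside (0, 1)")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError(f"dropout_prob must be in [0, 1), got {self.dropout_prob}")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    groups: tuple[GroupSpec, ...]
    trials_per_fly: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_fly < 1:
            raise ValueError("trials_per_fly must be >= 1")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError(f"group labels must be unique, got {labels}")
        object.__setattr__(self, "groups", tuple(self.groups))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortSpec":
        groups = tuple(GroupSpec(**g) for g in d["groups"])
        return cls(groups=groups,
                   trials_per_fly=int(d.get("trials_per_fly", 40)),
                   seed=int(d.get("seed", 0)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticCohortSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _latent_p(group: GroupSpec, rng: np.random.Generator) -> np.ndarray:
    if group.icc == 0.0:
        return np.full(group.n_flies, group.mean_lcp)
    mu, rho = group.mean_lcp, group.icc
    alpha = mu * (1.0 - rho) / rho
    beta = (1.0 - mu) * (1.0 - rho) / rho
    return rng.beta(alpha, beta, size=group.n_flies)


def sample_fly_counts(
    group: GroupSpec, trials_per_fly: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fly-level draw for one group: (p_i, n_trials_i, n_toward_i).

    The fast path for simulation studies that never need trial rows:
    latent probabilities, per-fly completed trial counts (dropout
    applied), and binomial toward counts.
    """
    m = trials_per_fly
    p = _latent_p(group, rng)
    n_trials = np.full(group.n_flies, m, dtype=int)
    if group.dropout_prob > 0.0 and m > 1:
        drop = rng.random(group.n_flies) < group.dropout_prob
        n_trials[drop] = rng.integers(1, m, size=int(drop.sum()))
    n_toward = rng.binomial(n_trials, p)
    return p, n_trials, n_toward


def sample_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Generate per-trial records plus the ground-truth per-fly table.

    Returns the trial list and a DataFrame with one row per fly:
    fly_id, group, lane, p_true (the latent choice probability),
    n_trials, n_toward.  Identical specs (including seed) reproduce the
    dataset bit for bit.
    """
    rng = make_rng(spec.seed, "synthetic-cohort")
    m = spec.trials_per_fly
    trials: list[TrialRecord] = []
    truth_rows = []
    for group in spec.groups:
        p, n_trials, _ = sample_fly_counts(group, m, rng)
        lanes = rng.integers(1, N_LANES + 1, size=group.n_flies)
        for i in range(group.n_flies):
            fly_id = f"{group.label}-{i + 1:04d}"
            lane = f"L{lanes[i]:02d}"
            k = int(n_trials[i])
            lit = rng.random(k) < 0.5
            toward = rng.random(k) < p[i]
            for t in range(k):
                trials.append(
                    TrialRecord(
                        fly_id=fly_id,
                        group_label=group.label,
                        lane_id=lane,
                        trial_index=t + 1,
                        lit_side="left" if lit[t] else "right",
                        score=1 if toward[t] else -1,
                    )
                )
            truth_rows.append(
                {
                    "fly_id": fly_id, "group": group.label, "lane": lane,
                    "p_true": float(p[i]), "n_trials": k,
                    "n_toward": int(toward.sum()),
                }
            )
    return trials, pd.DataFrame(truth_rows)


#: study-like defaults: group sizes before exclusion, pooled mean LCPs,
#: and exclusion counts matching the four-arm larval-exposure design
#: (Control / aMW / 5-HTP / escitalopram).  The ICC values are a
#: calibration: they reproduce group MADn levels of about
#: 0.31/0.31/0.31/0.39 on the phototaxis-index scale, i.e. a dispersion
#: range near 0.074 concentrated in the escitalopram-like arm.
PAPER_LIKE_GROUPS: tuple[dict, ...] = (
    {"label": "Control", "n_flies": 308, "mean_lcp": 0.73, "icc": 0.100,
     "dropout_prob": 7 / 308},
    {"label": "aMW", "n_flies": 318, "mean_lcp": 0.73, "icc": 0.100,
     "dropout_prob": 8 / 318},
    {"label": "5-HTP", "n_flies": 307, "mean_lcp": 0.65, "icc": 0.079,
     "dropout_prob": 6 / 307},
    {"label": "Escitalopram", "n_flies": 330, "mean_lcp": 0.52, "icc": 0.109,
     "dropout_prob": 9 / 330},
)


def paper_like_spec(seed: int) -> SyntheticCohortSpec:
    """Ready-made four-group cohort spec emulating the study design.

    Four treatment arms with ~310-330 flies scheduled for 40 trials each,
    group mean LCPs 0.73/0.73/0.65/0.52, overdispersion calibrated so the
    escitalopram-like arm is the most variable, and dropout tuned to
    exclude roughly 6-9 flies per arm, leaving about 301/310/301/321.
    """
    return SyntheticCohortSpec(
        groups=tuple(GroupSpec(**g) for g in PAPER_LIKE_GROUPS),
        trials_per_fly=40,
        seed=seed,
    )


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
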