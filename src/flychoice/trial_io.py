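"""Reading and aggregating per-trial T-maze choice logs.

A trial log is a delimited text table with one row per choice: which fly,
which treatment group, which lane of the apparatus, which arm was lit and
whether the fly ran toward it.  The reader is dialect-agnostic: a column
map names the physical columns and an encoding map translates the raw
choice values to the canonical ±1 score (+1 toward the lit arm, -1 away).
Per-fly aggregates are the light-choice probability (LCP, the fraction of
+1 trials) and the phototaxis index (mean of the ±1 scores), linked by
index = 2·LCP - 1.  Flies that did not complete the scheduled number of
trials (default 40) are excluded from analysis but reported.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "FlyRecord",
    "CohortDataset",
    "ConfigError",
    "DataError",
    "read_trials",
    "aggregate_flies",
    "filter_complete",
    "write_fly_table",
    "read_fly_table",
    "write_trials",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_ENCODING_MAP",
]


class ConfigError(ValueError):
    """A column map or configuration value does not fit the input."""


class DataError(ValueError):
    """The input data violate a contract (bad value, duplicate, overrun)."""


SIDES = ("left", "right")

#: logical field -> column name used by the synthetic generator's writer,
#: and the default dialect the reader expects.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "fly_id": "fly_id",
    "group_label": "group",
    "lane_id": "lane",
    "trial_index": "trial",
    "lit_side": "lit_side",
    "score": "score",
}

#: raw score value -> canonical ±1.
DEFAULT_ENCODING_MAP: dict[str, int] = {
    "1": 1, "+1": 1, "-1": -1,
    "toward": 1, "away": -1,
    "T": 1, "A": -1,
}


@dataclass(frozen=True)
class TrialRecord:
    """One T-maze decision."""

    fly_id: str
    group_label: str
    trial_index: int
    score: int
    lit_side: str | None = None
    lane_id: str | None = None

    def __post_init__(self) -> None:
        if self.score not in (1, -1):
            raise DataError(f"score must be +1 or -1, got {self.score!r}")
        if self.trial_index < 1:
            raise DataError(f"trial_index must be >= 1, got {self.trial_index}")
        if self.lit_side is not None and self.lit_side not in SIDES:
            raise DataError(f"lit_side must be one of {SIDES}, got {self.lit_side!r}")


@dataclass(frozen=True)
class FlyRecord:
    """Per-fly aggregate of a block of binary light/dark choices.

    ``lcp`` and ``phototaxis_index`` are exact rationals of the two counts;
    the float views are correctly rounded from those rationals, so the
    identity index = 2·LCP - 1 holds exactly in rational arithmetic.
    """

    fly_id: str
    group_label: str
    n_trials: int
    n_toward: int
    lane_id: str | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise DataError(f"n_trials must be >= 1, got {self.n_trials}")
        if not 0 <= self.n_toward <= self.n_trials:
            raise DataError(
                f"n_toward={self.n_toward} outside [0, {self.n_trials}] for fly {self.fly_id}"
            )

    @property
    def lcp_exact(self) -> Fraction:
        return Fraction(self.n_toward, self.n_trials)

    @property
    def phototaxis_index_exact(self) -> Fraction:
        return 2 * self.lcp_exact - 1

    @property
    def lcp(self) -> float:
        return float(self.lcp_exact)

    @property
    def phototaxis_index(self) -> float:
        return float(self.phototaxis_index_exact)


@dataclass
class CohortDataset:
    """Retained and excluded flies after the trial-completion filter."""

    flies: list[FlyRecord]
    excluded: list[FlyRecord]
    group_labels: list[str]
    required_trials: int = 40
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fly in self.flies:
            if fly.n_trials != self.required_trials:
                raise DataError(
                    f"retained fly {fly.fly_id} has {fly.n_trials} trials, "
                    f"expected {self.required_trials}"
                )
        for fly in self.excluded:
            if fly.n_trials >= self.required_trials:
                raise DataError(
                    f"excluded fly {fly.fly_id} has {fly.n_trials} trials, "
                    f"expected fewer than {self.required_trials}"
                )

    def group(self, label: str) -> list[FlyRecord]:
        return [f for f in self.flies if f.group_label == label]

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.group(g)) for g in self.group_labels}

    def indices_by_group(self) -> dict[str, np.ndarray]:
        """Per-group arrays of phototaxis indices, in group-label order."""
        return {
            g: np.array([f.phototaxis_index for f in self.group(g)])
            for g in self.group_labels
        }

    def lcps_by_group(self) -> dict[str, np.ndarray]:
        return {g: np.array([f.lcp for f in self.group(g)]) for g in self.group_labels}


def _sniff_delimiter(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_trials(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    encoding_map: Mapping[str, int] | None = None,
    delimiter: str | None = None,
) -> list[TrialRecord]:
    """Read and validate a per-trial choice log.

    ``column_map`` maps the logical fields (fly_id, group_label,
    trial_index, and either score or the pair lit_side/chosen_side;
    optionally lane_id, lit_side) to column names.  ``encoding_map``
    translates raw score values to ±1 and must cover every value observed.
    Row numbers in error messages are 1-based data rows (header excluded).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    emap = {str(k): int(v) for k, v in (encoding_map or DEFAULT_ENCODING_MAP).items()}
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str)

    for logical in ("fly_id", "group_label", "trial_index"):
        col = cmap.get(logical)
        if col is None or col not in df.columns:
            raise ConfigError(f"column map lacks a valid column for {logical!r} "
                              f"(mapped to {col!r}; columns: {list(df.columns)})")
    have_score = cmap.get("score") in df.columns
    have_pair = (cmap.get("lit_side") in df.columns
                 and cmap.get("chosen_side", "chosen_side") in df.columns)
    if not have_score and not have_pair:
        raise ConfigError(
            "column map must provide a score column or a (lit_side, chosen_side) pair"
        )

    fly = df[cmap["fly_id"]].astype(str)
    group = df[cmap["group_label"]].astype(str)
    try:
        trial = df[cmap["trial_index"]].astype(int)
    except (TypeError, ValueError) as exc:
        raise DataError(f"trial_index column is not integral: {exc}") from exc

    lane_col = cmap.get("lane_id")
    lane = df[lane_col].astype(str) if lane_col in df.columns else None

    lit_col = cmap.get("lit_side")
    lit = None
    if lit_col in df.columns:
        lit = df[lit_col].astype(str).str.lower()
        bad = ~lit.isin(SIDES) & lit.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise DataError(f"unrecognised lit_side {lit.iloc[row - 1]!r} at data row {row}")

    if have_score:
        raw = df[cmap["score"]].astype(str)
        unknown = ~raw.isin(emap)
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0]) + 1
            raise DataError(
                f"choice value {raw.iloc[row - 1]!r} at data row {row} "
                f"is not covered by the encoding map"
            )
        score = raw.map(emap).astype(int)
        if not score.isin((1, -1)).all():
            bad = ~score.isin((1, -1))
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise DataError(f"encoding map yields non-±1 score at data row {row}")
    else:
        chosen = df[cmap.get("chosen_side", "chosen_side")].astype(str).str.lower()
        bad = ~chosen.isin(SIDES)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise DataError(f"unrecognised chosen_side {chosen.iloc[row - 1]!r} at data row {row}")
        score = np.where(chosen.to_numpy() == lit.to_numpy(), 1, -1)
        score = pd.Series(score, index=df.index)

    dup = pd.DataFrame({"fly": fly, "trial": trial}).duplicated(keep=False)
    if dup.any():
        first = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataError(
            f"duplicate (fly_id, trial_index) = ({fly.iloc[first]!r}, {trial.iloc[first]}) "
            f"at data row {first + 1}"
        )

    records = []
    for i in range(len(df)):
        records.append(
            TrialRecord(
                fly_id=fly.iloc[i],
                group_label=group.iloc[i],
                trial_index=int(trial.iloc[i]),
                score=int(score.iloc[i]),
                lit_side=None if lit is None else lit.iloc[i],
                lane_id=None if lane is None else lane.iloc[i],
            )
        )
    return records


def aggregate_flies(trials: Iterable[TrialRecord]) -> list[FlyRecord]:
    """One FlyRecord per distinct fly, in order of first appearance."""
    order: dict[str, dict] = {}
    for t in trials:
        rec = order.setdefault(
            t.fly_id, {"group": t.group_label, "lane": t.lane_id, "n": 0, "toward": 0}
        )
        if rec["group"] != t.group_label:
            raise DataError(f"fly {t.fly_id} appears under two groups "
                            f"({rec['group']!r}, {t.group_label!r})")
        rec["n"] += 1
        rec["toward"] += t.score == 1
    return [
        FlyRecord(fly_id=fid, group_label=r["group"], lane_id=r["lane"],
                  n_trials=r["n"], n_toward=r["toward"])
        for fid, r in order.items()
    ]


def filter_complete(
    flies: Sequence[FlyRecord], required_trials: int = 40
) -> CohortDataset:
    """Partition flies into retained (exactly ``required_trials``) and excluded.

    A fly with more trials than the schedule is corrupt data, not a
    candidate for truncation.
    """
    if required_trials < 1:
        raise ValueError("required_trials must be >= 1")
    retained, excluded = [], []
    labels: list[str] = []
    for fly in flies:
        if fly.group_label not in labels:
            labels.append(fly.group_label)
        if fly.n_trials > required_trials:
            raise DataError(
                f"fly {fly.fly_id} logged {fly.n_trials} trials, more than the "
                f"scheduled {required_trials}"
            )
        (retained if fly.n_trials == required_trials else excluded).append(fly)
    excl_counts = {g: sum(1 for f in excluded if f.group_label == g) for g in labels}
    prov = {
        "n_input_flies": len(flies),
        "n_retained": len(retained),
        "n_excluded": len(excluded),
        "excluded_per_group": excl_counts,
        "required_trials": required_trials,
    }
    return CohortDataset(
        flies=retained, excluded=excluded, group_labels=labels,
        required_trials=required_trials, provenance=prov,
    )


def _fly_frame(flies: Sequence[FlyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fly_id": [f.fly_id for f in flies],
            "group": [f.group_label for f in flies],
            "lane": [f.lane_id for f in flies],
            "n_trials": [f.n_trials for f in flies],
            "n_toward": [f.n_toward for f in flies],
            "lcp": [f.lcp for f in flies],
            "phototaxis_index": [f.phototaxis_index for f in flies],
        }
    )


def write_fly_table(cohort: CohortDataset, path: str | Path) -> None:
    """Write retained flies as TSV; the exclusion report goes alongside."""
    path = Path(path)
    _fly_frame(cohort.flies).to_csv(path, sep="\t", index=False)
    if cohort.excluded:
        excl = path.with_name(path.stem + ".excluded.tsv")
        _fly_frame(cohort.excluded).to_csv(excl, sep="\t", index=False)


def read_fly_table(path: str | Path) -> list[FlyRecord]:
    """Re-read a per-fly table written by :func:`write_fly_table`."""
    df = pd.read_csv(path, sep="\t")
    return [
        FlyRecord(
            fly_id=str(r.fly_id), group_label=str(r.group),
            lane_id=None if pd.isna(r.lane) else str(r.lane),
            n_trials=int(r.n_trials), n_toward=int(r.n_toward),
        )
        for r in df.itertuples()
    ]


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write trials in the default dialect (TSV) the reader understands."""
    df = pd.DataFrame(
        {
            "fly_id": [t.fly_id for t in trials],
            "group": [t.group_label for t in trials],
            "lane": [t.lane_id for t in trials],
            "trial": [t.trial_index for t in trials],
            "lit_side": [t.lit_side for t in trials],
            "score": [t.score for t in trials],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for report provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()
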