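"""End-to-end orchestration: config, staged analysis, machine-readable reports.

``run_analysis`` executes the full chain — read or simulate trials,
aggregate to flies, apply the completion filter, run the robustness
screens, then location, dispersion and pooled analyses — and writes TSV
tables plus one consolidated JSON report.  Every stochastic result
records its iteration count, seed stream and p-value convention; the
input digest ties a report to its exact input bytes.  Re-running with
the same config and input reproduces the same numbers.

Seed streams are derived per analysis family from the single master
seed, so changing the bootstrap never perturbs a permutation test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dispersion import (
    bca_ci,
    global_dispersion_test,
    madn,
    pairwise_dispersion_tests,
    summarize_dispersion,
)
from .location import pairwise_mean_tests, perm_kw_test, summarize_groups
from .pooled import chisq_groups_by_choice, pool_counts, pooled_contrasts
from .resampling import CONVENTIONS, make_rng
from .robustness import lane_side_balance, screen_outliers
from .synthetic import SyntheticCohortSpec, sample_cohort
from .trial_io import (
    CohortDataset,
    aggregate_flies,
    file_digest,
    filter_complete,
    read_trials,
    write_fly_table,
)

__all__ = ["AnalysisConfig", "run_analysis"]

log = logging.getLogger("flychoice")


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    input_path: str | None = None
    synthetic: SyntheticCohortSpec | None = None
    column_map: dict[str, str] | None = None
    encoding_map: dict[str, int] | None = None
    required_trials: int = 40
    b_perm: int = 10_000
    b_boot: int = 10_000
    level: float = 0.95
    seed: int = 0
    convention: str = "proportion_ge"
    outlier_k: float = 3.0
    outlier_scale: str = "raw_mad"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.input_path is None and self.synthetic is None:
            raise ValueError("config needs an input_path or a synthetic spec")
        if self.b_perm < 1 or self.b_boot < 1:
            raise ValueError("b_perm and b_boot must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"convention must be one of {CONVENTIONS}")
        if self.required_trials < 1:
            raise ValueError("required_trials must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "AnalysisConfig":
        """Load a YAML/JSON config; keyword overrides win over the file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticCohortSpec.from_dict(raw["synthetic"])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = dataclasses.asdict(obj)
        d.pop("null_stats", None)
        return _jsonable(d)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return {"columns": list(map(str, obj.columns)),
                "index": list(map(str, obj.index)),
                "data": obj.to_numpy().tolist()}
    return obj


def _load_cohort(config: AnalysisConfig) -> tuple[list, CohortDataset, dict]:
    prov: dict[str, Any] = {"flychoice_version": __version__}
    if config.input_path is not None:
        trials = read_trials(config.input_path, config.column_map, config.encoding_map)
        prov["input_path"] = str(config.input_path)
        prov["input_sha256"] = file_digest(config.input_path)
    else:
        trials, _ = sample_cohort(config.synthetic)
        prov["synthetic_spec"] = config.synthetic.to_dict()
    flies = aggregate_flies(trials)
    cohort = filter_complete(flies, config.required_trials)
    prov["filter"] = cohort.provenance
    return trials, cohort, prov


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline and return (and optionally write) the report.

    Report sections: provenance, cohort, robustness, location, dispersion
    and pooled (the pooled section is descriptive only).  If
    ``config.out_dir`` is set, TSV tables and ``report.json`` are written
    there.
    """
    trials, cohort, prov = _load_cohort(config)
    prov["config"] = {k: v for k, v in config.to_dict().items()}
    seed, B, convention = config.seed, config.b_perm, config.convention

    log.info("cohort: %s flies retained, %s excluded",
             len(cohort.flies), len(cohort.excluded))

    # --- robustness screens (run before inference, as pre-specified) ---
    outliers = screen_outliers(cohort, k=config.outlier_k, scale=config.outlier_scale)
    balance = lane_side_balance(trials, cohort, level=config.level)

    lcps = cohort.lcps_by_group()
    indices = cohort.indices_by_group()

    # --- location: per-fly LCP ---
    summaries = summarize_groups(lcps)
    kw = perm_kw_test(lcps, B, make_rng(seed, "location-kw"), convention)
    loc_pairs = pairwise_mean_tests(lcps, B, make_rng(seed, "location-pairwise"),
                                    convention)

    # --- dispersion: per-fly phototaxis index ---
    disp = summarize_dispersion(indices)
    disp_global = global_dispersion_test(indices, B,
                                         make_rng(seed, "dispersion-global"),
                                         convention)
    disp_pairs = pairwise_dispersion_tests(indices, B,
                                           make_rng(seed, "dispersion-pairwise"),
                                           convention)
    cis = [
        bca_ci(indices[g], madn, n_boot=config.b_boot, level=config.level,
               rng=make_rng(seed, f"dispersion-bca-{g}"), group_label=g)
        for g in cohort.group_labels
    ]

    # --- pooled descriptives ---
    pooled = pool_counts(cohort, config.level)
    chisq = chisq_groups_by_choice(
        [(p.n_toward, p.n_trials_total - p.n_toward) for p in pooled]
    )
    contrasts = pooled_contrasts(pooled, config.level)

    report = {
        "provenance": prov,
        "cohort": {
            "group_labels": cohort.group_labels,
            "group_sizes": cohort.group_sizes(),
            "n_excluded": len(cohort.excluded),
            "excluded_per_group": cohort.provenance["excluded_per_group"],
            "required_trials": cohort.required_trials,
        },
        "robustness": {
            "outlier_screen": outliers,
            "balance": {
                "group_by_lane": balance.group_by_lane,
                "lane_chisq": balance.lane_chisq,
                "lane_imbalance_flag": balance.lane_imbalance_flag,
                "per_side_rates": balance.per_side_rates,
                "notes": balance.notes,
            },
        },
        "location": {
            "summaries": summaries,
            "global": kw,
            "pairwise": loc_pairs,
            "seed_streams": {"global": "location-kw", "pairwise": "location-pairwise"},
        },
        "dispersion": {
            "summaries": disp,
            "global": disp_global,
            "pairwise": disp_pairs,
            "bca": cis,
        },
        "pooled": {
            "descriptive_only": True,
            "proportions": pooled,
            "chisq": {"statistic": chisq[0], "df": chisq[1], "p": chisq[2]},
            "contrasts": contrasts,
        },
    }
    report = _jsonable(report)

    if config.out_dir is not None:
        _write_report(report, cohort, Path(config.out_dir))
    return report


def _write_report(report: dict, cohort: CohortDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fly_table(cohort, out_dir / "flies.tsv")

    pd.DataFrame(report["location"]["summaries"]).to_csv(
        out_dir / "location_summaries.tsv", sep="\t", index=False)
    pd.DataFrame(report["location"]["pairwise"]).to_csv(
        out_dir / "location_pairwise.tsv", sep="\t", index=False)
    pd.DataFrame(report["dispersion"]["summaries"]).merge(
        pd.DataFrame(report["dispersion"]["bca"]),
        left_on="group_label", right_on="group_label", how="left",
    ).to_csv(out_dir / "dispersion_summaries.tsv", sep="\t", index=False)
    pd.DataFrame(report["dispersion"]["pairwise"]).to_csv(
        out_dir / "dispersion_pairwise.tsv", sep="\t", index=False)
    pd.DataFrame(report["pooled"]["proportions"]).to_csv(
        out_dir / "pooled_proportions.tsv", sep="\t", index=False)
    pd.DataFrame(report["pooled"]["contrasts"]).to_csv(
        out_dir / "pooled_contrasts.tsv", sep="\t", index=False)
    (out_dir / "robustness.json").write_text(
        json.dumps(report["robustness"], indent=2))
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    log.info("report written to %s", out_dir)
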