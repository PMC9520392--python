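"""End-to-end orchestration: features -> imputation -> CT-HMM -> ARM -> LRTs.

Each participant is processed independently (sequential by default;
callers may parallelize externally).  Participants whose EM fit fails to
converge — or who carry too little usable data to attempt a fit — are
logged with the reason and excluded from the cohort table, and the run
writes a JSON manifest listing every artifact with the stage parameters
and seeds that produced it.  All randomness flows from one root seed,
split deterministically per participant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dormancy
from .association import ArmScore, associate_all, build_cohort_table, compute_arm
from .cthmm import FitConfig, InsufficientDataError, em_fit
from .features import CsvDialect, HourlySeries, bin_hourly, read_hourly_csv, write_hourly_csv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    input_dir: str  # per-participant subdirectories with raw CSVs
    output_dir: str
    covariates_csv: str | None = None
    tz_offset_hours: float = 0.0
    floor_quantile: float = dormancy.DEFAULT_FLOOR_QUANTILE
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    dialect: CsvDialect = field(default_factory=CsvDialect)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fit = FitConfig(**raw.pop("fit", {}))
        dialect = CsvDialect(**raw.pop("dialect", {}))
        return cls(fit=fit, dialect=dialect, **raw)


@dataclass
class RunResult:
    manifest: dict
    cohort: pd.DataFrame
    results: pd.DataFrame | None
    exclusions: dict[str, str]


def process_participant(
    series: HourlySeries,
    floor_quantile: float = dormancy.DEFAULT_FLOOR_QUANTILE,
    fit_config: FitConfig | None = None,
    hsmm_seed: int = 0,
):
    """Impute one participant's series and fit the CT-HMM.

    Returns ``(fitted, imputed_series, impute_fit)``; degenerate missingness
    falls back to single-branch imputation, and insufficient data surfaces
    as ``InsufficientDataError`` for the caller to treat as an exclusion.
    """
    miss = np.isnan(series.data["X"].to_numpy(dtype=float))
    model = None
    if 0 < miss.sum() < len(series):
        try:
            model = dormancy.fit_dormancy_hsmm(miss.astype(int), seed=hsmm_seed)
        except (dormancy.DegenerateSequenceError, ValueError):
            model = None
    if miss.any():
        imputed, fit = dormancy.impute_accelerometer(series, model, floor_quantile)
    else:
        imputed, fit = series.copy(), None
    fitted = em_fit(imputed, fit_config)
    return fitted, imputed, fit


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline over a directory of per-participant raw CSVs."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    part_dirs = sorted(d for d in in_dir.iterdir() if d.is_dir())
    if not part_dirs:
        raise FileNotFoundError(f"no participant directories under {in_dir}")

    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=len(part_dirs))

    scores: list[ArmScore] = []
    exclusions: dict[str, str] = {}
    manifest: dict = {
        "seed": config.seed,
        "floor_quantile": config.floor_quantile,
        "fit": {"tol": config.fit.tol, "max_iter": config.fit.max_iter, "min_hours": config.fit.min_hours},
        "participants": {},
        "files": [],
    }

    for pdir, pseed in zip(part_dirs, seeds):
        pid = pdir.name
        try:
            hourly_csv = pdir / "hourly.csv"
            if hourly_csv.exists():
                series = read_hourly_csv(hourly_csv)
            else:
                accel = pd.read_csv(pdir / "accelerometer.csv")
                screens_path = pdir / "screen_events.csv"
                screens = pd.read_csv(screens_path) if screens_path.exists() else None
                series = bin_hourly(
                    accel, screens, participant_id=pid,
                    tz_offset_hours=config.tz_offset_hours, dialect=config.dialect,
                )
            feat_path = out_dir / f"{pid}_features.csv"
            write_hourly_csv(series, feat_path)
            fitted, imputed, _ = process_participant(
                series, config.floor_quantile, config.fit, hsmm_seed=int(pseed)
            )
            imp_path = out_dir / f"{pid}_imputed.csv"
            write_hourly_csv(imputed, imp_path)
            model_path = out_dir / f"{pid}_model.json"
            fitted.to_json(model_path)
            manifest["files"] += [str(feat_path), str(imp_path), str(model_path)]
            manifest["participants"][pid] = {"seed": int(pseed), "converged": bool(fitted.converged)}
            score = compute_arm(fitted, pid)
            if score.converged:
                scores.append(score)
            else:
                exclusions[pid] = fitted.message or "EM did not converge"
                logger.warning("excluding %s: %s", pid, exclusions[pid])
        except InsufficientDataError as err:
            exclusions[pid] = str(err)
            manifest["participants"][pid] = {"seed": int(pseed), "converged": False}
            logger.warning("excluding %s: %s", pid, err)

    covariates = (
        pd.read_csv(config.covariates_csv)
        if config.covariates_csv
        else pd.DataFrame({"participant_id": [s.participant_id for s in scores]})
    )
    covariates["participant_id"] = covariates["participant_id"].astype(str)
    cohort = build_cohort_table(scores, covariates)
    cohort_path = out_dir / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    manifest["files"].append(str(cohort_path))

    results = None
    if {"age", "sex"}.issubset(cohort.columns) and len(cohort) >= 5:
        results = associate_all(cohort)
        results_path = out_dir / "results.csv"
        results.to_csv(results_path, index=False)
        manifest["files"].append(str(results_path))

    manifest["exclusions"] = exclusions
    manifest["n_analyzed"] = len(cohort)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return RunResult(manifest=manifest, cohort=cohort, results=results, exclusions=exclusions)
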