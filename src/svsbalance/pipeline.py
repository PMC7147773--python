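"""End-to-end orchestration: simulate → extract → analyze → report.

A run is governed by one :class:`RunConfig`; every stage's parameters are
serialized into the output directory together with a log and a checksum
manifest, so a run is reproducible from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as svs_io
from .errors import SVSError
from .inference import analyze_measures, build_report
from .kinematics import MARKER_NAMES, MeasurementParams, measure_trial
from .synth import CohortSpec, simulate_cohort, simulate_trial, write_fixture_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    seed: int = 0
    out_dir: str = "svs_run"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    measurement: MeasurementParams = field(default_factory=MeasurementParams)
    alpha: float = 0.05
    outlier_threshold: float = 4.0
    write_trials: bool = False  # write trajectory CSVs and read them back

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortSpec(**raw.pop("cohort", {}))
        measurement = MeasurementParams(**raw.pop("measurement", {}))
        return cls(cohort=cohort, measurement=measurement, **raw)


def _measures_rows(meta: dict, tm) -> list:
    rows = []
    for name, value in tm.to_dict().items():
        if value is None or name.startswith("step_width_") and name != "step_width_sd":
            continue
        rows.append({**meta, "measure": name, "value": value})
    return rows


def simulate_and_measure_cohort(
    spec: CohortSpec, params: MeasurementParams | None = None
) -> pd.DataFrame:
    """Generate a full cohort in memory and run the measurement pipeline on it.

    Ground truth is produced by the generator but deliberately discarded
    here: the measurement pipeline sees marker trajectories only.
    """
    params = params or MeasurementParams()
    profiles, factors, manifest = simulate_cohort(spec)
    by_id = {p.participant_id: p for p in profiles}
    rows = []
    for r in manifest.itertuples(index=False):
        cell = (r.task, r.balance, r.stimulation, r.technique)
        trial, _truth = simulate_trial(
            by_id[r.participant], cell, r.seed, spec, factors[r.participant]
        )
        trial.trial_index = r.trial
        rows.extend(_measures_rows(trial.metadata(), measure_trial(trial, params)))
    return pd.DataFrame(rows)


def extract_measures(
    trial_dir, params: MeasurementParams | None = None
) -> pd.DataFrame:
    """Measure every trial listed in ``trial_dir/manifest.csv``."""
    params = params or MeasurementParams()
    trial_dir = Path(trial_dir)
    manifest = pd.read_csv(trial_dir / "manifest.csv")
    rows = []
    for r in manifest.itertuples(index=False):
        meta = {
            "participant": r.participant,
            "task": r.task,
            "balance": r.balance,
            "stimulation": r.stimulation,
            "technique": r.technique,
            "trial": r.trial,
        }
        trial = svs_io.read_trial_csv(trial_dir / r.file, meta)
        try:
            tm = measure_trial(trial, params)
        except SVSError as exc:
            raise SVSError(f"extract failed for {r.file}: {exc}") from exc
        rows.extend(_measures_rows(meta, tm))
    return pd.DataFrame(rows)


def validate_inputs(trial_dir, strict: bool = False) -> pd.DataFrame:
    """Schema-check a trial directory; returns a table of issues (empty = clean)."""
    trial_dir = Path(trial_dir)
    issues = []
    manifest_path = trial_dir / "manifest.csv"
    if not manifest_path.exists():
        return pd.DataFrame(
            [{"file": "manifest.csv", "level": "error", "issue": "missing manifest"}]
        )
    manifest = pd.read_csv(manifest_path)
    required = {"participant", "task", "balance", "stimulation", "technique", "trial", "file"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        issues.append(
            {
                "file": "manifest.csv",
                "level": "error",
                "issue": f"missing metadata columns: {sorted(missing_cols)}",
            }
        )
    dup = manifest.duplicated(
        subset=[c for c in ("participant", "task", "balance", "stimulation", "technique", "trial") if c in manifest.columns]
    )
    for idx in manifest.index[dup]:
        issues.append(
            {
                "file": str(manifest.loc[idx, "file"]),
                "level": "error",
                "issue": "duplicate trial record",
            }
        )
    for r in manifest.itertuples(index=False):
        path = trial_dir / r.file
        if not path.exists():
            issues.append({"file": r.file, "level": "error", "issue": "file not found"})
            continue
        try:
            trial = svs_io.read_trial_csv(path)
        except SVSError as exc:
            issues.append({"file": r.file, "level": "error", "issue": str(exc)})
            continue
        if trial.rate != 120:
            issues.append(
                {
                    "file": r.file,
                    "level": "warning",
                    "issue": f"rate_hz={trial.rate:g} (expected 120; measures still computable)",
                }
            )
        for name in MARKER_NAMES:
            if name not in trial.markers:
                issues.append(
                    {"file": r.file, "level": "error", "issue": f"missing marker {name}"}
                )
    report = pd.DataFrame(issues, columns=["file", "level", "issue"])
    if strict and (report["level"] == "error").any():
        raise SVSError(f"validation failed with {len(report)} issue(s)")
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of artifact paths.

    The output directory receives a copy of the config, a run log, the
    per-trial measures, the per-task ANOVA tables, post-hoc and outlier
    tables, a plain-text summary, and a checksum manifest of every artifact.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("svsbalance")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        spec = dataclasses.replace(config.cohort, seed=config.seed)
        config.to_yaml(out / "config.yaml")
        logger.info("run parameters: %s", dataclasses.asdict(config))

        stage = "simulate"
        if config.write_trials:
            dataset_dir = out / "dataset"
            write_fixture_dataset(dataset_dir, spec)
            stage = "validate"
            validation = validate_inputs(dataset_dir)
            validation.to_csv(out / "validation.csv", index=False)
            stage = "extract"
            measures = extract_measures(dataset_dir, config.measurement)
        else:
            stage = "extract"
            measures = simulate_and_measure_cohort(spec, config.measurement)
        svs_io.write_measures_csv(measures, out / "measures.csv")

        stage = "analyze"
        reports = analyze_measures(
            measures, alpha=config.alpha, outlier_threshold=config.outlier_threshold
        )

        stage = "report"
        tables, text = build_report(reports, alpha=config.alpha)
        for task, table in tables.items():
            table.to_csv(out / f"anova_{task}.csv", index=False)
        posthoc = [
            rep.posthoc.assign(task=task, measure=measure)
            for (task, measure), rep in reports.items()
            if rep.posthoc is not None
        ]
        pd.concat(posthoc, ignore_index=True).to_csv(
            out / "posthoc.csv", index=False
        ) if posthoc else pd.DataFrame(
            columns=["task", "measure", "cell_1", "cell_2", "mean_diff", "q", "p_adj"]
        ).to_csv(out / "posthoc.csv", index=False)
        outliers = [
            rep.outlier_flags.assign(task=task)
            for (task, measure), rep in reports.items()
            if rep.outlier_flags is not None and len(rep.outlier_flags)
        ]
        (
            pd.concat(outliers, ignore_index=True)
            if outliers
            else pd.DataFrame(columns=["task", "measure", "participant", "studentized_residual"])
        ).to_csv(out / "outliers.csv", index=False)
        (out / "summary.txt").write_text(text)

        artifacts = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "artifacts.csv")
        pd.DataFrame(
            [{"file": str(p.relative_to(out)), "sha256": _sha256(p)} for p in artifacts]
        ).to_csv(out / "artifacts.csv", index=False)
        return {"out_dir": str(out), "n_measures": len(measures), "reports": reports}
    except SVSError as exc:
        raise SVSError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
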