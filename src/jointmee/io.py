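"""File formats and the end-to-end study pipeline.

Trial files are plain CSV: a ``percent`` column (0–99) followed by twelve
data columns ``<side>_<joint>_{moment|velocity}`` (N·m, rad·s⁻¹) for the
six bilateral sagittal DOFs.  A study is described by a manifest directory
holding ``subjects.csv`` and ``trials.csv`` plus one trial file per row.

``run_pipeline`` ties the stages together per condition: subject-level
train/validation split, constrained calibration on the training trials,
validation predictions, RMSE tables, Bland–Altman agreement, and the
empirical-equation comparison.  All outputs are deterministic under a
fixed seed and config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import core, empirical, stats
from .calibration import (
    CalibrationResult,
    EmaxPolicy,
    OptimizerConfig,
    TrainingSet,
    calibrate,
)
from .synthetic import SyntheticStudy, condition_name
from .types import (
    DOF_LABELS,
    ConfigurationError,
    GaitTrial,
    NormativeTorques,
    ParameterSet,
    StructuralError,
    SubjectProfile,
)

__all__ = [
    "TRIAL_COLUMNS",
    "StudyManifest",
    "PipelineConfig",
    "read_trial",
    "write_trial",
    "write_study",
    "read_study",
    "run_pipeline",
]

_FLOAT_FMT = "%.10g"


def _trial_columns(dof_labels: Sequence[str]) -> list[str]:
    cols = ["percent"]
    for kind in ("moment", "velocity"):
        cols += [f"{d}_{kind}" for d in dof_labels]
    return cols


TRIAL_COLUMNS: list[str] = _trial_columns(DOF_LABELS)


def write_trial(trial: GaitTrial, path: str | Path) -> None:
    """Write one trial's waveforms in the trial-file CSV schema."""
    df = pd.DataFrame({"percent": np.arange(trial.n_samples, dtype=int)})
    for i, d in enumerate(trial.dof_labels):
        df[f"{d}_moment"] = trial.torques[i]
    for i, d in enumerate(trial.dof_labels):
        df[f"{d}_velocity"] = trial.velocities[i]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trial(
    path: str | Path,
    subject_id: str = "",
    speed: float = 1.0,
    grade: float = 0.0,
    measured_rate: float | None = None,
    dof_labels: Sequence[str] = DOF_LABELS,
    n_samples: int = 100,
) -> GaitTrial:
    """Parse a trial CSV, validating the schema row/column by row/column.

    Columns may appear in any order; they are matched by header name.
    """
    df = pd.read_csv(path)
    expected = _trial_columns(dof_labels)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise StructuralError(f"{path}: missing columns {missing}")
    if len(df) != n_samples:
        raise StructuralError(f"{path}: expected {n_samples} data rows, found {len(df)}")
    pct = df["percent"].to_numpy()
    if not np.array_equal(pct, np.arange(n_samples)):
        raise StructuralError(f"{path}: percent column must be 0..{n_samples - 1}")
    for col in expected:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise StructuralError(f"{path}: non-numeric cell at row {row}, column {col!r}")
    torques = np.vstack([df[f"{d}_moment"].to_numpy(float) for d in dof_labels])
    velocities = np.vstack([df[f"{d}_velocity"].to_numpy(float) for d in dof_labels])
    return GaitTrial(
        subject_id=subject_id,
        speed=speed,
        grade=grade,
        torques=torques,
        velocities=velocities,
        measured_rate=measured_rate,
        dof_labels=tuple(dof_labels),
    )


@dataclass(frozen=True)
class StudyManifest:
    """Subjects and trials tables anchoring a study directory.

    ``subjects``: id, sex, mass, height, age, tau_knee_max (optional).
    ``trials``: subject_id, speed, grade, trial_file, measured_rate
    (W·kg⁻¹, optional).  Every trial must reference a known subject and an
    existing file.
    """

    root: Path
    subjects: pd.DataFrame
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        ids = set(self.subjects["id"])
        unknown = set(self.trials["subject_id"]) - ids
        if unknown:
            raise ConfigurationError(f"trials reference unknown subjects: {sorted(unknown)}")
        for f in self.trials["trial_file"]:
            if not (self.root / f).exists():
                raise ConfigurationError(f"missing trial file: {f}")

    def subject_profiles(self) -> dict[str, SubjectProfile]:
        out = {}
        for _, row in self.subjects.iterrows():
            tau = row.get("tau_knee_max")
            out[row["id"]] = SubjectProfile(
                subject_id=str(row["id"]),
                mass=float(row["mass"]),
                height=float(row["height"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                tau_knee_max=None if pd.isna(tau) else float(tau),
            )
        return out

    def load_trials(self) -> list[tuple[GaitTrial, SubjectProfile]]:
        profiles = self.subject_profiles()
        out = []
        for _, row in self.trials.iterrows():
            rate = row.get("measured_rate")
            trial = read_trial(
                self.root / row["trial_file"],
                subject_id=str(row["subject_id"]),
                speed=float(row["speed"]),
                grade=float(row["grade"]),
                measured_rate=None if pd.isna(rate) else float(rate),
            )
            out.append((trial, profiles[trial.subject_id]))
        return out


def write_study(study: SyntheticStudy, out_dir: str | Path) -> StudyManifest:
    """Materialise an in-memory study as a manifest directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subj_rows = [
        {
            "id": s.subject_id, "sex": s.sex, "mass": s.mass,
            "height": s.height, "age": s.age, "tau_knee_max": s.tau_knee_max,
        }
        for s in study.subjects
    ]
    trial_rows = []
    for tr in study.trials:
        fname = f"trial_{tr.subject_id}_{condition_name(tr.grade)}_{tr.speed:g}.csv"
        write_trial(tr, out / fname)
        trial_rows.append(
            {
                "subject_id": tr.subject_id, "speed": tr.speed, "grade": tr.grade,
                "trial_file": fname, "measured_rate": tr.measured_rate,
            }
        )
    subjects = pd.DataFrame(subj_rows)
    trials = pd.DataFrame(trial_rows)
    subjects.to_csv(out / "subjects.csv", index=False, float_format=_FLOAT_FMT)
    trials.to_csv(out / "trials.csv", index=False, float_format=_FLOAT_FMT)
    return StudyManifest(root=out, subjects=subjects, trials=trials)


def read_study(root: str | Path) -> StudyManifest:
    root = Path(root)
    return StudyManifest(
        root=root,
        subjects=pd.read_csv(root / "subjects.csv"),
        trials=pd.read_csv(root / "trials.csv"),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline settings: the subject split, solver config, and bounds policy.

    The train/validation split is by subject (both speeds of a subject stay
    together); with ``train_subjects=None`` the first two thirds of the
    cohort (alternating sexes, hence sex-balanced) train and the rest
    validate.
    """

    train_subjects: tuple[str, ...] | None = None
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    emax: EmaxPolicy = field(default_factory=EmaxPolicy.default)
    norms: NormativeTorques = field(default_factory=NormativeTorques)
    conditions: tuple[str, ...] = ("level", "uphill", "downhill")
    include_basal: bool = True


def _default_split(subject_ids: Sequence[str]) -> tuple[list[str], list[str]]:
    n_train = max(1, round(len(subject_ids) * 2 / 3))
    return list(subject_ids[:n_train]), list(subject_ids[n_train:])


def run_pipeline(
    manifest: StudyManifest,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Calibrate, validate, and compare, per walking condition.

    Returns a results bundle keyed by condition with the calibration
    result, per-trial predictions, RMSE summary, Bland–Altman report, and
    the empirical-model comparison table; when ``out_dir`` is given all
    tables are also written as CSV/JSON with the seed and config echoed.
    """
    cfg = config or PipelineConfig()
    pairs = manifest.load_trials()
    if any(tr.measured_rate is None for tr, _ in pairs):
        raise ConfigurationError("every trial needs measured_rate for the pipeline")
    subject_ids = list(manifest.subjects["id"])
    if cfg.train_subjects is None:
        train_ids, val_ids = _default_split(subject_ids)
    else:
        train_ids = list(cfg.train_subjects)
        val_ids = [s for s in subject_ids if s not in train_ids]
    if not val_ids:
        raise ConfigurationError("train/validation split leaves no validation subjects")

    results: dict = {"train_subjects": train_ids, "validation_subjects": val_ids,
                     "seed": cfg.optimizer.seed, "conditions": {}}
    rmse_rows = []
    for condition in cfg.conditions:
        cond_pairs = [
            (tr, s) for tr, s in pairs if condition_name(tr.grade) == condition
        ]
        if not cond_pairs:
            continue
        train_pairs = [(t, s) for t, s in cond_pairs if t.subject_id in train_ids]
        val_pairs = [(t, s) for t, s in cond_pairs if t.subject_id in val_ids]
        training = TrainingSet(
            condition=condition,
            trials=tuple(train_pairs),
            measured_cost=np.array([t.measured_cost for t, _ in train_pairs]),
        )
        fit = calibrate(
            training, cfg.norms, cfg.emax, cfg.optimizer, include_basal=cfg.include_basal
        )

        def _predict(pairs_):
            pred, meas = [], []
            for tr, subj in pairs_:
                bd = core.metabolic_rate_series(
                    tr, subj, fit.params, cfg.norms, include_basal=cfg.include_basal
                )
                pred.append(core.metabolic_cost(bd, subj, tr.speed))
                meas.append(tr.measured_cost)
            return np.array(pred), np.array(meas)

        pred_tr, meas_tr = _predict(train_pairs)
        pred_va, meas_va = _predict(val_pairs)
        agreement = stats.bland_altman(pred_va, meas_va)
        comparison = _empirical_comparison(val_pairs, pred_va, meas_va)
        results["conditions"][condition] = {
            "calibration": fit,
            "feasible": fit.feasible,
            "train_rmse": stats.rmse(pred_tr, meas_tr),
            "validation_rmse": stats.rmse(pred_va, meas_va),
            "predictions": pd.DataFrame(
                {
                    "subject_id": [t.subject_id for t, _ in val_pairs],
                    "speed": [t.speed for t, _ in val_pairs],
                    "measured_cost": meas_va,
                    "predicted_cost": pred_va,
                }
            ),
            "bland_altman": agreement,
            "comparison": comparison,
        }
        rmse_rows += [
            {"group": "training", "condition": condition,
             "n": len(train_pairs), "rmse": stats.rmse(pred_tr, meas_tr)},
            {"group": "validation", "condition": condition,
             "n": len(val_pairs), "rmse": stats.rmse(pred_va, meas_va)},
        ]
    results["rmse_table"] = pd.DataFrame(rmse_rows)

    if out_dir is not None:
        _write_bundle(results, cfg, Path(out_dir))
    return results


def _empirical_comparison(val_pairs, pred, meas) -> pd.DataFrame:
    """Empirical-equation predictions beside the fitted joint-space model."""
    trials = [
        (s, empirical.WalkingCondition(speed=t.speed, grade=t.grade))
        for t, s in val_pairs
    ]
    rows = []
    preds = {"joint_space_fit": np.asarray(pred)}
    grade = trials[0][1].grade
    if grade >= 0:
        preds["pandolf"] = np.array(
            [empirical.pandolf_cost(s.mass, c) for s, c in trials]
        )
    if grade == 0:
        preds["looney"] = np.array([empirical.looney_cost(c) for _, c in trials])
    meas = np.asarray(meas)
    for name, p in preds.items():
        rows.append(
            {
                "model": name,
                "n": len(p),
                "mean": float(p.mean()),
                "sd": float(p.std(ddof=1)) if len(p) > 1 else 0.0,
                "rmse": stats.rmse(p, meas),
            }
        )
    return pd.DataFrame(rows)


def _write_bundle(results: dict, cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    results["rmse_table"].to_csv(out / "rmse_table.csv", index=False,
                                 float_format=_FLOAT_FMT)
    echo = {
        "seed": cfg.optimizer.seed,
        "train_subjects": results["train_subjects"],
        "validation_subjects": results["validation_subjects"],
        "optimizer": {k: getattr(cfg.optimizer, k)
                      for k in ("swarm_size", "swarm_tol", "local_tol",
                                "penalty_weight", "seed", "swarm_max_iters")},
    }
    (out / "config_echo.json").write_text(json.dumps(echo, indent=2, sort_keys=True))
    for condition, res in results["conditions"].items():
        fit: CalibrationResult = res["calibration"]
        payload = {
            "condition": condition,
            "feasible": fit.feasible,
            "objective_value": fit.objective_value,
            "constraint_report": fit.constraint_report,
            "stage_trace": fit.stage_trace,
            "swarm_seed": fit.swarm_seed,
            "n_objective_evals": fit.n_objective_evals,
            "params": {k: getattr(fit.params, k) for k in
                       ("w0am", "w1am", "w2am", "w3am", "w4am",
                        "w0sl", "w1sl", "w2sl", "w3sl", "w4sl")},
        }
        (out / f"calibration_{condition}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True)
        )
        res["predictions"].to_csv(out / f"predictions_{condition}.csv",
                                  index=False, float_format=_FLOAT_FMT)
        res["comparison"].to_csv(out / f"comparison_{condition}.csv",
                                 index=False, float_format=_FLOAT_FMT)
        ba = res["bland_altman"]
        (out / f"bland_altman_{condition}.json").write_text(
            json.dumps({"bias": ba.bias, "loa_low": ba.loa_low,
                        "loa_high": ba.loa_high, "n_outside": ba.n_outside},
                       indent=2, sort_keys=True)
        )
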