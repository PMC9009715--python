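"""Synthetic gait study generator.

Produces cohorts, gait-cycle waveforms, and "measured" metabolic costs
with the statistical structure the calibration pipeline assumes: 12
subjects (sex-stratified anthropometrics), six conditions per subject
(speeds 0.8 and 1.3 m·s⁻¹ crossed with grades −8/0/+8 %), 100-sample
bilateral hip/knee/ankle moment and velocity waveforms, and measured
costs derived from a known, strictly feasible ground-truth parameter set
plus multiplicative noise.

The waveforms are truncated Fourier series with randomized phases — they
have the shape, scale, and grade/speed trends of averaged gait data but
are *not* biomechanically realistic curves.  Everything is a pure
function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import core
from .calibration import (
    linear_coefficient_constraints,
    multiplier_constraints,
    no_recharge_constraint,
)
from .types import (
    DOF_LABELS,
    DomainError,
    GaitTrial,
    NormativeTorques,
    ParameterSet,
    SubjectProfile,
)

__all__ = [
    "CohortSpec",
    "WaveformSpec",
    "SyntheticStudy",
    "DEFAULT_TRUE_PARAMS",
    "STUDY_CONDITIONS",
    "condition_name",
    "generate_cohort",
    "generate_trial",
    "generate_measured_cost",
    "generate_study",
]

#: Ground-truth weighting parameters used to synthesise measured costs.
#: Chosen strictly feasible for any plausible subject: the affine terms are
#: positive, the strength multipliers stay near 1, and h_sl > 1 makes the
#: no-recharge inequality hold identically (|x| ≥ −x).
DEFAULT_TRUE_PARAMS = ParameterSet(
    w0am=0.30, w1am=1.0e-3, w2am=0.0, w3am=0.0, w4am=5.0e-4,
    w0sl=1.05, w1sl=0.0, w2sl=0.0, w3sl=0.0, w4sl=2.0e-4,
    label="synthetic-truth",
)

#: The six study conditions: (speed m/s, grade %).
STUDY_CONDITIONS: tuple[tuple[float, float], ...] = (
    (1.3, 0.0), (0.8, 0.0), (1.3, 8.0), (0.8, 8.0), (1.3, -8.0), (0.8, -8.0),
)


def condition_name(grade: float) -> str:
    return "level" if grade == 0 else ("uphill" if grade > 0 else "downhill")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size and sex-stratified anthropometric distributions.

    Each distribution entry is (mean, SD); defaults follow a healthy adult
    treadmill cohort (males 74.72 ± 14.73 kg, 1.80 ± 0.08 m, 25.00 ± 5.94 y;
    females 64.30 ± 9.32 kg, 1.68 ± 0.08 m, 22.25 ± 3.95 y).  Sexes
    alternate male/female so any leading split stays sex-balanced.
    """

    n_subjects: int = 12
    male: dict = field(
        default_factory=lambda: {
            "mass": (74.72, 14.73), "height": (1.80, 0.08), "age": (25.00, 5.94)
        }
    )
    female: dict = field(
        default_factory=lambda: {
            "mass": (64.30, 9.32), "height": (1.68, 0.08), "age": (22.25, 3.95)
        }
    )
    seed: int = 0


@dataclass(frozen=True)
class WaveformSpec:
    """Shape and scale of the synthetic joint waveforms.

    Torque amplitudes are N·m per (hip, knee, ankle) at a 70 kg reference
    body and scale linearly with mass; velocity amplitudes are rad·s⁻¹ at
    1.3 m·s⁻¹ and scale linearly with speed.  ``grade_gain`` (per % grade)
    scales torque amplitudes so uphill > level > downhill; ``noise_sd`` is
    a fractional amplitude jitter per trial.
    """

    n_dof: int = 6
    n_samples: int = 100
    torque_amp: tuple[float, float, float] = (50.0, 45.0, 70.0)
    velocity_amp: tuple[float, float, float] = (2.0, 3.5, 2.5)
    harmonics: int = 3
    grade_gain: float = 0.04
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if min(self.torque_amp) <= 0 or min(self.velocity_amp) <= 0:
            raise DomainError("waveform amplitudes must be > 0")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from N(mean, sd) truncated to positive support by rejection."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise DomainError(f"could not draw positive value from N({mean}, {sd})")


def generate_cohort(spec: CohortSpec) -> list[SubjectProfile]:
    """Draw a deterministic cohort; knee torque is imputed by sex."""
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for k in range(spec.n_subjects):
        sex = "male" if k % 2 == 0 else "female"
        dist = spec.male if sex == "male" else spec.female
        subjects.append(
            SubjectProfile(
                subject_id=f"S{k + 1:02d}",
                mass=_truncated_normal(rng, *dist["mass"]),
                height=_truncated_normal(rng, *dist["height"]),
                age=_truncated_normal(rng, *dist["age"]),
                sex=sex,
            )
        )
    return subjects


def _fourier_series(
    rng: np.random.Generator, n_samples: int, harmonics: int
) -> np.ndarray:
    """Random-phase harmonic series over one cycle, normalised to peak 1."""
    t = np.arange(n_samples) / n_samples
    series = np.zeros(n_samples)
    for k in range(1, harmonics + 1):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        series += np.cos(2.0 * np.pi * k * t + phase) / k
    peak = np.abs(series).max()
    return series / peak if peak > 0 else series


def generate_trial(
    subject: SubjectProfile,
    speed: float,
    grade: float,
    spec: WaveformSpec | None = None,
    seed: int = 0,
) -> GaitTrial:
    """Synthesise one averaged gait cycle for a (speed, grade) condition."""
    spec = spec or WaveformSpec()
    rng = np.random.default_rng(seed)
    mass_factor = subject.mass / 70.0
    speed_factor = speed / 1.3
    grade_factor = max(0.2, 1.0 + spec.grade_gain * grade)
    torques = np.empty((spec.n_dof, spec.n_samples))
    velocities = np.empty_like(torques)
    for i in range(spec.n_dof):
        joint = i % 3  # hip, knee, ankle within each leg
        tq_jitter = 1.0 + rng.normal(0.0, spec.noise_sd)
        qd_jitter = 1.0 + rng.normal(0.0, spec.noise_sd)
        torques[i] = (
            spec.torque_amp[joint]
            * mass_factor
            * grade_factor
            * abs(tq_jitter)
            * _fourier_series(rng, spec.n_samples, spec.harmonics)
        )
        velocities[i] = (
            spec.velocity_amp[joint]
            * speed_factor
            * abs(qd_jitter)
            * _fourier_series(rng, spec.n_samples, spec.harmonics)
        )
    labels = DOF_LABELS if spec.n_dof == len(DOF_LABELS) else tuple(
        f"dof_{i}" for i in range(spec.n_dof)
    )
    return GaitTrial(
        subject_id=subject.subject_id,
        speed=speed,
        grade=grade,
        torques=torques,
        velocities=velocities,
        dof_labels=labels,
    )


def generate_measured_cost(
    trial: GaitTrial,
    subject: SubjectProfile,
    true_params: ParameterSet = DEFAULT_TRUE_PARAMS,
    norms: NormativeTorques | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> float:
    """Ground-truth metabolic cost with multiplicative measurement noise.

    Refuses infeasible ground truth (negative coefficient margins or a
    violated no-recharge bound on this trial), which would make the
    resulting fixture unlearnable under the calibration constraints.
    """
    norms = norms or NormativeTorques()
    lin = linear_coefficient_constraints(subject, true_params)
    mult = multiplier_constraints(subject, true_params, norms)
    h = core.compute_heat_coefficients(subject, true_params, norms)
    worst = min(min(lin), mult[0].min(), mult[1].min(), no_recharge_constraint(trial, h))
    if worst < 0:
        raise DomainError(
            f"ground-truth parameters are infeasible (worst margin {worst:.3g})"
        )
    bd = core.metabolic_rate_series(trial, subject, true_params, norms)
    clean = core.metabolic_cost(bd, subject, trial.speed)
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        noisy = clean * (1.0 + rng.normal(0.0, noise_sd)) if noise_sd > 0 else clean
        if noisy > 0:
            return float(noisy)
    raise DomainError("could not draw a positive noisy cost")


@dataclass(frozen=True)
class SyntheticStudy:
    """A full in-memory synthetic study: cohort plus all condition trials."""

    subjects: tuple[SubjectProfile, ...]
    trials: tuple[GaitTrial, ...]
    true_params: ParameterSet
    norms: NormativeTorques
    seed: int

    def trials_for(
        self, condition: str, subject_ids: Sequence[str] | None = None
    ) -> list[tuple[GaitTrial, SubjectProfile]]:
        by_id = {s.subject_id: s for s in self.subjects}
        out = []
        for tr in self.trials:
            if condition_name(tr.grade) != condition:
                continue
            if subject_ids is not None and tr.subject_id not in subject_ids:
                continue
            out.append((tr, by_id[tr.subject_id]))
        return out


def generate_study(
    n_subjects: int = 12,
    seed: int = 0,
    noise_sd: float = 0.05,
    true_params: ParameterSet = DEFAULT_TRUE_PARAMS,
    cohort_spec: CohortSpec | None = None,
    waveform_spec: WaveformSpec | None = None,
    norms: NormativeTorques | None = None,
    conditions: Sequence[tuple[float, float]] = STUDY_CONDITIONS,
) -> SyntheticStudy:
    """Generate the full study: cohort × six conditions, with measured costs.

    All per-trial randomness is derived from ``seed`` through a single
    generator, so the study is reproducible end to end.
    """
    cohort_spec = cohort_spec or CohortSpec(n_subjects=n_subjects, seed=seed)
    waveform_spec = waveform_spec or WaveformSpec()
    norms = norms or NormativeTorques()
    subjects = generate_cohort(cohort_spec)
    master = np.random.default_rng(seed)
    trials = []
    for subject in subjects:
        for speed, grade in conditions:
            trial_seed = int(master.integers(0, 2**31 - 1))
            noise_seed = int(master.integers(0, 2**31 - 1))
            trial = generate_trial(subject, speed, grade, waveform_spec, trial_seed)
            cost = generate_measured_cost(
                trial, subject, true_params, norms, noise_sd, noise_seed
            )
            trials.append(
                GaitTrial(
                    subject_id=trial.subject_id,
                    speed=trial.speed,
                    grade=trial.grade,
                    torques=trial.torques,
                    velocities=trial.velocities,
                    measured_rate=cost * speed,  # store as W·kg⁻¹
                    dof_labels=trial.dof_labels,
                )
            )
    return SyntheticStudy(
        subjects=tuple(subjects),
        trials=tuple(trials),
        true_params=true_params,
        norms=norms,
        seed=seed,
    )
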