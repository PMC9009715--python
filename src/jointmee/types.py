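"""Domain types for the joint-space metabolic energy expenditure model.

The model operates on averaged gait cycles: per-trial joint moments (N·m)
and joint angular velocities (rad·s⁻¹) for the six sagittal lower-extremity
degrees of freedom (hip flexion, knee flexion, ankle dorsiflexion,
bilaterally), resampled to 100 uniformly spaced points over one cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

__all__ = [
    "DOF_LABELS",
    "DomainError",
    "StructuralError",
    "InvalidParameterError",
    "ConfigurationError",
    "SubjectProfile",
    "GaitTrial",
    "ParameterSet",
    "NormativeTorques",
    "HeatCoefficients",
    "EnergyBreakdown",
    "load_parameter_set",
    "TAU_KNEE_MAX_MALE",
    "TAU_KNEE_MAX_FEMALE",
]

#: Canonical degree-of-freedom ordering: right leg then left leg,
#: proximal to distal within each leg.
DOF_LABELS: tuple[str, ...] = (
    "r_hip_flexion",
    "r_knee_flexion",
    "r_ankle_dorsiflexion",
    "l_hip_flexion",
    "l_knee_flexion",
    "l_ankle_dorsiflexion",
)

#: Population-average maximum isometric knee extension torque (N·m),
#: used to impute a subject's maximum when it was not measured.
TAU_KNEE_MAX_MALE = 212.4
TAU_KNEE_MAX_FEMALE = 107.6


class DomainError(ValueError):
    """An input is outside the physical/statistical domain of an operation."""


class StructuralError(ValueError):
    """Array shapes or table layout do not match the declared schema."""


class InvalidParameterError(ValueError):
    """A weighting-parameter set contains non-finite or malformed entries."""


class ConfigurationError(ValueError):
    """A required configuration entry is missing or inconsistent."""


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics and strength measure feeding the heat coefficients.

    Parameters
    ----------
    mass : float
        Body mass M in kg.
    height : float
        Stature H in m.
    age : float
        Age A in years.
    sex : str
        ``"male"`` or ``"female"``.
    tau_knee_max : float, optional
        Maximum isometric knee extension torque in N·m.  When not measured
        it is imputed from population averages by sex (212.4 N·m male,
        107.6 N·m female).
    """

    subject_id: str
    mass: float
    height: float
    age: float
    sex: str
    tau_knee_max: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.tau_knee_max is None:
            imputed = TAU_KNEE_MAX_MALE if self.sex == "male" else TAU_KNEE_MAX_FEMALE
            object.__setattr__(self, "tau_knee_max", imputed)
        for name in ("mass", "height", "age", "tau_knee_max"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class GaitTrial:
    """One averaged gait cycle under a (speed, grade) condition.

    ``torques`` and ``velocities`` are ``(n_dof, n_samples)`` arrays in N·m
    and rad·s⁻¹ sharing DOF order ``dof_labels``; samples are uniformly
    spaced over one full cycle.  ``measured_rate`` is the gross metabolic
    rate from indirect calorimetry in W·kg⁻¹, when available.
    """

    subject_id: str
    speed: float
    grade: float
    torques: np.ndarray
    velocities: np.ndarray
    measured_rate: float | None = None
    dof_labels: tuple[str, ...] = DOF_LABELS

    def __post_init__(self) -> None:
        tq = np.asarray(self.torques, dtype=float)
        qd = np.asarray(self.velocities, dtype=float)
        object.__setattr__(self, "torques", tq)
        object.__setattr__(self, "velocities", qd)
        if tq.ndim != 2 or tq.shape != qd.shape:
            raise StructuralError(
                f"torques {tq.shape} and velocities {qd.shape} must be equal 2-D shapes"
            )
        if tq.shape[0] != len(self.dof_labels):
            raise StructuralError(
                f"{tq.shape[0]} DOF rows but {len(self.dof_labels)} dof_labels"
            )
        if not (np.isfinite(tq).all() and np.isfinite(qd).all()):
            raise StructuralError("torque/velocity arrays must be finite")
        if self.speed <= 0:
            raise DomainError(f"speed must be > 0, got {self.speed}")

    @property
    def n_dof(self) -> int:
        return self.torques.shape[0]

    @property
    def n_samples(self) -> int:
        return self.torques.shape[1]

    @property
    def measured_cost(self) -> float | None:
        """Measured metabolic cost in J·kg⁻¹·m⁻¹ (rate divided by speed)."""
        if self.measured_rate is None:
            return None
        return self.measured_rate / self.speed


#: Serialization order of the weighting vector w.
W_NAMES: tuple[str, ...] = (
    "w0am", "w1am", "w2am", "w3am", "w4am",
    "w0sl", "w1sl", "w2sl", "w3sl", "w4sl",
)


@dataclass(frozen=True)
class ParameterSet:
    """The 10 weighting parameters of the heat-coefficient model.

    ``w0am..w3am`` form the affine anthropometric term of the
    torque-associated coefficient; ``w4am`` scales its strength-dependent
    multiplier; the ``sl`` family does the same for the joint-power
    coefficient.  Units are such that h_am·|τ| and h_sl·|τ·q̇| are watts.
    """

    w0am: float
    w1am: float
    w2am: float
    w3am: float
    w4am: float
    w0sl: float
    w1sl: float
    w2sl: float
    w3sl: float
    w4sl: float
    label: str = ""

    def __post_init__(self) -> None:
        vec = self.as_vector()
        if not np.isfinite(vec).all():
            raise InvalidParameterError(f"non-finite weighting parameters: {vec}")

    def as_vector(self) -> np.ndarray:
        """Return w = [w0am..w4am, w0sl..w4sl] as a length-10 array."""
        return np.array([getattr(self, n) for n in W_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, w, label: str = "") -> "ParameterSet":
        w = np.asarray(w, dtype=float)
        if w.shape != (10,):
            raise InvalidParameterError(f"expected 10 parameters, got shape {w.shape}")
        return cls(**dict(zip(W_NAMES, w.tolist())), label=label)

    def relabel(self, label: str) -> "ParameterSet":
        return replace(self, label=label)


@dataclass(frozen=True)
class NormativeTorques:
    """Population reference torques entering the coefficient multiplier.

    ``tau_knee_avg_max`` is the average human's maximum knee torque
    (denominator of the strength ratio); ``tau_i_avg_max`` is the average
    maximum torque per DOF.  Defaults of 160 N·m (midpoint of the
    sex-specific knee averages) are configurable stand-ins: calibration
    re-estimates the w4 weights, which absorb this scale.
    """

    tau_knee_avg_max: float = 160.0
    tau_i_avg_max: np.ndarray = field(
        default_factory=lambda: np.full(len(DOF_LABELS), 160.0)
    )

    def __post_init__(self) -> None:
        arr = np.asarray(self.tau_i_avg_max, dtype=float)
        object.__setattr__(self, "tau_i_avg_max", arr)
        if self.tau_knee_avg_max <= 0 or (arr <= 0).any() or not np.isfinite(arr).all():
            raise DomainError("normative torques must be finite and > 0")


@dataclass(frozen=True)
class HeatCoefficients:
    """Per-DOF heat coefficients: h_am (W per N·m) and h_sl (dimensionless)."""

    h_am: np.ndarray
    h_sl: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.h_am, dtype=float)
        s = np.asarray(self.h_sl, dtype=float)
        object.__setattr__(self, "h_am", a)
        object.__setattr__(self, "h_sl", s)
        if a.shape != s.shape or a.ndim != 1:
            raise StructuralError("h_am and h_sl must be 1-D arrays of equal length")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Time-resolved energy budget of one gait cycle.

    ``rate_series`` is the total metabolic rate Ė_met(t) in W;
    ``work_rate_series`` the internal mechanical work rate; the heat series
    is the net heat-liberation rate; ``basal_rate`` the non-muscular term.
    ``cost_per_kg_per_m`` is the per-distance metabolic cost E^M.
    """

    rate_series: np.ndarray
    work_rate_series: np.ndarray
    heat_rate_series: np.ndarray
    basal_rate: float
    mean_rate_per_kg: float
    cost_per_kg_per_m: float

    @property
    def mean_rate(self) -> float:
        """Cycle-mean total metabolic rate in W."""
        return float(np.mean(self.rate_series))


def load_parameter_set(label: str) -> ParameterSet:
    """Load a packaged weighting-parameter set by label.

    Available labels: ``roberts2016`` (the original level-walking
    calibration), ``level``, ``uphill``, ``downhill`` (the graded-walking
    recalibrations), and ``swarm_initial_level`` / ``_uphill`` /
    ``_downhill`` (the swarm-stage initial values).
    """
    if label.startswith("swarm_initial_"):
        condition = label.removeprefix("swarm_initial_")
        payload = json.loads(
            resources.files("jointmee.params").joinpath("swarm_initial.json").read_text()
        )
        if condition not in payload:
            raise ConfigurationError(f"no swarm initial values for {condition!r}")
        return ParameterSet(**payload[condition], label=label)
    path = resources.files("jointmee.params").joinpath(f"{label}.json")
    try:
        payload = json.loads(path.read_text())
    except FileNotFoundError:
        raise ConfigurationError(f"unknown parameter-set label {label!r}") from None
    return ParameterSet(**payload, label=label)
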