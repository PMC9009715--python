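"""Joint-space metabolic energy expenditure (MEE) model.

The instantaneous whole-body metabolic rate is decomposed as

    Ė_met(t) = Ẇ_int(t) + [U̇_t(t) − Q̇_ext(t)] + Ė_o

where Ẇ_int = Σ_i τ_i(t)·q̇_i(t) is the internal mechanical work rate over
the n joint degrees of freedom, the bracketed term is the net heat
liberation rate Σ_i h_i^am·|τ_i| + Σ_i h_i^sl·|τ_i·q̇_i|, and Ė_o is the
non-muscular (basal) rate from the Harris–Benedict equations.

The heat coefficients are subject-specific:

    h_i^am = (w0am + w1am·M + w2am·A + w3am·H)
             · (1 + w4am·(τ_knee^max/τ̃_knee^max)·τ̃_i^max)

with mass M (kg), age A (yr), height H (m), the subject's maximum knee
torque τ_knee^max, and population reference torques τ̃; h_i^sl is the same
form with the `sl` weights.  Negative coefficients are *not* clipped here —
feasibility of a weighting-parameter set is the calibration module's job.
"""

from __future__ import annotations

import numpy as np

from .types import (
    DomainError,
    EnergyBreakdown,
    GaitTrial,
    HeatCoefficients,
    NormativeTorques,
    ParameterSet,
    StructuralError,
    SubjectProfile,
)

__all__ = [
    "compute_heat_coefficients",
    "internal_work_rate",
    "heat_rate",
    "basal_rate",
    "metabolic_rate_series",
    "metabolic_cost",
]

# Harris-Benedict coefficients (kcal/day; height in cm) and kcal/day -> W.
_HB_MALE = (66.5, 13.75, 5.003, 6.755)
_HB_FEMALE = (655.1, 9.563, 1.850, 4.676)
_KCAL_PER_DAY_TO_W = 4184.0 / 86400.0


def compute_heat_coefficients(
    subject: SubjectProfile,
    params: ParameterSet,
    norms: NormativeTorques,
) -> HeatCoefficients:
    """Evaluate the per-DOF heat coefficients h_am and h_sl for a subject.

    Returns the raw values; entries may be negative for infeasible
    parameter sets and are deliberately not clipped.
    """
    n = len(norms.tau_i_avg_max)
    lin_am = (
        params.w0am
        + params.w1am * subject.mass
        + params.w2am * subject.age
        + params.w3am * subject.height
    )
    lin_sl = (
        params.w0sl
        + params.w1sl * subject.mass
        + params.w2sl * subject.age
        + params.w3sl * subject.height
    )
    ratio = subject.tau_knee_max / norms.tau_knee_avg_max
    mult_am = 1.0 + params.w4am * ratio * norms.tau_i_avg_max
    mult_sl = 1.0 + params.w4sl * ratio * norms.tau_i_avg_max
    return HeatCoefficients(h_am=lin_am * mult_am, h_sl=lin_sl * mult_sl)


def internal_work_rate(trial: GaitTrial) -> np.ndarray:
    """Per-sample internal mechanical work rate Σ_i τ_i·q̇_i in W.

    May be negative during eccentric (energy-absorbing) phases.
    """
    return np.einsum("it,it->t", trial.torques, trial.velocities)


def heat_rate(trial: GaitTrial, h: HeatCoefficients) -> np.ndarray:
    """Per-sample net heat liberation rate (U̇_t − Q̇_ext) in W.

    Non-negative whenever both coefficient families are non-negative.
    """
    if h.h_am.shape[0] != trial.n_dof:
        raise StructuralError(
            f"{h.h_am.shape[0]} heat coefficients for a {trial.n_dof}-DOF trial"
        )
    abs_tq = np.abs(trial.torques)
    abs_pw = np.abs(trial.torques * trial.velocities)
    return h.h_am @ abs_tq + h.h_sl @ abs_pw


def basal_rate(subject: SubjectProfile) -> float:
    """Basal metabolic rate Ė_o in W via the Harris–Benedict equations."""
    c0, cm, ch, ca = _HB_MALE if subject.sex == "male" else _HB_FEMALE
    kcal_day = c0 + cm * subject.mass + ch * (100.0 * subject.height) - ca * subject.age
    return kcal_day * _KCAL_PER_DAY_TO_W


def metabolic_rate_series(
    trial: GaitTrial,
    subject: SubjectProfile,
    params: ParameterSet,
    norms: NormativeTorques,
    include_basal: bool = True,
) -> EnergyBreakdown:
    """Assemble the full energy budget of one gait cycle.

    The cycle mean is the arithmetic mean of the uniformly spaced samples
    (equivalent to trapezoidal integration on the periodic grid).  With
    ``include_basal`` the Harris–Benedict rate is added so the result is a
    gross rate, directly comparable to calorimetry.
    """
    h = compute_heat_coefficients(subject, params, norms)
    work = internal_work_rate(trial)
    heat = heat_rate(trial, h)
    e0 = basal_rate(subject) if include_basal else 0.0
    total = work + heat + e0
    mean_rate_per_kg = float(np.mean(total)) / subject.mass
    return EnergyBreakdown(
        rate_series=total,
        work_rate_series=work,
        heat_rate_series=heat,
        basal_rate=e0,
        mean_rate_per_kg=mean_rate_per_kg,
        cost_per_kg_per_m=mean_rate_per_kg / trial.speed,
    )


def metabolic_cost(
    breakdown: EnergyBreakdown, subject: SubjectProfile, speed: float
) -> float:
    """Per-distance metabolic cost E^M in J·kg⁻¹·m⁻¹.

    Cost is the cycle-mean rate normalised by body mass and divided by the
    walking speed.
    """
    if speed <= 0:
        raise DomainError(f"speed must be > 0, got {speed}")
    return breakdown.mean_rate / subject.mass / speed
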