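"""Empirical walking-economy equations used for model comparison.

Two closed-form predictors are built in:

* Pandolf: metabolic rate (W) for walking with load,
  Ṁ = 1.5·M + 2.0·(M+L)·(L/M)² + η·(M+L)·(1.5·V² + 0.35·V·G),
  with body mass M (kg), load L (kg), speed V (m·s⁻¹), grade G (%), and
  terrain coefficient η.  With L = 0 the per-mass cost is mass-independent.
* Looney (level): metabolic rate per mass (W·kg⁻¹),
  Ṁ/M = 1.44 + 1.94·S^0.43 + 0.24·S⁴, speed S in m·s⁻¹.

Both are converted to per-distance cost (J·kg⁻¹·m⁻¹) by dividing the
per-mass rate by speed.  Downhill Pandolf (the Santee correction), the
Looney grade terms, and Ludlow & Weyand are accepted as user-supplied
callables/coefficients rather than hard-coded, since their exact constants
are not packaged here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import DomainError, SubjectProfile

__all__ = [
    "WalkingCondition",
    "UnsupportedConditionError",
    "pandolf_cost",
    "looney_cost",
    "model_comparison_table",
]


class UnsupportedConditionError(DomainError):
    """The requested condition needs an extension formula that was not supplied."""


@dataclass(frozen=True)
class WalkingCondition:
    """Speed (m·s⁻¹), signed grade (%), carried load (kg), terrain coefficient."""

    speed: float
    grade: float = 0.0
    load: float = 0.0
    terrain_coeff: float = 1.0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise DomainError(f"speed must be > 0, got {self.speed}")


def pandolf_cost(
    mass: float,
    cond: WalkingCondition,
    downhill_correction: Callable[[float, WalkingCondition], float] | None = None,
) -> float:
    """Pandolf per-distance metabolic cost in J·kg⁻¹·m⁻¹.

    The classic equation covers G ≥ 0; a negative grade requires an
    explicit ``downhill_correction(mass, cond) -> rate_W`` hook (no silent
    extrapolation).
    """
    if mass <= 0:
        raise DomainError(f"mass must be > 0, got {mass}")
    m, l, v, g, eta = mass, cond.load, cond.speed, cond.grade, cond.terrain_coeff
    if g < 0:
        if downhill_correction is None:
            raise UnsupportedConditionError(
                "Pandolf is defined for grade >= 0; supply downhill_correction "
                "for negative grades"
            )
        return downhill_correction(mass, cond) / (m * v)
    rate_w = 1.5 * m + 2.0 * (m + l) * (l / m) ** 2 + eta * (m + l) * (
        1.5 * v**2 + 0.35 * v * g
    )
    return rate_w / (m * v)


def looney_cost(
    cond: WalkingCondition,
    grade_model: Callable[[WalkingCondition], float] | None = None,
) -> float:
    """Looney per-distance metabolic cost in J·kg⁻¹·m⁻¹ (level walking).

    A non-zero grade requires an explicit ``grade_model(cond) -> rate_W_per_kg``
    hook.
    """
    s = cond.speed
    if s <= 0:
        raise DomainError(f"speed must be > 0, got {s}")
    if cond.grade != 0:
        if grade_model is None:
            raise UnsupportedConditionError(
                "the core Looney equation is for level walking; supply grade_model"
            )
        return grade_model(cond) / s
    rate_per_kg = 1.44 + 1.94 * s**0.43 + 0.24 * s**4
    return rate_per_kg / s


def model_comparison_table(
    models: Mapping[str, Callable[[SubjectProfile, WalkingCondition], float]],
    trials: Sequence[tuple[SubjectProfile, WalkingCondition]],
    measured: Sequence[float],
    condition_of: Callable[[WalkingCondition], str] | None = None,
) -> pd.DataFrame:
    """Per-model, per-condition mean ± SD and RMSE against measured cost.

    ``models`` maps a display name to ``f(subject, condition) -> cost``.
    Conditions are labelled by grade sign unless ``condition_of`` overrides.
    Returns a tidy frame with columns
    ``model, condition, n, mean, sd, rmse`` (costs in J·kg⁻¹·m⁻¹; SD is the
    sample standard deviation).
    """
    if len(trials) == 0:
        raise DomainError("empty trial list")
    measured_arr = np.asarray(measured, dtype=float)
    if measured_arr.shape != (len(trials),):
        raise DomainError("measured costs must align with trials")

    def _label(cond: WalkingCondition) -> str:
        if condition_of is not None:
            return condition_of(cond)
        return "level" if cond.grade == 0 else ("uphill" if cond.grade > 0 else "downhill")

    rows = []
    labels = np.array([_label(c) for _, c in trials])
    for name, fn in models.items():
        pred = np.array([fn(subj, cond) for subj, cond in trials])
        for cond_label in dict.fromkeys(labels):  # stable order
            sel = labels == cond_label
            p, m = pred[sel], measured_arr[sel]
            rows.append(
                {
                    "model": name,
                    "condition": cond_label,
                    "n": int(sel.sum()),
                    "mean": float(p.mean()),
                    "sd": float(p.std(ddof=1)) if sel.sum() > 1 else 0.0,
                    "rmse": float(np.sqrt(np.mean((p - m) ** 2))),
                }
            )
    return pd.DataFrame(rows)
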