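"""Constrained calibration of the heat-coefficient weighting parameters.

One parameter set is fitted per walking condition by minimising the mean
squared difference between measured and modelled per-distance metabolic
cost,

    f(w) = Σ_trials (E^Ex − E^M(w))² / N,

subject to (a) non-negativity of both affine coefficient terms for every
training subject, (b) non-negativity of every strength multiplier
1 + w4·(τ_knee^max/τ̃_knee^max)·τ̃_i^max, (c) a per-sample "no recharge"
bound — negative joint work may not pump metabolic energy back:
τ_i·q̇_i + h_i^am·|τ_i| + h_i^sl·|τ_i·q̇_i| ≥ 0 at every grid point of
every training trial — and (d) per-trial bounds 0 ≤ E^M ≤ E^max, where
E^max is a condition/speed-specific multiple (110–115 %) of the measured
cost.

The solve is two-stage: an unbounded global-best particle swarm (100
particles, constraint violations folded in as an additive quadratic
penalty, stopping when the relative improvement of the best penalized
objective stalls below 1e-6), then gradient-based local refinement (SLSQP)
initialised at the swarm best with the constraints enforced explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from . import core
from .types import (
    ConfigurationError,
    DomainError,
    GaitTrial,
    HeatCoefficients,
    NormativeTorques,
    ParameterSet,
    SubjectProfile,
)

__all__ = [
    "TrainingSet",
    "EmaxPolicy",
    "OptimizerConfig",
    "CalibrationResult",
    "objective",
    "linear_coefficient_constraints",
    "multiplier_constraints",
    "no_recharge_constraint",
    "emax_constraint",
    "calibrate",
]

#: Absolute slack allowed on constraint margins when declaring feasibility.
FEASIBILITY_TOL = 1e-8


@dataclass(frozen=True)
class TrainingSet:
    """Trials of one walking condition with their measured costs.

    ``measured_cost`` holds E^Ex in J·kg⁻¹·m⁻¹, aligned with ``trials``.
    """

    condition: str
    trials: tuple[tuple[GaitTrial, SubjectProfile], ...]
    measured_cost: np.ndarray

    def __post_init__(self) -> None:
        mc = np.asarray(self.measured_cost, dtype=float)
        object.__setattr__(self, "measured_cost", mc)
        object.__setattr__(self, "trials", tuple(self.trials))
        if len(self.trials) == 0:
            raise DomainError("training set must contain at least one trial")
        if mc.shape != (len(self.trials),):
            raise DomainError("measured_cost must align with trials")
        if (mc <= 0).any():
            raise DomainError("measured costs must be > 0")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def subjects(self) -> list[SubjectProfile]:
        """Unique subjects, in first-appearance order."""
        seen: dict[str, SubjectProfile] = {}
        for _, subj in self.trials:
            seen.setdefault(subj.subject_id, subj)
        return list(seen.values())


@dataclass(frozen=True)
class EmaxPolicy:
    """Per-(condition, speed) upper-bound fractions for E^max = f·E^Ex."""

    fractions: Mapping[tuple[str, float], float]

    @classmethod
    def default(cls) -> "EmaxPolicy":
        # 110 % everywhere except downhill at the fast speed (115 %).
        return cls(
            fractions={
                ("level", 1.3): 1.10,
                ("level", 0.8): 1.10,
                ("uphill", 1.3): 1.10,
                ("uphill", 0.8): 1.10,
                ("downhill", 1.3): 1.15,
                ("downhill", 0.8): 1.10,
            }
        )

    def fraction(self, condition: str, speed: float) -> float:
        for (cond, spd), frac in self.fractions.items():
            if cond == condition and abs(spd - speed) < 1e-9:
                if frac < 1.0:
                    raise ConfigurationError(
                        f"E^max fraction must be >= 1, got {frac} for {condition}@{speed}"
                    )
                return frac
        raise ConfigurationError(
            f"no E^max fraction configured for condition {condition!r} at {speed} m/s"
        )


#: Internal scaling of the design variables: the solver works in units of
#: these magnitudes so that all ten dimensions are O(1).  The affine
#: weights act on anthropometrics (mass ~70, age ~25, height ~1.7) while
#: the w4 weights multiply a torque ratio ~200, hence the disparity.
DEFAULT_SCALE = (5.0, 0.05, 0.1, 2.0, 0.005, 5.0, 0.05, 0.1, 2.0, 0.005)


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings of the two-stage solver.

    ``swarm_span`` is the width (in scaled units) of the uniform box the
    particles start in — the search itself is unbounded;
    ``penalty_weight=None`` selects the default 1e3·(mean E^Ex)²;
    ``n_refine`` is the number of distinct swarm bests refined locally.
    """

    swarm_size: int = 100
    swarm_tol: float = 1e-6
    swarm_stall_iters: int = 20
    swarm_max_iters: int = 400
    swarm_span: float = 4.0
    local_tol: float = 1e-6
    local_max_iters: int = 300
    n_refine: int = 3
    penalty_weight: float | None = None
    scale: tuple[float, ...] = DEFAULT_SCALE
    seed: int = 0

    @classmethod
    def from_mapping(cls, block: Mapping) -> "OptimizerConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(block) - known
        if unknown:
            raise ConfigurationError(f"unknown optimizer settings: {sorted(unknown)}")
        return cls(**block)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one per-condition calibration."""

    params: ParameterSet
    objective_value: float
    constraint_report: dict[str, float]
    feasible: bool
    swarm_seed: int
    n_objective_evals: int
    stage_trace: dict[str, float]

    @property
    def worst_margin(self) -> float:
        return min(self.constraint_report.values())


# ----------------------------------------------------------------- operations


def objective(
    params: ParameterSet, training: TrainingSet, norms: NormativeTorques
) -> float:
    """Mean squared cost residual Σ(E^Ex − E^M)²/N over the training set.

    This is the reference (readable) path through the full per-trial model;
    the solver uses an algebraically equivalent precomputed form.
    """
    resid = []
    for (trial, subject), measured in zip(training.trials, training.measured_cost):
        bd = core.metabolic_rate_series(trial, subject, params, norms)
        resid.append(measured - core.metabolic_cost(bd, subject, trial.speed))
    r = np.asarray(resid)
    return float(r @ r / training.n_trials)


def linear_coefficient_constraints(
    subject: SubjectProfile, params: ParameterSet
) -> tuple[float, float]:
    """The two affine coefficient terms; feasible iff both are ≥ 0."""
    am = (
        params.w0am
        + params.w1am * subject.mass
        + params.w2am * subject.age
        + params.w3am * subject.height
    )
    sl = (
        params.w0sl
        + params.w1sl * subject.mass
        + params.w2sl * subject.age
        + params.w3sl * subject.height
    )
    return am, sl


def multiplier_constraints(
    subject: SubjectProfile, params: ParameterSet, norms: NormativeTorques
) -> tuple[np.ndarray, np.ndarray]:
    """Per-DOF strength-multiplier margins for both coefficient families."""
    ratio = subject.tau_knee_max / norms.tau_knee_avg_max
    am = 1.0 + params.w4am * ratio * norms.tau_i_avg_max
    sl = 1.0 + params.w4sl * ratio * norms.tau_i_avg_max
    return am, sl


def no_recharge_constraint(trial: GaitTrial, h: HeatCoefficients) -> float:
    """Worst per-(DOF, sample) margin of the no-recharge inequality.

    Feasible iff the minimum of τ·q̇ + h_am·|τ| + h_sl·|τ·q̇| over the
    sampled grid is ≥ 0.
    """
    power = trial.torques * trial.velocities
    margin = (
        power
        + h.h_am[:, None] * np.abs(trial.torques)
        + h.h_sl[:, None] * np.abs(power)
    )
    return float(margin.min())


def emax_constraint(
    model_costs: Sequence[float],
    measured_costs: Sequence[float],
    policy: EmaxPolicy,
    condition: str,
    speeds: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial lower (E^M ≥ 0) and upper (E^max − E^M ≥ 0) margins."""
    em = np.asarray(model_costs, dtype=float)
    ex = np.asarray(measured_costs, dtype=float)
    if em.shape != ex.shape or em.shape != (len(speeds),):
        raise DomainError("model costs, measured costs and speeds must align")
    fracs = np.array([policy.fraction(condition, s) for s in speeds])
    return em.copy(), fracs * ex - em


# ------------------------------------------------------- fast problem kernel


class _Problem:
    """Precomputed per-trial features making w -> (objective, margins) cheap.

    For each trial only the cycle-mean work rate, per-DOF mean |τ| and
    |τ·q̇|, the basal rate, and the full |τ|/power grids (for the
    no-recharge margin) are needed; the objective is then affine-quadratic
    in the coefficient families.
    """

    def __init__(
        self,
        training: TrainingSet,
        norms: NormativeTorques,
        policy: EmaxPolicy,
        include_basal: bool = True,
    ):
        self.training = training
        self.norms = norms
        self.policy = policy
        self.n_evals = 0
        self.trial_feats = []
        for (trial, subj), measured in zip(training.trials, training.measured_cost):
            power = trial.torques * trial.velocities
            e0 = core.basal_rate(subj) if include_basal else 0.0
            self.trial_feats.append(
                {
                    "subject": subj,
                    "speed": trial.speed,
                    "measured": measured,
                    "mean_work": float(power.sum(axis=0).mean()),
                    "mean_abs_tq": np.abs(trial.torques).mean(axis=1),
                    "mean_abs_pw": np.abs(power).mean(axis=1),
                    "abs_tq": np.abs(trial.torques),
                    "abs_pw": np.abs(power),
                    "power": power,
                    "basal": e0,
                    "emax_frac": policy.fraction(training.condition, trial.speed),
                }
            )
        self.subjects = training.subjects()

    def _coeffs(self, w: np.ndarray, subj: SubjectProfile):
        lin_am = w[0] + w[1] * subj.mass + w[2] * subj.age + w[3] * subj.height
        lin_sl = w[5] + w[6] * subj.mass + w[7] * subj.age + w[8] * subj.height
        ratio = subj.tau_knee_max / self.norms.tau_knee_avg_max
        mult_am = 1.0 + w[4] * ratio * self.norms.tau_i_avg_max
        mult_sl = 1.0 + w[9] * ratio * self.norms.tau_i_avg_max
        return lin_am * mult_am, lin_sl * mult_sl

    def model_costs(self, w: np.ndarray) -> np.ndarray:
        costs = np.empty(len(self.trial_feats))
        for k, ft in enumerate(self.trial_feats):
            h_am, h_sl = self._coeffs(w, ft["subject"])
            mean_rate = (
                ft["mean_work"]
                + h_am @ ft["mean_abs_tq"]
                + h_sl @ ft["mean_abs_pw"]
                + ft["basal"]
            )
            costs[k] = mean_rate / ft["subject"].mass / ft["speed"]
        return costs

    def objective(self, w: np.ndarray) -> float:
        self.n_evals += 1
        r = self.training.measured_cost - self.model_costs(w)
        return float(r @ r / len(r))

    def margins(self, w: np.ndarray) -> np.ndarray:
        """All constraint margins concatenated; feasible iff all ≥ 0."""
        params = ParameterSet.from_vector(w)
        out: list[float] = []
        for subj in self.subjects:
            am, sl = linear_coefficient_constraints(subj, params)
            out += [am, sl]
            m_am, m_sl = multiplier_constraints(subj, params, self.norms)
            out += m_am.tolist() + m_sl.tolist()
        costs = self.model_costs(w)
        for ft, cost in zip(self.trial_feats, costs):
            h_am, h_sl = self._coeffs(w, ft["subject"])
            margin = (
                ft["power"] + h_am[:, None] * ft["abs_tq"] + h_sl[:, None] * ft["abs_pw"]
            )
            out.append(float(margin.min()))
            out += [cost, ft["emax_frac"] * ft["measured"] - cost]
        return np.asarray(out)

    def margin_report(self, w: np.ndarray) -> dict[str, float]:
        params = ParameterSet.from_vector(w)
        lin_am = min(
            linear_coefficient_constraints(s, params)[0] for s in self.subjects
        )
        lin_sl = min(
            linear_coefficient_constraints(s, params)[1] for s in self.subjects
        )
        mult_am = min(
            multiplier_constraints(s, params, self.norms)[0].min()
            for s in self.subjects
        )
        mult_sl = min(
            multiplier_constraints(s, params, self.norms)[1].min()
            for s in self.subjects
        )
        costs = self.model_costs(w)
        no_recharge = min(
            float(
                (
                    ft["power"]
                    + self._coeffs(w, ft["subject"])[0][:, None] * ft["abs_tq"]
                    + self._coeffs(w, ft["subject"])[1][:, None] * ft["abs_pw"]
                ).min()
            )
            for ft in self.trial_feats
        )
        lower = float(costs.min())
        upper = float(
            min(
                ft["emax_frac"] * ft["measured"] - c
                for ft, c in zip(self.trial_feats, costs)
            )
        )
        return {
            "linear_am": lin_am,
            "linear_sl": lin_sl,
            "multiplier_am": mult_am,
            "multiplier_sl": mult_sl,
            "no_recharge": no_recharge,
            "emax_lower": lower,
            "emax_upper": upper,
        }

    def penalized(self, w: np.ndarray, weight: float) -> float:
        viol = np.minimum(self.margins(w), 0.0)
        return self.objective(w) + weight * float(viol @ viol)


def _particle_swarm(
    pen, weight: float, cfg: OptimizerConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded global-best particle swarm on the penalized objective.

    Operates in the solver's scaled coordinates.  Returns the personal
    bests (positions, values), sorted best-first, so the caller can refine
    several distinct candidates.
    """
    n, dim = cfg.swarm_size, 10
    span = cfg.swarm_span
    x = rng.uniform(-span / 2.0, span / 2.0, size=(n, dim))
    x[0] = 0.0  # the zero-coefficient point is always evaluated
    v = np.zeros_like(x)
    f = np.array([pen(xi) for xi in x])
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])

    chi, c1, c2 = 0.7298, 1.49618, 1.49618
    stall = 0
    for _ in range(cfg.swarm_max_iters):
        r1 = rng.uniform(size=(n, dim))
        r2 = rng.uniform(size=(n, dim))
        v = chi * (v + c1 * r1 * (pbest_x - x) + c2 * r2 * (gbest_x - x))
        np.clip(v, -span, span, out=v)
        x = x + v
        f = np.array([pen(xi) for xi in x])
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        new_best = float(pbest_f[g])
        rel_change = (gbest_f - new_best) / max(abs(gbest_f), 1e-12)
        if new_best < gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), new_best
        stall = stall + 1 if rel_change < cfg.swarm_tol else 0
        if stall >= cfg.swarm_stall_iters:
            break
    order = np.argsort(pbest_f)
    return pbest_x[order], pbest_f[order]


def calibrate(
    training: TrainingSet,
    norms: NormativeTorques | None = None,
    policy: EmaxPolicy | None = None,
    config: OptimizerConfig | None = None,
    include_basal: bool = True,
) -> CalibrationResult:
    """Fit one weighting-parameter set to a condition's training trials.

    Stage 1 explores with an unbounded particle swarm on the
    penalty-augmented objective; stage 2 refines the swarm best with SLSQP
    under the explicit inequality constraints.  The refined point is kept
    only if it does not worsen the penalized objective, so the stage trace
    is monotone.  Results are fully determined by ``config.seed``.
    """
    norms = norms or NormativeTorques()
    policy = policy or EmaxPolicy.default()
    cfg = config or OptimizerConfig()
    problem = _Problem(training, norms, policy, include_basal=include_basal)
    weight = (
        cfg.penalty_weight
        if cfg.penalty_weight is not None
        else 1e3 * float(np.mean(training.measured_cost)) ** 2
    )
    scale = np.asarray(cfg.scale, dtype=float)

    def pen(z: np.ndarray) -> float:
        return problem.penalized(z * scale, weight)

    rng = np.random.default_rng(cfg.seed)
    cand_z, cand_f = _particle_swarm(pen, weight, cfg, rng)
    z_swarm, f_swarm_pen = cand_z[0], float(cand_f[0])

    z_ref, f_ref_pen = z_swarm, f_swarm_pen
    for z0 in cand_z[: max(1, cfg.n_refine)]:
        res = minimize(
            lambda z: problem.objective(z * scale),
            z0,
            method="SLSQP",
            constraints=[{"type": "ineq", "fun": lambda z: problem.margins(z * scale)}],
            options={"ftol": cfg.local_tol, "maxiter": cfg.local_max_iters},
        )
        f_pen = pen(np.asarray(res.x, dtype=float))
        if f_pen < f_ref_pen:
            z_ref, f_ref_pen = np.asarray(res.x, dtype=float), f_pen

    # Minimum-norm polish: the model is over-parameterized, so many weight
    # vectors fit the training costs almost equally well but extrapolate very
    # differently.  The mean-of-N-squared-residuals objective carries a
    # relative sampling error of about sqrt(2/N); objective differences
    # inside that band (plus an absolute floor below measurement precision)
    # are statistically indistinguishable, so among such points the solver
    # prefers the smallest coefficients in scaled units (the
    # one-standard-error rule).  The polish is accepted only if it keeps the
    # stage trace monotone.
    f_best = problem.objective(z_ref * scale)
    f_allow = (
        f_best * (1.0 + np.sqrt(2.0 / training.n_trials))
        + (1e-3 * float(np.mean(training.measured_cost))) ** 2
    )
    polish = minimize(
        lambda z: float(z @ z),
        z_ref,
        method="SLSQP",
        constraints=[
            {"type": "ineq", "fun": lambda z: problem.margins(z * scale)},
            {"type": "ineq", "fun": lambda z: f_allow - problem.objective(z * scale)},
        ],
        options={"ftol": 1e-8, "maxiter": cfg.local_max_iters},
    )
    z_pol = np.asarray(polish.x, dtype=float)
    f_pol_pen = pen(z_pol)
    if (
        polish.success
        and problem.objective(z_pol * scale) <= f_allow * (1.0 + 1e-6)
        and f_pol_pen <= f_swarm_pen
        and float(z_pol @ z_pol) < float(z_ref @ z_ref)
    ):
        z_ref, f_ref_pen = z_pol, f_pol_pen
    w_ref = z_ref * scale

    report = problem.margin_report(w_ref)
    feasible = min(report.values()) >= -FEASIBILITY_TOL
    return CalibrationResult(
        params=ParameterSet.from_vector(w_ref, label=f"fit:{training.condition}"),
        objective_value=problem.objective(w_ref),
        constraint_report=report,
        feasible=feasible,
        swarm_seed=cfg.seed,
        n_objective_evals=problem.n_evals,
        stage_trace={"swarm": f_swarm_pen, "refined": f_ref_pen},
    )
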