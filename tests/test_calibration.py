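"""Calibration: constraint margins, objective oracle, and the two-stage solver."""

import numpy as np
import pytest

from jointmee import (
    EmaxPolicy,
    GaitTrial,
    HeatCoefficients,
    NormativeTorques,
    OptimizerConfig,
    ParameterSet,
    SubjectProfile,
    TrainingSet,
    calibrate,
    emax_constraint,
    linear_coefficient_constraints,
    multiplier_constraints,
    no_recharge_constraint,
    objective,
)
from jointmee.calibration import _Problem
from jointmee.synthetic import DEFAULT_TRUE_PARAMS, generate_study
from jointmee.types import ConfigurationError, DomainError


def small_training_set(seed=0, noise_sd=0.0, condition="level"):
    study = generate_study(n_subjects=6, seed=seed, noise_sd=noise_sd)
    pairs = study.trials_for(condition)
    return study, TrainingSet(
        condition=condition,
        trials=tuple(pairs),
        measured_cost=np.array([t.measured_cost for t, _ in pairs]),
    )


FAST = OptimizerConfig(swarm_size=30, swarm_max_iters=60, swarm_stall_iters=10,
                       n_refine=2, seed=0)


class TestConstraintOperations:
    def test_level_linear_margin_matches_hand_value(self, subject4, level_params):
        am, _ = linear_coefficient_constraints(subject4, level_params)
        assert am == pytest.approx(1.6662, abs=1e-3)

    def test_zero_weights_sit_on_boundary(self, subject4, zero_params):
        assert linear_coefficient_constraints(subject4, zero_params) == (0.0, 0.0)

    def test_negative_intercept_infeasible(self, subject4):
        p = ParameterSet.from_vector([-1.0] + [0.0] * 9)
        am, sl = linear_coefficient_constraints(subject4, p)
        assert am == -1.0 and sl == 0.0

    def test_multiplier_margins_identity_when_w4_zero(self, subject4, zero_params, norms):
        am, sl = multiplier_constraints(subject4, zero_params, norms)
        np.testing.assert_allclose(am, 1.0)
        np.testing.assert_allclose(sl, 1.0)

    def test_multiplier_boundary_construction(self, subject4, norms):
        ratio = subject4.tau_knee_max / norms.tau_knee_avg_max
        w4 = -1.0 / (ratio * norms.tau_i_avg_max[0])
        p = ParameterSet.from_vector([0, 0, 0, 0, w4, 0, 0, 0, 0, 0])
        am, _ = multiplier_constraints(subject4, p, norms)
        assert am[0] == pytest.approx(0.0, abs=1e-14)

    def test_multiplier_matches_direct_formula(self, subject4, level_params, norms):
        am, sl = multiplier_constraints(subject4, level_params, norms)
        ratio = subject4.tau_knee_max / norms.tau_knee_avg_max
        np.testing.assert_allclose(
            am, 1 + level_params.w4am * ratio * norms.tau_i_avg_max, rtol=1e-12
        )
        np.testing.assert_allclose(
            sl, 1 + level_params.w4sl * ratio * norms.tau_i_avg_max, rtol=1e-12
        )

    def test_no_recharge_zero_torques(self):
        tr = GaitTrial("R", 1.0, 0.0, np.zeros((6, 10)), np.zeros((6, 10)))
        h = HeatCoefficients(h_am=np.ones(6), h_sl=np.ones(6))
        assert no_recharge_constraint(tr, h) == 0.0

    def test_no_recharge_algebraic_bound(self, random_trial):
        # h_sl >= 1 and h_am >= 0 imply the margin is non-negative: |x| >= -x
        tr = random_trial(seed=4)
        h = HeatCoefficients(h_am=np.zeros(6), h_sl=np.full(6, 1.0))
        assert no_recharge_constraint(tr, h) >= -1e-12

    def test_no_recharge_matches_double_loop(self, random_trial):
        tr = random_trial(seed=5)
        rng = np.random.default_rng(5)
        h = HeatCoefficients(h_am=rng.uniform(0, 1, 6), h_sl=rng.uniform(0, 1, 6))
        worst = np.inf
        for i in range(tr.n_dof):
            for t in range(tr.n_samples):
                tau, qd = tr.torques[i, t], tr.velocities[i, t]
                worst = min(
                    worst, tau * qd + h.h_am[i] * abs(tau) + h.h_sl[i] * abs(tau * qd)
                )
        assert no_recharge_constraint(tr, h) == pytest.approx(worst, rel=1e-12)

    def test_emax_margins(self):
        policy = EmaxPolicy.default()
        lower, upper = emax_constraint(
            [4.0, 4.8], [4.0, 4.0], policy, "level", [1.3, 0.8]
        )
        np.testing.assert_allclose(lower, [4.0, 4.8])
        np.testing.assert_allclose(upper, [0.4, -0.4])
        with pytest.raises(ConfigurationError):
            EmaxPolicy.default().fraction("level", 2.0)


class TestObjective:
    def test_perfect_fit_is_zero(self, norms):
        study, ts = small_training_set(seed=2, noise_sd=0.0)
        assert objective(study.true_params, ts, norms) == pytest.approx(0.0, abs=1e-18)

    def test_single_trial_residual_squared(self, norms):
        study, ts = small_training_set(seed=2, noise_sd=0.0)
        one = TrainingSet(
            condition=ts.condition,
            trials=ts.trials[:1],
            measured_cost=ts.measured_cost[:1] + 0.5,
        )
        assert objective(study.true_params, one, norms) == pytest.approx(0.25, rel=1e-9)

    def test_matches_hand_rolled_loop(self, norms):
        from jointmee import core

        study, ts = small_training_set(seed=3, noise_sd=0.05)
        params = DEFAULT_TRUE_PARAMS
        total = 0.0
        for (trial, subj), meas in zip(ts.trials, ts.measured_cost):
            bd = core.metabolic_rate_series(trial, subj, params, norms)
            total += (meas - core.metabolic_cost(bd, subj, trial.speed)) ** 2
        assert objective(params, ts, norms) == pytest.approx(
            total / ts.n_trials, rel=1e-12
        )

    def test_fast_problem_kernel_agrees_with_reference_path(self, norms):
        study, ts = small_training_set(seed=4, noise_sd=0.05)
        problem = _Problem(ts, norms, EmaxPolicy.default())
        rng = np.random.default_rng(0)
        for _ in range(10):
            w = rng.normal(0, 1, 10) * np.array([1, .01, .05, 1, 1e-3] * 2)
            p = ParameterSet.from_vector(w)
            assert problem.objective(w) == pytest.approx(
                objective(p, ts, norms), rel=1e-10
            )

    def test_empty_training_set_rejected(self):
        with pytest.raises(DomainError):
            TrainingSet(condition="level", trials=(), measured_cost=np.array([]))


class TestCalibrate:
    def test_noiseless_fit_approaches_the_generating_optimum(self, norms):
        # the generator's own parameters give objective 0, an upper bound the
        # solver must approach: training RMSE below 1% of the mean cost
        study, ts = small_training_set(seed=0, noise_sd=0.0)
        res = calibrate(ts, norms, config=FAST)
        assert objective(study.true_params, ts, norms) == pytest.approx(0.0, abs=1e-18)
        assert np.sqrt(res.objective_value) < 0.01 * float(ts.measured_cost.mean())

    def test_deterministic_under_seed(self, norms):
        _, ts = small_training_set(seed=1, noise_sd=0.02)
        r1 = calibrate(ts, norms, config=FAST)
        r2 = calibrate(ts, norms, config=FAST)
        np.testing.assert_array_equal(r1.params.as_vector(), r2.params.as_vector())
        assert r1.objective_value == r2.objective_value
        assert r1.stage_trace == r2.stage_trace

    def test_monotone_stages_and_feasibility_closure(self, norms):
        _, ts = small_training_set(seed=1, noise_sd=0.02)
        res = calibrate(ts, norms, config=FAST)
        assert res.stage_trace["refined"] <= res.stage_trace["swarm"] + 1e-15
        if res.feasible:
            problem = _Problem(ts, norms, EmaxPolicy.default())
            assert problem.margins(res.params.as_vector()).min() >= -1e-8

    def test_penalty_equals_objective_at_feasible_point(self, norms):
        study, ts = small_training_set(seed=2, noise_sd=0.0)
        problem = _Problem(ts, norms, EmaxPolicy.default())
        w = study.true_params.as_vector()
        assert problem.margins(w).min() >= 0
        assert problem.penalized(w, 1e6) == pytest.approx(
            problem.objective(w), rel=1e-12
        )
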