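"""Unit tests of the energy-model primitives against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jointmee import (
    GaitTrial,
    HeatCoefficients,
    NormativeTorques,
    ParameterSet,
    SubjectProfile,
)
from jointmee.core import (
    basal_rate,
    compute_heat_coefficients,
    heat_rate,
    internal_work_rate,
    metabolic_cost,
    metabolic_rate_series,
)
from jointmee.types import DomainError, InvalidParameterError, StructuralError


def loop_work_rate(trial):
    out = np.zeros(trial.n_samples)
    for t in range(trial.n_samples):
        for i in range(trial.n_dof):
            out[t] += trial.torques[i, t] * trial.velocities[i, t]
    return out


def loop_heat_rate(trial, h):
    out = np.zeros(trial.n_samples)
    for t in range(trial.n_samples):
        for i in range(trial.n_dof):
            tau = trial.torques[i, t]
            out[t] += h.h_am[i] * abs(tau) + h.h_sl[i] * abs(tau * trial.velocities[i, t])
    return out


class TestHeatCoefficients:
    def test_zero_weights_give_zero_coefficients(self, subject4, zero_params, norms):
        h = compute_heat_coefficients(subject4, zero_params, norms)
        assert np.all(h.h_am == 0.0) and np.all(h.h_sl == 0.0)

    def test_level_set_linear_terms_match_hand_arithmetic(
        self, subject4, level_params, norms
    ):
        # hand-evaluated affine terms for the 90.58 kg / 34 y / 1.72 m subject
        lin_am = 4.49 + 1.35e-2 * 90.58 + (-4.87e-2) * 34 + (-1.39) * 1.72
        lin_sl = -1.46 + (-1.44e-2) * 90.58 + 3.55e-3 * 34 + 1.75 * 1.72
        assert lin_am == pytest.approx(1.6662, abs=1e-4)
        assert lin_sl == pytest.approx(0.3663, abs=1e-4)
        h = compute_heat_coefficients(subject4, level_params, norms)
        ratio = subject4.tau_knee_max / norms.tau_knee_avg_max
        expected_am = lin_am * (1 + level_params.w4am * ratio * norms.tau_i_avg_max)
        np.testing.assert_allclose(h.h_am, expected_am, rtol=1e-12)
        expected_sl = lin_sl * (1 + level_params.w4sl * ratio * norms.tau_i_avg_max)
        np.testing.assert_allclose(h.h_sl, expected_sl, rtol=1e-12)

    def test_nonfinite_weights_rejected(self):
        with pytest.raises(InvalidParameterError):
            ParameterSet.from_vector([np.nan] + [0.0] * 9)

    def test_nonpositive_norms_rejected(self):
        with pytest.raises(DomainError):
            NormativeTorques(tau_knee_avg_max=-1.0)


class TestWorkAndHeatRates:
    def test_zero_velocity_means_zero_work(self, random_trial):
        tr = random_trial(seed=1)
        still = GaitTrial(
            "R", 1.3, 0.0, tr.torques, np.zeros_like(tr.velocities),
            dof_labels=tr.dof_labels,
        )
        assert np.all(internal_work_rate(still) == 0.0)

    def test_single_term_product(self):
        tr = GaitTrial(
            "R", 1.0, 0.0,
            torques=np.array([[10.0], [0], [0], [0], [0], [0]]),
            velocities=np.array([[2.0], [0], [0], [0], [0], [0]]),
        )
        assert internal_work_rate(tr)[0] == pytest.approx(20.0)
        h = HeatCoefficients(
            h_am=np.array([0.5, 0, 0, 0, 0, 0]), h_sl=np.array([0.1, 0, 0, 0, 0, 0])
        )
        assert heat_rate(tr, h)[0] == pytest.approx(0.5 * 10 + 0.1 * 20)

    @pytest.mark.parametrize("seed", range(5))
    def test_work_rate_matches_double_loop(self, random_trial, seed):
        tr = random_trial(seed=seed)
        np.testing.assert_allclose(
            internal_work_rate(tr), loop_work_rate(tr), rtol=1e-12
        )

    def test_heat_rate_sign_symmetric(self, random_trial):
        tr = random_trial(seed=7)
        h = HeatCoefficients(h_am=np.full(6, 0.3), h_sl=np.full(6, 0.2))
        flipped = GaitTrial(
            "R", 1.3, 0.0, -tr.torques, -tr.velocities, dof_labels=tr.dof_labels
        )
        np.testing.assert_allclose(heat_rate(tr, h), heat_rate(flipped, h), rtol=1e-12)

    def test_heat_rate_shape_mismatch(self, random_trial):
        tr = random_trial(seed=0)
        h = HeatCoefficients(h_am=np.ones(4), h_sl=np.ones(4))
        with pytest.raises(StructuralError):
            heat_rate(tr, h)

    @given(k=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_torque_scale_covariance(self, k):
        rng = np.random.default_rng(11)
        tq = rng.normal(0, 40, (6, 50))
        qd = rng.normal(0, 2, (6, 50))
        base = GaitTrial("R", 1.3, 0.0, tq, qd)
        scaled = GaitTrial("R", 1.3, 0.0, k * tq, qd)
        np.testing.assert_allclose(
            internal_work_rate(scaled), k * internal_work_rate(base), rtol=1e-9
        )
        h = HeatCoefficients(h_am=np.full(6, 0.4), h_sl=np.zeros(6))
        np.testing.assert_allclose(
            heat_rate(scaled, h), k * heat_rate(base, h), rtol=1e-9
        )


class TestBasalRate:
    def test_male_hand_value(self, subject4):
        # 66.5 + 13.75*90.58 + 5.003*172 - 6.755*34 = 1942.8 kcal/day = 94.08 W
        assert basal_rate(subject4) == pytest.approx(94.08, abs=0.01)

    def test_linearity_in_mass(self):
        a = SubjectProfile("a", mass=70.0, height=1.75, age=30, sex="male")
        b = SubjectProfile("b", mass=80.0, height=1.75, age=30, sex="male")
        dw = basal_rate(b) - basal_rate(a)
        assert dw == pytest.approx(13.75 * 10 * 4184 / 86400, rel=1e-12)

    def test_female_uses_female_coefficients(self):
        m = SubjectProfile("m", mass=65.0, height=1.68, age=25, sex="male")
        f = SubjectProfile("f", mass=65.0, height=1.68, age=25, sex="female")
        assert basal_rate(f) != basal_rate(m)
        expected = (655.1 + 9.563 * 65 + 1.850 * 168 - 4.676 * 25) * 4184 / 86400
        assert basal_rate(f) == pytest.approx(expected, rel=1e-12)


class TestRateSeriesAndCost:
    def test_zero_weights_without_basal_collapses_to_work(
        self, random_trial, subject4, zero_params, norms
    ):
        tr = random_trial(seed=3)
        bd = metabolic_rate_series(tr, subject4, zero_params, norms, include_basal=False)
        np.testing.assert_allclose(bd.rate_series, bd.work_rate_series, rtol=1e-12)

    def test_zero_torques_constant_at_basal(self, subject4, zero_params, norms):
        tr = GaitTrial("R", 1.3, 0.0, np.zeros((6, 100)), np.zeros((6, 100)))
        bd = metabolic_rate_series(tr, subject4, zero_params, norms)
        np.testing.assert_allclose(bd.rate_series, basal_rate(subject4), rtol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_mean_rate_matches_brute_force(
        self, random_trial, subject4, level_params, norms, seed
    ):
        tr = random_trial(seed=seed)
        bd = metabolic_rate_series(tr, subject4, level_params, norms)
        h = compute_heat_coefficients(subject4, level_params, norms)
        per_sample = (
            loop_work_rate(tr) + loop_heat_rate(tr, h) + basal_rate(subject4)
        )
        assert bd.mean_rate == pytest.approx(per_sample.sum() / tr.n_samples, rel=1e-12)

    def test_cost_is_direct_division(self):
        from jointmee.types import EnergyBreakdown

        bd = EnergyBreakdown(
            rate_series=np.full(100, 468.0),
            work_rate_series=np.zeros(100),
            heat_rate_series=np.zeros(100),
            basal_rate=0.0,
            mean_rate_per_kg=468.0 / 90.0,
            cost_per_kg_per_m=4.0,
        )
        subj = SubjectProfile("s", mass=90.0, height=1.8, age=30, sex="male")
        assert metabolic_cost(bd, subj, 1.3) == pytest.approx(4.0, rel=1e-12)
        assert metabolic_cost(bd, subj, 2.6) == pytest.approx(2.0, rel=1e-12)
        with pytest.raises(DomainError):
            metabolic_cost(bd, subj, 0.0)

    def test_units_round_trip(self, random_trial, subject4, level_params, norms):
        tr = random_trial(seed=9)
        bd = metabolic_rate_series(tr, subject4, level_params, norms)
        assert bd.cost_per_kg_per_m * tr.speed * subject4.mass == pytest.approx(
            bd.mean_rate, rel=1e-12
        )
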