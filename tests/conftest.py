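import numpy as np
import pytest

from jointmee import (
    GaitTrial,
    NormativeTorques,
    ParameterSet,
    SubjectProfile,
    load_parameter_set,
)


@pytest.fixture(scope="session")
def norms():
    return NormativeTorques()


@pytest.fixture(scope="session")
def subject4():
    # validation-group male: 90.58 kg, 1.72 m, 34 y; knee torque imputed
    return SubjectProfile("S04", mass=90.58, height=1.72, age=34, sex="male")


@pytest.fixture(scope="session")
def level_params():
    return load_parameter_set("level")


@pytest.fixture
def random_trial():
    """Factory for random, well-formed 6x100 trials."""

    def make(seed=0, n_dof=6, n_samples=100, scale=50.0, speed=1.3, grade=0.0):
        rng = np.random.default_rng(seed)
        labels = tuple(f"dof_{i}" for i in range(n_dof))
        return GaitTrial(
            subject_id="R",
            speed=speed,
            grade=grade,
            torques=rng.normal(0.0, scale, (n_dof, n_samples)),
            velocities=rng.normal(0.0, 2.0, (n_dof, n_samples)),
            dof_labels=labels,
        )

    return make


@pytest.fixture(scope="session")
def zero_params():
    return ParameterSet.from_vector(np.zeros(10), label="zeros")
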