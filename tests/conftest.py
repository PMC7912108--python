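"""Shared fixtures.

The planner run is the expensive step (~2 s), so the subject-A front-reach
normalized plan is computed once per session and shared.
"""

import numpy as np
import pytest

import reachplan as rp
from reachplan.arm import ArmParameters


@pytest.fixture(scope="session")
def subject_a_front():
    params, k = rp.load_subject_parameters("A", "front")
    return params, k


@pytest.fixture(scope="session")
def front_task(subject_a_front):
    params, _ = subject_a_front
    return rp.task_geometry("front", 8.0, params)


@pytest.fixture(scope="session")
def normalized_plan(subject_a_front, front_task):
    """(norm_traj, norm_tau) for subject A reaching front, D_ref = 1 s."""
    params, _ = subject_a_front
    return rp.normalized_trajectory(params, front_task)


@pytest.fixture(scope="session")
def constant_inertia_arm():
    """Arm with a nearly massless forearm and negligible viscosity.

    The inertia matrix is then constant and the Coriolis/centrifugal terms
    vanish, so torque is a fixed linear map of joint acceleration and
    torque-change minimization coincides with per-joint jerk minimization:
    the optimal angle profiles are the minimum-jerk quintic blend (the
    single-link/1-DOF reduction).
    """
    eps = 1e-9
    return ArmParameters(
        L1=0.30, L2=0.30, S1=0.15, S2=eps * 0.3, m1=1.0, m2=eps,
        I1=0.05, I2=0.05, B=np.eye(2) * 1e-12,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
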