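"""Shared fixtures: geometries, inertial parameters, smooth trajectories."""

import numpy as np
import pytest

from reachdyn.limb import ArmGeometry, InertialParams, JointSeries


@pytest.fixture
def geometry() -> ArmGeometry:
    return ArmGeometry(l1=0.15, l2=0.20)


@pytest.fixture
def inertial(geometry) -> InertialParams:
    from reachdyn.limb import inertial_params_from_anthropometry
    return inertial_params_from_anthropometry(6.0, geometry)


def make_smooth_joint_series(rng: np.random.Generator, n: int = 501,
                             fs: float = 1000.0, fmax: float = 2.0) -> JointSeries:
    """Band-limited random two-joint trajectory with analytic derivatives."""
    t = np.arange(n) / fs
    theta = np.zeros((n, 2))
    omega = np.zeros((n, 2))
    alpha = np.zeros((n, 2))
    base = np.array([rng.uniform(0.3, 1.0), rng.uniform(0.8, 2.0)])
    for j in range(2):
        th = np.full(n, base[j])
        om = np.zeros(n)
        al = np.zeros(n)
        for _ in range(3):
            A = rng.uniform(0.02, 0.12)
            w = 2 * np.pi * rng.uniform(0.3, fmax)
            ph = rng.uniform(0, 2 * np.pi)
            th = th + A * np.sin(w * t + ph)
            om = om + A * w * np.cos(w * t + ph)
            al = al - A * w * w * np.sin(w * t + ph)
        theta[:, j], omega[:, j], alpha[:, j] = th, om, al
    return JointSeries(theta=theta, omega=omega, alpha=alpha, fs=fs)


def make_random_inertial(rng: np.random.Generator) -> InertialParams:
    l1, l2 = rng.uniform(0.12, 0.25), rng.uniform(0.15, 0.3)
    m1, m2 = rng.uniform(0.1, 0.5), rng.uniform(0.1, 0.5)
    r1, r2 = rng.uniform(0.3, 0.6) * l1, rng.uniform(0.3, 0.6) * l2
    p = InertialParams(m1=m1, m2=m2, r1=r1, r2=r2,
                       I1=m1 * (0.3 * l1) ** 2, I2=m2 * (0.3 * l2) ** 2,
                       l1=l1, l2=l2)
    p.check_positive_definite()
    return p
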