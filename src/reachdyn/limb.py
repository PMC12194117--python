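"""Two-link planar limb model: kinematics, dynamics, and torque decomposition.

The arm is modelled as a planar two-link chain (upper arm + forearm/hand)
moving in a horizontal plane with full weight support, so gravity plays no
role.  Shoulder angle ``theta_s`` is measured from the workspace +x axis to
the upper arm; elbow angle ``theta_e`` is the internal angle of the forearm
relative to the extension of the upper arm (``theta_e = 0`` is a fully
extended arm, positive values flex the elbow counter-clockwise).

Joint torques are decomposed into three components per joint:

* **net** torque — the part proportional to the joint's own angular
  acceleration (diagonal inertia term),
* **coupling** (interaction) torque — the passive torque arising from motion
  of the *other* joint: off-diagonal inertial terms plus the
  centripetal/Coriolis velocity products,
* **muscle** torque — net minus coupling; equals the generalized applied
  torque of the standard two-link equations of motion (and in practice folds
  in musculoskeletal viscoelastic effects).

With the composite inertial coefficients

    a1 = I1 + I2 + m1*r1^2 + m2*(l1^2 + r2^2)
    a2 = m2*l1*r2
    a3 = I2 + m2*r2^2

and c = cos(theta_e), s = sin(theta_e), the decomposition reads

    T_n[shoulder] = (a1 + 2*a2*c) * alpha_s
    T_n[elbow]    = a3 * alpha_e
    T_c[shoulder] = -(a3 + a2*c) * alpha_e + a2*s*(2*w_s*w_e + w_e^2)
    T_c[elbow]    = -(a3 + a2*c) * alpha_s - a2*s*w_s^2
    T_m[j]        = T_n[j] - T_c[j]

so that T_m solves  M(theta) alpha + C(theta, omega) = T_m  with

    M = [[a1 + 2*a2*c, a3 + a2*c], [a3 + a2*c, a3]]
    C = [-a2*s*(2*w_s*w_e + w_e^2), a2*s*w_s^2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArmGeometry",
    "InertialParams",
    "JointSeries",
    "HandSeries",
    "TorqueDecomposition",
    "inertial_params_from_anthropometry",
    "forward_kinematics",
    "inverse_kinematics",
    "inverse_dynamics",
    "forward_dynamics",
]


class ReachabilityError(ValueError):
    """A requested hand position lies outside the arm's reachable annulus."""


@dataclass(frozen=True)
class ArmGeometry:
    """Segment lengths of the two-link arm.

    l1: shoulder-to-elbow (upper arm) length in metres.
    l2: elbow-to-hand (forearm + hand) length in metres.
    """

    l1: float
    l2: float

    def __post_init__(self) -> None:
        if not (self.l1 > 0 and self.l2 > 0):
            raise ValueError("segment lengths must be positive")


@dataclass(frozen=True)
class InertialParams:
    """Segment inertial properties plus optional exoskeleton-link additions.

    Masses in kg, centre-of-mass distances (from the proximal joint) in
    metres, moments of inertia about each segment COM in kg m^2.  The
    ``exo_a1/a2/a3`` terms are additive corrections to the composite
    coefficients for any co-moving manipulandum linkage.
    """

    m1: float
    m2: float
    r1: float
    r2: float
    I1: float
    I2: float
    l1: float
    l2: float
    exo_a1: float = 0.0
    exo_a2: float = 0.0
    exo_a3: float = 0.0

    def __post_init__(self) -> None:
        if min(self.m1, self.m2, self.I1, self.I2) < 0:
            raise ValueError("masses and inertias must be non-negative")
        if not (0 < self.r1 <= self.l1 and 0 < self.r2 <= self.l2):
            raise ValueError("COM distances must satisfy 0 < r <= segment length")

    @property
    def a1(self) -> float:
        return (
            self.I1
            + self.I2
            + self.m1 * self.r1**2
            + self.m2 * (self.l1**2 + self.r2**2)
            + self.exo_a1
        )

    @property
    def a2(self) -> float:
        return self.m2 * self.l1 * self.r2 + self.exo_a2

    @property
    def a3(self) -> float:
        return self.I2 + self.m2 * self.r2**2 + self.exo_a3

    def inertia_matrix(self, theta_e: float) -> np.ndarray:
        c = np.cos(theta_e)
        m12 = self.a3 + self.a2 * c
        return np.array([[self.a1 + 2 * self.a2 * c, m12], [m12, self.a3]])

    def check_positive_definite(self, n_grid: int = 181) -> None:
        """Verify the inertia matrix is positive definite over theta_e in [0, pi]."""
        for te in np.linspace(0.0, np.pi, n_grid):
            m = self.inertia_matrix(te)
            if m[0, 0] <= 0 or np.linalg.det(m) <= 0:
                raise ValueError(
                    f"inertia matrix not positive definite at theta_e={te:.3f} rad"
                )


@dataclass
class JointSeries:
    """Uniformly sampled shoulder/elbow angles, velocities and accelerations.

    Arrays are shape ``(n, 2)`` with column 0 = shoulder, column 1 = elbow.
    """

    theta: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        shapes = {self.theta.shape, self.omega.shape, self.alpha.shape}
        if len(shapes) != 1:
            raise ValueError("theta/omega/alpha channel lengths disagree")
        if self.theta.shape[1] != 2:
            raise ValueError("expected arrays of shape (n, 2)")
        if not (np.isfinite(self.theta).all() and np.isfinite(self.omega).all()
                and np.isfinite(self.alpha).all()):
            raise ValueError("joint series contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


@dataclass
class HandSeries:
    """Hand position and velocity in the workspace plane, shape ``(n, 2)``."""

    pos: np.ndarray
    vel: np.ndarray
    fs: float = 1000.0
    acc: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.atleast_2d(np.asarray(self.pos, dtype=float))
        self.vel = np.atleast_2d(np.asarray(self.vel, dtype=float))
        if self.pos.shape != self.vel.shape or self.pos.shape[1] != 2:
            raise ValueError("pos/vel must both be (n, 2)")
        if self.acc is not None:
            self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
            if self.acc.shape != self.pos.shape:
                raise ValueError("acc must match pos shape")

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def speed(self) -> np.ndarray:
        return np.hypot(self.vel[:, 0], self.vel[:, 1])


@dataclass
class TorqueDecomposition:
    """Net, coupling and muscle torque series per joint (shape ``(n, 2)``)."""

    net: np.ndarray
    coupling: np.ndarray
    muscle: np.ndarray
    fs: float = 1000.0

    JOINTS = ("shoulder", "elbow")

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        component, joint = key
        col = self.JOINTS.index(joint)
        return getattr(self, component)[:, col]


def inertial_params_from_anthropometry(
    body_mass: float,
    geometry: ArmGeometry,
    anthro_config: dict | None = None,
) -> InertialParams:
    """Estimate segment inertial parameters from body mass and segment lengths.

    The scaling model is the standard proportional one: segment mass is a
    fixed fraction of body mass, the COM sits at a fixed fraction of segment
    length, and the moment of inertia about the COM is ``m * (gyr * l)^2``
    with a gyration-radius fraction ``gyr``.

    anthro_config keys (all optional): ``m1``, ``m2`` (mass fractions),
    ``com`` (COM fraction of segment length, shared), ``gyr`` (gyration
    fraction, shared), ``exo_a1/a2/a3`` (additive manipulandum corrections).
    """
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    cfg = dict(DEFAULT_ANTHRO)
    if anthro_config:
        cfg.update(anthro_config)
    m1 = cfg["m1"] * body_mass
    m2 = cfg["m2"] * body_mass
    r1 = cfg["com"] * geometry.l1
    r2 = cfg["com"] * geometry.l2
    I1 = m1 * (cfg["gyr"] * geometry.l1) ** 2
    I2 = m2 * (cfg["gyr"] * geometry.l2) ** 2
    params = InertialParams(
        m1=m1, m2=m2, r1=r1, r2=r2, I1=I1, I2=I2,
        l1=geometry.l1, l2=geometry.l2,
        exo_a1=cfg.get("exo_a1", 0.0),
        exo_a2=cfg.get("exo_a2", 0.0),
        exo_a3=cfg.get("exo_a3", 0.0),
    )
    params.check_positive_definite()
    return params


#: Default proportional anthropometry (fraction of body mass / segment length).
#: Mass fractions are in the range used for primate upper-limb scaling; COM at
#: 45% of segment length from the proximal joint, gyration radius 30% of
#: segment length.
DEFAULT_ANTHRO = {"m1": 0.03, "m2": 0.025, "com": 0.45, "gyr": 0.3}


def forward_kinematics(js: JointSeries, geom: ArmGeometry) -> HandSeries:
    """Hand position/velocity from joint angles by the planar chain equations."""
    ts, te = js.theta[:, 0], js.theta[:, 1]
    ws, we = js.omega[:, 0], js.omega[:, 1]
    l1, l2 = geom.l1, geom.l2
    x = l1 * np.cos(ts) + l2 * np.cos(ts + te)
    y = l1 * np.sin(ts) + l2 * np.sin(ts + te)
    # analytic differentiation of the position equations
    vx = -l1 * np.sin(ts) * ws - l2 * np.sin(ts + te) * (ws + we)
    vy = l1 * np.cos(ts) * ws + l2 * np.cos(ts + te) * (ws + we)
    return HandSeries(pos=np.column_stack([x, y]),
                      vel=np.column_stack([vx, vy]), fs=js.fs)


def _ik_angles(pos: np.ndarray, geom: ArmGeometry, elbow_sign: int) -> np.ndarray:
    l1, l2 = geom.l1, geom.l2
    x, y = pos[:, 0], pos[:, 1]
    d2 = x * x + y * y
    cos_te = (d2 - l1 * l1 - l2 * l2) / (2 * l1 * l2)
    bad = (cos_te < -1 - 1e-12) | (cos_te > 1 + 1e-12)
    if bad.any():
        i = int(np.argmax(bad))
        raise ReachabilityError(
            f"hand point {i} at ({x[i]:.4f}, {y[i]:.4f}) is outside the "
            f"reachable annulus [{abs(l1 - l2):.4f}, {l1 + l2:.4f}] m"
        )
    te = elbow_sign * np.arccos(np.clip(cos_te, -1.0, 1.0))
    ts = np.arctan2(y, x) - np.arctan2(l2 * np.sin(te), l1 + l2 * np.cos(te))
    return np.column_stack([ts, te])


def _jacobian(theta: np.ndarray, geom: ArmGeometry) -> np.ndarray:
    """Stack of 2x2 hand Jacobians, shape (n, 2, 2)."""
    ts, te = theta[:, 0], theta[:, 1]
    l1, l2 = geom.l1, geom.l2
    s1, c1 = np.sin(ts), np.cos(ts)
    s12, c12 = np.sin(ts + te), np.cos(ts + te)
    J = np.empty((theta.shape[0], 2, 2))
    J[:, 0, 0] = -l1 * s1 - l2 * s12
    J[:, 0, 1] = -l2 * s12
    J[:, 1, 0] = l1 * c1 + l2 * c12
    J[:, 1, 1] = l2 * c12
    return J


def _jacobian_dot(theta: np.ndarray, omega: np.ndarray, geom: ArmGeometry) -> np.ndarray:
    ts, te = theta[:, 0], theta[:, 1]
    ws, we = omega[:, 0], omega[:, 1]
    l1, l2 = geom.l1, geom.l2
    s1, c1 = np.sin(ts), np.cos(ts)
    s12, c12 = np.sin(ts + te), np.cos(ts + te)
    w12 = ws + we
    Jd = np.empty((theta.shape[0], 2, 2))
    Jd[:, 0, 0] = -l1 * c1 * ws - l2 * c12 * w12
    Jd[:, 0, 1] = -l2 * c12 * w12
    Jd[:, 1, 0] = -l1 * s1 * ws - l2 * s12 * w12
    Jd[:, 1, 1] = -l2 * s12 * w12
    return Jd


def inverse_kinematics(
    hand: HandSeries,
    geom: ArmGeometry,
    elbow_sign: int = 1,
    derivatives: str = "jacobian",
) -> JointSeries:
    """Joint angles (and derivatives) for a hand path.

    ``elbow_sign`` selects between the two mirror-image arm postures
    (default +1: elbow flexed counter-clockwise).  With
    ``derivatives='jacobian'`` the angular velocities/accelerations are
    obtained from the hand velocity/acceleration through the analytic
    Jacobian relations (requires ``hand.acc``); ``'finite'`` uses centred
    finite differences of the angle series instead.
    """
    if elbow_sign not in (1, -1):
        raise ValueError("elbow_sign must be +1 or -1")
    theta = _ik_angles(hand.pos, geom, elbow_sign)
    if derivatives == "jacobian":
        if hand.acc is None:
            raise ValueError("jacobian derivatives require hand accelerations")
        J = _jacobian(theta, geom)
        omega = np.linalg.solve(J, hand.vel[..., None])[..., 0]
        Jd = _jacobian_dot(theta, omega, geom)
        rhs = hand.acc - (Jd @ omega[..., None])[..., 0]
        alpha = np.linalg.solve(J, rhs[..., None])[..., 0]
    elif derivatives == "finite":
        dt = 1.0 / hand.fs
        omega = np.gradient(np.unwrap(theta, axis=0), dt, axis=0)
        alpha = np.gradient(omega, dt, axis=0)
    else:
        raise ValueError("derivatives must be 'jacobian' or 'finite'")
    return JointSeries(theta=theta, omega=omega, alpha=alpha, fs=hand.fs)


def inverse_dynamics(js: JointSeries, params: InertialParams) -> TorqueDecomposition:
    """Decompose joint torques into net, coupling and muscle components.

    See the module docstring for the closed-form expressions.  The identity
    ``muscle = net - coupling`` holds exactly by construction, and ``muscle``
    equals the generalized applied torque of the two-link equations of motion.
    """
    a1, a2, a3 = params.a1, params.a2, params.a3
    te = js.theta[:, 1]
    ws, we = js.omega[:, 0], js.omega[:, 1]
    als, ale = js.alpha[:, 0], js.alpha[:, 1]
    c, s = np.cos(te), np.sin(te)

    net_s = (a1 + 2 * a2 * c) * als
    net_e = a3 * ale
    coup_s = -(a3 + a2 * c) * ale + a2 * s * (2 * ws * we + we * we)
    coup_e = -(a3 + a2 * c) * als - a2 * s * ws * ws

    net = np.column_stack([net_s, net_e])
    coupling = np.column_stack([coup_s, coup_e])
    return TorqueDecomposition(net=net, coupling=coupling,
                               muscle=net - coupling, fs=js.fs)


def _accelerations(theta: np.ndarray, omega: np.ndarray, torque: np.ndarray,
                   params: InertialParams) -> np.ndarray:
    """Solve M(theta) alpha = torque - C(theta, omega) for one state."""
    a1, a2, a3 = params.a1, params.a2, params.a3
    c, s = np.cos(theta[1]), np.sin(theta[1])
    m12 = a3 + a2 * c
    M = np.array([[a1 + 2 * a2 * c, m12], [m12, a3]])
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    if abs(det) < 1e-12:
        raise ArithmeticError("inertia matrix is singular or near-singular")
    C = np.array([-a2 * s * (2 * omega[0] * omega[1] + omega[1] ** 2),
                  a2 * s * omega[0] ** 2])
    rhs = torque - C
    return np.array([M[1, 1] * rhs[0] - M[0, 1] * rhs[1],
                     -M[1, 0] * rhs[0] + M[0, 0] * rhs[1]]) / det


def forward_dynamics(
    muscle_torque: np.ndarray,
    initial_theta: np.ndarray,
    initial_omega: np.ndarray,
    params: InertialParams,
    fs: float = 1000.0,
) -> JointSeries:
    """Integrate the two-link equations of motion under applied muscle torque.

    Fixed-step classical Runge-Kutta (RK4) at step ``1/fs``; the torque at
    half-steps is interpolated with a 4-point cubic stencil so the control
    input does not limit the integrator's accuracy.  Returns a JointSeries
    of the same length as the torque series, with accelerations recomputed
    from the equations of motion at each sample (so an inverse-dynamics
    round trip closes).
    """
    tq = np.atleast_2d(np.asarray(muscle_torque, dtype=float))
    n = tq.shape[0]
    dt = 1.0 / fs
    theta = np.empty((n, 2))
    omega = np.empty((n, 2))
    theta[0] = np.asarray(initial_theta, dtype=float)
    omega[0] = np.asarray(initial_omega, dtype=float)

    def deriv(th, om, torque):
        return om, _accelerations(th, om, torque, params)

    for i in range(n - 1):
        if 0 < i < n - 2:
            tq_mid = (9.0 * (tq[i] + tq[i + 1]) - tq[i - 1] - tq[i + 2]) / 16.0
        else:
            tq_mid = 0.5 * (tq[i] + tq[i + 1])
        k1_t, k1_w = deriv(theta[i], omega[i], tq[i])
        k2_t, k2_w = deriv(theta[i] + 0.5 * dt * k1_t, omega[i] + 0.5 * dt * k1_w, tq_mid)
        k3_t, k3_w = deriv(theta[i] + 0.5 * dt * k2_t, omega[i] + 0.5 * dt * k2_w, tq_mid)
        k4_t, k4_w = deriv(theta[i] + dt * k3_t, omega[i] + dt * k3_w, tq[i + 1])
        theta[i + 1] = theta[i] + dt / 6 * (k1_t + 2 * k2_t + 2 * k3_t + k4_t)
        omega[i + 1] = omega[i] + dt / 6 * (k1_w + 2 * k2_w + 2 * k3_w + k4_w)

    alpha = np.empty((n, 2))
    for i in range(n):
        alpha[i] = _accelerations(theta[i], omega[i], tq[i], params)
    return JointSeries(theta=theta, omega=omega, alpha=alpha, fs=fs)
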