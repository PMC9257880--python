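"""Compass-type biped mechanics.

The walker is a planar two-link inverted pendulum: a point mass ``M`` at the
hip, one point mass ``m`` on each leg at a distance ``b`` below the hip, and
massless rigid legs of length ``l``.  The stance leg pivots without friction
about its ground contact; the swing leg hangs from the frictionless hip
joint.  Generalized coordinates are

* ``theta1`` — stance-leg angle from the vertical, and
* ``theta2`` — relative angle between stance and swing legs,

so the swing leg's absolute angle from the vertical is ``theta1 - theta2``.
The convention is chosen such that forward progress corresponds to
``theta1`` decreasing through zero during a step, and touchdown happens in
front of the walker with ``theta1 < 0``.

Continuous dynamics take the standard manipulator form

    M(q) q'' + C(q, q') + G(q) = u

with ``u = (u1, u2)`` the ankle and hip torques.  Touchdown is an
instantaneous, fully inelastic, no-slip collision that swaps the leg roles;
angles negate and angular velocities map linearly through a pair of
configuration-dependent matrices derived from conservation of angular
momentum (of the whole walker about the new contact point, and of the
trailing leg about the hip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WalkerParams",
    "WalkerState",
    "Torques",
    "mass_matrix",
    "swing_accelerations",
    "touchdown_condition",
    "collision_map",
    "mechanical_energy",
]

#: Default stance-angle magnitude beyond which a trial counts as a fall.
FALL_ANGLE = math.pi / 2
#: Angular-velocity magnitude beyond which a trial counts as a fall (rad/s).
FALL_RATE = 50.0
#: A trial counts as a fall if no touchdown occurs for this long (s).
MAX_STEP_TIME = 5.0


@dataclass(frozen=True)
class WalkerParams:
    """Anthropometric parameters of the compass walker.

    Defaults are a 50 kg trunk with 11 kg legs of unit length, mass centers
    0.4 m below the hip — standard adult values from gait biomechanics
    tables.
    """

    M: float = 50.0  # hip (trunk) mass, kg
    m: float = 11.0  # leg mass, kg
    l: float = 1.0   # leg length, m
    b: float = 0.4   # distance of leg mass below the hip, m
    g: float = 9.8   # gravitational acceleration, m/s^2

    def __post_init__(self) -> None:
        for name in ("M", "m", "l", "b", "g"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"walker parameter {name} must be positive")
        if not self.b < self.l:
            raise ValueError("leg mass must sit between hip and foot (b < l)")


@dataclass
class WalkerState:
    """Configuration and angular velocities of the walker at an instant."""

    theta1: float
    theta2: float
    dtheta1: float
    dtheta2: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.theta1, self.theta2, self.dtheta1, self.dtheta2], dtype=float
        )

    @classmethod
    def from_array(cls, a) -> "WalkerState":
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))


@dataclass(frozen=True)
class Torques:
    """Ankle (``u1``) and hip (``u2``) joint torques, N·m."""

    u1: float = 0.0
    u2: float = 0.0


def mass_matrix(theta2: float, params: WalkerParams) -> np.ndarray:
    """Configuration-dependent 2x2 inertia matrix ``M(q)``.

    Depends only on the inter-leg angle.  Symmetric positive definite for
    physical parameters.
    """
    M, m, l, b = params.M, params.m, params.l, params.b
    c2 = math.cos(theta2)
    m11 = M * l * l + m * (l * l + (l - b) ** 2) - 2.0 * m * l * b * c2 + m * b * b
    m12 = m * l * b * c2 - m * b * b
    m22 = m * b * b
    return np.array([[m11, m12], [m12, m22]])


def _bias_forces(state: WalkerState, params: WalkerParams) -> np.ndarray:
    """Coriolis/centrifugal plus gravity generalized forces (LHS terms)."""
    M, m, l, b, g = params.M, params.m, params.l, params.b, params.g
    th1, th2, d1, d2 = state.theta1, state.theta2, state.dtheta1, state.dtheta2
    s2 = math.sin(th2)
    c1 = -m * l * b * (d2 - 2.0 * d1) * d2 * s2
    c2 = -m * l * b * d1 * d1 * s2
    g1 = -(g * m * (2.0 * l - b) + g * M * l) * math.sin(th1) - g * m * b * math.sin(
        th2 - th1
    )
    g2 = g * m * b * math.sin(th2 - th1)
    return np.array([c1 + g1, c2 + g2])


def swing_accelerations(
    state: WalkerState, torques: Torques, params: WalkerParams
) -> tuple[float, float]:
    """Angular accelerations ``(theta1'', theta2'')`` during the swing phase.

    Solves ``M(q) q'' = u - C(q, q') - G(q)``.  Raises ``ArithmeticError``
    if the inertia matrix is (numerically) singular, which cannot happen for
    physical parameters.
    """
    Mq = mass_matrix(state.theta2, params)
    rhs = np.array([torques.u1, torques.u2]) - _bias_forces(state, params)
    det = Mq[0, 0] * Mq[1, 1] - Mq[0, 1] * Mq[1, 0]
    if not abs(det) > 1e-12 * abs(Mq[0, 0] * Mq[1, 1]):
        raise ArithmeticError("singular inertia matrix: nonphysical parameters")
    dd1 = (Mq[1, 1] * rhs[0] - Mq[0, 1] * rhs[1]) / det
    dd2 = (Mq[0, 0] * rhs[1] - Mq[1, 0] * rhs[0]) / det
    return dd1, dd2


def touchdown_condition(state: WalkerState, tol: float = 1e-10) -> bool:
    """True iff the swing foot is striking the ground in front of the walker.

    Three conditions must hold simultaneously: the legs are symmetric about
    the vertical (``2*theta1 - theta2 = 0`` within ``tol``), the stance leg
    has rotated past vertical (``theta1 < 0``, contact in front), and the
    feet are closing (``2*dtheta1 - dtheta2 < 0``); the last condition
    ignores the swing foot scuffing the ground on its way forward.
    """
    s = 2.0 * state.theta1 - state.theta2
    return (
        abs(s) <= tol
        and state.theta1 < 0.0
        and 2.0 * state.dtheta1 - state.dtheta2 < 0.0
    )


def _collision_matrices(theta1_minus: float, params: WalkerParams):
    M, m, l, b = params.M, params.m, params.l, params.b
    c2 = math.cos(2.0 * theta1_minus)
    q_plus = np.array(
        [
            [
                -M * l * l - 2.0 * m * (l - b) ** 2 - 2.0 * m * l * b * (1.0 - c2),
                m * b * (b - l * c2),
            ],
            [-m * l * (b - l * c2), m * l * b],
        ]
    )
    q_minus = np.array(
        [
            [
                2.0 * m * (l - b) * (b - l * c2) - M * l * l * c2,
                -m * (l - b) * b,
            ],
            [m * l * (l - b), 0.0],
        ]
    )
    return q_plus, q_minus


def collision_map(
    state_minus: WalkerState,
    params: WalkerParams,
    *,
    check: bool = True,
    tol: float = 1e-8,
) -> WalkerState:
    """Instantaneous leg-swap map applied at touchdown.

    Angles swap roles and negate (``theta1+ = -theta1-``,
    ``theta2+ = -theta2-``); angular velocities change discontinuously
    through the fully inelastic impact,
    ``qdot+ = Q+(theta1-)^{-1} Q-(theta1-) qdot-``.  The impact conserves
    the walker's angular momentum about the new contact point and the
    trailing leg's angular momentum about the hip; it can only dissipate
    kinetic energy.

    With ``check=True`` the pre-impact state must satisfy the touchdown
    conditions (within ``tol`` on the contact geometry).
    """
    if check and not touchdown_condition(state_minus, tol=tol):
        raise ValueError("collision_map called on a state not at touchdown")
    q_plus, q_minus = _collision_matrices(state_minus.theta1, params)
    det = q_plus[0, 0] * q_plus[1, 1] - q_plus[0, 1] * q_plus[1, 0]
    if not abs(det) > 0.0:
        raise ArithmeticError("singular impact matrix")
    rhs = q_minus @ np.array([state_minus.dtheta1, state_minus.dtheta2])
    d1p = (q_plus[1, 1] * rhs[0] - q_plus[0, 1] * rhs[1]) / det
    d2p = (q_plus[0, 0] * rhs[1] - q_plus[1, 0] * rhs[0]) / det
    return WalkerState(-state_minus.theta1, -state_minus.theta2, d1p, d2p)


def mechanical_energy(state: WalkerState, params: WalkerParams) -> float:
    """Total mechanical energy (J), kinetic plus gravitational potential.

    The potential datum is the stance-foot contact point.  Conserved along
    passive (torque-free) swing trajectories; a test instrument for the
    integrator and for the inelasticity of the collision map.
    """
    M, m, l, b, g = params.M, params.m, params.l, params.b, params.g
    qd = np.array([state.dtheta1, state.dtheta2])
    kinetic = 0.5 * qd @ mass_matrix(state.theta2, params) @ qd
    potential = g * (
        (M * l + m * (2.0 * l - b)) * math.cos(state.theta1)
        - m * b * math.cos(state.theta1 - state.theta2)
    )
    return float(kinetic + potential)


def kinetic_energy(state: WalkerState, params: WalkerParams) -> float:
    """Kinetic part of :func:`mechanical_energy` (J)."""
    qd = np.array([state.dtheta1, state.dtheta2])
    return float(0.5 * qd @ mass_matrix(state.theta2, params) @ qd)


def step_length(theta1_minus: float, l: float) -> float:
    """Distance between successive contact points for touchdown angle
    ``theta1_minus`` (m): ``2 l |sin theta1-|``."""
    return 2.0 * l * abs(math.sin(theta1_minus))
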