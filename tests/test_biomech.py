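"""Mechanics: equations of motion, touchdown logic, impact map, energy."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phasewalk.biomech import (
    Torques,
    WalkerParams,
    WalkerState,
    collision_map,
    kinetic_energy,
    mass_matrix,
    mechanical_energy,
    swing_accelerations,
    touchdown_condition,
)
from phasewalk import _kernels
from phasewalk.cpg import CPGParams, ResetMode


def test_walker_params_validation():
    with pytest.raises(ValueError):
        WalkerParams(M=-1.0)
    with pytest.raises(ValueError):
        WalkerParams(b=1.5, l=1.0)


def test_upright_equilibrium(walker):
    dd = swing_accelerations(WalkerState(0, 0, 0, 0), Torques(0, 0), walker)
    assert dd == pytest.approx((0.0, 0.0), abs=1e-14)


def test_mass_matrix_symmetric_positive_definite(walker):
    for th2 in np.linspace(-math.pi, math.pi, 61):
        M = mass_matrix(th2, walker)
        assert M[0, 1] == M[1, 0]
        assert np.all(np.linalg.eigvalsh(M) > 0)


def test_equations_of_motion_match_lagrangian_oracle(walker):
    """The implemented dynamics equal an independent symbolic derivation.

    The oracle derives the two-link equations from the Lagrangian with
    sympy (hip mass M at distance l from the contact, leg masses m at
    distance b below the hip) and solves for the accelerations.
    """
    sympy = pytest.importorskip("sympy")
    sp = sympy
    Ms, ms, ls, bs, gs = sp.symbols("M m l b g", positive=True)
    t = sp.symbols("t")
    q1, q2 = sp.Function("q1")(t), sp.Function("q2")(t)
    ph = sp.Matrix([-ls * sp.sin(q1), ls * sp.cos(q1)])
    pst = (ls - bs) / ls * ph
    psi = q1 - q2
    psw = ph + bs * sp.Matrix([sp.sin(psi), -sp.cos(psi)])

    def v2(p):
        return sp.diff(p, t).dot(sp.diff(p, t))

    T = sp.Rational(1, 2) * (Ms * v2(ph) + ms * v2(pst) + ms * v2(psw))
    V = gs * (Ms * ph[1] + ms * pst[1] + ms * psw[1])
    L = T - V
    u1s, u2s = sp.symbols("u1 u2")
    eqs = [
        sp.Eq(sp.diff(sp.diff(L, sp.diff(q, t)), t) - sp.diff(L, q), u)
        for q, u in ((q1, u1s), (q2, u2s))
    ]
    dd1s, dd2s = sp.symbols("dd1 dd2")
    sol = sp.solve(
        [
            e.subs({sp.Derivative(q1, (t, 2)): dd1s, sp.Derivative(q2, (t, 2)): dd2s})
            for e in eqs
        ],
        [dd1s, dd2s],
    )
    subs_num = {
        Ms: walker.M, ms: walker.m, ls: walker.l, bs: walker.b, gs: walker.g,
    }
    rng = np.random.default_rng(7)
    for _ in range(5):
        th1, th2 = rng.uniform(-0.6, 0.6, 2)
        d1, d2 = rng.uniform(-2, 2, 2)
        u1, u2 = rng.uniform(-20, 20, 2)
        local = dict(subs_num)
        local.update({
            q1: th1, q2: th2,
            sp.Derivative(q1, t): d1, sp.Derivative(q2, t): d2,
            u1s: u1, u2s: u2,
        })
        expected = (float(sol[dd1s].subs(local)), float(sol[dd2s].subs(local)))
        got = swing_accelerations(
            WalkerState(th1, th2, d1, d2), Torques(u1, u2), walker
        )
        assert got == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize(
    "state,expected",
    [
        ((-0.2, -0.4, -0.5, 0.5), True),    # symmetric, in front, closing
        ((0.2, 0.4, -0.5, 0.5), False),     # contact behind the walker
        ((-0.2, -0.4, 0.5, 0.5), False),    # scuffing (feet not closing)
        ((-0.2, -0.3, -0.5, 0.5), False),   # off the contact surface
    ],
)
def test_touchdown_condition(state, expected):
    assert touchdown_condition(WalkerState(*state)) is expected


def test_collision_zero_velocity_maps_to_zero(walker):
    post = collision_map(WalkerState(-0.15, -0.3, 0.0, 0.0), walker, check=False)
    assert post.theta1 == pytest.approx(0.15)
    assert post.theta2 == pytest.approx(0.3)
    assert (post.dtheta1, post.dtheta2) == pytest.approx((0.0, 0.0), abs=1e-15)


def test_collision_requires_touchdown_state(walker):
    with pytest.raises(ValueError):
        collision_map(WalkerState(0.2, 0.4, -0.5, 0.5), walker)


def _momentum_oracle(state, walker):
    """Post-impact velocities from first principles: conservation of the
    walker's angular momentum about the new contact point and of the
    trailing leg's about the hip, with the leg-role relabeling."""
    M, m, l, b = walker.M, walker.m, walker.l, walker.b
    th1, d1, d2 = state.theta1, state.dtheta1, state.dtheta2
    psi = -th1  # swing absolute angle on the contact surface

    def rot(a):
        return np.array([-math.sin(a), math.cos(a)])

    ph = l * rot(th1)
    pst = (l - b) * rot(th1)
    psw = ph + b * np.array([math.sin(psi), -math.cos(psi)])
    P = ph + l * np.array([math.sin(psi), -math.cos(psi)])
    dpsi = d1 - d2
    dr = lambda a: np.array([-math.cos(a), -math.sin(a)])
    vh = l * dr(th1) * d1
    vst = (l - b) * dr(th1) * d1
    vsw = vh + b * np.array([math.cos(psi), math.sin(psi)]) * dpsi

    def cross(r, v):
        return r[0] * v[1] - r[1] * v[0]

    L_P = M * cross(ph - P, vh) + m * cross(pst - P, vst) + m * cross(psw - P, vsw)
    L_H = m * cross(pst - ph, vst)
    # post-impact: same physical points, new pivot P, new coords th1+ = -th1
    th1p = -th1
    A = np.zeros((2, 2))
    rhs = np.array([L_P, L_H])
    for j, (e1, e2) in enumerate(((1.0, 0.0), (0.0, 1.0))):
        vh_p = l * dr(th1p) * e1
        vst_p = (l - b) * dr(th1p) * e1
        psi_p = th1p - (-2.0 * th1)
        vsw_p = vh_p + b * np.array([math.cos(psi_p), math.sin(psi_p)]) * (e1 - e2)
        ph_p = P + l * rot(th1p)
        pst_p = P + (l - b) * rot(th1p)
        psw_p = ph_p + b * np.array([math.sin(psi_p), -math.cos(psi_p)])
        A[0, j] = (
            M * cross(ph_p - P, vh_p)
            + m * cross(pst_p - P, vst_p)
            + m * cross(psw_p - P, vsw_p)
        )
        A[1, j] = m * cross(psw_p - ph_p, vsw_p)
    return np.linalg.solve(A, rhs)


@pytest.mark.parametrize("th1,d1,d2", [
    (-0.131, -0.56, -0.26),
    (-0.2, -0.8, -0.5),
    (-0.05, -0.3, 0.1),
    (-0.35, -1.2, -0.9),
])
def test_collision_matches_conservation_oracle(walker, th1, d1, d2):
    pre = WalkerState(th1, 2 * th1, d1, d2)
    post = collision_map(pre, walker, check=False)
    expected = _momentum_oracle(pre, walker)
    assert (post.dtheta1, post.dtheta2) == pytest.approx(tuple(expected), rel=1e-10)


def test_collision_never_creates_kinetic_energy(walker):
    rng = np.random.default_rng(11)
    for _ in range(50):
        th1 = rng.uniform(-0.4, -0.02)
        d1 = rng.uniform(-1.5, -0.05)
        d2 = rng.uniform(2.0 * d1 + 1e-3, 2.0 * d1 + 1.5)  # ensures 2 d1 - d2 < 0
        pre = WalkerState(th1, 2 * th1, d1, d2)
        post = collision_map(pre, walker)
        assert kinetic_energy(post, walker) <= kinetic_energy(pre, walker) + 1e-12


def test_collision_angle_part_is_sign_involution(walker):
    pre = WalkerState(-0.13, -0.26, -0.5, -0.2)
    post = collision_map(pre, walker, check=False)
    # applying the angle negation twice returns the original angles
    assert (-post.theta1, -post.theta2) == (pre.theta1, pre.theta2)
    # post-collision state lies on the touchdown section of the next step
    assert 2 * post.theta1 - post.theta2 == pytest.approx(0.0, abs=1e-15)


def test_passive_energy_conservation_under_refinement(walker):
    """Torque-free swings conserve mechanical energy; the drift shrinks
    with the integration step (RK4 order) and is far below 1e-6 J."""
    cpg = CPGParams(A1=0.0, A2=0.0, delta=0.0, mode=ResetMode.FLIP)
    y0 = np.array([0.1, -0.1, -0.3, 0.4, 0.0])
    e0 = mechanical_energy(WalkerState(*y0[:4]), walker)
    drifts = []
    for dt in (1e-3, 5e-4):
        res = _kernels.walk(y0, walker, cpg, dt=dt, max_steps=100, t_stop=0.4)
        e1 = mechanical_energy(WalkerState(*res.y_final[:4]), walker)
        drifts.append(abs(e1 - e0))
    assert drifts[0] < 1e-6
    assert drifts[1] <= drifts[0] + 1e-15


def test_energy_datum_and_quadratic_kinetic(walker):
    rest = WalkerState(0.0, 0.0, 0.0, 0.0)
    e_rest = mechanical_energy(rest, walker)
    assert e_rest == pytest.approx(kinetic_energy(rest, walker) + e_rest)
    s1 = WalkerState(0.1, 0.2, 0.3, -0.4)
    s2 = WalkerState(0.1, 0.2, 0.6, -0.8)
    assert kinetic_energy(s2, walker) == pytest.approx(
        4.0 * kinetic_energy(s1, walker), rel=1e-12
    )


@given(
    th1=st.floats(-0.5, 0.5),
    th2=st.floats(-1.0, 1.0),
    d1=st.floats(-2, 2),
    d2=st.floats(-2, 2),
)
def test_energy_decomposition_consistent(th1, th2, d1, d2):
    walker = WalkerParams()
    s = WalkerState(th1, th2, d1, d2)
    frozen = WalkerState(th1, th2, 0.0, 0.0)
    assert mechanical_energy(s, walker) == pytest.approx(
        kinetic_energy(s, walker) + mechanical_energy(frozen, walker), rel=1e-9, abs=1e-9
    )
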