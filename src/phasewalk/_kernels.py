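"""Compiled integration kernels for the walker + CPG hybrid system.

Two engines share the same dynamics and event handling:

* :func:`walk` — deterministic (noise-free) flow integrated with classical
  RK4, used for limit-cycle finding, calibration sweeps, Floquet analysis
  and phase-response experiments.  Touchdown events are located by bisection
  on the integration step, so event times are resolved far below the step
  size.
* :func:`trial` — stochastic Euler–Maruyama integration with additive
  joint-torque noise, used for the stride-interval experiments.  Events are
  located by linear interpolation within the (very small) step.

State vectors are ``y = (theta1, theta2, dtheta1, dtheta2, phi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .biomech import WalkerParams, WalkerState
from .cpg import CPGParams, ResetMode

STATUS_COMPLETED = 0   # reached the requested number of touchdowns
STATUS_FELL = 1        # fall condition triggered
STATUS_CONVERGED = 2   # early-stop convergence criterion satisfied
STATUS_TIME = 3        # reached the requested stop time

_ARM_TOL = 1e-9        # contact function must exceed this before re-arming
_FALL_ANGLE = math.pi / 2
_FALL_RATE = 50.0


def pack_state(state: WalkerState, phi: float) -> np.ndarray:
    return np.array(
        [state.theta1, state.theta2, state.dtheta1, state.dtheta2, phi % (2 * math.pi)],
        dtype=np.float64,
    )


@njit(cache=True)
def _accels(th1, th2, d1, d2, u1, u2, M, m, l, b, g):
    c2 = math.cos(th2)
    m11 = M * l * l + m * (l * l + (l - b) ** 2) - 2.0 * m * l * b * c2 + m * b * b
    m12 = m * l * b * c2 - m * b * b
    m22 = m * b * b
    s2 = math.sin(th2)
    cc1 = -m * l * b * (d2 - 2.0 * d1) * d2 * s2
    cc2 = -m * l * b * d1 * d1 * s2
    g1 = -(g * m * (2.0 * l - b) + g * M * l) * math.sin(th1) - g * m * b * math.sin(th2 - th1)
    g2 = g * m * b * math.sin(th2 - th1)
    r1 = u1 - cc1 - g1
    r2 = u2 - cc2 - g2
    det = m11 * m22 - m12 * m12
    return (m22 * r1 - m12 * r2) / det, (m11 * r2 - m12 * r1) / det


@njit(cache=True)
def _deriv(y, out, M, m, l, b, g, omega, A1, A2, delta, nt1, nt2):
    u1 = A1 * math.cos(y[4]) + nt1
    u2 = A2 * math.cos(y[4] + delta) + nt2
    dd1, dd2 = _accels(y[0], y[1], y[2], y[3], u1, u2, M, m, l, b, g)
    out[0] = y[2]
    out[1] = y[3]
    out[2] = dd1
    out[3] = dd2
    out[4] = omega


@njit(cache=True)
def _rk4_step(y, h, M, m, l, b, g, omega, A1, A2, delta):
    k1 = np.empty(5)
    k2 = np.empty(5)
    k3 = np.empty(5)
    k4 = np.empty(5)
    tmp = np.empty(5)
    _deriv(y, k1, M, m, l, b, g, omega, A1, A2, delta, 0.0, 0.0)
    for i in range(5):
        tmp[i] = y[i] + 0.5 * h * k1[i]
    _deriv(tmp, k2, M, m, l, b, g, omega, A1, A2, delta, 0.0, 0.0)
    for i in range(5):
        tmp[i] = y[i] + 0.5 * h * k2[i]
    _deriv(tmp, k3, M, m, l, b, g, omega, A1, A2, delta, 0.0, 0.0)
    for i in range(5):
        tmp[i] = y[i] + h * k3[i]
    _deriv(tmp, k4, M, m, l, b, g, omega, A1, A2, delta, 0.0, 0.0)
    out = np.empty(5)
    for i in range(5):
        out[i] = y[i] + (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
    return out


@njit(cache=True)
def _collision_vel(th1m, d1, d2, M, m, l, b):
    c2 = math.cos(2.0 * th1m)
    qp11 = -M * l * l - 2.0 * m * (l - b) ** 2 - 2.0 * m * l * b * (1.0 - c2)
    qp12 = m * b * (b - l * c2)
    qp21 = -m * l * (b - l * c2)
    qp22 = m * l * b
    qm11 = 2.0 * m * (l - b) * (b - l * c2) - M * l * l * c2
    qm12 = -m * (l - b) * b
    qm21 = m * l * (l - b)
    r1 = qm11 * d1 + qm12 * d2
    r2 = qm21 * d1
    det = qp11 * qp22 - qp12 * qp21
    return (qp22 * r1 - qp12 * r2) / det, (qp11 * r2 - qp21 * r1) / det


@njit(cache=True)
def _phase_update(phi, mode, phi0):
    # mode 0: reset to phi0; mode 1: flip by -pi
    if mode == 0:
        return phi0
    return (phi - math.pi) % (2.0 * math.pi)


@njit(cache=True)
def _circ(a, b):
    return (a - b + math.pi) % (2.0 * math.pi) - math.pi


@njit(cache=True)
def _walk_rk4(
    y0,
    M, m, l, b, g,
    omega, A1, A2, delta, mode, phi0,
    dt, max_steps, t_stop, max_step_time,
    tau_tol, tau_consec, phi_tol, phi_consec,
    td_times, pre_states, post_states,
):
    y = y0.copy()
    t = 0.0
    s = 2.0 * y[0] - y[1]
    armed = s > _ARM_TOL
    t_last_td = 0.0
    n = 0
    status = STATUS_COMPLETED
    tau_count = 0
    phi_count = 0
    prev_tau = -1.0
    # a start exactly on the contact surface moving into contact is an
    # immediate touchdown (e.g. flows resumed at an event time)
    if abs(s) <= _ARM_TOL and y[0] < 0.0 and 2.0 * y[2] - y[3] < 0.0 and max_steps > 0:
        td_times[0] = 0.0
        for i in range(5):
            pre_states[0, i] = y[i]
        p1, p2 = _collision_vel(y[0], y[2], y[3], M, m, l, b)
        y[0] = -y[0]
        y[1] = -y[1]
        y[2] = p1
        y[3] = p2
        y[4] = _phase_update(y[4] % (2.0 * math.pi), mode, phi0)
        for i in range(5):
            post_states[0, i] = y[i]
        n = 1
        s = 0.0
        armed = False
    while True:
        if n >= max_steps:
            status = STATUS_COMPLETED
            break
        if t_stop > 0.0 and t >= t_stop - 1e-15:
            status = STATUS_TIME
            break
        h = dt
        if t_stop > 0.0 and t + h > t_stop:
            h = t_stop - t
        y_new = _rk4_step(y, h, M, m, l, b, g, omega, A1, A2, delta)
        s_new = 2.0 * y_new[0] - y_new[1]
        if armed and s_new <= 0.0:
            lo = 0.0
            hi = h
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                ym = _rk4_step(y, mid, M, m, l, b, g, omega, A1, A2, delta)
                sm = 2.0 * ym[0] - ym[1]
                if sm <= 0.0:
                    hi = mid
                else:
                    lo = mid
                if hi - lo < 1e-16:
                    break
            ye = _rk4_step(y, hi, M, m, l, b, g, omega, A1, A2, delta)
            if ye[0] < 0.0 and 2.0 * ye[2] - ye[3] < 0.0:
                t_evt = t + hi
                td_times[n] = t_evt
                for i in range(5):
                    pre_states[n, i] = ye[i]
                p1, p2 = _collision_vel(ye[0], ye[2], ye[3], M, m, l, b)
                phi_new = _phase_update(ye[4] % (2.0 * math.pi), mode, phi0)
                y[0] = -ye[0]
                y[1] = -ye[1]
                y[2] = p1
                y[3] = p2
                y[4] = phi_new
                for i in range(5):
                    post_states[n, i] = y[i]
                t = t_evt
                t_last_td = t_evt
                n += 1
                armed = False
                s = 0.0
                # early-stop criteria evaluated per touchdown
                if phi_tol > 0.0 and n >= 2:
                    if abs(_circ(post_states[n - 1, 4], post_states[n - 2, 4])) < phi_tol:
                        phi_count += 1
                        if phi_count >= phi_consec:
                            status = STATUS_CONVERGED
                            break
                    else:
                        phi_count = 0
                if tau_tol > 0.0 and n >= 4 and n % 2 == 0:
                    tau = td_times[n - 1] - td_times[n - 3]
                    if prev_tau > 0.0 and abs(tau - prev_tau) < tau_tol:
                        tau_count += 1
                        if tau_count >= tau_consec:
                            status = STATUS_CONVERGED
                            break
                    else:
                        tau_count = 0
                    prev_tau = tau
                continue
            else:
                # ground crossing behind the walker or while scuffing: ignore
                armed = False
                y = y_new
                t += h
                s = s_new
        else:
            y = y_new
            t += h
            s = s_new
            if not armed and s > _ARM_TOL:
                armed = True
        if abs(y[0]) > _FALL_ANGLE or abs(y[2]) > _FALL_RATE:
            status = STATUS_FELL
            break
        if t - t_last_td > max_step_time:
            status = STATUS_FELL
            break
    return n, status, t, y


@njit(cache=True)
def _trial_em(
    y0,
    M, m, l, b, g,
    omega, A1, A2, delta, mode, phi0,
    xi, disc, seed,
    dt, max_steps, max_step_time,
    td_times, td_th1m, td_phi_pre, td_phi_post,
    rec_every, rec_t, rec_y, rec_u,
):
    # disc: 0 = step_held (one draw per joint per step cycle, std xi),
    #       1 = wiener (per integration step, scaled 1/sqrt(dt)),
    #       2 = per_step (per integration step, std xi)
    np.random.seed(seed)
    noise_scale = xi / math.sqrt(dt) if disc == 1 else xi
    y = y0.copy()
    t = 0.0
    s = 2.0 * y[0] - y[1]
    armed = s > _ARM_TOL
    t_last_td = 0.0
    n = 0
    status = STATUS_COMPLETED
    k1 = np.empty(5)
    y_new = np.empty(5)
    rec_cap = rec_t.shape[0]
    rec_n = 0
    istep = 0
    nt1 = 0.0
    nt2 = 0.0
    if disc == 0 and xi > 0.0:
        nt1 = xi * np.random.standard_normal()
        nt2 = xi * np.random.standard_normal()
    while True:
        if n >= max_steps:
            status = STATUS_COMPLETED
            break
        if disc != 0 and xi > 0.0:
            nt1 = noise_scale * np.random.standard_normal()
            nt2 = noise_scale * np.random.standard_normal()
        _deriv(y, k1, M, m, l, b, g, omega, A1, A2, delta, nt1, nt2)
        if rec_every > 0 and istep % rec_every == 0 and rec_n < rec_cap:
            rec_t[rec_n] = t
            for i in range(5):
                rec_y[rec_n, i] = y[i]
            rec_u[rec_n, 0] = A1 * math.cos(y[4]) + nt1
            rec_u[rec_n, 1] = A2 * math.cos(y[4] + delta) + nt2
            rec_n += 1
        for i in range(5):
            y_new[i] = y[i] + dt * k1[i]
        s_new = 2.0 * y_new[0] - y_new[1]
        istep += 1
        if armed and s_new <= 0.0:
            f = s / (s - s_new) if s != s_new else 1.0
            ye = np.empty(5)
            for i in range(5):
                ye[i] = y[i] + f * (y_new[i] - y[i])
            if ye[0] < 0.0 and 2.0 * ye[2] - ye[3] < 0.0:
                t_evt = t + f * dt
                td_times[n] = t_evt
                td_th1m[n] = ye[0]
                phi_pre = ye[4] % (2.0 * math.pi)
                td_phi_pre[n] = phi_pre
                p1, p2 = _collision_vel(ye[0], ye[2], ye[3], M, m, l, b)
                phi_new = _phase_update(phi_pre, mode, phi0)
                td_phi_post[n] = phi_new
                y[0] = -ye[0]
                y[1] = -ye[1]
                y[2] = p1
                y[3] = p2
                y[4] = phi_new
                if disc == 0 and xi > 0.0:
                    nt1 = xi * np.random.standard_normal()
                    nt2 = xi * np.random.standard_normal()
                t = t_evt
                t_last_td = t_evt
                n += 1
                armed = False
                s = 0.0
                continue
            else:
                armed = False
                for i in range(5):
                    y[i] = y_new[i]
                t += dt
                s = s_new
        else:
            for i in range(5):
                y[i] = y_new[i]
            t += dt
            s = s_new
            if not armed and s > _ARM_TOL:
                armed = True
        if not (math.isfinite(y[0]) and math.isfinite(y[2]) and math.isfinite(y[3])):
            status = STATUS_FELL
            break
        if abs(y[0]) > _FALL_ANGLE or abs(y[2]) > _FALL_RATE:
            status = STATUS_FELL
            break
        if t - t_last_td > max_step_time:
            status = STATUS_FELL
            break
    return n, status, t, rec_n


@dataclass
class WalkResult:
    """Raw output of a deterministic walk: one row per touchdown."""

    n_steps: int
    status: int
    t_final: float
    y_final: np.ndarray
    td_times: np.ndarray      # touchdown times, s
    pre_states: np.ndarray    # (n, 5) state just before each touchdown
    post_states: np.ndarray   # (n, 5) state just after each touchdown


def walk(
    y0: np.ndarray,
    walker: WalkerParams,
    cpg: CPGParams,
    *,
    dt: float = 1e-3,
    max_steps: int = 100,
    t_stop: float = 0.0,
    max_step_time: float = 5.0,
    tau_tol: float = 0.0,
    tau_consecutive: int = 5,
    phi_tol: float = 0.0,
    phi_consecutive: int = 5,
) -> WalkResult:
    """Integrate the noise-free walker with RK4 until ``max_steps``
    touchdowns, a stop time, a fall, or an early-stop convergence criterion
    (on stride periods when ``tau_tol > 0``, on post-contact phases when
    ``phi_tol > 0``)."""
    cap = int(max_steps)
    td = np.zeros(cap)
    pre = np.zeros((cap, 5))
    post = np.zeros((cap, 5))
    mode = 0 if cpg.mode is ResetMode.RESETTING else 1
    n, status, t, y = _walk_rk4(
        np.asarray(y0, dtype=np.float64),
        walker.M, walker.m, walker.l, walker.b, walker.g,
        cpg.omega, cpg.A1, cpg.A2, cpg.delta, mode, cpg.phi0,
        dt, cap, t_stop, max_step_time,
        tau_tol, tau_consecutive, phi_tol, phi_consecutive,
        td, pre, post,
    )
    return WalkResult(n, status, t, y, td[:n], pre, post)


@dataclass
class RawTrial:
    """Raw output of a stochastic trial."""

    n_steps: int
    status: int
    t_final: float
    td_times: np.ndarray
    td_theta1_minus: np.ndarray
    td_phi_pre: np.ndarray
    td_phi_post: np.ndarray
    traj_t: np.ndarray | None = None
    traj_y: np.ndarray | None = None
    traj_u: np.ndarray | None = None


def trial(
    y0: np.ndarray,
    walker: WalkerParams,
    cpg: CPGParams,
    *,
    xi: float,
    seed: int,
    dt: float = 1e-5,
    n_steps: int = 1300,
    max_step_time: float = 5.0,
    discretization: str = "step_held",
    record_every: int = 0,
    record_cap: int = 2_000_000,
) -> RawTrial:
    """Stochastic trial with additive torque noise of amplitude ``xi``.

    ``discretization`` selects how the unit-variance Gaussian noise series
    enters the integration: ``step_held`` draws one value per joint per
    step cycle (redrawn at each touchdown) and holds it as a constant
    torque offset of standard deviation ``xi``; ``wiener`` draws every
    integration step with the SDE scaling (velocity contribution
    ``xi sqrt(dt)``); ``per_step`` draws every integration step without
    the scaling (contribution ``xi dt``).
    """
    cap = int(n_steps)
    td = np.zeros(cap)
    th1m = np.zeros(cap)
    phi_pre = np.zeros(cap)
    phi_post = np.zeros(cap)
    if record_every > 0:
        rcap = record_cap
    else:
        rcap = 1
    rec_t = np.zeros(rcap)
    rec_y = np.zeros((rcap, 5))
    rec_u = np.zeros((rcap, 2))
    mode = 0 if cpg.mode is ResetMode.RESETTING else 1
    disc_codes = {"step_held": 0, "wiener": 1, "per_step": 2}
    if discretization not in disc_codes:
        raise ValueError(f"unknown noise discretization {discretization!r}")
    n, status, t, rec_n = _trial_em(
        np.asarray(y0, dtype=np.float64),
        walker.M, walker.m, walker.l, walker.b, walker.g,
        cpg.omega, cpg.A1, cpg.A2, cpg.delta, mode, cpg.phi0,
        float(xi), disc_codes[discretization], int(seed),
        dt, cap, max_step_time,
        td, th1m, phi_pre, phi_post,
        int(record_every), rec_t, rec_y, rec_u,
    )
    out = RawTrial(n, status, t, td[:n], th1m[:n], phi_pre[:n], phi_post[:n])
    if record_every > 0:
        out.traj_t = rec_t[:rec_n]
        out.traj_y = rec_y[:rec_n]
        out.traj_u = rec_u[:rec_n]
    return out
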