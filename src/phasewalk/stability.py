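"""Limit-cycle machinery: Poincaré maps, Floquet multipliers, phase response.

The Poincaré section is the post-touchdown surface ``2 theta1 - theta2 = 0``.
Because the collision map folds the leg swap into the coordinates, the
natural return map is the *touchdown-to-touchdown (one-step) map*; the
stride map is its second iterate, so stride-map multipliers are the squares
of step-map multipliers.  Section coordinates:

* resetting mode — ``(theta1, dtheta1, dtheta2)``; the oscillator phase is
  pinned to ``phi0`` at every touchdown and carries no Floquet mode (this
  is the geometric content of the phase-resetting mechanism);
* flip mode — ``(theta1, dtheta1, dtheta2, phi)``; the free-running phase
  is a live coordinate.

Steady period-1 walking locks the step period to ``pi/omega`` (the
feedforward pattern must repeat, negated, each step), so the stride period
is ``2 pi / omega`` in either mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .biomech import WalkerParams, WalkerState
from .cpg import CPGParams, ResetMode, wrap_phase

__all__ = [
    "LimitCycle",
    "FloquetSpectrum",
    "PRCSample",
    "stride_map",
    "step_map",
    "find_limit_cycle",
    "floquet_multipliers",
    "phase_response",
    "energy_cost",
]

DEFAULT_DT = 2.5e-4  # RK4 step for all noiseless flows (s)


def section_dim(cpg: CPGParams) -> int:
    return 4 if cpg.mode is ResetMode.FLIP else 3


def _to_full(z: np.ndarray, cpg: CPGParams) -> np.ndarray:
    """Section coordinates -> full state (theta2 = 2 theta1 on the section)."""
    phi = z[3] if cpg.mode is ResetMode.FLIP else cpg.phi0
    return np.array([z[0], 2.0 * z[0], z[1], z[2], phi])


def _to_section(y: np.ndarray, cpg: CPGParams) -> np.ndarray:
    if cpg.mode is ResetMode.FLIP:
        return np.array([y[0], y[2], y[3], y[4]])
    return np.array([y[0], y[2], y[3]])


def _return_map(
    z: np.ndarray, walker: WalkerParams, cpg: CPGParams, n_steps: int, dt: float
) -> tuple[np.ndarray, _kernels.WalkResult]:
    res = _kernels.walk(_to_full(z, cpg), walker, cpg, dt=dt, max_steps=n_steps)
    if res.n_steps < n_steps:
        raise RuntimeError(
            f"walker fell after {res.n_steps}/{n_steps} touchdowns during map evaluation"
        )
    return _to_section(res.post_states[n_steps - 1], cpg), res


def step_map(
    z: np.ndarray, walker: WalkerParams, cpg: CPGParams, *, dt: float = DEFAULT_DT
) -> np.ndarray:
    """One-step (touchdown-to-touchdown) Poincaré return map on the section."""
    return _return_map(np.asarray(z, float), walker, cpg, 1, dt)[0]


def stride_map(
    z: np.ndarray, walker: WalkerParams, cpg: CPGParams, *, dt: float = DEFAULT_DT
) -> np.ndarray:
    """Two-step (stride) return map: the second iterate of :func:`step_map`."""
    return _return_map(np.asarray(z, float), walker, cpg, 2, dt)[0]


@dataclass
class LimitCycle:
    """A noiseless periodic gait, anchored at its post-touchdown fixed point."""

    fixed_point: np.ndarray     # section coordinates
    post_state: np.ndarray      # full 5-state just after touchdown
    tau: float                  # stride period (s)
    step_period: float          # single-step period (s)
    theta1_minus: float         # stance angle at touchdown (rad)
    v: float                    # gait speed (m/s)
    epsilon: float              # energy cost over one step cycle ((N·m)^2·s)
    mode: ResetMode
    cpg: CPGParams
    residual: float             # |P(z*) - z*| of the solved fixed point


@dataclass
class FloquetSpectrum:
    """Eigenvalues of the linearized Poincaré return map at a fixed point."""

    multipliers: np.ndarray
    map_steps: int              # 1 = touchdown map, 2 = stride map

    @property
    def dominant_magnitude(self) -> float:
        return float(np.max(np.abs(self.multipliers)))

    @property
    def dominant(self) -> complex:
        return complex(self.multipliers[int(np.argmax(np.abs(self.multipliers)))])

    @property
    def dominant_is_real_positive(self) -> bool:
        lam = self.dominant
        return abs(lam.imag) < 1e-8 * max(1.0, abs(lam.real)) and lam.real > 0

    @property
    def stable(self) -> bool:
        return self.dominant_magnitude < 1.0


@dataclass
class PRCSample:
    """Asymptotic locomotion-phase shift caused by one impulsive perturbation."""

    perturbation_phase: float   # fraction of the stride cycle in [0, 1)
    perturbation: np.ndarray    # velocity impulse (dtheta1, dtheta2), rad/s
    phase_shift_s: float        # asymptotic touchdown-time offset (s)
    phase_shift_rad: float      # same, as locomotion phase (2 pi per stride)


def energy_cost(cpg: CPGParams, phi_plus: float, step_period: float) -> float:
    """Torque cost ``int (u1^2 + u2^2) dt`` over one noiseless step cycle.

    On the cycle the torques are pure sinusoids starting at phase
    ``phi_plus``, so the integral has the closed form
    ``sum_i Ai^2 [T/2 + (sin 2(phi_i + w T) - sin 2 phi_i)/(4 w)]``.  With
    the period-1 lock ``w T = pi`` the oscillatory part vanishes and
    ``epsilon = (A1^2 + A2^2) T / 2``.
    """
    w, T = cpg.omega, step_period
    total = 0.0
    for amp, ph in ((cpg.A1, phi_plus), (cpg.A2, phi_plus + cpg.delta)):
        total += amp * amp * (
            0.5 * T + (math.sin(2.0 * (ph + w * T)) - math.sin(2.0 * ph)) / (4.0 * w)
        )
    return total


def converge_forward(
    walker: WalkerParams,
    cpg: CPGParams,
    initial: WalkerState,
    phi_initial: float,
    *,
    dt: float = DEFAULT_DT,
    max_steps: int = 400,
    tau_tol: float = 1e-9,
) -> np.ndarray | None:
    """Forward-simulate until stride periods converge; return the section
    fixed-point estimate, or None if the walker falls or never settles."""
    y0 = _kernels.pack_state(initial, phi_initial)
    res = _kernels.walk(
        y0, walker, cpg, dt=dt, max_steps=max_steps,
        tau_tol=tau_tol, tau_consecutive=5,
    )
    if res.status != _kernels.STATUS_CONVERGED:
        return None
    return _to_section(res.post_states[res.n_steps - 1], cpg)


def find_limit_cycle(
    walker: WalkerParams,
    cpg: CPGParams,
    guess: np.ndarray,
    *,
    dt: float = DEFAULT_DT,
    tol: float = 1e-10,
    max_iter: int = 30,
    fd_step: float = 1e-6,
) -> LimitCycle:
    """Damped Newton solve for a fixed point of the stride map.

    ``guess`` is a section state (use :func:`converge_forward` to obtain
    one).  The Jacobian is estimated by central finite differences.  Raises
    ``RuntimeError`` naming the last residual on divergence.
    """
    z = np.asarray(guess, dtype=float).copy()
    d = section_dim(cpg)
    if len(z) != d:
        raise ValueError(f"guess has dimension {len(z)}, expected {d}")

    def F(zz: np.ndarray) -> np.ndarray:
        out = _return_map(zz, walker, cpg, 2, dt)[0] - zz
        if d == 4:
            out[3] = (out[3] + math.pi) % (2.0 * math.pi) - math.pi
        return out

    f = F(z)
    for _ in range(max_iter):
        nf = float(np.max(np.abs(f)))
        if nf < tol:
            break
        J = np.zeros((d, d))
        for j in range(d):
            zp = z.copy(); zp[j] += fd_step
            zm = z.copy(); zm[j] -= fd_step
            df = F(zp) - F(zm)
            J[:, j] = df / (2.0 * fd_step)
        try:
            dz = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular Newton system at residual {nf:.3e}") from exc
        lam = 1.0
        for _ in range(8):
            z_try = z + lam * dz
            try:
                f_try = F(z_try)
            except RuntimeError:
                lam *= 0.5
                continue
            if np.max(np.abs(f_try)) < nf:
                z, f = z_try, f_try
                break
            lam *= 0.5
        else:
            raise RuntimeError(f"Newton stalled at residual {nf:.3e}")
    else:
        raise RuntimeError(
            f"no convergence in {max_iter} Newton iterations; "
            f"last residual {float(np.max(np.abs(f))):.3e}"
        )

    _, res = _return_map(z, walker, cpg, 2, dt)
    tau = float(res.td_times[1])
    step_period = float(res.td_times[0])
    th1m = float(res.pre_states[1, 0])
    v = 2.0 * walker.l * abs(math.sin(th1m)) / step_period
    phi_plus = float(res.post_states[1, 4])
    eps = energy_cost(cpg, phi_plus, step_period)
    return LimitCycle(
        fixed_point=z,
        post_state=_to_full(z, cpg),
        tau=tau,
        step_period=step_period,
        theta1_minus=th1m,
        v=v,
        epsilon=eps,
        mode=cpg.mode,
        cpg=cpg,
        residual=float(np.max(np.abs(f))),
    )


def floquet_multipliers(
    cycle: LimitCycle,
    walker: WalkerParams,
    cpg: CPGParams | None = None,
    *,
    h: float = 1e-6,
    map_steps: int = 1,
    dt: float = DEFAULT_DT,
) -> FloquetSpectrum:
    """Floquet multipliers of the touchdown Poincaré return map.

    Central-difference Jacobian of the ``map_steps``-step return map at the
    cycle's fixed point (default: the one-step touchdown map; the stride
    map's multipliers are its squares).
    """
    cpg = cycle.cpg if cpg is None else cpg
    z = cycle.fixed_point
    d = len(z)
    J = np.zeros((d, d))
    for j in range(d):
        zp = z.copy(); zp[j] += h
        zm = z.copy(); zm[j] -= h
        fp = _return_map(zp, walker, cpg, map_steps, dt)[0]
        fm = _return_map(zm, walker, cpg, map_steps, dt)[0]
        df = fp - fm
        if d == 4:
            df[3] = (df[3] + math.pi) % (2.0 * math.pi) - math.pi
        J[:, j] = df / (2.0 * h)
    if not np.all(np.isfinite(J)):
        raise ArithmeticError("non-finite Jacobian in Floquet analysis")
    mult = np.linalg.eigvals(J)
    order = np.argsort(-np.abs(mult))
    return FloquetSpectrum(multipliers=mult[order], map_steps=map_steps)


def phase_response(
    cycle: LimitCycle,
    walker: WalkerParams,
    cpg: CPGParams | None = None,
    *,
    perturbation: tuple[float, float],
    at_phase: float,
    horizon: int = 30,
    dt: float = DEFAULT_DT,
) -> PRCSample:
    """Asymptotic locomotion-phase shift from a velocity impulse.

    The impulse ``(d dtheta1, d dtheta2)`` is applied at ``at_phase``
    (fraction of the stride cycle) after a touchdown on the limit cycle;
    the shift is the difference of the ``horizon``-th subsequent touchdown
    time between perturbed and unperturbed runs.  With phase resetting the
    shift is generically nonzero and depends on ``at_phase``; without it
    the free-running oscillator re-entrains the gait and the shift decays
    to zero.
    """
    cpg = cycle.cpg if cpg is None else cpg
    if not 0.0 <= at_phase < 1.0:
        raise ValueError("at_phase must lie in [0, 1)")
    y0 = cycle.post_state
    n_steps = 2 * horizon
    ref = _kernels.walk(y0, walker, cpg, dt=dt, max_steps=n_steps)
    if ref.n_steps < n_steps:
        raise RuntimeError("reference flow fell before the horizon")
    t_ref = float(ref.td_times[n_steps - 1])
    if at_phase > 0.0:
        lead = _kernels.walk(
            y0, walker, cpg, dt=dt, max_steps=n_steps + 4,
            t_stop=at_phase * cycle.tau,
        )
        y = lead.y_final.copy()
        k = lead.n_steps
        t_lead = lead.t_final
    else:
        y = y0.copy()
        k = 0
        t_lead = 0.0
    y[2] += perturbation[0]
    y[3] += perturbation[1]
    rest = _kernels.walk(y, walker, cpg, dt=dt, max_steps=n_steps - k)
    if rest.n_steps < n_steps - k:
        raise RuntimeError("perturbed flow fell before the horizon")
    t_pert = float(t_lead + rest.td_times[n_steps - k - 1])
    shift = t_pert - t_ref
    return PRCSample(
        perturbation_phase=at_phase,
        perturbation=np.asarray(perturbation, float),
        phase_shift_s=shift,
        phase_shift_rad=2.0 * math.pi * shift / cycle.tau,
    )
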