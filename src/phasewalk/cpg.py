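"""Phase-oscillator central pattern generator (CPG).

A single oscillator with phase ``phi`` advancing at a constant intrinsic
frequency ``omega`` drives the walker through feedforward sinusoidal
torques,

    u1 = A1 cos(phi) + sigma1
    u2 = A2 cos(phi + delta) + sigma2,

where ``sigma1, sigma2`` are additive torque-noise terms.  At every foot
contact the oscillator is updated in one of two ways:

* **resetting** — the phase is reset to a constant ``phi0``, coupling the
  neural rhythm to the mechanical event (sensory phase resetting);
* **flip** — the phase jumps by ``-pi`` so the torque pattern negates,
  mirroring the leg-role exchange, but the rhythm itself keeps free-running.

``phi0`` is not a free parameter: it is designated as the post-contact phase
to which the non-resetting, noise-free gait converges on its limit cycle, so
that the two modes share the identical noiseless gait and differ only in
their response to perturbations.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

from .biomech import Torques, WalkerParams, WalkerState

__all__ = [
    "ResetMode",
    "CPGParams",
    "CPGState",
    "phase_advance",
    "feedforward_torques",
    "touchdown_phase_update",
    "calibrate_phi0",
]

TWO_PI = 2.0 * math.pi


class ResetMode(enum.Enum):
    """How the oscillator phase is updated at touchdown."""

    RESETTING = "resetting"
    FLIP = "flip"


def wrap_phase(phi: float) -> float:
    """Reduce a phase to [0, 2*pi)."""
    return phi % TWO_PI


@dataclass(frozen=True)
class CPGParams:
    """Oscillator frequency, torque amplitudes/phasing, and reset rule.

    ``omega`` defaults to 4.8 rad/s, matching the stride cadence of human
    walking (period-1 gaits of this controller lock the step period to
    ``pi/omega`` ≈ 0.654 s, i.e. a ~1.31 s stride).
    """

    omega: float = 4.8       # intrinsic frequency, rad/s
    A1: float = 4.9          # ankle torque amplitude, N·m
    A2: float = 10.0         # hip torque amplitude, N·m
    delta: float = 0.47      # phase lead of u2 over u1, rad
    phi0: float = 0.0        # reset phase, rad (calibrated, see calibrate_phi0)
    mode: ResetMode = ResetMode.RESETTING

    def __post_init__(self) -> None:
        if not self.omega > 0.0:
            raise ValueError("omega must be positive")
        if self.A1 < 0.0 or self.A2 < 0.0:
            raise ValueError("torque amplitudes must be non-negative")
        object.__setattr__(self, "delta", wrap_phase(self.delta))
        object.__setattr__(self, "phi0", wrap_phase(self.phi0))
        if isinstance(self.mode, str):
            object.__setattr__(self, "mode", ResetMode(self.mode))

    def with_mode(self, mode: ResetMode | str) -> "CPGParams":
        return replace(self, mode=ResetMode(mode) if isinstance(mode, str) else mode)

    def with_phi0(self, phi0: float) -> "CPGParams":
        return replace(self, phi0=wrap_phase(phi0))


@dataclass
class CPGState:
    """Oscillator phase, wrapped to [0, 2*pi)."""

    phi: float = 0.0

    def __post_init__(self) -> None:
        self.phi = wrap_phase(self.phi)


def phase_advance(phi: float, omega: float, dt: float) -> float:
    """Advance the free-running phase by ``omega * dt``, wrapped."""
    if dt < 0.0:
        raise ValueError("dt must be non-negative")
    return wrap_phase(phi + omega * dt)


def feedforward_torques(
    phi: float, params: CPGParams, noise: tuple[float, float] = (0.0, 0.0)
) -> Torques:
    """Sinusoidal motor command at phase ``phi`` plus additive torque noise."""
    return Torques(
        params.A1 * math.cos(phi) + noise[0],
        params.A2 * math.cos(phi + params.delta) + noise[1],
    )


def touchdown_phase_update(phi_minus: float, params: CPGParams) -> float:
    """Oscillator phase just after a touchdown event.

    Resetting mode returns the constant ``phi0``; flip mode returns
    ``phi- - pi`` (wrapped), which negates both feedforward torques in step
    with the leg-role exchange.
    """
    if params.mode is ResetMode.RESETTING:
        return params.phi0
    return wrap_phase(phi_minus - math.pi)


def calibrate_phi0(
    walker: WalkerParams,
    cpg: CPGParams,
    initial: WalkerState,
    phi_initial: float = 0.0,
    *,
    dt: float = 1e-3,
    tol: float = 1e-9,
    consecutive: int = 5,
    max_steps: int = 2000,
) -> float:
    """Post-contact phase of the converged non-resetting, noise-free gait.

    Runs the flip-mode model without noise from ``initial`` and returns the
    value to which the post-touchdown phase ``phi+`` converges on the limit
    cycle.  Convergence requires ``consecutive`` successive touchdowns with
    circular phase difference below ``tol``.  With this ``phi0`` the
    noiseless gaits of the resetting and flip modes coincide.

    Raises ``RuntimeError`` if no convergence occurs within ``max_steps``
    touchdowns (unstable or non-walking parameters).
    """
    from . import _kernels

    y0 = _kernels.pack_state(initial, phi_initial)
    res = _kernels.walk(
        y0,
        walker,
        cpg.with_mode(ResetMode.FLIP),
        dt=dt,
        max_steps=max_steps,
        phi_tol=tol,
        phi_consecutive=consecutive,
    )
    if res.status == _kernels.STATUS_FELL:
        raise RuntimeError("phi0 calibration failed: the model fell")
    phis = res.post_states[: res.n_steps, 4]
    if res.status != _kernels.STATUS_CONVERGED:
        last = 0.0 if len(phis) < 2 else abs(_circ_diff(phis[-1], phis[-2]))
        raise RuntimeError(
            f"phi0 calibration did not converge within {max_steps} steps "
            f"(last phase change {last:.3e} rad)"
        )
    return wrap_phase(float(phis[res.n_steps - 1]))


def _circ_diff(a: float, b: float) -> float:
    """Signed circular difference a - b in (-pi, pi]."""
    return (a - b + math.pi) % TWO_PI - math.pi
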