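"""Stochastic trial engine and stride-interval extraction.

A trial integrates the coupled walker + CPG system with the Euler–Maruyama
scheme (default time step 1e-5 s) under additive joint-torque noise

    sigma_i = xi * U_i,   i = 1, 2,

with ``U_1, U_2`` independent unit-variance Gaussian white-noise series.
Three readings of the noise discretization are provided (see
:class:`NoiseSpec`); the default holds one draw per joint constant over
each step cycle, redrawn at every touchdown — the reading that reproduces
the reference stride-interval variability (SD ~ 0.03 s at xi = 1) and
keeps both reset modes walking for xi <= 1.  At every touchdown the
collision map and the oscillator's
phase update are applied instantaneously (without noise), and integration
resumes from the event time.

A *step* is one touchdown-to-touchdown interval; a *stride* is two
consecutive steps, so stride intervals are differences between every other
touchdown and do not overlap.  The standard trial protocol walks 1300
steps (650 strides) and discards the first 150 strides as transient,
leaving N = 500 intervals for analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernels
from .biomech import WalkerParams, WalkerState, step_length
from .cpg import CPGParams

__all__ = [
    "NoiseSpec",
    "StrideSeries",
    "TrialResult",
    "run_trial",
    "analysis_window",
    "gait_speed",
    "write_stride_csv",
    "read_stride_csv",
]

#: Strides shorter than this trigger a diagnostic warning (s).
SHORT_STRIDE_WARN = 0.1


@dataclass(frozen=True)
class NoiseSpec:
    """Additive torque-noise configuration.

    ``discretization`` selects how the unit-variance white Gaussian series
    enters the integration:

    * ``"step_held"`` (default) — one draw per joint per step cycle, held
      as a constant torque offset of SD ``xi`` until the next touchdown
      (discrete-time white noise at the gait's own rate);
    * ``"wiener"`` — a fresh draw every integration step with the SDE
      (Euler–Maruyama) scaling, velocity contribution ``xi sqrt(dt)``;
    * ``"per_step"`` — a fresh draw every integration step held over
      ``dt``, velocity contribution ``xi dt``.
    """

    xi: float
    seed: int
    discretization: str = "step_held"

    def __post_init__(self) -> None:
        if self.xi < 0:
            raise ValueError("noise amplitude xi must be non-negative")
        if self.discretization not in ("step_held", "wiener", "per_step"):
            raise ValueError(
                "discretization must be 'step_held', 'wiener' or 'per_step'"
            )


@dataclass
class StrideSeries:
    """Ordered stride intervals (s)."""

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if len(self.x) < 1:
            raise ValueError("stride series must be non-empty")
        if not np.all(self.x > 0):
            raise ValueError("stride intervals must be strictly positive")

    @property
    def N(self) -> int:
        return len(self.x)


@dataclass
class TrialResult:
    """Outcome of one stochastic trial."""

    stride_intervals: StrideSeries | None
    step_times: np.ndarray            # touchdown times incl. t = 0 start
    theta1_minus: np.ndarray          # pre-impact stance angle per touchdown
    fell: bool
    hip_displacement: float           # total forward travel (m)
    walker: WalkerParams
    cpg: CPGParams
    noise: NoiseSpec
    dt: float
    n_steps_requested: int
    trajectory: dict | None = None    # optional subsampled records

    @property
    def n_steps(self) -> int:
        return len(self.step_times) - 1


def default_initial_state(cycle) -> tuple[WalkerState, float]:
    """Initial condition from a limit cycle's post-touchdown fixed point."""
    y = cycle.post_state
    return WalkerState(y[0], y[1], y[2], y[3]), float(y[4])


def run_trial(
    walker: WalkerParams,
    cpg: CPGParams,
    noise: NoiseSpec,
    *,
    n_steps: int = 1300,
    dt: float = 1e-5,
    initial: WalkerState,
    phi_initial: float | None = None,
    record_every: int = 0,
) -> TrialResult:
    """Run one Euler–Maruyama trial of ``n_steps`` touchdowns.

    The initial state should normally be the noiseless limit-cycle fixed
    point for the trial's parameter set (see ``stability.find_limit_cycle``);
    transients from other starts are removed by the stride discard anyway.
    A fall terminates the trial early and is reported in ``fell`` rather
    than raised.  ``record_every`` > 0 stores every that-many-th
    integration sample of the trajectory (1e-3 s at the default dt with
    ``record_every=100``).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    phi = cpg.phi0 if phi_initial is None else phi_initial
    y0 = _kernels.pack_state(initial, phi)
    raw = _kernels.trial(
        y0,
        walker,
        cpg,
        xi=noise.xi,
        seed=noise.seed,
        dt=dt,
        n_steps=n_steps,
        discretization=noise.discretization,
        record_every=record_every,
    )
    if not np.all(np.isfinite(raw.td_times)):
        raise ArithmeticError("non-finite state encountered during trial")
    fell = raw.status == _kernels.STATUS_FELL
    td = np.concatenate([[0.0], raw.td_times])
    strides = np.diff(td[::2])
    series = None
    if len(strides) >= 1 and not fell:
        if np.any(strides < SHORT_STRIDE_WARN):
            warnings.warn(
                f"{np.sum(strides < SHORT_STRIDE_WARN)} stride interval(s) "
                f"below {SHORT_STRIDE_WARN} s: event handling may be suspect",
                RuntimeWarning,
            )
        series = StrideSeries(strides)
    hip = float(np.sum(2.0 * walker.l * np.abs(np.sin(raw.td_theta1_minus))))
    traj = None
    if record_every > 0:
        traj = {"t": raw.traj_t, "state": raw.traj_y, "u": raw.traj_u}
    return TrialResult(
        stride_intervals=series,
        step_times=td,
        theta1_minus=raw.td_theta1_minus,
        fell=fell,
        hip_displacement=hip,
        walker=walker,
        cpg=cpg,
        noise=noise,
        dt=dt,
        n_steps_requested=n_steps,
        trajectory=traj,
    )


def analysis_window(
    trial: TrialResult, discard: int = 150, keep: int = 500
) -> StrideSeries:
    """Strides ``discard+1 .. discard+keep`` of a trial.

    The defaults implement the standard protocol: drop 150 transient
    strides, analyze the next 500.  Raises ``ValueError`` naming the
    shortfall if the trial is too short (e.g. because it fell).
    """
    if trial.stride_intervals is None:
        raise ValueError("trial has no analyzable strides (fell before two steps)")
    x = trial.stride_intervals.x
    if len(x) < discard + keep:
        raise ValueError(
            f"trial has only {len(x)} strides; {discard + keep} needed "
            f"({max(len(x) - discard, 0)} available after discarding {discard})"
        )
    return StrideSeries(x[discard : discard + keep])


def gait_speed(trial: TrialResult, discard: int = 150, keep: int | None = None) -> float:
    """Mean forward speed over the analysis window (m/s).

    Forward travel is accumulated from per-step contact geometry: the
    contact point (and hip) advance ``2 l |sin theta1-|`` per step.  The
    window spans strides ``discard+1 .. discard+keep`` (all remaining
    strides when ``keep`` is None).
    """
    if trial.fell:
        raise ValueError("gait speed undefined for a fallen trial")
    if trial.n_steps < 2:
        raise ValueError("need at least 2 touchdowns to estimate speed")
    n_strides = trial.n_steps // 2
    if keep is None:
        keep = n_strides - discard
    if keep <= 0 or discard + keep > n_strides:
        raise ValueError("analysis window exceeds available strides")
    first_step = 2 * discard       # index into touchdown list (0 = start)
    last_step = 2 * (discard + keep)
    dist = float(
        np.sum(
            2.0
            * trial.walker.l
            * np.abs(np.sin(trial.theta1_minus[first_step:last_step]))
        )
    )
    elapsed = trial.step_times[last_step] - trial.step_times[first_step]
    return dist / elapsed


# ---------------------------------------------------------------------------
# delimited-text I/O: one stride series per file, parameters in '#' headers


def _header_lines(trial: TrialResult) -> list[str]:
    c, w, n = trial.cpg, trial.walker, trial.noise
    items = {
        "M": w.M, "m": w.m, "l": w.l, "b": w.b, "g": w.g,
        "omega": c.omega, "A1": c.A1, "A2": c.A2, "delta": c.delta,
        "phi0": c.phi0, "mode": c.mode.value,
        "xi": n.xi, "seed": n.seed, "discretization": n.discretization,
        "dt": trial.dt, "n_steps": trial.n_steps_requested,
        "fell": trial.fell,
    }
    return [f"# {k}={v}" for k, v in items.items()]


def write_stride_csv(path, trial: TrialResult) -> None:
    """Write a trial's stride intervals as CSV with '# key=value' metadata."""
    path = Path(path)
    lines = _header_lines(trial)
    lines.append("stride,interval_s")
    if trial.stride_intervals is not None:
        for i, v in enumerate(trial.stride_intervals.x, start=1):
            lines.append(f"{i},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_stride_csv(path) -> tuple[StrideSeries, dict]:
    """Read a stride-series CSV written by :func:`write_stride_csv`.

    Returns the series and the metadata dict (values as strings).
    """
    meta: dict[str, str] = {}
    xs: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif not line.startswith("stride,"):
                _, _, val = line.partition(",")
                xs.append(float(val))
    return StrideSeries(np.array(xs)), meta
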