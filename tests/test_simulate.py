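"""Trial engine: noiseless consistency, reproducibility, windows, speed, I/O."""

import math

import numpy as np
import pytest

from phasewalk.cpg import ResetMode
from phasewalk.simulate import (
    NoiseSpec,
    StrideSeries,
    analysis_window,
    gait_speed,
    read_stride_csv,
    run_trial,
    write_stride_csv,
)

DT = 1e-4  # trial integration step used in these tests


@pytest.fixture(scope="module")
def quiet_trial(walker, cpg_resetting, initial_04):
    return run_trial(
        walker, cpg_resetting, NoiseSpec(xi=0.0, seed=0),
        n_steps=40, dt=DT, initial=initial_04,
    )


def test_noiseless_trial_has_constant_stride_intervals(quiet_trial, v04_cycle):
    """Started on the limit cycle, a noise-free trial repeats the stride
    period (up to the first-order integrator's O(dt) cycle offset and a
    short settling transient onto the discrete-scheme cycle)."""
    x = quiet_trial.stride_intervals.x
    assert not quiet_trial.fell
    assert len(x) == 20
    assert np.allclose(x, v04_cycle.tau, atol=1e-3)
    assert np.std(x[5:]) < 1e-5


def test_noiseless_modes_agree(walker, cpg_resetting, cpg_flip, initial_04):
    """Without noise the resetting and flip modes walk the same gait: from
    the shared fixed point their stride sequences coincide up to the
    integrator's O(dt) per-step phase error (the resetting mode pins the
    oscillator to phi0 each touchdown, the flip mode free-runs)."""
    a = run_trial(walker, cpg_resetting, NoiseSpec(xi=0.0, seed=0),
                  n_steps=30, dt=DT, initial=initial_04)
    b = run_trial(walker, cpg_flip, NoiseSpec(xi=0.0, seed=0),
                  n_steps=30, dt=DT, initial=initial_04)
    assert np.allclose(a.stride_intervals.x, b.stride_intervals.x, atol=1e-3)
    assert np.allclose(a.theta1_minus, b.theta1_minus, atol=1e-3)
    # identical configurations lead to identical first touchdowns
    assert a.step_times[1] == b.step_times[1]


def test_seed_reproducibility(walker, cpg_resetting, initial_04):
    kw = dict(n_steps=30, dt=DT, initial=initial_04)
    a = run_trial(walker, cpg_resetting, NoiseSpec(xi=1.0, seed=42), **kw)
    b = run_trial(walker, cpg_resetting, NoiseSpec(xi=1.0, seed=42), **kw)
    c = run_trial(walker, cpg_resetting, NoiseSpec(xi=1.0, seed=43), **kw)
    assert np.array_equal(a.step_times, b.step_times)
    assert not np.array_equal(a.step_times, c.step_times)


def test_stride_count_is_half_step_count(walker, cpg_resetting, initial_04):
    t = run_trial(walker, cpg_resetting, NoiseSpec(xi=0.01, seed=5),
                  n_steps=31, dt=DT, initial=initial_04)
    assert t.n_steps == 31
    assert t.stride_intervals.N == 15  # floor(31 / 2)
    # strides are differences between every other touchdown
    td = t.step_times
    assert t.stride_intervals.x == pytest.approx(np.diff(td[::2])[:15])


def test_noise_discretizations_differ(walker, cpg_resetting, initial_04):
    kw = dict(n_steps=20, dt=DT, initial=initial_04)
    sds = {}
    for disc in ("step_held", "wiener", "per_step"):
        t = run_trial(walker, cpg_resetting,
                      NoiseSpec(xi=0.5, seed=11, discretization=disc), **kw)
        sds[disc] = float(np.std(t.stride_intervals.x))
    assert sds["per_step"] < sds["step_held"]
    assert sds["per_step"] < sds["wiener"]


def test_analysis_window_defaults_and_errors(walker, cpg_resetting, initial_04):
    t = run_trial(walker, cpg_resetting, NoiseSpec(xi=0.01, seed=1),
                  n_steps=60, dt=DT, initial=initial_04)
    full = analysis_window(t, discard=0, keep=30)
    assert np.array_equal(full.x, t.stride_intervals.x)
    w = analysis_window(t, discard=10, keep=15)
    assert np.array_equal(w.x, t.stride_intervals.x[10:25])
    with pytest.raises(ValueError, match="30"):
        analysis_window(t, discard=0, keep=31)
    with pytest.raises(ValueError, match="available"):
        analysis_window(t)  # 150 + 500 strides unavailable


def test_gait_speed_geometry_oracle(quiet_trial, walker, v04_cycle):
    """On the limit cycle, v = 2 l |sin theta1-| / T exactly."""
    v = gait_speed(quiet_trial, discard=2, keep=10)
    expected = (
        2.0 * walker.l * abs(math.sin(v04_cycle.theta1_minus))
        / v04_cycle.step_period
    )
    # the trial integrates with first-order Euler at dt = 1e-4, so its
    # realized cycle sits O(dt) away from the RK4 reference cycle
    assert v == pytest.approx(expected, rel=2e-3)
    assert v == pytest.approx(0.4, abs=0.01)


def test_gait_speed_scales_inversely_with_duration(quiet_trial):
    """Doubling all durations at fixed geometry halves the speed."""
    t2 = type(quiet_trial)(**{**quiet_trial.__dict__})
    t2.step_times = 2.0 * quiet_trial.step_times
    assert gait_speed(t2, discard=2, keep=10) == pytest.approx(
        0.5 * gait_speed(quiet_trial, discard=2, keep=10)
    )


def test_stride_series_validation():
    with pytest.raises(ValueError):
        StrideSeries(np.array([1.0, -0.5]))
    with pytest.raises(ValueError):
        StrideSeries(np.array([]))


def test_stride_csv_roundtrip(tmp_path, walker, cpg_resetting, initial_04):
    t = run_trial(walker, cpg_resetting, NoiseSpec(xi=0.1, seed=3),
                  n_steps=20, dt=DT, initial=initial_04)
    path = tmp_path / "strides.csv"
    write_stride_csv(path, t)
    series, meta = read_stride_csv(path)
    assert np.array_equal(series.x, t.stride_intervals.x)
    assert meta["mode"] == "resetting"
    assert float(meta["xi"]) == 0.1
    assert int(meta["seed"]) == 3
    assert meta["discretization"] == "step_held"
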