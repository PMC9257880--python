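"""Poincaré maps, Floquet spectra, and phase-response behavior."""

import math

import numpy as np
import pytest

from phasewalk.cpg import CPGParams, ResetMode
from phasewalk.simulate import NoiseSpec, run_trial
from phasewalk.stability import (
    find_limit_cycle,
    floquet_multipliers,
    phase_response,
    step_map,
    stride_map,
)


def test_fixed_point_maps_to_itself(walker, v04_cycle, cpg_flip):
    z = v04_cycle.fixed_point
    err = np.abs(stride_map(z, walker, cpg_flip) - z)
    err[3] = abs((err[3] + math.pi) % (2 * math.pi) - math.pi)
    assert np.max(err) < 1e-9


def test_stride_map_is_step_map_squared(walker, v04_cycle, cpg_flip):
    z = v04_cycle.fixed_point + np.array([1e-3, -2e-3, 1e-3, 5e-4])
    once = step_map(z, walker, cpg_flip)
    twice = step_map(once, walker, cpg_flip)
    assert np.allclose(twice, stride_map(z, walker, cpg_flip), atol=1e-10)


def test_cycle_locks_step_period_to_half_oscillator_cycle(v04_cycle):
    T = math.pi / v04_cycle.cpg.omega
    assert v04_cycle.step_period == pytest.approx(T, abs=1e-7)
    assert v04_cycle.tau == pytest.approx(2 * T, abs=1e-7)


def test_cycle_speed_near_reference(v04_cycle):
    assert v04_cycle.v == pytest.approx(0.4, abs=0.01)


def test_map_matches_full_trial_extraction(walker, v04_cycle, cpg_resetting,
                                           initial_04):
    """Cross-module consistency: the noiseless trial engine reproduces the
    stride map's touchdown states."""
    trial = run_trial(
        walker, cpg_resetting, NoiseSpec(xi=0.0, seed=0),
        n_steps=4, dt=1e-4, initial=initial_04,
    )
    z = v04_cycle.fixed_point[:3]
    mapped = stride_map(z, walker, cpg_resetting)
    # trial touchdown times should be near multiples of the step period
    assert np.allclose(
        np.diff(trial.step_times), v04_cycle.step_period, atol=1e-3
    )
    assert np.allclose(mapped, z, atol=1e-8)


def test_reset_and_flip_cycles_coincide(walker, v04_cycle, cpg_resetting):
    cyc_r = find_limit_cycle(walker, cpg_resetting, v04_cycle.fixed_point[:3])
    assert cyc_r.fixed_point == pytest.approx(v04_cycle.fixed_point[:3], abs=1e-8)
    assert cyc_r.tau == pytest.approx(v04_cycle.tau, abs=1e-8)
    assert cyc_r.epsilon == pytest.approx(v04_cycle.epsilon, rel=1e-8)


def test_flip_dominant_multiplier(walker, v04_cycle):
    spec = floquet_multipliers(v04_cycle, walker)
    assert spec.stable
    assert spec.dominant_is_real_positive
    assert spec.dominant_magnitude == pytest.approx(0.65, abs=0.02)


def test_reset_dominant_close_to_flip(walker, v04_cycle, cpg_resetting):
    cyc_r = find_limit_cycle(walker, cpg_resetting, v04_cycle.fixed_point[:3])
    s_flip = floquet_multipliers(v04_cycle, walker)
    s_reset = floquet_multipliers(cyc_r, walker)
    assert s_reset.dominant_is_real_positive
    assert s_reset.dominant_magnitude == pytest.approx(
        s_flip.dominant_magnitude, abs=0.01
    )


def test_stride_map_multipliers_are_squares(walker, v04_cycle):
    one = floquet_multipliers(v04_cycle, walker, map_steps=1)
    two = floquet_multipliers(v04_cycle, walker, map_steps=2)
    assert two.dominant_magnitude == pytest.approx(
        one.dominant_magnitude**2, abs=1e-3
    )


def test_multipliers_stable_under_fd_step(walker, v04_cycle):
    mags = [
        floquet_multipliers(v04_cycle, walker, h=h).dominant_magnitude
        for h in (1e-7, 1e-6, 1e-5)
    ]
    assert max(mags) - min(mags) < 1e-3


def test_perturbation_decay_follows_dominant_multiplier(walker, v04_cycle,
                                                        cpg_flip):
    """Deviation norms contract per step at the dominant rate (log-linear
    fit within 5%) once the fast modes have died out."""
    lam = floquet_multipliers(v04_cycle, walker).dominant_magnitude
    z0 = v04_cycle.fixed_point
    z = z0 + 1e-4 * np.array([1.0, 1.0, 1.0, 1.0])
    norms = []
    for _ in range(10):
        z = step_map(z, walker, cpg_flip)
        d = z - z0
        d[3] = (d[3] + math.pi) % (2 * math.pi) - math.pi
        norms.append(np.linalg.norm(d))
    rate = np.exp(np.polyfit(np.arange(4, 10), np.log(norms[4:]), 1)[0])
    assert rate == pytest.approx(lam, rel=0.05)


def test_prc_zero_perturbation_zero_shift(walker, v04_cycle):
    s = phase_response(v04_cycle, walker, perturbation=(0.0, 0.0), at_phase=0.3)
    assert s.phase_shift_s == pytest.approx(0.0, abs=1e-9)


def test_prc_reset_shifts_flip_does_not(walker, v04_cycle, cpg_resetting):
    cyc_r = find_limit_cycle(walker, cpg_resetting, v04_cycle.fixed_point[:3])
    shifts_r = [
        phase_response(cyc_r, walker, perturbation=(0.0, 0.05), at_phase=f,
                       horizon=25).phase_shift_s
        for f in (0.2, 0.5, 0.8)
    ]
    shifts_f = [
        phase_response(v04_cycle, walker, perturbation=(0.0, 0.05), at_phase=f,
                       horizon=25).phase_shift_s
        for f in (0.2, 0.5, 0.8)
    ]
    assert all(abs(s) > 1e-4 for s in shifts_r)
    assert len({round(s, 4) for s in shifts_r}) > 1  # phase dependence
    assert all(abs(s) < 1e-4 for s in shifts_f)


def test_prc_linear_in_small_impulses(walker, v04_cycle, cpg_resetting):
    cyc_r = find_limit_cycle(walker, cpg_resetting, v04_cycle.fixed_point[:3])
    shifts = [
        phase_response(cyc_r, walker, perturbation=(0.0, eps), at_phase=0.35,
                       horizon=25).phase_shift_s
        for eps in (0.01, 0.02, 0.04)
    ]
    assert shifts[1] == pytest.approx(2 * shifts[0], rel=0.05)
    assert shifts[2] == pytest.approx(4 * shifts[0], rel=0.1)
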