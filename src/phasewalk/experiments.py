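"""Batch experiment layer: replicated stochastic trials and summaries.

Seeded batch runs over cells of (reset mode, gait speed, noise
amplitude): single exemplar trials for the
two modes at v = 0.4 and xi = 1; the scaling exponent alpha versus noise
amplitude (10 replicates per cell); alpha versus gait speed at xi = 1e-2;
accumulated-profile exports; and the calibration/stability analyses.  Each
cell replicate gets a unique seed derived reproducibly from the base seed,
recorded in every output file header.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomech import WalkerParams, WalkerState
from .cpg import CPGParams, ResetMode
from .dfa import accumulate, dfa
from .simulate import NoiseSpec, analysis_window, gait_speed, run_trial, write_stride_csv

__all__ = [
    "ExperimentConfig",
    "derive_seed",
    "run_cells",
    "aggregate_alpha",
]

MODES = (ResetMode.RESETTING, ResetMode.FLIP)


def derive_seed(base: int, mode: str, v: float, xi: float, replicate: int) -> int:
    """Deterministic per-cell seed below 2^31, unique per (mode, v, xi, rep)."""
    key = f"{mode}|{v:.6g}|{xi:.6g}|{replicate}".encode()
    return (int(base) ^ zlib.crc32(key)) & 0x7FFFFFFF


@dataclass
class ExperimentConfig:
    """One batch experiment: the cross product of modes, speeds and noise
    amplitudes, with ``replicates`` seeded trials per cell."""

    experiment: str
    speeds: tuple[float, ...] = (0.4,)
    xis: tuple[float, ...] = (1.0,)
    modes: tuple[ResetMode, ...] = MODES
    replicates: int = 10
    base_seed: int = 0
    n_steps: int = 1300
    dt: float = 1e-5
    discard: int = 150
    keep: int = 500
    discretization: str = "step_held"
    outdir: Path | None = None

    def cells(self):
        for mode in self.modes:
            for v in self.speeds:
                for xi in self.xis:
                    yield mode, v, xi

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        """Load a flat key-value config file (YAML)."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "experiment" not in raw:
            raise ValueError("config must be a mapping with an 'experiment' key")
        for key in ("speeds", "xis", "modes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(
                    ResetMode(v) if key == "modes" else float(v) for v in raw[key]
                )
        if "outdir" in raw and raw["outdir"] is not None:
            raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)

    @classmethod
    def preset(cls, name: str, base_seed: int = 0, replicates: int = 10,
               outdir=None) -> "ExperimentConfig":
        """Named experiment presets: exemplar trials (fig3), alpha versus
        noise amplitude (fig4), alpha versus speed (fig5), accumulated
        profiles (fig7)."""
        presets = {
            "fig3": dict(speeds=(0.4,), xis=(1.0,), replicates=1),
            "fig4": dict(speeds=(0.4,), xis=(1e-3, 1e-2, 1e-1, 1.0)),
            "fig5": dict(speeds=(0.3, 0.4, 0.5), xis=(1e-2,)),
            "fig7": dict(speeds=(0.4,), xis=(1.0,), replicates=1),
        }
        if name not in presets:
            raise ValueError(f"unknown experiment preset {name!r}")
        kw = presets[name]
        kw.setdefault("replicates", replicates)
        return cls(experiment=name, base_seed=base_seed, outdir=outdir, **kw)


def _calibration_row(table: pd.DataFrame, v: float) -> pd.Series:
    match = table[np.isclose(table.v_target, v, atol=1e-9)]
    if match.empty:
        raise ValueError(
            f"no calibration row for v = {v}; run the calibration first "
            f"(phasewalk calibrate) or pass a table containing this speed"
        )
    return match.iloc[0]


def run_cells(
    config: ExperimentConfig,
    walker: WalkerParams,
    calibration: pd.DataFrame,
    *,
    fixed_points: dict[float, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Run every (mode, speed, xi, replicate) trial of the experiment.

    ``calibration`` must hold one row per requested speed with columns
    ``v_target, A1, A2, delta, phi0``.  ``fixed_points`` may map speeds to
    post-touchdown full states (from the stability module); otherwise the
    trial starts from the calibration row's section geometry re-derived by
    a short noiseless walk.  Returns one row per trial with alpha, stride
    SD, realized speed and fall status; per-trial stride CSVs are written
    when the config has an output directory.
    """
    from . import _kernels
    from .stability import converge_forward

    rows = []
    for mode, v, xi in config.cells():
        cal = _calibration_row(calibration, v)
        cpg = CPGParams(
            A1=float(cal.A1), A2=float(cal.A2), delta=float(cal.delta),
            phi0=float(cal.phi0), mode=mode,
        )
        if fixed_points is not None and v in fixed_points:
            y0 = fixed_points[v]
        else:
            flip = cpg.with_mode(ResetMode.FLIP)
            T = math.pi / cpg.omega
            a = math.asin(min(v * T / 2.0, 0.99))
            z = converge_forward(
                walker, flip,
                WalkerState(a, 2 * a, -0.45 * v / 0.4, -0.8 * v / 0.4), 1.2,
            )
            if z is None:
                raise RuntimeError(f"could not re-derive fixed point at v = {v}")
            y0 = np.array([z[0], 2 * z[0], z[1], z[2], z[3]])
        initial = WalkerState(y0[0], y0[1], y0[2], y0[3])
        for rep in range(config.replicates):
            seed = derive_seed(config.base_seed, mode.value, v, xi, rep)
            noise = NoiseSpec(xi=xi, seed=seed,
                              discretization=config.discretization)
            trial = run_trial(
                walker, cpg, noise,
                n_steps=config.n_steps, dt=config.dt,
                initial=initial, phi_initial=float(y0[4]),
            )
            rec = {
                "experiment": config.experiment, "mode": mode.value,
                "v_target": v, "xi": xi, "replicate": rep, "seed": seed,
                "fell": trial.fell, "alpha": math.nan,
                "stride_sd": math.nan, "v_realized": math.nan,
            }
            if not trial.fell:
                window = analysis_window(trial, config.discard, config.keep)
                res = dfa(window.x)
                rec["alpha"] = res.alpha
                rec["stride_sd"] = float(window.x.std())
                rec["v_realized"] = gait_speed(trial, config.discard, config.keep)
            rows.append(rec)
            if config.outdir is not None:
                outdir = Path(config.outdir)
                outdir.mkdir(parents=True, exist_ok=True)
                name = f"{config.experiment}_{mode.value}_v{v:g}_xi{xi:g}_r{rep}.csv"
                write_stride_csv(outdir / name, trial)
    return pd.DataFrame(rows)


def aggregate_alpha(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and replicate count of alpha per (mode, v, xi) cell.

    A single-replicate cell reports a missing SD (not zero); fallen trials
    are excluded from the statistics but counted.
    """
    out = []
    for (mode, v, xi), grp in trials.groupby(["mode", "v_target", "xi"]):
        ok = grp[~grp.fell]
        out.append({
            "mode": mode, "v_target": v, "xi": xi,
            "n": len(grp), "n_walked": len(ok),
            "alpha_mean": float(ok.alpha.mean()) if len(ok) else math.nan,
            "alpha_sd": float(ok.alpha.std(ddof=1)) if len(ok) > 1 else math.nan,
            "stride_sd_mean": float(ok.stride_sd.mean()) if len(ok) else math.nan,
        })
    return pd.DataFrame(out)
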