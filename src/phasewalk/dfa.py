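"""Detrended fluctuation analysis (DFA-1) of stride-interval series.

Given a series ``x(1..N)``, the accumulated profile

    y(i) = sum_{k<=i} (x(k) - xbar)

is divided into ``floor(N/n)`` non-overlapping segments of length ``n``
(taken from the start; the remainder is discarded).  Each segment is
detrended by its own least-squares line and the fluctuation function
``F(n)`` is the root-mean-square residual pooled over all retained
segments.  ``F(n) ~ n^alpha`` defines the scaling exponent ``alpha``,
estimated as the slope of an unweighted least-squares line through
``(log n, log F(n))`` over a log-spaced grid of box sizes.

Interpretation of ``alpha`` for stride intervals: 0.5 is uncorrelated
(white) noise — and any shuffled rearrangement of a series yields 0.5;
values below 0.5 indicate statistical anti-persistence, values in
(0.5, 1.0] statistical persistence, and values above 1.0 brown noise
(integrated white noise).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AccumulatedProfile",
    "DFAResult",
    "ScalingClass",
    "accumulate",
    "box_grid",
    "fluctuation",
    "fit_alpha",
    "dfa",
    "shuffle_surrogate",
    "classify",
]


@dataclass
class AccumulatedProfile:
    """Accumulated deviations from the mean stride interval."""

    y: np.ndarray
    xbar: float

    @property
    def N(self) -> int:
        return len(self.y)


@dataclass
class DFAResult:
    """Box sizes, fluctuation function, and fitted scaling exponent."""

    n: np.ndarray
    F: np.ndarray
    alpha: float
    intercept: float

    @property
    def n_count(self) -> int:
        return len(self.n)

    @property
    def scaling_class(self) -> "ScalingClass":
        return classify(self.alpha)


class ScalingClass(enum.Enum):
    """Taxonomy of the DFA exponent for a stride-interval series."""

    ANTI_PERSISTENT = "anti-persistent"  # alpha < 0.5
    UNCORRELATED = "uncorrelated"        # alpha == 0.5
    PERSISTENT = "persistent"            # 0.5 < alpha <= 1.0
    BROWN = "brown"                      # alpha > 1.0


def classify(alpha: float) -> ScalingClass:
    if alpha < 0.5:
        return ScalingClass.ANTI_PERSISTENT
    if alpha == 0.5:
        return ScalingClass.UNCORRELATED
    if alpha <= 1.0:
        return ScalingClass.PERSISTENT
    return ScalingClass.BROWN


def accumulate(x) -> AccumulatedProfile:
    """Accumulated sum of deviations from the series mean.

    The final element is zero up to rounding (telescoping sum).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("x must be a non-empty 1-D series")
    xbar = float(x.mean())
    return AccumulatedProfile(np.cumsum(x - xbar), xbar)


def box_grid(N: int, count: int = 20) -> np.ndarray:
    """Box sizes distributed equally on a logarithmic scale in [4, N/4].

    Real-valued log-spaced sizes are rounded to the nearest integer and
    duplicates are resolved upward (so the grid is strictly increasing);
    if the range is too short to hold ``count`` distinct integers the grid
    is truncated.  For ``N = 500`` and ``count = 20`` this yields twenty
    sizes from 4 to 125, including 87 and 104.
    """
    if N < 16:
        raise ValueError("need N >= 16 for a valid box grid (min box 4, max N/4)")
    nmax = N // 4
    raw = 4.0 * (nmax / 4.0) ** (np.arange(count) / (count - 1))
    grid: list[int] = []
    prev = 0
    for r in raw:
        n = max(int(math.floor(r + 0.5)), prev + 1)
        if n > nmax:
            break
        grid.append(n)
        prev = n
    return np.array(grid, dtype=int)


def fluctuation(profile: AccumulatedProfile, n: int) -> float:
    """RMS residual of the linearly detrended profile at box size ``n``.

    Segments are taken from the start of the profile only; any remainder
    shorter than ``n`` is discarded.  Raises ``ValueError`` on a degenerate
    profile whose residuals all vanish (e.g. an exactly constant series),
    since ``log F`` is undefined there.
    """
    y = profile.y
    N = len(y)
    if not 1 <= n <= N // 4:
        raise ValueError(f"box size {n} outside valid range [1, N/4 = {N // 4}]")
    m = N // n
    seg = y[: m * n].reshape(m, n).T            # (n, m)
    t = np.arange(n, dtype=float)
    design = np.column_stack([t, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
    resid = seg - design @ coef
    f = math.sqrt(float(np.mean(resid**2)))
    if f <= 0.0:
        raise ValueError("degenerate series: all detrended residuals are zero")
    return f


def fit_alpha(n, F) -> tuple[float, float]:
    """Slope and intercept of the least-squares line through
    ``(log n, log F)`` (natural logarithm; the slope is base-invariant)."""
    n = np.asarray(n, dtype=float)
    F = np.asarray(F, dtype=float)
    ok = F > 0
    if ok.sum() < 3:
        raise ValueError("need at least 3 valid (n, F) pairs with F > 0")
    slope, intercept = np.polyfit(np.log(n[ok]), np.log(F[ok]), 1)
    return float(slope), float(intercept)


def dfa(x, count: int = 20) -> DFAResult:
    """Full DFA-1 pipeline: profile, log-spaced boxes, F(n), fitted alpha."""
    profile = accumulate(x)
    ns = box_grid(profile.N, count)
    F = np.array([fluctuation(profile, int(n)) for n in ns])
    alpha, intercept = fit_alpha(ns, F)
    return DFAResult(ns, F, alpha, intercept)


def shuffle_surrogate(x, seed: int) -> np.ndarray:
    """Seeded uniformly-random permutation of the series.

    Shuffling destroys temporal ordering while preserving the value
    distribution, so DFA of the surrogate recovers alpha = 0.5 regardless
    of the original correlations.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to shuffle")
    rng = np.random.default_rng(seed)
    return rng.permutation(x)
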