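"""Reference time series with known scaling structure.

These generators exist to validate the DFA stage independently of the
walker simulator: white noise (alpha = 0.5), brown noise — integrated
white noise (alpha ~ 1.5), and fractional Gaussian noise with prescribed
Hurst exponent H (alpha ~ H).  fGn is synthesized by circulant embedding
of its exact autocovariance, which is exact in distribution; the lag-k
autocovariance of unit-variance fGn is

    gamma(k) = ( |k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H} ) / 2,

so in particular gamma(1) = 2^{2H-1} - 1, a closed form the tests use as
an oracle for the generator itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["SeriesSpec", "generate", "fgn_autocovariance"]


@dataclass(frozen=True)
class SeriesSpec:
    """What to generate: process kind, length, scaling, offset and seed."""

    kind: Literal["white", "brown", "fgn"]
    N: int
    hurst: float | None = None   # fgn only, 0 < H < 1
    mean: float = 0.0
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "brown", "fgn"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.N < 16:
            raise ValueError("N must be at least 16")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.kind == "fgn":
            if self.hurst is None or not 0.0 < self.hurst < 1.0:
                raise ValueError("fgn requires 0 < hurst < 1")


def fgn_autocovariance(k, hurst: float) -> np.ndarray:
    """Exact autocovariance of unit-variance fractional Gaussian noise."""
    k = np.abs(np.asarray(k, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)


def _fgn(N: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    # circulant embedding (Davies–Harte): the circulant extension of the
    # fGn covariance has non-negative eigenvalues for 0 < H < 1, so the
    # synthesis is exact in distribution (tiny negative round-off clipped)
    gamma = fgn_autocovariance(np.arange(N), hurst)
    m = 2 * (N - 1)
    row = np.concatenate([gamma, gamma[N - 2:0:-1]])
    lam = np.maximum(np.fft.fft(row).real, 0.0)
    half = m // 2
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.normal()
    w[half] = np.sqrt(lam[half] / m) * rng.normal()
    a = rng.normal(size=half - 1)
    b = rng.normal(size=half - 1)
    w[1:half] = np.sqrt(lam[1:half] / (2.0 * m)) * (a + 1j * b)
    w[half + 1:] = np.conj(w[1:half][::-1])
    return np.fft.fft(w).real[:N]


def generate(spec: SeriesSpec) -> np.ndarray:
    """Draw one realization of the specified process.

    White and fGn series have distributional mean ``spec.mean`` and
    standard deviation ``spec.sd`` (sample statistics match within standard
    error).  Brown noise is nonstationary, so the realization is affinely
    rescaled to the requested sample mean and sample SD.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "white":
        return rng.normal(spec.mean, spec.sd, size=spec.N)
    if spec.kind == "brown":
        y = np.cumsum(rng.normal(size=spec.N))
        y = (y - y.mean()) / y.std()
        return spec.mean + spec.sd * y
    x = _fgn(spec.N, float(spec.hurst), rng)
    return spec.mean + spec.sd * x
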