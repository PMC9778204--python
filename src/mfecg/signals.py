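"""Synthetic test signals with known complexity and multifractality.

Every generator is a pure, seed-deterministic function. The fixtures fall in
three groups:

* stationary noises with a tunable spectral slope (white, 1/f) — the classic
  multiscale-entropy benchmarks: coarse-graining kills the entropy of white
  noise but leaves 1/f noise roughly flat;
* exactly-known multifractals (binomial cascade, fractional Brownian motion)
  whose scaling exponents are available in closed form, used to validate the
  wavelet-leaders estimators;
* two ECG-like classes built from the same PQRST template whose only
  difference is the noise/beat-timing process, so that the coarse-grained
  sample entropy at large scales orders them (NSR-like > CHF-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "SyntheticSignal",
    "white_noise",
    "one_over_f_noise",
    "binomial_cascade",
    "cascade_tau",
    "cascade_zeta",
    "cascade_alpha",
    "fbm",
    "fgn_autocovariance",
    "synthetic_ecg",
]


@dataclass(frozen=True)
class SyntheticSignal:
    """A generated test signal plus the parameters that produced it."""

    values: np.ndarray
    fs: float
    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.values)


def white_noise(n: int, seed: int | None = None) -> SyntheticSignal:
    """Zero-centered i.i.d. uniform white noise of length ``n``."""
    if n < 1:
        raise ValueError(f"white_noise requires n >= 1, got {n}")
    rng = np.random.default_rng(seed)
    values = rng.uniform(-0.5, 0.5, size=n)
    return SyntheticSignal(values=values, fs=1.0, kind="white",
                           params={"n": n}, seed=seed)


def one_over_f_noise(n: int, seed: int | None = None) -> SyntheticSignal:
    """1/f (pink) noise by spectral shaping of uniform white noise.

    Start from uniformly distributed white noise, take the FFT, impose a
    1/f power spectrum (amplitude scaled by 1/sqrt(f), DC bin zeroed) and
    invert. The periodogram log-log slope is -1 up to estimation noise.
    """
    if n < 16:
        raise ValueError(f"one_over_f_noise requires n >= 16, got {n}")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-0.5, 0.5, size=n)
    spectrum = np.fft.rfft(u)
    freqs = np.fft.rfftfreq(n)
    spectrum[0] = 0.0
    spectrum[1:] = spectrum[1:] / np.sqrt(freqs[1:])
    values = np.fft.irfft(spectrum, n=n)
    return SyntheticSignal(values=values, fs=1.0, kind="pink",
                           params={"n": n}, seed=seed)


def cascade_tau(p: float, q: np.ndarray | float) -> np.ndarray | float:
    """Closed-form partition exponents tau(q) = -log2(p^q + (1-p)^q)."""
    q = np.asarray(q, dtype=float)
    return -np.log2(p ** q + (1.0 - p) ** q)


def cascade_zeta(p: float, q: np.ndarray | float) -> np.ndarray | float:
    """Scaling function of the cascade *primitive*: zeta(q) = 1 + tau(q)."""
    return 1.0 + cascade_tau(p, q)


def cascade_alpha(p: float, q: np.ndarray | float) -> np.ndarray | float:
    """Analytic alpha(q) = d(tau+1)/dq for the binomial cascade primitive."""
    q = np.asarray(q, dtype=float)
    pq, rq = p ** q, (1.0 - p) ** q
    return (pq * np.log(p) + rq * np.log(1.0 - p)) / (-(pq + rq) * np.log(2.0))


def binomial_cascade(levels: int, p: float,
                     seed: int | None = None) -> SyntheticSignal:
    """Primitive (cumulative sum) of a binomial multiplicative measure.

    The unit mass is split recursively ``levels`` times into left/right
    weights (p, 1-p); with a seed, the weight order is shuffled independently
    at every node, which randomizes the path without changing the exponents.
    The returned signal is the running integral of the measure over the
    2**levels cells, so its increments are the cell masses and the leaders
    scaling function is zeta(q) = 1 - log2(p^q + (1-p)^q).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"cascade weight p must lie in (0,1), got {p}")
    if levels < 4:
        raise ValueError(f"binomial_cascade requires levels >= 4, got {levels}")
    rng = np.random.default_rng(seed) if seed is not None else None
    mass = np.ones(1)
    for _ in range(levels):
        left = np.full(mass.shape, p)
        if rng is not None:
            flip = rng.random(mass.shape) < 0.5
            left = np.where(flip, 1.0 - p, p)
        children = np.empty(2 * mass.size)
        children[0::2] = mass * left
        children[1::2] = mass * (1.0 - left)
        mass = children
    values = np.cumsum(mass)
    return SyntheticSignal(values=values, fs=1.0, kind="cascade",
                           params={"levels": levels, "p": p}, seed=seed)


def fgn_autocovariance(H: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance of unit-variance fractional Gaussian noise."""
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H)
                  + np.abs(k - 1) ** (2 * H))


def fbm(n: int, H: float, seed: int | None = None) -> SyntheticSignal:
    """Fractional Brownian motion path by circulant embedding.

    Exact synthesis (Davies-Harte): embed the fGn covariance in a circulant
    matrix, take its FFT eigenvalues, and color complex white noise. Falls
    back to a Cholesky factorization for small n if the embedding is not
    nonnegative definite.
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"Hurst exponent must lie in (0,1), got {H}")
    if n < 1:
        raise ValueError(f"fbm requires n >= 1, got {n}")
    rng = np.random.default_rng(seed)
    gamma = fgn_autocovariance(H, np.arange(n))
    # first row of the 2n-circulant embedding
    row = np.concatenate([gamma, gamma[-2:0:-1]]) if n > 1 else gamma
    eig = np.fft.fft(row).real
    if np.min(eig) > -1e-10:
        eig = np.clip(eig, 0.0, None)
        m = len(row)
        z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        coeff = np.fft.fft(np.sqrt(eig / (2.0 * m)) * z)
        fgn = np.sqrt(2.0) * coeff[:n].real
    else:  # pragma: no cover - Davies-Harte is valid for all H for fGn
        if n > 4096:
            raise RuntimeError("circulant embedding failed for large n")
        cov = fgn_autocovariance(H, np.subtract.outer(np.arange(n),
                                                      np.arange(n)))
        fgn = np.linalg.cholesky(cov) @ rng.standard_normal(n)
    values = np.cumsum(fgn)
    return SyntheticSignal(values=values, fs=1.0, kind="fbm",
                           params={"n": n, "H": H}, seed=seed)


# PQRST template: (amplitude mV, center offset s, width s) per wave.
_ECG_WAVES = (
    (0.12, -0.20, 0.025),   # P
    (-0.10, -0.03, 0.010),  # Q
    (1.00, 0.00, 0.012),    # R
    (-0.15, 0.03, 0.010),   # S
    (0.30, 0.25, 0.045),    # T
)


def _pqrst_trace(n: int, fs: float, beat_times: np.ndarray) -> np.ndarray:
    t = np.arange(n) / fs
    x = np.zeros(n)
    for amp, mu, sd in _ECG_WAVES:
        for bt in beat_times:
            c = bt + mu
            lo = max(0, int((c - 5 * sd) * fs))
            hi = min(n, int((c + 5 * sd) * fs) + 1)
            if hi > lo:
                x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / sd) ** 2)
    return x


def synthetic_ecg(kind: str, fs: float = 128.0, duration: float = 64.0,
                  seed: int | None = None) -> SyntheticSignal:
    """ECG-like signal of one of two complexity classes.

    Both classes share the same PQRST template (sum of five displaced
    Gaussians) repeated at ~1 Hz plus a slow baseline drift; the classes
    differ only in the stochastic part, which is the controlled variable:

    * ``ecg_nsr_like`` — beat-to-beat (RR) jitter of ~6% plus additive 1/f
      noise (sd 0.12 mV), i.e. complexity that survives coarse-graining;
    * ``ecg_chf_like`` — nearly metronomic beats (0.5% jitter) plus
      low-amplitude white noise (sd 0.04 mV) that averages away.

    Consequently the mean first-moment multiscale entropy over scales 10-20
    is higher for the NSR-like class on cohorts of segments.
    """
    if kind not in ("ecg_nsr_like", "ecg_chf_like"):
        raise ValueError(f"unknown ECG kind {kind!r}")
    n = int(round(fs * duration))
    if n < 256:
        raise ValueError(
            f"fs*duration must be >= 256 samples, got {fs}*{duration}={n}")
    rng = np.random.default_rng(seed)
    n_beats = int(duration) + 4
    base_rr = 1.0
    if kind == "ecg_nsr_like":
        # correlated (1/f-shaped) RR jitter, ~6% coefficient of variation
        jit = one_over_f_noise(max(16, n_beats),
                               seed=int(rng.integers(2 ** 31))).values[:n_beats]
        jit = (jit - jit.mean()) / (jit.std() + 1e-12)
        rr = base_rr * (1.0 + 0.06 * np.clip(jit, -3, 3))
        noise_raw = one_over_f_noise(n, seed=int(rng.integers(2 ** 31))).values
        noise = 0.12 * noise_raw / (noise_raw.std() + 1e-12)
    else:
        rr = base_rr * (1.0 + 0.005 * rng.standard_normal(n_beats))
        noise = 0.04 * rng.standard_normal(n)
    beat_times = np.cumsum(rr) - rr[0] + 0.3
    beat_times = beat_times[beat_times < duration + 0.5]
    x = _pqrst_trace(n, fs, beat_times)
    t = np.arange(n) / fs
    drift = 0.08 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    values = x + drift + noise
    return SyntheticSignal(values=values, fs=fs, kind=kind,
                           params={"fs": fs, "duration": duration}, seed=seed)
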