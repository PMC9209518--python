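"""Fractional Brownian motion sampling.

Chromocenter motion is modelled as fBm — the standard stationary-increment
Gaussian process for (sub/super)diffusive motion — with Hurst index
H = alpha / 2, so that the ensemble MSD per coordinate is
E[x(t)^2] = sigma^2 * t^alpha.

Sampling uses the Davies–Harte circulant embedding (O(n log n)); if the
embedding is not nonnegative-definite for a given (n, H) it falls back to an
exact Cholesky factorization of the fGn covariance.
"""
from __future__ import annotations

import numpy as np

__all__ = ["fgn", "fbm_path"]


def _fgn_autocov(n: int, hurst: float) -> np.ndarray:
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2.0 * k ** h2 + np.abs(k - 1) ** h2)


def fgn(n: int, hurst: float, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw ``size`` independent unit-variance fractional Gaussian noise series.

    Returns an array of shape ``(size, n)``; each row has increments at unit
    spacing with ``Var = 1`` and correlation structure of fGn with the given
    Hurst index.
    """
    if not 0.0 < hurst <= 1.0:
        raise ValueError("hurst must be in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(hurst - 0.5) < 1e-12:  # ordinary white noise
        return rng.standard_normal((size, n))

    r = _fgn_autocov(n, hurst)
    # circulant embedding: first row [r0 .. r_{n-1}, r_n, r_{n-1} .. r_1]
    r_ext = _fgn_autocov(n + 1, hurst)
    row = np.concatenate([r_ext, r_ext[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        return _fgn_cholesky(r, rng, size)
    lam = np.clip(lam, 0.0, None)
    m = row.size
    out = np.empty((size, n))
    for i in range(size):
        z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        w = np.fft.fft(np.sqrt(lam / (2.0 * m)) * z)
        out[i] = w[:n].real * np.sqrt(2.0)
    return out


def _fgn_cholesky(r: np.ndarray, rng: np.random.Generator, size: int) -> np.ndarray:
    n = r.size
    cov = r[np.abs(np.subtract.outer(np.arange(n), np.arange(n)))]
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return rng.standard_normal((size, n)) @ chol.T


def fbm_path(n_steps: int, hurst: float, dt: float, sigma2: float,
             rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Sample fBm paths with ``E[x(t)^2] = sigma2 * t^(2H)``.

    Returns shape ``(size, n_steps + 1)`` including the origin at 0.
    """
    inc = fgn(n_steps, hurst, rng, size=size)
    inc *= np.sqrt(sigma2) * dt ** hurst  # self-similarity scaling
    out = np.zeros((size, n_steps + 1))
    np.cumsum(inc, axis=1, out=out[:, 1:])
    return out
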