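"""Synthetic TCSPC photon-arrival histograms.

Photon arrival times follow a monoexponential decay, optionally convolved
with an instrument response function, folded into the laser repetition
period (25 ns at 40 MHz) and binned; counts are a multinomial draw of the
requested photon number from the resulting bin probabilities.
"""
from __future__ import annotations

import numpy as np

from ..flim import FlimHistogram

__all__ = ["make_flim_histogram", "gaussian_irf"]

_FINE_OVERSAMPLE = 16
_N_WRAPS = 8  # decay periods folded into the window


def gaussian_irf(center_ns: float, sigma_ns: float):
    """A Gaussian IRF spec understood by :func:`make_flim_histogram`."""
    return {"center_ns": float(center_ns), "sigma_ns": float(sigma_ns)}


def _bin_probs(tau_ns: float, edges: np.ndarray, rep_period_ns: float,
               irf) -> np.ndarray:
    if irf is None:
        # delta IRF at t=0: the folded decay is a truncated exponential
        p = np.exp(-edges[:-1] / tau_ns) - np.exp(-edges[1:] / tau_ns)
        return p / p.sum()
    # numeric: oversampled decay, convolved with the IRF, folded into the window
    n_fine = (edges.size - 1) * _FINE_OVERSAMPLE
    dt = rep_period_ns / n_fine
    t = (np.arange(n_fine * _N_WRAPS) + 0.5) * dt
    decay = np.exp(-t / tau_ns)
    kern_t = (np.arange(n_fine) + 0.5) * dt
    kern = np.exp(-0.5 * ((kern_t - irf["center_ns"]) / irf["sigma_ns"]) ** 2)
    kern /= kern.sum()
    conv = np.convolve(decay, kern)[: n_fine * _N_WRAPS]
    folded = conv.reshape(_N_WRAPS, n_fine).sum(axis=0)
    p = folded.reshape(edges.size - 1, _FINE_OVERSAMPLE).sum(axis=1)
    return p / p.sum()


def make_flim_histogram(tau_ns: float, n_photons: int, irf=None,
                        bin_width_ns: float = None, n_bins: int = 256,
                        rep_period_ns: float = 25.0, seed: int = 0,
                        region_label: str = "heterochromatin",
                        n_pixels: int = 1) -> FlimHistogram:
    """Draw a photon-arrival histogram for a region of known lifetime."""
    if tau_ns <= 0:
        raise ValueError("tau_ns must be positive")
    if n_photons < 1:
        raise ValueError("n_photons must be at least 1")
    if bin_width_ns is not None:
        n_bins = int(round(rep_period_ns / bin_width_ns))
    edges = np.linspace(0.0, rep_period_ns, n_bins + 1)
    p = _bin_probs(tau_ns, edges, rep_period_ns, irf)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(n_photons), p)
    return FlimHistogram(bin_edges_ns=edges, counts=counts,
                        region_label=region_label, n_pixels=n_pixels,
                        rep_period_ns=rep_period_ns)
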