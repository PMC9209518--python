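"""Synthetic FRAP traces with known generative parameters."""
from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from ..frap import FrapTrace
from ..presets import FrapPreset

__all__ = ["make_frap_trace", "frap_times"]

# arbitrary-unit intensity scales shared by all FRAP presets
_SIGNAL_AMPLITUDE = 1000.0
_BACKGROUND_LEVEL = 100.0


def frap_times(preset: FrapPreset) -> np.ndarray:
    """Acquisition timestamps implied by a preset.

    Pre-bleach frames are spaced ``frame_interval_s`` apart; post-bleach
    frames continue at ``post_bleach_interval_s`` when that is set (nonuniform
    protocols), otherwise at the same interval.
    """
    npre = preset.pre_bleach_frames
    npost = preset.n_frames - npre
    pre = np.arange(npre) * preset.frame_interval_s
    post_dt = preset.post_bleach_interval_s or preset.frame_interval_s
    post = pre[-1] + preset.frame_interval_s + post_dt * np.arange(npost)
    return np.concatenate([pre, post])


def make_frap_trace(preset: FrapPreset, seed: int,
                    noise_sd: Optional[float] = None) -> Tuple[FrapTrace, dict]:
    """Generate one FRAP trace and its ground truth.

    The noiseless bleached-ROI signal is constant before the bleach and
    follows ``Y0 + (P - Y0)(1 - exp(-K x))`` after it, with Y0 the bleach
    depth and P the plateau implied by the mobile fraction.  All three ROIs
    (bleached, unbleached control, background) decay with the same
    monoexponential acquisition-bleaching factor, and carry independent
    multiplicative Gaussian noise.
    """
    for fname in ("bleach_depth", "mobile_fraction", "k_per_s",
                  "acq_bleach_per_s"):
        if not math.isfinite(getattr(preset, fname)):
            raise ValueError(f"non-finite preset field {fname}")
    sd = preset.noise_sd if noise_sd is None else float(noise_sd)
    rng = np.random.default_rng(seed)

    t = frap_times(preset)
    bleach_frame = preset.pre_bleach_frames
    x = t - t[bleach_frame]

    y0 = preset.bleach_depth
    plateau = preset.plateau
    signal = np.ones_like(t)
    post = slice(bleach_frame, None)
    signal[post] = y0 + (plateau - y0) * (1.0 - np.exp(-preset.k_per_s * x[post]))

    acq = np.exp(-preset.acq_bleach_per_s * t)
    i_background = _BACKGROUND_LEVEL * acq
    i_control = (_BACKGROUND_LEVEL + _SIGNAL_AMPLITUDE) * acq
    i_bleached = (_BACKGROUND_LEVEL + _SIGNAL_AMPLITUDE * signal) * acq
    if sd > 0:
        i_bleached = i_bleached * (1.0 + sd * rng.standard_normal(t.size))
        i_control = i_control * (1.0 + sd * rng.standard_normal(t.size))
        i_background = i_background * (1.0 + sd * rng.standard_normal(t.size))

    trace = FrapTrace(t, i_bleached, i_control, i_background, bleach_frame)
    truth = {
        "preset": preset.name,
        "seed": int(seed),
        "y0": y0,
        "plateau": plateau,
        "k_per_s": preset.k_per_s,
        "t_half_s": math.log(2) / preset.k_per_s,
        "mobile_fraction": preset.mobile_fraction,
        "immobile_fraction": 1.0 - preset.mobile_fraction,
        "acq_bleach_per_s": preset.acq_bleach_per_s,
        "noise_sd": sd,
    }
    return trace, truth
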