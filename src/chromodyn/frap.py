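"""FRAP trace correction, one-phase-association fitting and condition summaries.

The corrected recovery curve is obtained by background subtraction, optional
division by an unbleached control ROI (removing shared acquisition
bleaching), and normalization to the mean pre-bleach level.  Post-bleach
frames are fitted to the one-phase association model

    Y(x) = Y0 + (Plateau - Y0) * (1 - exp(-K x)),   x = t - t_bleach,

from which the half-time t1/2 = ln2 / K follows.  The mobile fraction is
Fm = (Plateau - first post-bleach) / (pre-bleach - first post-bleach), using
the observed first post-bleach value of the corrected curve; the immobile
fraction is 1 - Fm.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stats import mann_whitney, descriptives

__all__ = [
    "FrapTrace",
    "FrapFit",
    "correct_trace",
    "fit_recovery",
    "half_time",
    "fractions",
    "half_crossing_time",
    "analyze_trace",
    "summarize_condition",
]


@dataclass
class FrapTrace:
    """Per-frame ROI intensities of one photobleaching experiment."""

    time_s: np.ndarray
    i_bleached: np.ndarray
    i_control: np.ndarray
    i_background: np.ndarray
    bleach_frame: int  # index of the first post-bleach frame

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.i_bleached = np.asarray(self.i_bleached, dtype=float)
        self.i_control = np.asarray(self.i_control, dtype=float)
        self.i_background = np.asarray(self.i_background, dtype=float)
        n = self.time_s.size
        if not (self.i_bleached.size == self.i_control.size
                == self.i_background.size == n):
            raise ValueError("all series must have equal length")
        if not 1 <= self.bleach_frame < n:
            raise ValueError("bleach_frame must lie strictly inside the series")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    def to_csv(self, path) -> None:
        path = Path(path)
        df = pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "time_s": self.time_s,
            "i_bleached": self.i_bleached,
            "i_control": self.i_control,
            "i_background": self.i_background,
        })
        with open(path, "w") as fh:
            fh.write(f"# bleach_frame={self.bleach_frame}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrapTrace":
        path = Path(path)
        bleach_frame = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "bleach_frame" in first:
            bleach_frame = int(first.split("=")[1])
        if bleach_frame is None:
            sidecar = path.with_suffix(".json")
            if sidecar.exists():
                bleach_frame = int(json.loads(sidecar.read_text())["bleach_frame"])
            else:
                raise ValueError(f"{path}: no bleach_frame header or sidecar JSON")
        df = pd.read_csv(path, comment="#")
        return cls(df["time_s"].to_numpy(), df["i_bleached"].to_numpy(),
                   df["i_control"].to_numpy(), df["i_background"].to_numpy(),
                   bleach_frame)


@dataclass
class FrapFit:
    """Result of a one-phase association fit on a corrected curve."""

    y0: float
    plateau: float
    k_per_s: float
    t_half_s: float
    mobile_fraction: float
    immobile_fraction: float
    rss: float
    converged: bool
    message: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def correct_trace(trace: FrapTrace, use_control: bool = True) -> np.ndarray:
    """Background-subtract, optionally control-correct, and normalize a trace.

    With ``use_control`` the per-frame ratio
    ``(bleached - background) / (control - background)`` cancels acquisition
    bleaching shared by all ROIs; either way the curve is divided by its mean
    over the pre-bleach frames, so the pre-bleach level is 1 by construction.
    """
    sig = trace.i_bleached - trace.i_background
    if use_control:
        ref = trace.i_control - trace.i_background
        bad = np.nonzero(ref <= 0)[0]
        if bad.size:
            raise ValueError(
                f"control - background is non-positive at frame {bad[0]}")
        ratio = sig / ref
    else:
        ratio = sig
    pre = ratio[: trace.bleach_frame]
    pre_mean = pre.mean()
    if pre_mean == 0:
        raise ValueError("pre-bleach mean is zero; cannot normalize")
    return ratio / pre_mean


def _model(x, y0, dp, k):
    return y0 + dp * (1.0 - np.exp(-k * x))


def fit_recovery(curve: np.ndarray, time_s: np.ndarray, bleach_frame: int,
                 max_restarts: int = 4) -> FrapFit:
    """Fit the one-phase association model to the post-bleach frames.

    Only frames from ``bleach_frame`` on enter the fit, with the clock reset
    to zero at the first post-bleach frame.  The plateau is constrained to
    lie at or above Y0 (parametrized as Y0 + dP with dP >= 0) and K > 0.
    """
    curve = np.asarray(curve, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    y = curve[bleach_frame:]
    x = time_s[bleach_frame:] - time_s[bleach_frame]
    if y.size < 8:
        raise ValueError("need at least 8 post-bleach frames")

    first_post = float(y[0])
    tail = float(np.mean(y[-max(1, y.size // 10):]))
    y0_init = first_post
    dp_init = max(tail - first_post, 1e-3)
    mid = y0_init + 0.5 * dp_init
    above = np.nonzero(y >= mid)[0]
    t_mid = x[above[0]] if above.size and x[above[0]] > 0 else (x[-1] / 4 or 1.0)
    k_init = math.log(2) / t_mid

    p0s = [(y0_init, dp_init, k_init)]
    for fac in (0.3, 3.0, 10.0, 0.1)[: max_restarts]:
        p0s.append((y0_init, dp_init, k_init * fac))

    best = None
    msg = ""
    for p0 in p0s:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _model, x, y, p0=p0,
                    bounds=([-np.inf, 0.0, 1e-8], [np.inf, np.inf, np.inf]),
                    maxfev=20000)
            rss = float(np.sum((_model(x, *popt) - y) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
        except (RuntimeError, ValueError) as exc:  # non-convergence
            msg = str(exc)
            continue
    if best is None:
        return FrapFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                       np.nan, converged=False, message=msg or "fit failed")

    (y0, dp, k), rss = best
    plateau = y0 + dp
    mob, imm = fractions(plateau, pre_bleach=1.0, first_post=first_post)
    return FrapFit(float(y0), float(plateau), float(k), math.log(2) / k,
                   mob, imm, rss, converged=True)


def half_time(k_per_s: float) -> float:
    """Half-time of recovery, ln(2)/K."""
    if k_per_s <= 0:
        raise ValueError("k must be positive")
    return math.log(2) / k_per_s


def fractions(fit_or_plateau, pre_bleach: float, first_post: float):
    """Mobile and immobile fractions from plateau and observed levels.

    ``Fm = (Plateau - first_post) / (pre_bleach - first_post)`` clamped to
    [0, 1] (noise can push the raw estimate slightly outside); the immobile
    fraction is its complement.
    """
    plateau = fit_or_plateau.plateau if isinstance(fit_or_plateau, FrapFit) \
        else float(fit_or_plateau)
    if pre_bleach <= first_post:
        raise ValueError("pre-bleach level must exceed the first post-bleach "
                         "value (bleach failed?)")
    fm = (plateau - first_post) / (pre_bleach - first_post)
    if not 0.0 <= fm <= 1.0:
        warnings.warn(f"mobile fraction {fm:.3f} clamped to [0, 1]")
        fm = min(max(fm, 0.0), 1.0)
    return float(fm), float(1.0 - fm)


def half_crossing_time(curve: np.ndarray, time_s: np.ndarray, bleach_frame: int,
                       level: float = 0.5) -> float:
    """First post-bleach time (s, from the bleach) the curve reaches ``level``.

    Linear interpolation between the bracketing frames; NaN if never reached.
    """
    y = np.asarray(curve, dtype=float)[bleach_frame:]
    t = np.asarray(time_s, dtype=float)[bleach_frame:]
    t = t - t[0]
    idx = np.nonzero(y >= level)[0]
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    if i == 0:
        return 0.0
    f = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def analyze_trace(trace: FrapTrace, use_control: bool = True) -> FrapFit:
    """Convenience: correct then fit a raw trace."""
    curve = correct_trace(trace, use_control=use_control)
    return fit_recovery(curve, trace.time_s, trace.bleach_frame)


def summarize_condition(fits: Sequence[FrapFit], labels: Sequence[str]) -> pd.DataFrame:
    """Per-condition descriptives for t1/2 and fractions, plus Mann–Whitney p.

    With two conditions a two-sided Mann–Whitney p is reported for each
    quantity; with a single condition only descriptives are returned.
    """
    if len(fits) != len(labels):
        raise ValueError("fits and labels must align")
    df = pd.DataFrame([f.as_dict() | {"condition": lab}
                       for f, lab in zip(fits, labels) if f.converged])
    conds = sorted(df["condition"].unique())
    rows = []
    for q in ("t_half_s", "mobile_fraction", "immobile_fraction"):
        for c in conds:
            d = descriptives(df.loc[df.condition == c, q])
            rows.append({"quantity": q, "condition": c, **d})
        if len(conds) == 2:
            a = df.loc[df.condition == conds[0], q]
            b = df.loc[df.condition == conds[1], q]
            if len(a) >= 2 and len(b) >= 2:
                _, p = mann_whitney(a, b)
                rows[-1]["p_mannwhitney"] = p
                rows[-2]["p_mannwhitney"] = p
    return pd.DataFrame(rows)
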