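"""Chromocenter detection, frame-to-frame linking, event calling and MSD.

Foci detected per frame are linked by minimum-total-displacement assignment
(Hungarian algorithm) with a hard displacement gate and optional gap
closing.  Coalescence is called where an ending track hands over to a
continuing one within the gate; cleavage where a newborn track appears next
to a continuing one.  Motion is quantified by the time-averaged MSD, fitted
as MSD = 4 * Dapp * tau^alpha (log-log regression) and, separately, by a
directed-diffusion fit MSD = 4 D tau + (v tau)^2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment, nnls

from .stats import descriptives

__all__ = [
    "Detection",
    "Track",
    "EventRecord",
    "MsdFit",
    "detect_foci",
    "link_tracks",
    "event_engagement",
    "engagement_summary",
    "msd",
    "fit_msd",
    "net_displacement_velocity",
    "evaluate_events",
]


@dataclass
class Detection:
    frame: int
    y_um: float
    x_um: float
    total_intensity: float = 0.0
    radius_um: float = 0.0

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.y_um, self.x_um])


@dataclass
class Track:
    id: int
    frames: List[int] = field(default_factory=list)
    positions: List[np.ndarray] = field(default_factory=list)
    intensities: List[float] = field(default_factory=list)
    parent_ids: List[int] = field(default_factory=list)
    child_ids: List[int] = field(default_factory=list)

    def add(self, det: Detection) -> None:
        self.frames.append(det.frame)
        self.positions.append(det.pos)
        self.intensities.append(det.total_intensity)

    @property
    def start(self) -> int:
        return self.frames[0]

    @property
    def end(self) -> int:
        return self.frames[-1]

    def duration_s(self, frame_interval_s: float) -> float:
        return (self.end - self.start) * frame_interval_s

    def xy(self) -> np.ndarray:
        return np.asarray(self.positions)


@dataclass
class EventRecord:
    kind: str  # "coalescence" | "cleavage"
    frame: int
    participants: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("coalescence", "cleavage"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class MsdFit:
    d_app: float        # um^2 / s^alpha
    alpha: float
    velocity: float     # um / s, directed-diffusion fit
    d_lin: float        # um^2 / s, diffusive part of the directed fit
    fit_lags: int
    r2: float


# ---------------------------------------------------------------------------
# detection

def detect_foci(stack: np.ndarray, pixel_size_um: float = 1.0,
                smoothing_sigma_px: float = 1.0,
                threshold: Optional[float] = None,
                threshold_frac: float = 0.15,
                min_area_px: int = 4,
                peak_min_distance_px: int = 4) -> List[List[Detection]]:
    """Detect bright foci in a (T, Y, X) stack, one detection list per frame.

    A single threshold, constant across the whole movie, is derived from the
    smoothed stack as ``median + threshold_frac * (p99.9 - median)`` unless
    given explicitly.  Touching foci are split by watershed from local
    intensity maxima, so close pairs stay resolvable irrespective of their
    relative brightness.  Centroids are intensity-weighted.
    """
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (T, Y, X) stack")
    sm = np.empty_like(stack)
    for i in range(stack.shape[0]):
        sm[i] = ndi.gaussian_filter(stack[i], smoothing_sigma_px)
    if threshold is None:
        med = np.median(sm)
        hi = np.percentile(sm, 99.9)
        threshold = med + threshold_frac * (hi - med)
    out: List[List[Detection]] = []
    for f in range(stack.shape[0]):
        mask = sm[f] > threshold
        peaks = peak_local_max(sm[f], min_distance=peak_min_distance_px,
                               threshold_abs=threshold, labels=mask,
                               exclude_border=False)
        markers = np.zeros(mask.shape, dtype=np.int32)
        for j, (py, px_) in enumerate(peaks, start=1):
            markers[py, px_] = j
        labels = watershed(-sm[f], markers=markers, mask=mask)
        n = labels.max()
        dets: List[Detection] = []
        if n:
            areas = ndi.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
            weights = np.clip(sm[f] - threshold, 0, None)
            coms = ndi.center_of_mass(weights, labels, range(1, n + 1))
            sums = ndi.sum_labels(stack[f], labels, range(1, n + 1))
            for j in range(n):
                if areas[j] < min_area_px:
                    continue
                cy, cx = coms[j]
                dets.append(Detection(
                    frame=f, y_um=cy * pixel_size_um, x_um=cx * pixel_size_um,
                    total_intensity=float(sums[j]),
                    radius_um=float(np.sqrt(areas[j] / np.pi) * pixel_size_um)))
        out.append(dets)
    return out


# ---------------------------------------------------------------------------
# linking

def _estimate_max_disp(detections: Sequence[Sequence[Detection]]) -> float:
    """3x the median nearest-neighbour frame-to-frame displacement."""
    ds = []
    for a, b in zip(detections, detections[1:]):
        if not a or not b:
            continue
        pa = np.array([[d.y_um, d.x_um] for d in a])
        pb = np.array([[d.y_um, d.x_um] for d in b])
        dist = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        ds.extend(dist.min(axis=1))
    if not ds:
        return 1.0
    return 3.0 * float(np.median(ds))


def link_tracks(detections: Sequence[Sequence[Detection]],
                max_disp_um: Optional[float] = None,
                max_gap_frames: int = 0,
                allow_merge_split: bool = True,
                ) -> Tuple[List[Track], List[EventRecord]]:
    """Link per-frame detections into tracks and call merge/split events.

    Frame pairs are assigned by the Hungarian algorithm on Euclidean
    distance, gated at ``max_disp_um`` (default: 3x the median
    nearest-neighbour displacement).  Unmatched detections seed new tracks;
    unmatched tracks stay open for ``max_gap_frames`` frames before closing.
    With ``allow_merge_split``, a track ending next to a continuing track is
    a coalescence, and a track born next to a continuing track a cleavage.
    """
    n_frames = len(detections)
    if all(len(d) == 0 for d in detections):
        return [], []
    if max_disp_um is None:
        max_disp_um = _estimate_max_disp(detections)
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be positive")

    tracks: List[Track] = []
    active: List[Tuple[Track, int]] = []  # (track, frames since last detection)
    for f in range(n_frames):
        dets = sorted(detections[f], key=lambda d: (d.y_um, d.x_um))
        assigned_det = set()
        if active and dets:
            tp = np.array([t.positions[-1] for t, _ in active])
            dp = np.array([[d.y_um, d.x_um] for d in dets])
            cost = np.linalg.norm(tp[:, None, :] - dp[None, :, :], axis=2)
            big = 1e6
            gated = np.where(cost <= max_disp_um, cost, big)
            rows, cols = linear_sum_assignment(gated)
            matched_tracks = set()
            for r, c in zip(rows, cols):
                if gated[r, c] >= big:
                    continue
                active[r][0].add(dets[c])
                matched_tracks.add(r)
                assigned_det.add(c)
            active = [(t, 0) if i in matched_tracks else (t, age + 1)
                      for i, (t, age) in enumerate(active)]
        else:
            active = [(t, age + 1) for t, age in active]
        active = [(t, age) for t, age in active if age <= max_gap_frames]
        for c, det in enumerate(dets):
            if c not in assigned_det:
                tr = Track(id=len(tracks))
                tr.add(det)
                tracks.append(tr)
                active.append((tr, 0))

    events: List[EventRecord] = []
    if allow_merge_split:
        by_frame: Dict[int, List[Track]] = {}
        for t in tracks:
            for fr, pos in zip(t.frames, t.positions):
                by_frame.setdefault(fr, []).append(t)

        def _pos_at(t: Track, fr: int):
            try:
                return t.positions[t.frames.index(fr)]
            except ValueError:
                return None

        for t in tracks:
            # coalescence: t ends, a neighbour continues through end+1
            if t.end < n_frames - 1:
                best = None
                for other in by_frame.get(t.end + 1, []):
                    if other is t or other.start > t.end:
                        continue
                    p = _pos_at(other, t.end + 1)
                    if p is None:
                        continue
                    d = float(np.linalg.norm(p - t.positions[-1]))
                    if d <= max_disp_um and (best is None or d < best[0]):
                        best = (d, other)
                if best is not None:
                    other = best[1]
                    events.append(EventRecord("coalescence", t.end + 1,
                                              (t.id, other.id)))
                    t.child_ids.append(other.id)
                    other.parent_ids.append(t.id)
            # cleavage: t is born next to a continuing neighbour
            if t.start > 0:
                best = None
                for other in by_frame.get(t.start - 1, []):
                    if other is t or other.end < t.start:
                        continue
                    p = _pos_at(other, t.start - 1)
                    if p is None:
                        continue
                    d = float(np.linalg.norm(p - t.positions[0]))
                    if d <= max_disp_um and (best is None or d < best[0]):
                        best = (d, other)
                if best is not None:
                    other = best[1]
                    events.append(EventRecord("cleavage", t.start,
                                              (other.id, t.id)))
                    other.child_ids.append(t.id)
                    t.parent_ids.append(other.id)
    return tracks, events


# ---------------------------------------------------------------------------
# event engagement

def event_engagement(tracks: Sequence[Track], events: Sequence[EventRecord],
                     frame_interval_s: float,
                     min_duration_s: float = 600.0) -> float:
    """Fraction of sufficiently long tracks participating in >=1 event.

    Tracks shorter than ``min_duration_s`` are excluded from both numerator
    and denominator; returns NaN (with a warning) when no track qualifies.
    """
    engaged = set()
    for e in events:
        engaged.update(e.participants)
    qualifying = [t for t in tracks
                  if t.duration_s(frame_interval_s) >= min_duration_s]
    if not qualifying:
        warnings.warn("no track meets the minimum duration; engagement undefined")
        return float("nan")
    hit = sum(1 for t in qualifying if t.id in engaged)
    return hit / len(qualifying)


def engagement_summary(per_cell_fractions: Sequence[float]) -> dict:
    """Median with interquartile range across cells (NaN cells dropped)."""
    return descriptives(per_cell_fractions)


# ---------------------------------------------------------------------------
# MSD

def msd(positions: np.ndarray, frame_interval_s: float,
        max_lag_fraction: float = 0.25) -> Tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD of a complete trajectory.

    ``MSD(tau_k) = mean_t |r(t + tau_k) - r(t)|^2`` for lags 1..floor(f*n).
    Returns (lag times in s, MSD in um^2).
    """
    r = np.asarray(positions, dtype=float)
    if r.ndim != 2:
        raise ValueError("positions must be (n, ndim)")
    n = r.shape[0]
    max_lag = int(np.floor(max_lag_fraction * n))
    if max_lag < 1:
        raise ValueError("trajectory too short for the requested lag range")
    lags = np.arange(1, max_lag + 1)
    out = np.empty(max_lag)
    for i, k in enumerate(lags):
        d = r[k:] - r[:-k]
        out[i] = np.mean(np.sum(d * d, axis=1))
    return lags * frame_interval_s, out


def msd_bruteforce(positions: np.ndarray, frame_interval_s: float,
                   max_lag_fraction: float = 0.25) -> Tuple[np.ndarray, np.ndarray]:
    """O(n^2) double-loop reference implementation of :func:`msd`."""
    r = np.asarray(positions, dtype=float)
    n = r.shape[0]
    max_lag = int(np.floor(max_lag_fraction * n))
    lags = np.arange(1, max_lag + 1)
    out = np.zeros(max_lag)
    for i, k in enumerate(lags):
        acc = 0.0
        cnt = 0
        for t in range(n - k):
            diff = r[t + k] - r[t]
            acc += float(diff @ diff)
            cnt += 1
        out[i] = acc / cnt
    return lags * frame_interval_s, out


def fit_msd(lag_s: np.ndarray, msd_um2: np.ndarray) -> MsdFit:
    """Fit anomalous-diffusion and directed-diffusion models to an MSD curve.

    alpha and Dapp come from the regression of log MSD on log tau
    (MSD = 4 Dapp tau^alpha); the velocity from a nonnegative least-squares
    fit of MSD = 4 D tau + (v tau)^2.
    """
    lag_s = np.asarray(lag_s, dtype=float)
    msd_um2 = np.asarray(msd_um2, dtype=float)
    keep = msd_um2 > 0
    if keep.sum() < 5:
        raise ValueError("need at least 5 positive MSD values")
    lt, lm = np.log(lag_s[keep]), np.log(msd_um2[keep])
    A = np.vstack([lt, np.ones_like(lt)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, lm, rcond=None)
    pred = A @ [slope, intercept]
    ss_tot = float(np.sum((lm - lm.mean()) ** 2))
    r2 = 1.0 - float(np.sum((lm - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    d_app = float(np.exp(intercept) / 4.0)

    B = np.vstack([4.0 * lag_s, lag_s ** 2]).T
    coef, _ = nnls(B, msd_um2)
    d_lin, v2 = coef
    return MsdFit(d_app=d_app, alpha=float(slope),
                  velocity=float(np.sqrt(v2)), d_lin=float(d_lin),
                  fit_lags=int(keep.sum()), r2=r2)


def net_displacement_velocity(positions: np.ndarray, duration_s: float) -> float:
    """Net start-to-end displacement over duration — a model-free velocity."""
    r = np.asarray(positions, dtype=float)
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return float(np.linalg.norm(r[-1] - r[0]) / duration_s)


# ---------------------------------------------------------------------------
# truth-matched evaluation

def evaluate_events(called: Sequence[EventRecord], truth: Sequence[dict],
                    tol_frames: int = 1) -> dict:
    """Match called events to ground truth by kind and frame (+/- tolerance).

    Truth records are dicts with at least ``kind`` and ``frame``.  Greedy
    one-to-one matching in order of frame distance; returns precision,
    recall and the match count.
    """
    unmatched_truth = list(range(len(truth)))
    n_match = 0
    for ev in sorted(called, key=lambda e: e.frame):
        best = None
        for j in unmatched_truth:
            tr = truth[j]
            if tr["kind"] != ev.kind:
                continue
            d = abs(tr["frame"] - ev.frame)
            if d <= tol_frames and (best is None or d < best[0]):
                best = (d, j)
        if best is not None:
            unmatched_truth.remove(best[1])
            n_match += 1
    precision = n_match / len(called) if called else (1.0 if not truth else 0.0)
    recall = n_match / len(truth) if truth else 1.0
    return {"precision": precision, "recall": recall, "n_matched": n_match,
            "n_called": len(called), "n_truth": len(truth)}


def tracks_to_frame(tracks: Sequence[Track], frame_interval_s: float) -> pd.DataFrame:
    """Flatten tracks into a (frame, time_s, track_id, y_um, x_um, intensity) table."""
    rows = []
    for t in tracks:
        for fr, pos, inten in zip(t.frames, t.positions, t.intensities):
            rows.append({"frame": fr, "time_s": fr * frame_interval_s,
                         "track_id": t.id, "y_um": pos[0], "x_um": pos[1],
                         "intensity": inten})
    return pd.DataFrame(rows)
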