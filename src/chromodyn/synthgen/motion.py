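"""Synthetic chromocenter trajectories and fusion/fission time-lapses.

Trajectories are 2D fractional Brownian motion (Hurst = alpha/2) scaled so
the ensemble MSD is ``4 * d_app * tau^alpha``, plus an optional constant
drift.  Time-lapses render foci as Gaussian blobs inside a nuclear disk;
fusion and fission events are scheduled as per-focus Poisson processes and
choreographed so that they remain resolvable by a frame-to-frame tracker:
a fusing partner is steered toward its target over the preceding frames
(bounded per-frame step) and daughters of a fission are displaced by about
one blob radius.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from ..fbm import fbm_path
from ..presets import DynamicsPreset, NucleusPreset

__all__ = ["make_trajectory", "make_timelapse", "truth_engagement",
           "TimelapseTruth"]

# rendering / choreography constants (um unless noted)
_BLOB_SIGMA_UM = 0.15
_EVENT_SEPARATION_UM = 0.9   # pre-merge / post-split spacing between partners
_STEER_STEP_UM = 0.8         # per-frame cap while steering a fusion partner
_MIN_SEPARATION_UM = 2.5     # initial focus spacing
_PAIR_MAX_DIST_UM = 5.0      # farthest partner considered for a fusion
_REPULSION_UM = 1.3          # enforced spacing between non-event foci
_SIDESTEP_UM = 0.9           # clearance a steered partner keeps from thirds


def make_trajectory(preset: DynamicsPreset, seed: int,
                    n_frames: Optional[int] = None,
                    origin: Tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Sample one 2D trajectory (n_frames, 2) in um.

    Per coordinate the fBm variance is ``2 * d_app * tau^alpha`` so the 2D
    MSD is ``4 * d_app * tau^alpha``; drift of magnitude ``velocity`` is
    added along a direction drawn uniformly from the circle.
    """
    rng = np.random.default_rng(seed)
    return _trajectory(preset, rng, n_frames or preset.n_frames, origin)


def _trajectory(preset: DynamicsPreset, rng: np.random.Generator,
                n_frames: int, origin) -> np.ndarray:
    hurst = preset.alpha / 2.0
    dt = preset.frame_interval_s
    if preset.d_app > 0:
        paths = fbm_path(n_frames - 1, hurst, dt, 2.0 * preset.d_app, rng, size=2)
    else:
        paths = np.zeros((2, n_frames))
    theta = rng.uniform(0, 2 * np.pi)
    t = np.arange(n_frames) * dt
    drift = preset.velocity * t
    pos = np.stack([paths[0] + drift * np.sin(theta),
                    paths[1] + drift * np.cos(theta)], axis=1)
    return pos + np.asarray(origin)


@dataclass
class _Focus:
    uid: int
    birth: int                    # first frame present
    death: int                    # last frame present (inclusive)
    pos: np.ndarray               # (n_frames, 2), valid on [birth, death]
    amplitude: float
    engaged: bool = False


@dataclass
class TimelapseTruth:
    """Ground truth of a rendered time-lapse."""

    frame_interval_s: float
    pixel_size_um: float
    foci: List[dict] = field(default_factory=list)     # uid, birth, death, positions
    events: List[dict] = field(default_factory=list)   # kind, frame, participants

    def as_dict(self) -> dict:
        return {"frame_interval_s": self.frame_interval_s,
                "pixel_size_um": self.pixel_size_um,
                "foci": self.foci, "events": self.events}


def truth_engagement(truth: TimelapseTruth, min_duration_s: float = 600.0) -> float:
    """Engagement fraction computed directly from ground truth.

    Mirrors the tracker-side definition: a truth focus is one track from its
    birth to its death; qualifying tracks last at least ``min_duration_s``;
    engaged tracks appear in at least one event.
    """
    engaged = set()
    for e in truth.events:
        engaged.update(e["participants"])
    qual = [f for f in truth.foci
            if (f["death"] - f["birth"]) * truth.frame_interval_s >= min_duration_s]
    if not qual:
        return float("nan")
    return sum(1 for f in qual if f["uid"] in engaged) / len(qual)


def _initial_positions(n: int, radius: float, rng: np.random.Generator,
                       min_sep: float) -> np.ndarray:
    sep = min_sep
    while sep >= _REPULSION_UM:  # relax gradually for crowded nuclei
        pts: List[np.ndarray] = []
        for _ in range(20000):
            if len(pts) == n:
                return np.array(pts)
            r = radius * 0.85 * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            p = np.array([r * np.sin(th), r * np.cos(th)])
            if all(np.linalg.norm(p - q) >= sep for q in pts):
                pts.append(p)
        sep *= 0.9
    raise ValueError("could not place foci inside the nucleus; "
                     "preset infeasible")


def simulate_dynamics(preset: DynamicsPreset, seed: int,
                      nucleus_radius_um: float = 7.0,
                      ) -> Tuple[List[_Focus], TimelapseTruth]:
    """Simulate focus genealogies and event times without rendering."""
    rng = np.random.default_rng(seed)
    n_frames = preset.n_frames
    dt = preset.frame_interval_s
    rate_per_s = (preset.fusion_rate + preset.fission_rate) / 60.0
    p_fusion = (preset.fusion_rate / (preset.fusion_rate + preset.fission_rate)
                if rate_per_s > 0 else 0.0)

    origins = _initial_positions(preset.n_foci, nucleus_radius_um, rng,
                                 _MIN_SEPARATION_UM)
    foci: List[_Focus] = []
    for i in range(preset.n_foci):
        pos = _trajectory(preset, rng, n_frames, origins[i])
        amp = float(rng.lognormal(mean=0.0, sigma=0.2))
        foci.append(_Focus(uid=i, birth=0, death=n_frames - 1, pos=pos,
                           amplitude=amp))
    _repel(foci, n_frames)  # keep wandering foci individually resolvable
    for fc in foci:  # keep base paths inside the nucleus
        r = np.linalg.norm(fc.pos, axis=1)
        scale = np.where(r > nucleus_radius_um * 0.95,
                         nucleus_radius_um * 0.95 / np.maximum(r, 1e-9), 1.0)
        fc.pos = fc.pos * scale[:, None]
    _repel(foci, n_frames)  # clipping can re-introduce boundary collisions
    truth = TimelapseTruth(frame_interval_s=dt, pixel_size_um=0.0)

    if rate_per_s > 0:
        p_event = 1.0 - math.exp(-rate_per_s * dt)
        frozen_until = {}  # uid -> frame before which no further event may fire
        windows = {}       # uid -> (lo, hi) frames of event choreography
        had_event = False
        for f in range(2, n_frames - 1):
            living = [fc for fc in foci if fc.birth <= f <= fc.death]
            for fc in list(living):
                if fc.death < f or f < frozen_until.get(fc.uid, 0):
                    continue
                if rng.uniform() >= p_event:
                    continue
                if rng.uniform() < p_fusion:
                    _try_fusion(fc, f, foci, preset, rng, frozen_until, truth,
                                windows)
                    had_event = True
                else:
                    child = _do_fission(fc, f, foci, preset, rng, frozen_until,
                                        truth, n_frames, nucleus_radius_um)
                    had_event = child is not None or had_event
        if had_event:
            _repel(foci, n_frames, windows=windows)

    for fc in foci:
        truth.foci.append({"uid": fc.uid, "birth": int(fc.birth),
                           "death": int(fc.death),
                           "positions": fc.pos[fc.birth:fc.death + 1].tolist()})
    return foci, truth


def _repel(foci: List[_Focus], n_frames: int, d_min: float = _REPULSION_UM,
           windows: Optional[dict] = None) -> None:
    """Enforce a minimum spacing between concurrently living foci.

    When two foci come closer than ``d_min`` at a frame, both are displaced
    symmetrically along their separation axis, and the displacement carries
    through the remainder of their paths (so per-frame steps stay small).
    Frames inside either focus' event-choreography window are skipped —
    fusion approaches must not be undone.
    """
    windows = windows or {}

    def in_window(uid, f):
        w = windows.get(uid)
        return w is not None and w[0] <= f <= w[1]

    for f in range(n_frames):
        living = [fc for fc in foci if fc.birth <= f <= fc.death]
        for i, a in enumerate(living):
            for b in living[i + 1:]:
                if in_window(a.uid, f) or in_window(b.uid, f):
                    continue
                d = a.pos[f] - b.pos[f]
                dist = float(np.linalg.norm(d))
                if dist >= d_min:
                    continue
                u = d / dist if dist > 1e-9 else _unit_det(a.uid, b.uid, f)
                shift = 0.5 * (d_min - dist) * u
                a.pos[f:] += shift
                b.pos[f:] -= shift


def _unit_det(ua: int, ub: int, f: int) -> np.ndarray:
    th = 2.399963 * (ua * 37 + ub * 11 + f)  # deterministic fallback direction
    return np.array([math.sin(th), math.cos(th)])


def _try_fusion(fc: _Focus, frame: int, foci: List[_Focus],
                preset: DynamicsPreset, rng: np.random.Generator,
                frozen_until: dict, truth: TimelapseTruth,
                windows: Optional[dict] = None) -> None:
    partners = [o for o in foci
                if o.uid != fc.uid and o.birth < frame - 1 and o.death >= frame
                and frame >= frozen_until.get(o.uid, 0)]
    if not partners:
        return
    dists = [np.linalg.norm(o.pos[frame] - fc.pos[frame]) for o in partners]
    j = int(np.argmin(dists))
    partner, dist = partners[j], dists[j]
    if dist > _PAIR_MAX_DIST_UM:
        return
    n_steer = max(1, int(math.ceil((dist - _EVENT_SEPARATION_UM)
                                   / _STEER_STEP_UM)) + 1)
    start = frame - n_steer
    if start <= partner.birth or start <= frozen_until.get(partner.uid, 0):
        return
    # radial approach: each frame the partner moves toward the survivor's
    # current position, never dropping below the event separation before the
    # merge frame, sidestepping any third focus that comes too close
    prev = partner.pos[start - 1].copy()
    for g in range(start, frame):
        rel = prev - fc.pos[g]
        d_prev = float(np.linalg.norm(rel))
        d_goal = max(_EVENT_SEPARATION_UM, d_prev - _STEER_STEP_UM)
        u = rel / d_prev if d_prev > 1e-9 else _unit(rng)
        cand = fc.pos[g] + d_goal * u
        thirds = [o for o in foci
                  if o.uid not in (fc.uid, partner.uid)
                  and o.birth <= g <= o.death]
        for k in range(1, 16):
            if all(np.linalg.norm(cand - o.pos[g]) >= _SIDESTEP_UM
                   for o in thirds):
                break
            ang = 0.2 * ((k + 1) // 2) * (1 if k % 2 else -1)
            rot = np.array([[math.cos(ang), -math.sin(ang)],
                            [math.sin(ang), math.cos(ang)]])
            cand = fc.pos[g] + d_goal * (rot @ u)
        partner.pos[g] = cand
        prev = cand
    partner.death = frame - 1
    fc.amplitude += partner.amplitude
    frozen_until[fc.uid] = frame + 3
    frozen_until[partner.uid] = 10 ** 9
    if windows is not None:
        windows[partner.uid] = (start, frame)
        windows[fc.uid] = (start, frame + 1)
    truth.events.append({"kind": "coalescence", "frame": int(frame),
                         "participants": [int(partner.uid), int(fc.uid)]})


def _do_fission(fc: _Focus, frame: int, foci: List[_Focus],
                preset: DynamicsPreset, rng: np.random.Generator,
                frozen_until: dict, truth: TimelapseTruth,
                n_frames: int, nucleus_radius_um: float) -> Optional[int]:
    if frame >= n_frames - 2:
        return None
    offset = _unit(rng) * _EVENT_SEPARATION_UM
    child_pos = np.zeros_like(fc.pos)
    tail = _trajectory(preset, rng, n_frames - frame, (0.0, 0.0))
    child_pos[frame:] = fc.pos[frame] + offset + tail
    child = _Focus(uid=_next_uid(foci), birth=frame, death=n_frames - 1,
                   pos=child_pos, amplitude=fc.amplitude * 0.45)
    fc.amplitude *= 0.55
    foci.append(child)
    frozen_until[fc.uid] = frame + 3
    frozen_until[child.uid] = frame + 3
    truth.events.append({"kind": "cleavage", "frame": int(frame),
                         "participants": [int(fc.uid), int(child.uid)]})
    return child.uid


def _next_uid(foci: List[_Focus]) -> int:
    return max(f.uid for f in foci) + 1


def _unit(rng: np.random.Generator) -> np.ndarray:
    th = rng.uniform(0, 2 * np.pi)
    return np.array([np.sin(th), np.cos(th)])


def make_timelapse(preset: DynamicsPreset, nucleus: NucleusPreset, seed: int
                   ) -> Tuple[np.ndarray, TimelapseTruth]:
    """Render a (T, Y, X) time-lapse of moving, fusing and splitting foci.

    Foci follow :func:`simulate_dynamics` genealogies; blobs of one merged
    focus carry the summed amplitude.  The truth records every event with
    its frame index and participant uids.
    """
    shape = tuple(nucleus.image_shape[-2:])
    px = nucleus.voxel_size_um
    if _BLOB_SIGMA_UM / px * 6 > min(shape):
        raise ValueError("focus blobs do not fit in the image; preset infeasible")
    foci, truth = simulate_dynamics(preset, seed,
                                    nucleus_radius_um=nucleus.nucleus_radius_um)
    truth.pixel_size_um = px
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))

    n_frames = preset.n_frames
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    center = np.array([shape[0] / 2, shape[1] / 2])
    nuc_mask = ((yy - center[0]) ** 2 + (xx - center[1]) ** 2
                <= (nucleus.nucleus_radius_um / px) ** 2)
    base = np.full(shape, nucleus.background, dtype=float)
    base[nuc_mask] += nucleus.eu_intensity * 0.3
    sigma_px = _BLOB_SIGMA_UM / px

    stack = np.empty((n_frames,) + shape, dtype=np.float32)
    half = int(math.ceil(4 * sigma_px))
    for f in range(n_frames):
        img = base.copy()
        for fc in foci:
            if not fc.birth <= f <= fc.death:
                continue
            cy, cx = fc.pos[f] / px + center
            y0, y1 = int(cy) - half, int(cy) + half + 1
            x0, x1 = int(cx) - half, int(cx) + half + 1
            y0c, x0c = max(y0, 0), max(x0, 0)
            y1c, x1c = min(y1, shape[0]), min(x1, shape[1])
            if y0c >= y1c or x0c >= x1c:
                continue
            ys = yy[y0c:y1c, x0c:x1c]
            xs = xx[y0c:y1c, x0c:x1c]
            img[y0c:y1c, x0c:x1c] += (nucleus.cc_intensity * fc.amplitude
                                      * np.exp(-((ys - cy) ** 2 + (xs - cx) ** 2)
                                               / (2 * sigma_px ** 2)))
        img += rng.normal(0.0, nucleus.noise_gaussian_sd, size=shape)
        stack[f] = img
    return stack, truth
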