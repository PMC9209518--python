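"""Synthetic two-channel nuclei: DAPI-like chromocenters and RNA-FISH foci.

Each nucleus is a bright disk of euchromatin signal containing chromocenter
disks; RNA foci are placed so that their true pixel-overlap fractions with
chromocenters satisfy a sampled localization class:

* ``within``    — more than half of the focus overlaps one chromocenter;
* ``periphery`` — a sub-50% overlap with exactly one chromocenter;
* ``between``   — sub-50% overlaps with at least two chromocenters.

Placement is verified on the rasterized truth masks, so every truth record
is consistent with its rendered object by construction.
"""
from __future__ import annotations

import math
import warnings
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from ..presets import NucleusPreset

__all__ = ["make_rna_foci_nucleus", "make_nucleus_image"]

_CLASSES = ("within", "periphery", "between")
_MAX_TRIES = 60


def _disk_mask(shape, cy, cx, r) -> np.ndarray:
    yy, xx = np.ogrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def _overlap_fractions(focus: np.ndarray, cc_labels: np.ndarray) -> Dict[int, float]:
    tot = int(focus.sum())
    if tot == 0:
        return {}
    vals, counts = np.unique(cc_labels[focus], return_counts=True)
    return {int(v): float(c) / tot for v, c in zip(vals, counts) if v != 0}


def _class_of(fracs: Dict[int, float]) -> str:
    if not fracs:
        return "unassociated"
    if max(fracs.values()) > 0.5:
        return "within"
    if len(fracs) >= 2:
        return "between"
    return "periphery"


def _place_chromocenters(preset: NucleusPreset, rng, n_cc: int,
                         n_between: int, shape, center, nuc_r_px):
    """Place chromocenter disks; ``n_between`` close pairs host between-foci."""
    px = preset.voxel_size_um
    radii = preset.cc_radius_um.draw(rng, size=n_cc) / px
    centers: List[np.ndarray] = []
    pair_of: Dict[int, int] = {}
    min_gap = 1.0 / px  # boundary gap between unrelated chromocenters

    def fits(p, r, gap_overrides=()):
        if np.linalg.norm(p - center) + r > nuc_r_px * 0.92:
            return False
        for j, q in enumerate(centers):
            gap = np.linalg.norm(p - q) - r - radii[j]
            need = dict(gap_overrides).get(j, min_gap)
            if gap < need:
                return False
        return True

    i = 0
    pairs_placed = 0
    attempts = 0
    while i < n_cc and attempts < 5000:
        attempts += 1
        rr = nuc_r_px * 0.8 * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        p = center + rr * np.array([math.sin(th), math.cos(th)])
        if not fits(p, radii[i]):
            continue
        centers.append(p)
        this = i
        i += 1
        if pairs_placed < n_between and i < n_cc:
            # partner with a small boundary gap to host a "between" focus
            gap = rng.uniform(0.22, 0.34) / px
            for _ in range(200):
                th2 = rng.uniform(0, 2 * math.pi)
                d = radii[this] + radii[i] + gap
                q = p + d * np.array([math.sin(th2), math.cos(th2)])
                if fits(q, radii[i], gap_overrides={this: gap - 1e-9}):
                    centers.append(q)
                    pair_of[this] = i
                    i += 1
                    pairs_placed += 1
                    break
    if i < n_cc:
        n_cc = i
    cc_labels = np.zeros(shape, dtype=np.int32)
    for j in range(n_cc):
        cc_labels[_disk_mask(shape, centers[j][0], centers[j][1], radii[j])] = j + 1
    return cc_labels, np.array(centers[:n_cc]), radii[:n_cc], pair_of


def make_rna_foci_nucleus(preset: NucleusPreset, seed: int
                          ) -> Tuple[np.ndarray, Dict[str, np.ndarray], dict]:
    """Generate one nucleus: (2, Y, X) image, truth masks, ground truth.

    Returns ``(image, masks, truth)`` where ``image[0]`` is the DAPI-like
    channel, ``image[1]`` the FISH channel; ``masks`` holds the truth label
    maps (``nucleus``, ``chromocenters``, ``rna``); ``truth`` records each
    focus' class and true overlap fractions (skipped placements included).
    """
    rng = np.random.default_rng(seed)
    shape = tuple(preset.image_shape[-2:])
    px = preset.voxel_size_um
    center = np.array([shape[0] / 2, shape[1] / 2])
    nuc_r_px = preset.nucleus_radius_um / px

    n_foci = int(round(float(preset.rna_foci_count.draw(rng))))
    classes = [_CLASSES[i] for i in
               rng.choice(3, size=n_foci, p=list(preset.rna_class_probs))]
    n_between = sum(1 for c in classes if c == "between")

    n_cc = max(int(round(float(preset.n_chromocenters.draw(rng)))),
               2 * n_between + 1)
    cc_labels, cc_centers, cc_radii, pair_of = _place_chromocenters(
        preset, rng, n_cc, n_between, shape, center, nuc_r_px)

    nucleus_mask = _disk_mask(shape, center[0], center[1], nuc_r_px)
    rna_labels = np.zeros(shape, dtype=np.int32)
    focus_truth: List[dict] = []
    pair_keys = list(pair_of.items())
    placed_centers: List[np.ndarray] = []

    between_idx = -1
    for fi, cls in enumerate(classes):
        r_f = float(preset.rna_focus_radius_um.draw(rng)) / px
        if cls == "between":
            between_idx += 1
        ok = False
        for _ in range(_MAX_TRIES):
            if cls == "within":
                j = int(rng.integers(len(cc_radii)))
                d = rng.uniform(0, max(cc_radii[j] - r_f, 0.0)) * 0.9
                th = rng.uniform(0, 2 * math.pi)
                c = cc_centers[j] + d * np.array([math.sin(th), math.cos(th)])
            elif cls == "periphery":
                j = int(rng.integers(len(cc_radii)))
                d = cc_radii[j] + rng.uniform(0.25, 0.6) * r_f
                th = rng.uniform(0, 2 * math.pi)
                c = cc_centers[j] + d * np.array([math.sin(th), math.cos(th)])
            else:  # between: each such focus owns one dedicated close pair
                if between_idx >= len(pair_keys):
                    break
                a, b = pair_keys[between_idx]
                pa, pb = cc_centers[a], cc_centers[b]
                ra, rb = cc_radii[a], cc_radii[b]
                dvec = pb - pa
                dist = np.linalg.norm(dvec)
                mid = pa + dvec * ((ra + (dist - ra - rb) / 2) / dist)
                c = mid + rng.normal(0, 0.3, size=2)
            cand = _disk_mask(shape, c[0], c[1], r_f)
            if np.linalg.norm(c - center) + r_f > nuc_r_px:
                continue
            if any(np.linalg.norm(c - q) < 2.5 * r_f for q in placed_centers):
                continue
            fr = _overlap_fractions(cand, cc_labels)
            if _class_of(fr) == cls:
                rna_labels[cand] = fi + 1
                placed_centers.append(c)
                focus_truth.append({"focus_id": fi + 1, "class": cls,
                                    "overlap_fractions": fr,
                                    "radius_um": r_f * px, "skipped": False})
                ok = True
                break
        if not ok:
            warnings.warn(f"focus {fi} ({cls}) could not be placed; skipped")
            focus_truth.append({"focus_id": fi + 1, "class": cls,
                                "overlap_fractions": {}, "radius_um": r_f * px,
                                "skipped": True})

    psf_px = preset.psf_sigma_um / px
    dapi = np.full(shape, preset.background, dtype=float)
    dapi[nucleus_mask] += preset.eu_intensity
    dapi += preset.cc_intensity * ndi.gaussian_filter(
        (cc_labels > 0).astype(float), psf_px)
    fish = np.full(shape, preset.background, dtype=float)
    fish[nucleus_mask] += 0.15 * preset.eu_intensity
    fish += preset.rna_intensity * ndi.gaussian_filter(
        (rna_labels > 0).astype(float), psf_px)
    dapi += rng.normal(0, preset.noise_gaussian_sd, shape)
    fish += rng.normal(0, preset.noise_gaussian_sd, shape)

    image = np.stack([dapi, fish]).astype(np.float32)
    masks = {"nucleus": nucleus_mask.astype(np.int32),
             "chromocenters": cc_labels, "rna": rna_labels}
    truth = {"preset": preset.name, "seed": int(seed),
             "n_chromocenters": int(cc_labels.max()),
             "cc_radii_um": (np.asarray(cc_radii) * px).tolist(),
             "foci": focus_truth}
    return image, masks, truth


def make_nucleus_image(preset: NucleusPreset, seed: int,
                       n_z: Optional[int] = None):
    """Single-channel nucleus rendering (2D, or a thin 3D stack of spheres).

    Used for segmentation/morphometry and FLIM-mask validation; returns
    ``(image, masks, truth)`` like :func:`make_rna_foci_nucleus` but with a
    single channel.
    """
    image, masks, truth = make_rna_foci_nucleus(preset, seed)
    if n_z is None:
        return image[0], masks, truth
    # extrude chromocenter disks into spheres around the central plane
    shape = tuple(preset.image_shape[-2:])
    px = preset.voxel_size_um
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    stack = np.empty((n_z,) + shape, dtype=np.float32)
    cc = masks["chromocenters"]
    objs = ndi.find_objects(cc)
    mid = n_z // 2
    yy, xx = np.ogrid[0:shape[0], 0:shape[1]]
    nuc = masks["nucleus"] > 0
    for z in range(n_z):
        img = np.full(shape, preset.background, dtype=float)
        img[nuc] += preset.eu_intensity
        plane = np.zeros(shape, dtype=float)
        for lab, sl in enumerate(objs, start=1):
            if sl is None:
                continue
            m = cc == lab
            r_px = math.sqrt(m.sum() / math.pi)
            dz = abs(z - mid)
            if dz * 1.0 >= r_px:  # unit z-spacing in px
                continue
            r_z = math.sqrt(r_px ** 2 - dz ** 2)
            cy, cx = ndi.center_of_mass(m)
            plane[(yy - cy) ** 2 + (xx - cx) ** 2 <= r_z ** 2] = 1.0
        img += preset.cc_intensity * ndi.gaussian_filter(plane, preset.psf_sigma_um / px)
        img += rng.normal(0, preset.noise_gaussian_sd, shape)
        stack[z] = img
    return stack, masks, truth
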