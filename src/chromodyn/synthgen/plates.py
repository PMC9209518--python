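"""Synthetic droplet-formation plates.

Each well is a bright-droplets-on-dark-background field.  Wells at protein
concentrations at or above the RNA species' critical concentration contain
genuine droplets (disks with log-normally distributed diameters around the
species' size scale); wells below it contain at most a few sub-threshold
specks.  A no-RNA species (infinite critical concentration) never forms
droplets — the protein does not phase separate on its own under these
conditions.
"""
from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np

from ..presets import DropletPlatePreset

__all__ = ["make_droplet_plate"]

_SPECK_DIAMETER_UM = 0.6   # below the 1-um detection cutoff
_MIN_TRUE_DROPLETS = 8


def _render_disks(shape, rng, centers, radii_px, intensity, background, noise_sd):
    img = np.full(shape, background, dtype=float)
    yy, xx = np.ogrid[0:shape[0], 0:shape[1]]
    for (cy, cx), r in zip(centers, radii_px):
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = background + intensity
    img += rng.normal(0, noise_sd, shape)
    return img.astype(np.float32)


def _place(rng, shape, radii_px):
    centers = []
    for r in radii_px:
        for _ in range(200):
            cy = rng.uniform(r + 2, shape[0] - r - 2)
            cx = rng.uniform(r + 2, shape[1] - r - 2)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 2) ** 2
                   for (y, x), rr in zip(centers, radii_px)):
                centers.append((cy, cx))
                break
        else:
            centers.append((rng.uniform(0, shape[0]), rng.uniform(0, shape[1])))
    return centers


def make_droplet_plate(preset: DropletPlatePreset, seed: int
                       ) -> Tuple[Dict[Tuple[str, float], np.ndarray], dict]:
    """Generate all well images of a plate and per-well ground truth.

    Returns ``(wells, truth)``: ``wells[(species, conc)]`` is the field
    image; ``truth["wells"]`` records the true droplet count and diameters
    of each well (specks are not counted as droplets).
    """
    rng = np.random.default_rng(seed)
    shape = tuple(preset.field_shape_px)
    px = preset.pixel_size_um
    wells: Dict[Tuple[str, float], np.ndarray] = {}
    truth_wells = []
    for sp in preset.rna_species:
        for conc in preset.protein_concs_uM:
            has = conc >= sp.critical_conc_uM and conc > 0
            if has:
                n = max(_MIN_TRUE_DROPLETS,
                        int(rng.poisson(preset.droplet_count_mean)))
                diam = rng.lognormal(math.log(sp.droplet_size_scale_um), 0.25,
                                     size=n)
                diam = np.clip(diam, 1.2, None)
            else:
                n = 0
                diam = np.array([])
            n_specks = int(rng.poisson(1.5))
            speck_d = np.full(n_specks, _SPECK_DIAMETER_UM)
            all_d = np.concatenate([diam, speck_d])
            radii_px = all_d / 2.0 / px
            centers = _place(rng, shape, radii_px)
            img = _render_disks(shape, rng, centers, radii_px,
                                preset.droplet_intensity, preset.background,
                                preset.noise_gaussian_sd)
            wells[(sp.name, conc)] = img
            truth_wells.append({
                "species": sp.name, "conc_uM": float(conc),
                "droplet_count": int(n),
                "diameters_um": diam.tolist(),
                "has_droplets": bool(has),
            })
    truth = {
        "preset": preset.name, "seed": int(seed),
        "critical_conc_uM": {sp.name: sp.critical_conc_uM
                             for sp in preset.rna_species},
        "wells": truth_wells,
    }
    return wells, truth
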