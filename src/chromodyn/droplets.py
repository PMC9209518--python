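"""Droplet-plate quantification: detection, critical concentration, sizes.

A well "has droplets" when at least ``min_count`` detected objects pass the
diameter and circularity filters; the critical concentration of an RNA
species is the minimum protein concentration of the dilution series at
which droplets are detected.  Detection patterns that are non-monotone in
concentration are flagged as QC failures.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .stats import descriptives, mann_whitney

__all__ = [
    "WellResult",
    "CriticalConcentration",
    "detect_droplets",
    "analyze_plate",
    "call_critical_concentration",
    "compare_species",
]


@dataclass
class WellResult:
    rna_species: str
    protein_conc_uM: float
    droplet_count: int
    diameters_um: List[float]
    droplets_detected: bool
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.droplet_count != len(self.diameters_um):
            raise ValueError("count must equal the number of diameters")
        if self.protein_conc_uM < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class CriticalConcentration:
    rna_species: str
    value_uM: Optional[float]       # None: no droplets at any tested conc
    series_uM: List[float] = field(default_factory=list)
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.value_uM is not None and self.value_uM not in self.series_uM:
            raise ValueError("critical concentration must lie on the series")


def detect_droplets(image: np.ndarray, pixel_size_um: float,
                    min_diameter_um: float = 1.0,
                    threshold: Optional[float] = None,
                    min_circularity: float = 0.6,
                    saturation_level: Optional[float] = None) -> pd.DataFrame:
    """Detect droplets in one well image; returns one row per droplet.

    Thresholding (default: midway between median and maximum) + connected
    components + a circularity filter (4 pi A / P^2 >= ``min_circularity``);
    diameters are equivalent-circle diameters.  A saturated image is flagged
    with a warning but still processed.
    """
    img = np.asarray(image, dtype=float)
    if saturation_level is not None and (img >= saturation_level).mean() > 0.2:
        warnings.warn("well image looks saturated; processing anyway")
    if threshold is None:
        threshold = 0.5 * (float(np.median(img)) + float(img.max()))
    mask = img > threshold
    labels, n = ndi.label(mask)
    rows = []
    if n:
        for p in measure.regionprops(labels):
            area_um2 = p.area * pixel_size_um ** 2
            diam = 2.0 * np.sqrt(area_um2 / np.pi)
            if diam < min_diameter_um:
                continue
            perim = max(p.perimeter, 1e-9)
            circ = min(4.0 * np.pi * p.area / perim ** 2, 1.0)
            if circ < min_circularity:
                continue
            rows.append({"label": p.label, "diameter_um": float(diam),
                         "area_um2": float(area_um2),
                         "circularity": float(circ),
                         "y_px": p.centroid[0], "x_px": p.centroid[1]})
    return pd.DataFrame(rows, columns=["label", "diameter_um", "area_um2",
                                       "circularity", "y_px", "x_px"])


def analyze_plate(wells: Dict[Tuple[str, float], np.ndarray],
                  pixel_size_um: float, min_diameter_um: float = 1.0,
                  min_count: int = 5, **detect_kwargs) -> List[WellResult]:
    """Run droplet detection on every well of a plate."""
    out = []
    for (species, conc), img in wells.items():
        df = detect_droplets(img, pixel_size_um,
                             min_diameter_um=min_diameter_um, **detect_kwargs)
        diams = df["diameter_um"].tolist()
        out.append(WellResult(rna_species=species, protein_conc_uM=float(conc),
                              droplet_count=len(diams), diameters_um=diams,
                              droplets_detected=len(diams) >= min_count))
    return out


def call_critical_concentration(results: Sequence[WellResult],
                                min_count: int = 5) -> CriticalConcentration:
    """Minimum tested concentration with detected droplets, for one species.

    ``droplets_detected`` is re-derived as ``droplet_count >= min_count``.
    A detection pattern that is not monotone in concentration (droplets at
    some concentration but not at a higher one) fails QC.
    """
    results = list(results)
    if not results:
        raise ValueError("empty dilution series")
    species = {r.rna_species for r in results}
    if len(species) > 1:
        raise ValueError("results span multiple species")
    ordered = sorted(results, key=lambda r: -r.protein_conc_uM)
    series = [r.protein_conc_uM for r in ordered]
    det = [r.droplet_count >= min_count for r in ordered]
    value = None
    for conc, d in zip(series, det):
        if d and conc > 0:
            value = conc
    # monotone means: a prefix of the descending series is all-detected
    first_false = det.index(False) if False in det else len(det)
    qc = all(not d for d in det[first_false:])
    return CriticalConcentration(rna_species=species.pop(), value_uM=value,
                                 series_uM=series, qc_pass=qc)


def compare_species(results: Sequence[WellResult], min_count: int = 5
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Critical-concentration table and pairwise diameter comparisons.

    Returns ``(species_table, pairwise)``: per-species critical
    concentration and diameter descriptives (over droplet-positive wells),
    and pairwise two-sided Mann–Whitney p-values on droplet diameters.
    """
    by_species: Dict[str, List[WellResult]] = {}
    for r in results:
        by_species.setdefault(r.rna_species, []).append(r)
    if len(by_species) < 2:
        raise ValueError("need at least two species to compare")
    rows = []
    diam: Dict[str, np.ndarray] = {}
    for sp, res in by_species.items():
        cc = call_critical_concentration(res, min_count=min_count)
        d = np.concatenate([r.diameters_um for r in res
                            if r.droplet_count >= min_count] or [[]])
        diam[sp] = d
        desc = descriptives(d) if d.size else {"n": 0, "median": np.nan,
                                               "mean": np.nan, "sem": np.nan,
                                               "q1": np.nan, "q3": np.nan}
        rows.append({"rna_species": sp, "critical_conc_uM": cc.value_uM,
                     "qc_pass": cc.qc_pass, "n_droplets": desc["n"],
                     "mean_diameter_um": desc["mean"],
                     "median_diameter_um": desc["median"]})
    table = pd.DataFrame(rows).sort_values(
        "critical_conc_uM", na_position="last").reset_index(drop=True)
    pair_rows = []
    names = sorted(by_species)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if diam[a].size >= 2 and diam[b].size >= 2:
                _, p = mann_whitney(diam[a], diam[b])
            else:
                p = np.nan
            pair_rows.append({"species_a": a, "species_b": b,
                              "p_diameter_mannwhitney": p})
    return table, pd.DataFrame(pair_rows)
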