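"""Nucleus/chromocenter segmentation, morphometry, colocalization, linescans.

Segmentation subtracts a percentile background estimate and applies one
constant threshold (held fixed across a batch of images and conditions);
chromocenters are connected components nested inside their parent nucleus.
Morphometry follows the mid-section convention: each chromocenter is
measured at its optimal focal plane, the z-slice where its cross-sectional
area is largest, with the major axis taken from the second-moment ellipse.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .stats import descriptives, mann_whitney

__all__ = [
    "LabelMap",
    "segment",
    "chromocenter_count_histogram",
    "morphometry",
    "intensity_at_foci",
    "pearson_colocalization",
    "linescan",
    "quartile_bin",
]


@dataclass
class LabelMap:
    """An integer label image plus the provenance of its segmentation."""

    data: np.ndarray
    channel: str = ""
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)

    @property
    def n_labels(self) -> int:
        return int(self.data.max())


def _labels(x) -> np.ndarray:
    return x.data if isinstance(x, LabelMap) else np.asarray(x)


def segment(image: np.ndarray, background_percentile: float = 50.0,
            nucleus_threshold: Optional[float] = None,
            cc_threshold: Optional[float] = None,
            nucleus_smooth_px: float = 4.0,
            min_nucleus_area_px: int = 500,
            min_cc_area_px: int = 9,
            channel: str = "") -> Tuple[LabelMap, LabelMap]:
    """Segment nuclei, then chromocenters inside them (2D or 3D input).

    The background is the given percentile of out-of-nucleus pixels and is
    subtracted before the chromocenter threshold is applied; for batch use,
    pass explicit thresholds so that one constant value serves all images.
    Auto thresholds: Otsu on the smoothed image for nuclei; background +
    35% of the span to the 99.9th percentile for chromocenters.
    """
    img = np.asarray(image, dtype=float)
    sm = ndi.gaussian_filter(img, nucleus_smooth_px)
    if nucleus_threshold is None:
        # three-level Otsu (background | nucleoplasm | bright foci); the
        # lowest boundary separates nuclei from background even when bright
        # chromocenters dominate the upper tail
        from skimage.filters import threshold_multiotsu, threshold_otsu
        try:
            nucleus_threshold = float(threshold_multiotsu(sm, classes=3)[0])
        except ValueError:
            nucleus_threshold = float(threshold_otsu(sm))
    nuc_mask = sm > nucleus_threshold
    # contrast guard: a threshold inside the noise of a featureless image
    # would label half the field as nucleus
    if nuc_mask.any() and not nuc_mask.all():
        bg = img[~nuc_mask]
        mad = 1.4826 * np.median(np.abs(bg - np.median(bg)))
        if np.median(img[nuc_mask]) - np.median(bg) < 3.0 * max(mad, 1e-12):
            nuc_mask[:] = False
    nuc_mask = ndi.binary_fill_holes(nuc_mask)
    nuc_labels, n_nuc = ndi.label(nuc_mask)
    if n_nuc:
        sizes = ndi.sum_labels(np.ones_like(nuc_labels), nuc_labels,
                               range(1, n_nuc + 1))
        keep = np.flatnonzero(sizes >= min_nucleus_area_px) + 1
        nuc_labels = np.where(np.isin(nuc_labels, keep), nuc_labels, 0)
        nuc_labels, n_nuc = _relabel(nuc_labels)
    if n_nuc == 0:
        warnings.warn("no nuclei found")
        empty = LabelMap(np.zeros_like(img, dtype=np.int32), channel)
        return empty, LabelMap(empty.data.copy(), channel)

    outside = img[nuc_labels == 0]
    background = float(np.percentile(outside, background_percentile)) \
        if outside.size else 0.0
    corrected = img - background
    if cc_threshold is None:
        # half-max between the nucleoplasm level and the brightest foci, so a
        # chromocenter's called boundary sits at its half-intensity radius
        inside = corrected[nuc_labels > 0]
        med = float(np.median(inside))
        hi = float(np.percentile(inside, 99.9))
        cc_threshold = med + 0.5 * (hi - med)
    cc_mask = (corrected > cc_threshold) & (nuc_labels > 0)
    cc_labels, n_cc = ndi.label(cc_mask)
    if n_cc:
        sizes = ndi.sum_labels(np.ones_like(cc_labels), cc_labels,
                               range(1, n_cc + 1))
        keep = np.flatnonzero(sizes >= min_cc_area_px) + 1
        cc_labels = np.where(np.isin(cc_labels, keep), cc_labels, 0)
        cc_labels, n_cc = _relabel(cc_labels)
    return (LabelMap(nuc_labels.astype(np.int32), channel, nucleus_threshold),
            LabelMap(cc_labels.astype(np.int32), channel, cc_threshold))


def _relabel(labels: np.ndarray) -> Tuple[np.ndarray, int]:
    vals = np.unique(labels)
    vals = vals[vals > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(vals, start=1):
        out[labels == old] = new
    return out, len(vals)


def assign_to_nuclei(cc_labels, nuc_labels) -> Dict[int, int]:
    """Map each chromocenter label to the nucleus containing its centroid."""
    cc = _labels(cc_labels)
    nuc = _labels(nuc_labels)
    out: Dict[int, int] = {}
    for lab in range(1, int(cc.max()) + 1):
        m = cc == lab
        if not m.any():
            continue
        com = tuple(int(round(c)) for c in ndi.center_of_mass(m))
        out[lab] = int(nuc[com])
    return out


def chromocenter_count_histogram(counts_by_condition: Dict[str, Sequence[int]]
                                 ) -> Tuple[pd.DataFrame, float]:
    """Percentage of nuclei per chromocenter-count bin, plus a shift test.

    ``counts_by_condition`` maps condition name to per-nucleus counts.
    Returns the percentage table and (for two conditions) the two-sided
    Mann–Whitney p on the raw counts; NaN otherwise.
    """
    rows = []
    all_counts = [c for v in counts_by_condition.values() for c in v]
    if not all_counts:
        raise ValueError("need at least one nucleus")
    bins = np.arange(0, max(all_counts) + 2)
    for cond, counts in counts_by_condition.items():
        counts = np.asarray(list(counts))
        hist, _ = np.histogram(counts, bins=bins)
        pct = 100.0 * hist / counts.size
        for b, p in zip(bins[:-1], pct):
            rows.append({"condition": cond, "n_chromocenters": int(b),
                         "pct_nuclei": float(p)})
        rows.append({"condition": cond, "n_chromocenters": -1,
                     "pct_nuclei": float(counts.mean())})  # mean marker row
    p_val = np.nan
    conds = list(counts_by_condition)
    if len(conds) == 2:
        _, p_val = mann_whitney(list(counts_by_condition[conds[0]]),
                                list(counts_by_condition[conds[1]]))
    return pd.DataFrame(rows), float(p_val)


def _optimal_z(mask3d: np.ndarray) -> int:
    areas = mask3d.sum(axis=(1, 2))
    return int(np.argmax(areas))


def morphometry(cc_labels, pixel_size_um: float = 1.0,
                nucleus_map: Optional[Dict[int, int]] = None,
                intensity_channels: Optional[Dict[str, np.ndarray]] = None
                ) -> pd.DataFrame:
    """Mid-section area, major axis and per-channel intensities per label.

    For 3D input the mid-section of each chromocenter is its optimal focal
    plane (the z maximizing its cross-sectional area); 2D images use the
    single plane.  Areas are reported in px and um^2, the major axis (from
    the second-moment ellipse) in um.
    """
    cc = _labels(cc_labels)
    is3d = cc.ndim == 3
    rows = []
    objects = ndi.find_objects(cc)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        m = cc[sl] == lab
        if is3d:
            z_local = _optimal_z(m)
            plane = m[z_local]
            z_opt = sl[0].start + z_local
        else:
            plane = m
            z_opt = 0
        area_px = int(plane.sum())
        if area_px == 0:
            continue
        props = measure.regionprops(plane.astype(np.uint8))[0]
        major = props.axis_major_length * pixel_size_um
        minor = props.axis_minor_length * pixel_size_um
        row = {"cc_id": lab,
               "nucleus_id": (nucleus_map or {}).get(lab, 0),
               "optimal_z": z_opt,
               "area_px": area_px,
               "area_um2": area_px * pixel_size_um ** 2,
               "major_axis_um": major,
               "minor_axis_um": minor}
        if intensity_channels:
            for name, chan in intensity_channels.items():
                chan = np.asarray(chan, dtype=float)
                plane_img = chan[z_opt] if is3d else chan
                vals = plane_img[sl[-2:]][plane]
                row[f"mean_{name}"] = float(vals.mean())
                row[f"total_{name}"] = float(vals.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def intensity_at_foci(channel: np.ndarray, cc_labels,
                      pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Mean channel intensity over each chromocenter's optimal focal plane."""
    df = morphometry(cc_labels, pixel_size_um,
                     intensity_channels={"channel": channel})
    return df[["cc_id", "optimal_z", "mean_channel"]].rename(
        columns={"mean_channel": "mean_intensity"})


def pearson_colocalization(ch1: np.ndarray, ch2: np.ndarray, cc_labels,
                           midsection_only: bool = True,
                           min_pixels: int = 10) -> pd.DataFrame:
    """Pixelwise Pearson r between two channels within each chromocenter.

    3D inputs are evaluated on each label's optimal focal plane when
    ``midsection_only`` (the mid-section convention); labels with fewer
    than ``min_pixels`` pixels or zero variance in either channel are
    excluded, with the exclusion reason recorded.
    """
    cc = _labels(cc_labels)
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    is3d = cc.ndim == 3
    rows = []
    for lab, sl in enumerate(ndi.find_objects(cc), start=1):
        if sl is None:
            continue
        m = cc[sl] == lab
        if is3d and midsection_only:
            z_local = _optimal_z(m)
            plane = m[z_local]
            z = sl[0].start + z_local
            a = ch1[z][sl[1:]][plane]
            b = ch2[z][sl[1:]][plane]
        else:
            a = ch1[sl][m]
            b = ch2[sl][m]
        if a.size < min_pixels:
            rows.append({"cc_id": lab, "pearson_r": np.nan,
                         "n_pixels": int(a.size), "excluded": "too_few_pixels"})
            continue
        if a.std() == 0 or b.std() == 0:
            rows.append({"cc_id": lab, "pearson_r": np.nan,
                         "n_pixels": int(a.size), "excluded": "zero_variance"})
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append({"cc_id": lab, "pearson_r": r, "n_pixels": int(a.size),
                     "excluded": ""})
    return pd.DataFrame(rows)


def linescan(channels: Sequence[np.ndarray], start: Tuple[float, float],
             end: Tuple[float, float], width_px: int = 1,
             pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Min-max-normalized intensity profiles along a line, per channel.

    Intensities are sampled along the segment (averaged across
    ``width_px``); each channel is scaled to [0, 1].  A flat channel
    normalizes to zeros with a warning.  Positions are in um.
    """
    from skimage.measure import profile_line

    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if np.allclose(start, end):
        raise ValueError("degenerate line: start equals end")
    out = {}
    n = None
    for i, ch in enumerate(channels):
        prof = profile_line(np.asarray(ch, dtype=float), start, end,
                            linewidth=width_px, mode="nearest")
        lo, hi = prof.min(), prof.max()
        if hi - lo <= 0:
            warnings.warn(f"channel {i} is flat along the line")
            norm = np.zeros_like(prof)
        else:
            norm = (prof - lo) / (hi - lo)
        out[f"ch{i}"] = norm
        n = prof.size
    length_um = float(np.linalg.norm(end - start)) * pixel_size_um
    out["position_um"] = np.linspace(0.0, length_um, n)
    return pd.DataFrame(out)


def quartile_bin(control: Sequence[float], treatment: Sequence[float]
                 ) -> dict:
    """Quartile-membership fractions with boundaries set by the control.

    Boundaries are the control sample's quartiles; both samples are binned
    (ties at a boundary fall in the lower bin) and a two-sided Mann–Whitney
    on the raw values tests for a shift.
    """
    c = np.asarray(list(control), dtype=float)
    t = np.asarray(list(treatment), dtype=float)
    if c.size < 4:
        raise ValueError("control sample too small to define quartiles")
    bounds = np.percentile(c, [25, 50, 75])

    def frac(v):
        # side="left": a value equal to a boundary goes to the lower bin
        idx = np.searchsorted(bounds, v, side="left")
        return np.bincount(idx, minlength=4) / v.size

    _, p = mann_whitney(c, t)
    return {"boundaries": bounds.tolist(),
            "control_fractions": frac(c).tolist(),
            "treatment_fractions": frac(t).tolist(),
            "p_mannwhitney": float(p)}
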