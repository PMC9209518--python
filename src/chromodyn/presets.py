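"""Typed presets for the synthetic generators.

All numeric preset values live in one editable registry file
(``chromodyn/data/presets.yaml``); the dataclasses here only validate and
carry them.  Users can load their own registry with :func:`load_registry`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "FrapPreset",
    "DynamicsPreset",
    "NucleusPreset",
    "DropletPlatePreset",
    "FlimPreset",
    "DistSpec",
    "load_registry",
    "frap_preset",
    "dynamics_preset",
    "nucleus_preset",
    "plate_preset",
    "flim_preset",
]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


@dataclass(frozen=True)
class FrapPreset:
    """Generative parameters of a photobleaching-recovery experiment.

    The noiseless post-bleach signal is the one-phase association curve
    ``Y0 + (P - Y0) * (1 - exp(-K t))`` with ``Y0 = bleach_depth`` and
    ``P = Y0 + mobile_fraction * (1 - Y0)``, multiplied by a shared
    monoexponential acquisition-bleaching factor.
    """

    name: str
    pre_bleach_frames: int
    frame_interval_s: float
    n_frames: int
    bleach_depth: float
    mobile_fraction: float
    k_per_s: float
    acq_bleach_per_s: float = 0.0
    noise_sd: float = 0.0
    post_bleach_interval_s: Optional[float] = None

    def __post_init__(self) -> None:
        for f in ("frame_interval_s", "bleach_depth", "mobile_fraction",
                  "k_per_s", "acq_bleach_per_s", "noise_sd"):
            _check(_finite(getattr(self, f)), f"{self.name}: {f} must be finite")
        _check(self.pre_bleach_frames >= 1, "need at least one pre-bleach frame")
        _check(self.n_frames > self.pre_bleach_frames, "need post-bleach frames")
        _check(0.0 <= self.mobile_fraction <= 1.0, "mobile_fraction must be in [0, 1]")
        _check(self.k_per_s > 0, "k_per_s must be positive")
        _check(0.0 <= self.bleach_depth < 1.0, "bleach_depth must be in [0, 1)")
        _check(self.noise_sd >= 0 and self.acq_bleach_per_s >= 0, "noise/bleach rates must be >= 0")

    @property
    def plateau(self) -> float:
        return self.bleach_depth + self.mobile_fraction * (1.0 - self.bleach_depth)


@dataclass(frozen=True)
class DynamicsPreset:
    """Motion and fusion/fission parameters for chromocenter time-lapses."""

    name: str
    n_foci: int
    d_app: float                 # um^2 / s^alpha
    alpha: float
    velocity: float              # um / s
    fusion_rate: float           # events per focus per minute
    fission_rate: float          # events per focus per minute
    frame_interval_s: float
    duration_s: float
    event_engagement_target: float = 0.0

    def __post_init__(self) -> None:
        _check(0.0 < self.alpha <= 2.0, "alpha must be in (0, 2]")
        _check(self.d_app >= 0 and self.velocity >= 0, "d_app/velocity must be >= 0")
        _check(self.fusion_rate >= 0 and self.fission_rate >= 0, "rates must be >= 0")
        _check(self.n_foci >= 1, "need at least one focus")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s)) + 1


@dataclass(frozen=True)
class DistSpec:
    """A tiny truncated-normal spec used for per-nucleus draws."""

    mean: float
    sd: float = 0.0
    min: float = 0.0

    def draw(self, rng, size=None):
        import numpy as np

        x = rng.normal(self.mean, self.sd, size=size)
        return np.maximum(x, self.min)


def _dist(d) -> DistSpec:
    if isinstance(d, DistSpec):
        return d
    if isinstance(d, dict):
        return DistSpec(**d)
    return DistSpec(mean=float(d))


@dataclass(frozen=True)
class NucleusPreset:
    name: str
    image_shape: tuple
    voxel_size_um: float
    nucleus_radius_um: float
    n_chromocenters: DistSpec
    cc_radius_um: DistSpec
    cc_intensity: float
    eu_intensity: float
    background: float
    rna_foci_count: DistSpec
    rna_focus_radius_um: DistSpec
    rna_intensity: float
    rna_class_probs: tuple
    psf_sigma_um: float
    noise_gaussian_sd: float

    def __post_init__(self) -> None:
        _check(abs(sum(self.rna_class_probs) - 1.0) < 1e-9,
               "rna_class_probs must sum to 1")
        _check(all(p >= 0 for p in self.rna_class_probs), "probabilities must be >= 0")
        for f in ("cc_intensity", "eu_intensity", "background", "rna_intensity"):
            _check(getattr(self, f) >= 0, f"{f} must be >= 0")


@dataclass(frozen=True)
class RnaSpecies:
    name: str
    critical_conc_uM: float
    droplet_size_scale_um: float

    def __post_init__(self) -> None:
        _check(self.critical_conc_uM > 0, "critical_conc_uM must be positive (inf = never)")


@dataclass(frozen=True)
class DropletPlatePreset:
    name: str
    protein_concs_uM: tuple
    rna_species: tuple
    field_shape_px: tuple
    pixel_size_um: float
    droplet_count_mean: float
    background: float
    droplet_intensity: float
    noise_gaussian_sd: float

    def __post_init__(self) -> None:
        concs = list(self.protein_concs_uM)
        _check(all(a > b for a, b in zip(concs, concs[1:])),
               "protein_concs_uM must be strictly decreasing")


@dataclass(frozen=True)
class FlimPreset:
    name: str
    tau_het_ns: float
    tau_eu_ns: float
    photons_per_region: int
    rep_period_ns: float = 25.0
    n_bins: int = 256

    def __post_init__(self) -> None:
        _check(self.tau_het_ns > 0 and self.tau_eu_ns > 0, "lifetimes must be positive")


_REGISTRY_CACHE: Optional[dict] = None


def load_registry(path: Optional[Path] = None) -> dict:
    """Load the preset registry (the bundled one unless ``path`` is given)."""
    global _REGISTRY_CACHE
    if path is None:
        if _REGISTRY_CACHE is None:
            text = resources.files("chromodyn.data").joinpath("presets.yaml").read_text()
            _REGISTRY_CACHE = yaml.safe_load(text)
        return _REGISTRY_CACHE
    return yaml.safe_load(Path(path).read_text())


def frap_preset(name: str, registry: Optional[dict] = None) -> FrapPreset:
    reg = registry or load_registry()
    return FrapPreset(name=name, **reg["frap"][name])


def dynamics_preset(name: str, registry: Optional[dict] = None) -> DynamicsPreset:
    reg = registry or load_registry()
    return DynamicsPreset(name=name, **reg["dynamics"][name])


def nucleus_preset(name: str, registry: Optional[dict] = None) -> NucleusPreset:
    reg = registry or load_registry()
    d = dict(reg["nuclei"][name])
    for f in ("n_chromocenters", "cc_radius_um", "rna_foci_count", "rna_focus_radius_um"):
        d[f] = _dist(d[f])
    d["image_shape"] = tuple(d["image_shape"])
    d["rna_class_probs"] = tuple(d["rna_class_probs"])
    return NucleusPreset(name=name, **d)


def plate_preset(name: str, registry: Optional[dict] = None) -> DropletPlatePreset:
    reg = registry or load_registry()
    d = dict(reg["plates"][name])
    d["rna_species"] = tuple(RnaSpecies(**s) for s in d["rna_species"])
    d["protein_concs_uM"] = tuple(float(c) for c in d["protein_concs_uM"])
    d["field_shape_px"] = tuple(d["field_shape_px"])
    return DropletPlatePreset(name=name, **d)


def flim_preset(name: str, registry: Optional[dict] = None) -> FlimPreset:
    reg = registry or load_registry()
    return FlimPreset(name=name, **reg["flim"][name])
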