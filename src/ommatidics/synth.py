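"""Synthetic data generators with known ground truth.

Each generator emulates the structure one analysis stage assumes and emits
its ground truth alongside the data, so every estimator in the package can
be validated without any specimen photographs:

* circular-arc eye profiles (constant curvature) with points at facet-row
  boundaries -- the interommatidial-angle construction is exact on these,
  with truth dphi = pitch / R radians;
* worker morphometry with species-specific intercepts and slopes against
  mesosoma length plus Gaussian residuals -- the linear structure the
  covariate-adjusted comparisons assume;
* brightness patches with truncated Gaussian pixel noise around a target
  brightness;
* subjects x regions facet-diameter tables with additive subject and
  region effects (compound-symmetric by construction) for the
  repeated-measures analysis.

All generators take a seed and are bit-reproducible; child streams are
derived deterministically via :class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import EYE_REGIONS, EyeProfile, PixelPatch, ValidationError

__all__ = [
    "EyeSimSpec",
    "MorphoSimSpec",
    "SpeciesLine",
    "synth_eye_profile",
    "synth_morphometry",
    "synth_patch",
    "synth_regional_D",
]


@dataclass
class EyeSimSpec:
    """Circular eye-profile simulation parameters.

    radius_R and facet_pitch in mm (pitch is the arc length spanned by one
    facet row); span_deg is the requested angular extent; noise_sd is the
    isotropic digitization jitter in mm.  The generated points sit at facet
    boundaries, so the realized span is the largest whole number of facet
    steps inside ``span_deg`` (reported back as ground truth).
    """

    radius_R: float = 0.5
    facet_pitch: float = 0.02
    span_deg: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_R <= 0:
            raise ValidationError("radius_R must be positive")
        if not (0 < self.facet_pitch < self.radius_R):
            raise ValidationError("need 0 < facet_pitch < radius_R")
        if not (0 < self.span_deg <= 180):
            raise ValidationError("span_deg must lie in (0, 180]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def synth_eye_profile(spec: EyeSimSpec):
    """Generate a circular-arc profile and its ground truth.

    Returns ``(EyeProfile, truth)`` with ``truth = {"dphi_deg", "span_deg",
    "radius_R", "center"}``.  The per-facet angle is pitch/R radians; the
    ground-truth span is the realized angular extent of the generated
    boundary points (an integer number of facet steps).
    """
    delta = spec.facet_pitch / spec.radius_R  # per-facet angle, rad
    span_rad = math.radians(spec.span_deg)
    n_steps = int(math.floor(span_rad / delta + 1e-12))
    if n_steps < 4:
        raise ValidationError(
            "facet pitch too coarse: fewer than 5 boundary points fit in the span"
        )
    angles = (np.arange(n_steps + 1) - n_steps / 2.0) * delta
    pts = spec.radius_R * np.column_stack([np.sin(angles), np.cos(angles)])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
    profile = EyeProfile(
        points=pts,
        apex_index=n_steps // 2,
        facet_rows_per_step=2,
        specimen_id=f"synthetic-R{spec.radius_R}-p{spec.facet_pitch}",
    )
    truth = {
        "dphi_deg": math.degrees(delta),
        "span_deg": math.degrees(n_steps * delta),
        "radius_R": spec.radius_R,
        "center": (0.0, 0.0),
    }
    return profile, truth


@dataclass
class SpeciesLine:
    """Generating line for one species: trait = intercept + slope * mesosoma."""

    species_id: str
    eye_area: tuple = (0.02, 0.03)  # (intercept mm^2, slope mm^2/mm)
    facet_count: tuple = (80.0, 80.0)
    facet_diameter_D: tuple = (12.0, 4.0)  # um


@dataclass
class MorphoSimSpec:
    """Worker-morphometry simulation parameters.

    Defaults mirror the focal study's sampling: up to 15 workers per
    species drawn from several colonies, mesosoma lengths spanning roughly
    1-2.3 mm, and residual scatter of the order of the reported standard
    errors.
    """

    species: Sequence[SpeciesLine] = field(default_factory=list)
    n_workers: int = 12
    n_colonies: int = 4
    mesosoma_range: tuple = (1.0, 2.3)
    resid_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "eye_area": 0.005,
            "facet_count": 15.0,
            "facet_diameter_D": 0.8,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValidationError("species list must not be empty")
        if self.n_workers < 2:
            raise ValidationError("need n >= 2 workers per species")
        if self.n_colonies < 1:
            raise ValidationError("need at least 1 colony")
        lo, hi = self.mesosoma_range
        if not (0 < lo < hi):
            raise ValidationError("mesosoma_range must be increasing and positive")
        if any(v < 0 for v in self.resid_sd.values()):
            raise ValidationError("residual SDs must be >= 0")


_TRAITS = ("eye_area", "facet_count", "facet_diameter_D")


def synth_morphometry(spec: MorphoSimSpec) -> pd.DataFrame:
    """Simulate a worker table from per-species linear trait models.

    Mesosoma lengths are uniform on ``mesosoma_range``; each trait is
    intercept + slope * mesosoma + N(0, resid_sd); colonies are assigned
    round-robin.  Returns a tidy DataFrame with one row per worker.
    """
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(len(spec.species))
    rows = []
    lo, hi = spec.mesosoma_range
    for line, ss in zip(spec.species, streams):
        rng = np.random.default_rng(ss)
        meso = rng.uniform(lo, hi, size=spec.n_workers)
        noise = {
            t: rng.normal(0.0, spec.resid_sd.get(t, 0.0), size=spec.n_workers)
            for t in _TRAITS
        }
        for i in range(spec.n_workers):
            row = {
                "species_id": line.species_id,
                "colony_id": f"{line.species_id}-c{i % spec.n_colonies}",
                "mesosoma_length": meso[i],
            }
            for t in _TRAITS:
                a, b = getattr(line, t)
                row[t] = a + b * meso[i] + noise[t][i]
            rows.append(row)
    return pd.DataFrame(rows)


def synth_patch(
    B_true: float, noise_sd: float = 0.0, size: int = 11, seed: int = 0
) -> PixelPatch:
    """Grayscale patch with mean brightness ``B_true`` percent.

    Pixel noise is Gaussian with SD ``noise_sd`` (in brightness percent),
    truncated to the representable [0, 255] range; at the boundaries
    (B_true 0 or 100) all pixels clip to the boundary value.
    """
    if not (0.0 <= B_true <= 100.0):
        raise ValidationError("B_true must lie in [0, 100]")
    if size < 1:
        raise ValidationError("size must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    base = B_true / 100.0 * 255.0
    rng = np.random.default_rng(seed)
    vals = np.full((size, size), base, dtype=float)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd * 255.0 / 100.0, size=vals.shape)
    return PixelPatch(np.clip(vals, 0.0, 255.0))


def synth_regional_D(
    subject_sd: float,
    region_effects: Sequence[float],
    resid_sd: float,
    n_subjects: int,
    seed: int = 0,
    region_names: Sequence[str] = EYE_REGIONS,
) -> pd.DataFrame:
    """Subjects x regions facet diameters with additive effects.

    value = grand + subject intercept (N(0, subject_sd)) + region effect +
    N(0, resid_sd): compound symmetric by construction, so the sphericity
    assumption holds in truth.  Returns a subjects x regions DataFrame.
    """
    region_effects = np.asarray(region_effects, dtype=float)
    if len(region_effects) < 3:
        raise ValidationError("need at least 3 regions")
    if len(region_effects) != len(region_names):
        raise ValidationError("region_effects and region_names length mismatch")
    if n_subjects < 3:
        raise ValidationError("need at least 3 subjects")
    if subject_sd < 0 or resid_sd < 0:
        raise ValidationError("SDs must be >= 0")
    rng = np.random.default_rng(seed)
    grand = 20.0  # um, typical centroid facet diameter
    subj = rng.normal(0.0, subject_sd, size=n_subjects)
    noise = rng.normal(0.0, resid_sd, size=(n_subjects, len(region_effects)))
    vals = grand + subj[:, None] + region_effects[None, :] + noise
    return pd.DataFrame(vals, columns=list(region_names))
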