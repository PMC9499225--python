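"""Domain types shared across the package.

The objects here mirror what is actually measured in a comparative study of
ant compound eyes: digitized eye-edge profiles (ordered 2D points in mm),
small pixel patches used for cuticular-brightness readings, per-worker
morphometrics, species-level summaries, color x activity contingency counts,
and survey rows (brightness + relative eye size) used to screen additional
pale taxa.

Validation is performed eagerly in ``__post_init__`` so that invalid objects
cannot circulate; all errors derive from :class:`OmmatidicsError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "OmmatidicsError",
    "ValidationError",
    "ConfigurationError",
    "DegenerateGeometryError",
    "EstimabilityError",
    "ResourceError",
    "ABSENT",
    "EYE_REGIONS",
    "EyeProfile",
    "PixelPatch",
    "WorkerRecord",
    "SpeciesRecord",
    "ContingencyTable",
    "SurveyRecord",
    "BrightnessResult",
    "OpticsResult",
]


class OmmatidicsError(Exception):
    """Base class for all package errors."""


class ValidationError(OmmatidicsError, ValueError):
    """Input data violates a documented precondition."""


class ConfigurationError(OmmatidicsError, KeyError):
    """An unknown fixture, scheme, or config key was requested."""


class DegenerateGeometryError(OmmatidicsError, ValueError):
    """A geometric construction has no solution (e.g. collinear points)."""


class EstimabilityError(OmmatidicsError, ValueError):
    """A model effect cannot be estimated from the supplied design."""


class ResourceError(OmmatidicsError, RuntimeError):
    """An exact computation would exceed its enumeration guard."""


class _Absent:
    """Sentinel for a biologically absent structure (e.g. no anterior ocellus).

    Distinct from missing data (``None``/NaN): absence is an observed state.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "ABSENT"


ABSENT = _Absent()

#: the five named eye regions used for regional facet-diameter measurements
EYE_REGIONS = ("anterior", "dorsal", "lateral", "posterior", "ventral")


@dataclass
class EyeProfile:
    """Ordered digitization of one eye's profile edge.

    Points run anterior to posterior along the eye edge, in millimetres
    (after applying ``scale_mm_per_unit``).  ``apex_index`` marks the point
    between two facets at the apex of the eye where the interommatidial-angle
    construction is anchored.  Consecutive points are assumed to sit at
    facet-row boundaries, so stepping ``k`` indices along the sequence moves
    ``k`` facet rows along the eye surface.
    """

    points: np.ndarray
    apex_index: int
    facet_rows_per_step: int = 2
    scale_mm_per_unit: float = 1.0
    specimen_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("points must be an (n, 2) array of x, y")
        if len(pts) < 5:
            raise ValidationError(f"need at least 5 points, got {len(pts)}")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("points contain non-finite coordinates")
        if self.scale_mm_per_unit <= 0:
            raise ValidationError("scale_mm_per_unit must be positive")
        if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise ValidationError("consecutive points must be distinct")
        if not (2 <= self.apex_index <= len(pts) - 3):
            raise ValidationError(
                f"apex_index {self.apex_index} needs >= 2 points on each side"
            )
        if self.facet_rows_per_step < 1:
            raise ValidationError("facet_rows_per_step must be >= 1")
        self.points = pts * float(self.scale_mm_per_unit)
        # scale already applied; keep the factor for provenance only
        self.apex_index = int(self.apex_index)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PixelPatch:
    """A small grid of RGB triples or grayscale values in 0-255.

    The brightness protocol samples an 11 x 11 patch, but any non-empty grid
    is accepted (e.g. cropped patches near an eye margin).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:
            pass
        elif v.ndim == 3 and v.shape[2] in (1, 3):
            pass
        else:
            raise ValidationError(
                "values must be HxW (gray) or HxWx3 (RGB), got shape "
                f"{v.shape}"
            )
        if v.size == 0:
            raise ValidationError("patch is empty")
        if not np.all(np.isfinite(v)):
            raise ValidationError("patch contains non-finite values")
        if v.min() < 0 or v.max() > 255:
            raise ValidationError("channel values must lie in [0, 255]")
        self.values = v

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def is_rgb(self) -> bool:
        return self.values.ndim == 3 and self.values.shape[2] == 3


@dataclass
class WorkerRecord:
    """Morphometrics of one worker specimen."""

    species_id: str
    colony_id: str
    mesosoma_length: float  # mm, Weber's length
    eye_area: float  # mm^2
    facet_count: int
    facet_diameter_D: float  # um
    ocellus_diameter: object = None  # um, ABSENT, or None (not measured)
    dphi_deg: float | None = None
    span_deg: float | None = None
    regional_D: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mesosoma_length <= 0:
            raise ValidationError("mesosoma_length must be > 0")
        if self.eye_area < 0:
            raise ValidationError("eye_area must be >= 0")
        if self.facet_count < 0:
            raise ValidationError("facet_count must be >= 0")
        if self.facet_diameter_D < 0:
            raise ValidationError("facet_diameter_D must be >= 0")
        bad = set(self.regional_D) - set(EYE_REGIONS)
        if bad:
            raise ValidationError(f"unknown eye regions: {sorted(bad)}")


@dataclass
class SpeciesRecord:
    """Species-level summary: brightness, classes, raw means and EMMs.

    Raw trait means and estimated marginal means (EMMs, evaluated at the
    genus-level covariate point ``emm_covariate_eval_point``) are stored as
    separate fields and never overloaded.  Species measured only for the
    ocellus carry NaN in the eye-trait fields.
    """

    genus: str
    species: str
    subfamily: str
    brightness_mean: float
    brightness_se: float
    brightness_n: int
    color_class: str  # pale | dark | indeterminate
    activity_class: str  # nocturnal | diurnal | variable
    foraging_raw: str = ""
    eye_area_mean: float = math.nan
    eye_area_se: float = math.nan
    eye_area_emm: float = math.nan
    eye_area_emm_se: float = math.nan
    facet_count_mean: float = math.nan
    facet_count_se: float = math.nan
    facet_count_emm: float = math.nan
    facet_count_emm_se: float = math.nan
    facet_diameter_D_mean: float = math.nan
    facet_diameter_D_se: float = math.nan
    facet_diameter_D_emm: float = math.nan
    facet_diameter_D_emm_se: float = math.nan
    mesosoma_mean: float = math.nan
    mesosoma_se: float = math.nan
    emm_covariate_eval_point: float = math.nan

    def __post_init__(self) -> None:
        if self.color_class not in ("pale", "dark", "indeterminate"):
            raise ValidationError(f"bad color_class {self.color_class!r}")
        if self.activity_class not in ("nocturnal", "diurnal", "variable"):
            raise ValidationError(f"bad activity_class {self.activity_class!r}")
        if not math.isnan(self.emm_covariate_eval_point):
            if self.emm_covariate_eval_point <= 0:
                raise ValidationError("EMM evaluation point must be positive")

    @property
    def label(self) -> str:
        return f"{self.genus} {self.species}"


@dataclass
class ContingencyTable:
    """Nonnegative counts cross-classifying color by activity period."""

    row_labels: Sequence[str]
    col_labels: Sequence[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValidationError("counts must be a 2D array")
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape does not match labels")
        if np.any(c < 0) or not np.all(c == np.round(c)):
            raise ValidationError("counts must be nonnegative integers")
        self.counts = c.astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SurveyRecord:
    """One row of the pale-species survey (candidate or dark reference)."""

    genus: str
    species: str
    brightness_mean: float  # NaN allowed for dark references (B < 70 by rule)
    relative_eye_size: float  # eye area / mesosoma length, mm
    role: str  # candidate | dark_reference
    brightness_n: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("candidate", "dark_reference"):
            raise ValidationError(f"bad survey role {self.role!r}")
        if not self.relative_eye_size > 0:
            raise ValidationError("relative_eye_size must be > 0")


@dataclass
class BrightnessResult:
    """Per-tagma and averaged brightness of one worker, in percent."""

    per_tagma: Mapping[str, float]
    worker_B: float

    def __post_init__(self) -> None:
        for tagma, b in self.per_tagma.items():
            if not (0.0 <= b <= 100.0):
                raise ValidationError(f"{tagma} brightness {b} outside [0, 100]")
        if not (0.0 <= self.worker_B <= 100.0):
            raise ValidationError("worker_B outside [0, 100]")


@dataclass
class OpticsResult:
    """Bundle of the geometric eye measures for one specimen.

    rho = D_um * dphi (radians); facet area = pi/4 * D^2.  Both identities
    hold by construction and are re-asserted here.
    """

    dphi_deg: float
    span_deg: float
    D_um: float
    eye_parameter_rho: float
    facet_area_um2: float
    replicates: Sequence[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        expect_rho = self.D_um * math.radians(self.dphi_deg)
        if abs(expect_rho - self.eye_parameter_rho) > 1e-12 * max(1.0, expect_rho):
            raise ValidationError("rho inconsistent with D * dphi(rad)")
        expect_area = math.pi / 4.0 * self.D_um**2
        if abs(expect_area - self.facet_area_um2) > 1e-12 * max(1.0, expect_area):
            raise ValidationError("facet area inconsistent with pi/4 * D^2")
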