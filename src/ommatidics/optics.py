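"""Geometric estimators for apposition compound eyes.

The central quantity is the interommatidial angle dphi, the angle between
the optical axes of adjacent ommatidia, estimated from a digitized eye-edge
profile by a radius-of-curvature construction: from the point between two
facets at the eye's apex, draw a chord to the point ``rows_per_step`` facet
rows anterior and another to the point the same number of rows posterior.
The perpendicular bisectors of these chords intersect at the local center
of curvature; the angle they enclose there spans ``2 * rows_per_step``
half-facet arcs, so dividing by ``rows_per_step`` recovers the per-facet
angle.  (With the conventional two-row step this is exactly "the angle
between the two perpendicular bisectors divided by two".)  On a circular
profile of radius R with facet pitch D the construction is exact:
dphi = D / R radians.

The visual field span is the angle between the outward eye-surface normals
at the anterior and posterior edges of the profile.  Each edge normal is
taken at the outermost point, directed through the circumcenter of the
three outermost points (the local osculating circle), which is exact for
circular profiles and uses the minimum number of points that determine a
curvature.

Derived quantities follow the standard optics of apposition eyes: the eye
parameter rho = D[um] x dphi[rad] (sensitivity-resolution tradeoff; ~0.3
for diffraction-limited diurnal eyes, >= 2 for nocturnal ones), facet area
pi/4 D^2, and the pale/dark sensitivity fold (D_pale/D_dark)^2.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .model import (
    DegenerateGeometryError,
    EyeProfile,
    OpticsResult,
    ValidationError,
)

__all__ = [
    "interommatidial_angle",
    "replicate_dphi",
    "visual_field_span",
    "eye_parameter",
    "facet_area",
    "sensitivity_fold",
    "diameter_ratio",
    "relative_eye_size",
    "regional_facet_diameter",
    "centroid_facet_diameter",
    "measure_profile",
]

#: bisector directions with normalized cross product below this are parallel
PARALLEL_TOL = 1e-12


def _bisector(p: np.ndarray, q: np.ndarray):
    """Perpendicular bisector of segment pq as (midpoint, direction)."""
    chord = q - p
    norm = np.hypot(*chord)
    if norm == 0.0:
        raise DegenerateGeometryError("repeated construction point")
    normal = np.array([-chord[1], chord[0]]) / norm
    return (p + q) / 2.0, normal


def _intersect(m1, d1, m2, d2) -> np.ndarray:
    """Intersection of lines m1 + t*d1 and m2 + s*d2."""
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(cross) < PARALLEL_TOL:
        raise DegenerateGeometryError(
            "perpendicular bisectors are parallel (collinear construction "
            "points / zero curvature)"
        )
    rhs = m2 - m1
    t = (rhs[0] * d2[1] - rhs[1] * d2[0]) / cross
    return m1 + t * d1


def interommatidial_angle(
    profile: EyeProfile,
    apex_index: int | None = None,
    rows_per_step: int | None = None,
) -> float:
    """Estimate the per-facet interommatidial angle, in degrees.

    ``apex_index`` and ``rows_per_step`` default to the profile's own
    values.  The estimate is exactly invariant under translation, rotation,
    and uniform scaling of the digitized coordinates.
    """
    pts = profile.points
    apex = profile.apex_index if apex_index is None else int(apex_index)
    k = profile.facet_rows_per_step if rows_per_step is None else int(rows_per_step)
    if k < 1:
        raise ValidationError("rows_per_step must be >= 1")
    if apex - k < 0 or apex + k >= len(pts):
        raise ValidationError(
            f"apex index {apex} is closer than {k} points to a profile end"
        )
    a, p_ant, p_post = pts[apex], pts[apex - k], pts[apex + k]
    m1, d1 = _bisector(a, p_ant)
    m2, d2 = _bisector(a, p_post)
    center = _intersect(m1, d1, m2, d2)
    v1, v2 = m1 - center, m2 - center
    n1, n2 = np.hypot(*v1), np.hypot(*v2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError("chord midpoint coincides with center")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    bisector_angle = math.acos(cosang)
    return math.degrees(bisector_angle / k)


def replicate_dphi(
    profile: EyeProfile,
    apex_indices: Sequence[int],
    rows_per_step: int | None = None,
) -> dict:
    """Average the interommatidial angle over replicate apex choices.

    The field protocol repeats the construction three times in the same eye
    region; any number >= 1 of replicates is accepted here.  Returns
    ``{"mean_deg", "replicates_deg"}``; a degenerate replicate raises with
    its index named.
    """
    if len(apex_indices) == 0:
        raise ValidationError("need at least one apex index")
    values = []
    for i, apex in enumerate(apex_indices):
        try:
            values.append(interommatidial_angle(profile, apex, rows_per_step))
        except (DegenerateGeometryError, ValidationError) as exc:
            raise type(exc)(f"replicate {i} (apex index {apex}): {exc}") from exc
    return {"mean_deg": float(np.mean(values)), "replicates_deg": values}


def _edge_normal(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Normal direction at the edge point p0 of the arc through p0, p1, p2.

    Direction from the circumcenter of the three points toward p0; exact for
    points on a circle.
    """
    m1, d1 = _bisector(p0, p1)
    m2, d2 = _bisector(p1, p2)
    center = _intersect(m1, d1, m2, d2)
    v = p0 - center
    n = np.hypot(*v)
    if n == 0.0:
        raise DegenerateGeometryError("edge point coincides with center")
    return v / n


def visual_field_span(profile: EyeProfile) -> float:
    """Angular span of the visual field along the anterior-posterior axis.

    The angle, in (0, 180] degrees, between the outward surface normals at
    the two ends of the profile.  Invariant under rigid motions and uniform
    scaling.
    """
    pts = profile.points
    n_ant = _edge_normal(pts[0], pts[1], pts[2])
    n_post = _edge_normal(pts[-1], pts[-2], pts[-3])
    cosang = float(np.clip(np.dot(n_ant, n_post), -1.0, 1.0))
    span = math.degrees(math.acos(cosang))
    if span == 0.0:
        raise DegenerateGeometryError("edge normals coincide; zero span")
    return span


def eye_parameter(D_um: float, dphi_deg: float) -> float:
    """Eye parameter rho = D[um] x dphi[rad], in um rad."""
    if D_um <= 0 or dphi_deg <= 0:
        raise ValidationError("D_um and dphi_deg must be positive")
    return D_um * math.radians(dphi_deg)


def facet_area(D_um: float) -> float:
    """Facet (lens) area pi/4 x D^2, in um^2."""
    if D_um < 0:
        raise ValidationError("D must be >= 0")
    return math.pi / 4.0 * D_um**2


def sensitivity_fold(D_num: float, D_den: float) -> float:
    """Facet-area fold [pi/4 D_num^2] / [pi/4 D_den^2] = (D_num/D_den)^2."""
    if D_num <= 0 or D_den <= 0:
        raise ValidationError("facet diameters must be positive")
    return (D_num / D_den) ** 2


def diameter_ratio(D_num: float, D_den: float) -> float:
    """Plain facet-diameter ratio D_num / D_den."""
    if D_num <= 0 or D_den <= 0:
        raise ValidationError("facet diameters must be positive")
    return D_num / D_den


def relative_eye_size(eye_area_mm2: float, mesosoma_mm: float) -> float:
    """Relative eye size = eye area / mesosoma length, in mm."""
    if mesosoma_mm <= 0:
        raise ValidationError("mesosoma length must be positive")
    if eye_area_mm2 < 0:
        raise ValidationError("eye area must be >= 0")
    return eye_area_mm2 / mesosoma_mm


def regional_facet_diameter(
    three_facet_total: float, scale_um_per_unit: float = 1.0
) -> float:
    """Mean regional D from the length of three facets in a row.

    ``three_facet_total`` is the measured total length; ``scale_um_per_unit``
    converts the measurement units to um (e.g. 1000 for a total in mm).
    """
    if three_facet_total <= 0:
        raise ValidationError("three-facet total must be positive")
    if scale_um_per_unit <= 0:
        raise ValidationError("scale must be positive")
    return three_facet_total / 3.0 * scale_um_per_unit


def centroid_facet_diameter(adjoining_diameters_um: Sequence[float]) -> float:
    """Mean of the four adjoining facet diameters at the eye centroid."""
    vals = np.asarray(adjoining_diameters_um, dtype=float)
    if vals.shape != (4,):
        raise ValidationError(f"need exactly 4 diameters, got {vals.shape}")
    if np.any(vals <= 0):
        raise ValidationError("facet diameters must be positive")
    return float(vals.mean())


def measure_profile(
    profile: EyeProfile,
    D_um: float,
    apex_indices: Sequence[int] | None = None,
) -> OpticsResult:
    """Full optics report for one digitized profile.

    ``apex_indices`` defaults to the single profile apex; with several
    indices the replicate mean is used, mirroring the triplicate protocol.
    """
    if apex_indices is None:
        apex_indices = [profile.apex_index]
    rep = replicate_dphi(profile, apex_indices)
    dphi = rep["mean_deg"]
    return OpticsResult(
        dphi_deg=dphi,
        span_deg=visual_field_span(profile),
        D_um=D_um,
        eye_parameter_rho=eye_parameter(D_um, dphi),
        facet_area_um2=facet_area(D_um),
        replicates=rep["replicates_deg"],
    )
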