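"""Radiographic deformity measures from 2-D landmark coordinates.

All measures are computed from named landmark points (millimetres) placed on
two standard views:

* **coronal** -- a full-length weight-bearing (long-leg) radiograph: femoral
  head centre, knee centre, ankle centre, the medial/lateral edges of the
  tibial plateau and the medial/lateral femoral condylar tangent points.
* **sagittal** -- a true lateral knee radiograph: two points on the medial
  plateau tangent and two on the posterior tibial cortex.

Coordinate convention: x increases toward lateral on the coronal view and
toward anterior on the sagittal view; y increases toward proximal.  Every
measure is a ratio of distances or an angle between lines, so all outputs are
invariant under translation, rotation and uniform scaling of the landmarks.

Measures
--------
``wbl_percent``
    The weight-bearing line (femoral head centre -> ankle centre) crossing of
    the tibial plateau, as a percentage of medial-to-lateral plateau width
    (medial edge = 0 %, lateral edge = 100 %).  Values outside [0, 100] are
    reported as-is; they indicate the mechanical axis passes outside the
    plateau.
``mpta`` / ``mldfa``
    Medial proximal tibial angle and mechanical lateral distal femoral angle.
    MPTA is the medial-side angle between the tibial mechanical axis (knee
    centre -> ankle centre) and the plateau line; varus knees measure < 90
    degrees.
``jlca``
    Joint-line convergence angle between the femoral condylar tangent and the
    tibial plateau line; unsigned magnitude by default.
``pts_brazier``
    Posterior tibial slope: angle between the medial plateau tangent and the
    perpendicular to the posterior tibial cortex, positive when the plateau
    drops posteriorly.

Planning
--------
``correction_rotation_deg`` / ``miniaci_correction_angle`` implement the
weight-bearing-line planning rule: rotate the ankle centre about a hinge
point near the lateral cortex until the weight-bearing line crosses the
plateau at the target coordinate (default 62.5 %).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import (
    DegenerateGeometryError,
    InvalidLandmarksError,
    PlanningInfeasibleError,
)

__all__ = [
    "CORONAL_LANDMARKS",
    "SAGITTAL_LANDMARKS",
    "LandmarkSet",
    "DeformityMeasures",
    "CorrectionTarget",
    "wbl_percent",
    "mpta",
    "mldfa",
    "jlca",
    "pts_brazier",
    "measure_coronal",
    "measure_all",
    "default_hinge",
    "correction_rotation_deg",
    "miniaci_correction_angle",
    "apply_correction",
    "rotate_point",
]

CORONAL_LANDMARKS = frozenset(
    {
        "femoral_head_center",
        "knee_center",
        "ankle_center",
        "plateau_medial_edge",
        "plateau_lateral_edge",
        "femoral_condyle_medial",
        "femoral_condyle_lateral",
    }
)
SAGITTAL_LANDMARKS = frozenset(
    {
        "plateau_tangent_anterior",
        "plateau_tangent_posterior",
        "posterior_cortex_proximal",
        "posterior_cortex_distal",
    }
)
_REQUIRED = {"coronal": CORONAL_LANDMARKS, "sagittal": SAGITTAL_LANDMARKS}

# landmark pairs that must be distinct for the view's measures to exist
_DISTINCT_PAIRS = {
    "coronal": (
        ("plateau_medial_edge", "plateau_lateral_edge"),
        ("femoral_condyle_medial", "femoral_condyle_lateral"),
        ("knee_center", "ankle_center"),
        ("femoral_head_center", "knee_center"),
    ),
    "sagittal": (
        ("posterior_cortex_proximal", "posterior_cortex_distal"),
        ("plateau_tangent_anterior", "plateau_tangent_posterior"),
    ),
}


@dataclass(frozen=True)
class LandmarkSet:
    """Named 2-D points (mm) of one radiographic view."""

    view: str
    points: Mapping[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        if self.view not in _REQUIRED:
            raise InvalidLandmarksError(
                f"unknown view {self.view!r}; expected 'coronal' or 'sagittal'"
            )
        pts = {k: (float(v[0]), float(v[1])) for k, v in dict(self.points).items()}
        missing = sorted(_REQUIRED[self.view] - pts.keys())
        if missing:
            raise InvalidLandmarksError(
                f"missing required {self.view} landmarks: {', '.join(missing)}"
            )
        for name, (x, y) in pts.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise InvalidLandmarksError(f"non-finite coordinate for {name!r}")
        for a, b in _DISTINCT_PAIRS[self.view]:
            if pts[a] == pts[b]:
                raise InvalidLandmarksError(f"landmarks {a!r} and {b!r} coincide")
        object.__setattr__(self, "points", pts)

    def p(self, name: str) -> np.ndarray:
        """Return landmark ``name`` as a length-2 array."""
        try:
            return np.asarray(self.points[name], dtype=float)
        except KeyError:
            raise InvalidLandmarksError(f"landmark {name!r} not present") from None

    def replace_point(self, name: str, xy: Iterable[float]) -> "LandmarkSet":
        pts = dict(self.points)
        x, y = xy
        pts[name] = (float(x), float(y))
        return LandmarkSet(self.view, pts)

    def transformed(
        self,
        rotation_deg: float = 0.0,
        translation: Tuple[float, float] = (0.0, 0.0),
        scale: float = 1.0,
    ) -> "LandmarkSet":
        """Apply a global similarity transform (rotation, translation, scale)."""
        a = math.radians(rotation_deg)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        t = np.asarray(translation, dtype=float)
        pts = {
            k: tuple(scale * (R @ np.asarray(v)) + t) for k, v in self.points.items()
        }
        return LandmarkSet(self.view, pts)


@dataclass(frozen=True)
class DeformityMeasures:
    """All coronal/sagittal deformity measures of one knee at one timepoint."""

    wbl_percent: float
    mpta: float
    mldfa: float
    jlca: float
    pts: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "wbl_percent": self.wbl_percent,
            "mpta": self.mpta,
            "mldfa": self.mldfa,
            "jlca": self.jlca,
            "pts": self.pts,
        }


@dataclass(frozen=True)
class CorrectionTarget:
    """Planning target: WBL crossing coordinate and valgus band."""

    target_wbl_percent: float = 62.5
    valgus_band_deg: Tuple[float, float] = (3.0, 5.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.target_wbl_percent < 100.0:
            raise ValueError("target WBL percent must lie strictly inside (0, 100)")
        lo, hi = self.valgus_band_deg
        if lo > hi:
            raise ValueError("valgus band lower bound exceeds upper bound")


def _cross(u: np.ndarray, v: np.ndarray) -> float:
    return float(u[0] * v[1] - u[1] * v[0])


def _angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    if np.linalg.norm(u) == 0.0 or np.linalg.norm(v) == 0.0:
        raise InvalidLandmarksError("zero-length direction")
    # atan2 form: well conditioned near 0 and 180 degrees
    return math.degrees(math.atan2(abs(_cross(u, v)), float(np.dot(u, v))))


def _require_view(lms: LandmarkSet, view: str) -> None:
    if lms.view != view:
        raise InvalidLandmarksError(f"expected a {view} landmark set, got {lms.view!r}")


def wbl_percent(coronal: LandmarkSet) -> float:
    """Weight-bearing-line crossing of the plateau, percent medial->lateral.

    Intersects the line femoral_head_center -> ankle_center with the infinite
    line through the plateau edges and parameterises it from the medial edge
    (0 %) to the lateral edge (100 %).  Not clamped: crossings outside the
    plateau report < 0 or > 100.
    """
    _require_view(coronal, "coronal")
    m = coronal.p("plateau_medial_edge")
    l = coronal.p("plateau_lateral_edge")
    d = l - m
    if np.linalg.norm(d) < 1e-12:
        raise InvalidLandmarksError("plateau edges coincide")
    h = coronal.p("femoral_head_center")
    a = coronal.p("ankle_center")
    w = a - h
    denom = _cross(d, w)
    if abs(denom) <= 1e-12 * np.linalg.norm(d) * np.linalg.norm(w):
        raise DegenerateGeometryError("weight-bearing line parallel to plateau line")
    s = _cross(h - m, w) / denom
    return 100.0 * s


def mpta(coronal: LandmarkSet) -> float:
    """Medial proximal tibial angle in degrees.

    Angle between the distal-pointing tibial mechanical axis (knee centre ->
    ankle centre) and the medial-pointing plateau direction.  90 when the
    axis is perpendicular to the plateau; varus knees (medial plateau edge
    distal) measure below 90.
    """
    _require_view(coronal, "coronal")
    axis = coronal.p("ankle_center") - coronal.p("knee_center")
    med = coronal.p("plateau_medial_edge") - coronal.p("plateau_lateral_edge")
    return _angle_between_deg(axis, med)


def mldfa(coronal: LandmarkSet) -> float:
    """Mechanical lateral distal femoral angle in degrees.

    Lateral-side angle between the femoral mechanical axis (head -> knee,
    measured toward proximal) and the condylar tangent; the femoral mirror of
    :func:`mpta`.
    """
    _require_view(coronal, "coronal")
    axis = coronal.p("femoral_head_center") - coronal.p("knee_center")
    lat = coronal.p("femoral_condyle_lateral") - coronal.p("femoral_condyle_medial")
    return _angle_between_deg(axis, lat)


def jlca(coronal: LandmarkSet, signed: bool = False) -> float:
    """Joint-line convergence angle in degrees.

    Angle between the femoral condylar tangent and the tibial plateau line.
    Unsigned magnitude (the convention radiographic reports use) unless
    ``signed=True``, in which case the angle is positive when the two lines
    converge toward the medial side.
    """
    _require_view(coronal, "coronal")
    m = coronal.p("plateau_medial_edge")
    l = coronal.p("plateau_lateral_edge")
    fm = coronal.p("femoral_condyle_medial")
    fl = coronal.p("femoral_condyle_lateral")
    dt = l - m
    df = fl - fm
    if np.linalg.norm(dt) < 1e-12 or np.linalg.norm(df) < 1e-12:
        raise InvalidLandmarksError("degenerate joint-line tangent")
    ang = _angle_between_deg(dt, df)
    ang = min(ang, 180.0 - ang)  # angle between undirected lines
    if not signed:
        return ang
    if ang == 0.0:
        return 0.0
    # intersection of the two lines; medial if it lies on the medial side of
    # the plateau midpoint along the medial direction
    denom = _cross(dt, df)
    t = _cross(fm - m, df) / denom
    inter = m + t * dt
    centre = 0.5 * (m + l)
    medial_dir = m - l
    return ang if float(np.dot(inter - centre, medial_dir)) > 0.0 else -ang


def pts_brazier(sagittal: LandmarkSet) -> float:
    """Posterior tibial slope in degrees (Brazier construction).

    Angle between the medial plateau tangent and the perpendicular to the
    posterior tibial cortex; positive when the plateau drops posteriorly.
    """
    _require_view(sagittal, "sagittal")
    c = sagittal.p("posterior_cortex_proximal") - sagittal.p("posterior_cortex_distal")
    if np.linalg.norm(c) < 1e-12:
        raise InvalidLandmarksError("degenerate posterior cortex line")
    # perpendicular to the cortex, pointing anterior when the cortex points
    # proximal (x anterior, y proximal)
    perp = np.array([c[1], -c[0]])
    t = sagittal.p("plateau_tangent_anterior") - sagittal.p("plateau_tangent_posterior")
    if np.linalg.norm(t) < 1e-12:
        raise InvalidLandmarksError("degenerate plateau tangent")
    ang = math.degrees(
        math.atan2(_cross(perp, t), float(np.dot(perp, t)))
    )
    # slope is an acute line-vs-line angle
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return ang


def measure_coronal(coronal: LandmarkSet) -> Dict[str, float]:
    return {
        "wbl_percent": wbl_percent(coronal),
        "mpta": mpta(coronal),
        "mldfa": mldfa(coronal),
        "jlca": jlca(coronal),
    }


def measure_all(coronal: LandmarkSet, sagittal: LandmarkSet) -> DeformityMeasures:
    """Compute every deformity measure for one knee."""
    c = measure_coronal(coronal)
    return DeformityMeasures(pts=pts_brazier(sagittal), **c)


def rotate_point(pt: np.ndarray, centre: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate ``pt`` about ``centre`` by ``angle_deg`` (counter-clockwise)."""
    a = math.radians(angle_deg)
    R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    return centre + R @ (np.asarray(pt, dtype=float) - centre)


def default_hinge(
    coronal: LandmarkSet, medial_offset_mm: float = 10.0, distal_offset_mm: float = 15.0
) -> np.ndarray:
    """Default osteotomy hinge: just medial and distal to the lateral plateau edge.

    The offsets are taken along the landmark-defined medial and distal
    directions, so the hinge transforms with the landmarks (planning is then
    frame-invariant).
    """
    lat = coronal.p("plateau_lateral_edge")
    med_dir = coronal.p("plateau_medial_edge") - lat
    med_dir = med_dir / np.linalg.norm(med_dir)
    dist_dir = coronal.p("ankle_center") - coronal.p("knee_center")
    dist_dir = dist_dir / np.linalg.norm(dist_dir)
    return lat + medial_offset_mm * med_dir + distal_offset_mm * dist_dir


def apply_correction(
    coronal: LandmarkSet, hinge: np.ndarray, rotation_deg: float
) -> LandmarkSet:
    """Rotate the distal fragment (ankle centre) about the hinge."""
    new_ankle = rotate_point(coronal.p("ankle_center"), np.asarray(hinge, float), rotation_deg)
    return coronal.replace_point("ankle_center", new_ankle)


def correction_rotation_deg(
    coronal: LandmarkSet,
    hinge: np.ndarray | None = None,
    target: CorrectionTarget | float = CorrectionTarget(),
    max_angle_deg: float = 45.0,
) -> float:
    """Signed rotation (degrees, counter-clockwise positive) of the ankle
    centre about ``hinge`` that places the weight-bearing line at the target
    plateau coordinate.

    The magnitude is the planned correction angle; the sign encodes the
    valgus sense for this particular limb (mirrored deformities yield the
    opposite sign).  Raises :class:`PlanningInfeasibleError` when no rotation
    below ``max_angle_deg`` reaches the target.
    """
    if isinstance(target, CorrectionTarget):
        target_pct = target.target_wbl_percent
    else:
        target_pct = float(target)
    if hinge is None:
        hinge = default_hinge(coronal)
    hinge = np.asarray(hinge, dtype=float)
    if np.allclose(hinge, coronal.p("ankle_center")):
        raise PlanningInfeasibleError("hinge coincides with the ankle centre")

    def wbl_at(beta: float) -> float:
        return wbl_percent(apply_correction(coronal, hinge, beta))

    need = target_pct - wbl_at(0.0)
    if abs(need) < 1e-12:
        return 0.0
    # valgus sense: the rotation direction that moves the WBL toward target
    eps = 1e-4
    slope = (wbl_at(eps) - wbl_at(-eps)) / (2 * eps)
    if slope == 0.0:
        raise PlanningInfeasibleError("WBL insensitive to rotation about this hinge")
    sense = 1.0 if (need > 0) == (slope > 0) else -1.0

    def f(beta: float) -> float:
        return wbl_at(sense * beta) - target_pct

    f0, f1 = f(0.0), f(max_angle_deg)
    if f0 == 0.0:
        return 0.0
    if f0 * f1 > 0:
        raise PlanningInfeasibleError(
            f"no rotation below {max_angle_deg} deg reaches WBL {target_pct}%"
        )
    beta = brentq(f, 0.0, max_angle_deg, xtol=1e-10, rtol=1e-14)
    return sense * beta


def miniaci_correction_angle(
    coronal: LandmarkSet,
    hinge: np.ndarray | None = None,
    target: CorrectionTarget | float = CorrectionTarget(),
    max_angle_deg: float = 45.0,
) -> float:
    """Planned coronal correction angle (degrees, >= 0).

    Smallest rotation of the distal fragment about the hinge, in the valgus
    sense of the limb, that places the weight-bearing line at the target.
    Re-measuring :func:`wbl_percent` after applying the returned rotation
    reproduces the target to well below 0.1 percentage points.
    """
    return abs(correction_rotation_deg(coronal, hinge, target, max_angle_deg))
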