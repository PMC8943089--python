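"""The Noyes 3-triangle gap method and a 3-D wedge-rotation model.

The intraoperative problem: open a medial wedge osteotomy so that the
coronal correction equals the planned valgus angle theta while the posterior
tibial slope is untouched.  The 3-triangle scheme prescribes two vertical gap
heights along the medial osteotomy side:

* ``Y1 = X1 * tan(theta)`` at the most posteromedial point, where ``X1`` is
  the coronal tibial width at that point;
* ``Y2 = Y1 * X2 / X1`` at a second point a distance ``L`` more anterior
  along the anteromedial cortex (which makes an angle ``alpha`` with the
  coronal plane), where ``X2 = X1 - L*cos(alpha)`` is the tibial width at the
  second point.

Because the two gaps are proportional to the distance of each point from the
lateral hinge, the opening is a pure valgus rotation about an
anteroposterior hinge axis and the slope is preserved.  Opening *equal* gaps
at the two points instead tilts the hinge axis and increases the slope.

``fit_wedge``/``slope_change`` make that statement quantitative: given
measured gaps at known points on the osteotomy plane they recover the rigid
opening (hinge-axis direction + opening angle) and decompose it into its
coronal (valgus) and sagittal (slope) components.

Wedge coordinate frame: x anterior, y medial (toward the opening), z
proximal (the gap direction); the hinge lies at the lateral cortex.  A wedge
opened by angle ``w`` about an in-plane axis separates the cut surfaces at a
station at in-plane distance ``s`` from the axis by ``s * tan(w)`` measured
perpendicular to the uncut plane -- the same convention as ``Y = X*tan(theta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import geometry
from .errors import (
    FitDegenerateError,
    GeometryInconsistentError,
    InconsistentRowError,
    OutOfModelError,
)

__all__ = [
    "TriangleInputs",
    "GapPlan",
    "WedgeModel",
    "OsteotomyPlan",
    "gap_posteromedial",
    "gap_anteromedial",
    "implied_alpha",
    "round_half_mm",
    "noyes_measurement_points",
    "noyes_gap_profile",
    "equal_gap_profile",
    "fit_wedge",
    "slope_change",
    "coronal_change",
    "plan_osteotomy",
    "load_table2",
    "audit_table2",
]

AP = np.array([1.0, 0.0, 0.0])  # anterior
ML = np.array([0.0, 1.0, 0.0])  # medial (toward the opening side)
UP = np.array([0.0, 0.0, 1.0])  # proximal / gap direction


@dataclass(frozen=True)
class TriangleInputs:
    """Intraoperative measurements feeding the gap formulas (mm / degrees).

    ``x1``: coronal tibial width at the posteromedial measurement point;
    ``l``: distance between the two gap-measurement points along the medial
    osteotomy side; ``alpha``: angle of the anteromedial tibial cortex
    against the coronal plane (default 45); ``theta``: planned coronal valgus
    correction angle.
    """

    x1: float
    theta: float
    l: float = 0.0
    alpha: float = 45.0

    def __post_init__(self) -> None:
        if not self.x1 > 0:
            raise OutOfModelError("tibial width x1 must be positive")
        if self.l < 0:
            raise OutOfModelError("inter-point distance l cannot be negative")
        if not 0.0 < self.alpha <= 90.0:
            raise OutOfModelError("cortex angle alpha must lie in (0, 90] degrees")
        if not 0.0 <= self.theta < 45.0:
            raise OutOfModelError("correction angle theta must lie in [0, 45) degrees")
        if self.x2 <= 0:
            raise GeometryInconsistentError(
                "anterior measurement point lies beyond the hinge (x2 <= 0)"
            )

    @property
    def x2(self) -> float:
        """Coronal tibial width at the anteromedial measurement point."""
        return self.x1 - self.l * math.cos(math.radians(self.alpha))


def round_half_mm(value: float) -> float:
    """Round a gap to the intraoperative 0.5 mm grid."""
    return round(value * 2.0) / 2.0


@dataclass(frozen=True)
class GapPlan:
    """Raw and 0.5 mm-rounded vertical gap heights (mm)."""

    y1: float
    y2: float

    @property
    def y1_rounded(self) -> float:
        return round_half_mm(self.y1)

    @property
    def y2_rounded(self) -> float:
        return round_half_mm(self.y2)


def gap_posteromedial(inputs: TriangleInputs) -> float:
    """Vertical gap Y1 at the posteromedial cortex: ``X1 * tan(theta)``."""
    return inputs.x1 * math.tan(math.radians(inputs.theta))


def gap_anteromedial(inputs: TriangleInputs, y1: float) -> float:
    """Vertical gap Y2 at the anteromedial point: ``Y1 * X2 / X1``.

    Similar triangles: both gaps are proportional to the distance of their
    measurement point from the lateral hinge, so Y2/Y1 = X2/X1.  Equals Y1
    when ``l == 0`` or ``alpha == 90``.
    """
    if y1 < 0:
        raise OutOfModelError("y1 cannot be negative")
    x2 = inputs.x2
    if x2 <= 0:
        raise GeometryInconsistentError(
            "anterior measurement point lies beyond the hinge (x2 <= 0)"
        )
    return y1 * x2 / inputs.x1


def implied_alpha(y1: float, y2: float, x1: float, l: float) -> float:
    """Cortex angle alpha (degrees) implied by a printed (Y1, Y2) pair.

    Inverts the Y2 formula: ``cos(alpha) = X1*(1 - Y2/Y1) / L``.  Raises
    :class:`InconsistentRowError` when the implied cosine falls outside
    [0, 1), i.e. when no admissible cortex angle can produce the pair.
    """
    if y1 <= 0 or l <= 0:
        raise OutOfModelError("implied_alpha requires y1 > 0 and l > 0")
    if y2 <= 0:
        raise OutOfModelError("implied_alpha requires y2 > 0")
    c = x1 * (1.0 - y2 / y1) / l
    if not 0.0 <= c < 1.0:
        raise InconsistentRowError(
            f"implied cos(alpha) = {c:.4f} outside [0, 1); "
            "gap pair inconsistent with the similar-triangles model"
        )
    return math.degrees(math.acos(c))


# ---------------------------------------------------------------------------
# wedge-rotation model


@dataclass(frozen=True)
class WedgeModel:
    """A rigid wedge opening on the osteotomy plane (z = 0).

    ``axis_direction`` is a unit vector in the plane; the distal fragment is
    fixed and the proximal fragment is rotated by ``opening_angle_deg`` about
    the axis through ``hinge_point``.  The gap at the hinge is zero.
    """

    hinge_point: np.ndarray
    axis_direction: np.ndarray
    opening_angle_deg: float
    measurement_points: Tuple[Tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        h = np.asarray(self.hinge_point, dtype=float).reshape(3)
        u = np.asarray(self.axis_direction, dtype=float).reshape(3)
        n = np.linalg.norm(u)
        if n == 0.0:
            raise FitDegenerateError("axis direction cannot be the zero vector")
        if self.opening_angle_deg < 0:
            raise OutOfModelError("opening angle cannot be negative")
        object.__setattr__(self, "hinge_point", h)
        object.__setattr__(self, "axis_direction", u / n)

    def signed_distance(self, point: Sequence[float]) -> float:
        """In-plane signed distance of ``point`` from the hinge axis.

        Positive on the side where the wedge opens upward.
        """
        d = np.asarray(point, dtype=float) - self.hinge_point
        u = self.axis_direction
        return float(u[0] * d[1] - u[1] * d[0])

    def gap_at(self, point: Sequence[float]) -> float:
        """Vertical gap (mm) the opening produces at ``point``."""
        return math.tan(math.radians(self.opening_angle_deg)) * self.signed_distance(
            point
        )

    def rotation_matrix(self) -> np.ndarray:
        """Exact rotation applied to the proximal fragment (Rodrigues)."""
        w = math.radians(self.opening_angle_deg)
        u = self.axis_direction
        K = np.array(
            [[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]], dtype=float
        )
        return np.eye(3) + math.sin(w) * K + (1 - math.cos(w)) * (K @ K)


def noyes_measurement_points(
    x1: float, l: float, alpha: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Canonical 3-D positions of the two gap-measurement points.

    Hinge at the origin; the posteromedial point sits at medial distance
    ``x1``; the anteromedial point lies ``l`` further along the anteromedial
    cortex (angle ``alpha`` to the coronal plane), hence ``l*sin(alpha)``
    more anterior and ``l*cos(alpha)`` less medial.
    """
    a = math.radians(alpha)
    p1 = np.array([0.0, float(x1), 0.0])
    p2 = p1 + l * np.array([math.sin(a), -math.cos(a), 0.0])
    return p1, p2


def noyes_gap_profile(
    inputs: TriangleInputs,
) -> List[Tuple[np.ndarray, float]]:
    """(point, gap) pairs prescribed by the 3-triangle method."""
    y1 = gap_posteromedial(inputs)
    y2 = gap_anteromedial(inputs, y1)
    p1, p2 = noyes_measurement_points(inputs.x1, inputs.l, inputs.alpha)
    return [(p1, y1), (p2, y2)]


def equal_gap_profile(
    inputs: TriangleInputs, gap: float | None = None
) -> List[Tuple[np.ndarray, float]]:
    """The same two points opened by one common gap (the failure mode).

    Defaults to the posteromedial gap of the correct plan, i.e. the surgeon
    opens Y1 everywhere.
    """
    if gap is None:
        gap = gap_posteromedial(inputs)
    p1, p2 = noyes_measurement_points(inputs.x1, inputs.l, inputs.alpha)
    return [(p1, float(gap)), (p2, float(gap))]


def fit_wedge(
    points_and_gaps: Sequence[Tuple[Sequence[float], float]],
    hinge_point: Sequence[float],
) -> WedgeModel:
    """Recover the rigid opening from measured gaps.

    Solves ``gap_i = tan(w) * (u x (p_i - h)) . z`` for the in-plane axis
    direction ``u`` and opening angle ``w`` (least squares when more than two
    measurements are given).  All points must lie on the osteotomy plane
    z = 0 of the hinge.
    """
    h = np.asarray(hinge_point, dtype=float).reshape(3)
    pts = [np.asarray(p, dtype=float).reshape(3) for p, _ in points_and_gaps]
    gaps = np.array([float(g) for _, g in points_and_gaps])
    if len(pts) < 2:
        raise FitDegenerateError("need at least two measurement points")
    if np.any(gaps < 0):
        raise OutOfModelError("gaps cannot be negative")
    D = np.array([p - h for p in pts])
    if np.allclose(gaps, 0.0):
        return WedgeModel(h, AP, 0.0, tuple(map(tuple, pts)))
    # gap_i = a*dy_i - b*dx_i with (a, b) = tan(w) * (ux, uy)
    A = np.column_stack([D[:, 1], -D[:, 0]])
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, float(np.abs(A).max()))) < 2:
        raise FitDegenerateError(
            "measurement points collinear with the hinge; axis not identifiable"
        )
    coef, *_ = np.linalg.lstsq(A, gaps, rcond=None)
    t = float(np.hypot(coef[0], coef[1]))
    u = np.array([coef[0] / t, coef[1] / t, 0.0])
    opening = math.degrees(math.atan(t))
    return WedgeModel(h, u, opening, tuple(map(tuple, pts)))


def slope_change(
    model: WedgeModel, sagittal_reference: Sequence[float] = AP
) -> float:
    """Posterior-tibial-slope change (degrees) produced by the opening.

    Rotates the plateau's anteroposterior tangent (``sagittal_reference``,
    anterior-pointing) with the proximal fragment and reports its elevation:
    positive when the anterior end rises, i.e. the plateau drops posteriorly
    and the slope increases.  Zero for an anteroposterior hinge axis.
    """
    t = model.rotation_matrix() @ (
        np.asarray(sagittal_reference, dtype=float)
        / np.linalg.norm(sagittal_reference)
    )
    return math.degrees(math.asin(max(-1.0, min(1.0, float(t[2])))))


def coronal_change(model: WedgeModel) -> float:
    """Coronal (valgus) correction angle (degrees) produced by the opening.

    Elevation gained by the medial-pointing plateau direction; positive =
    valgus (medial side opens upward).
    """
    t = model.rotation_matrix() @ ML
    return math.degrees(math.asin(max(-1.0, min(1.0, float(t[2])))))


# ---------------------------------------------------------------------------
# end-to-end plan


@dataclass(frozen=True)
class OsteotomyPlan:
    """Full plan: correction angle, gap heights and predicted slope effect."""

    theta_deg: float
    inputs: TriangleInputs
    gaps: GapPlan
    predicted_slope_change_deg: float

    def as_dict(self) -> dict:
        return {
            "theta_deg": self.theta_deg,
            "x1_mm": self.inputs.x1,
            "x2_mm": self.inputs.x2,
            "l_mm": self.inputs.l,
            "alpha_deg": self.inputs.alpha,
            "y1_mm": self.gaps.y1,
            "y2_mm": self.gaps.y2,
            "y1_rounded_mm": self.gaps.y1_rounded,
            "y2_rounded_mm": self.gaps.y2_rounded,
            "predicted_slope_change_deg": self.predicted_slope_change_deg,
        }


def plan_osteotomy(
    coronal: geometry.LandmarkSet,
    hinge: np.ndarray | None,
    target: geometry.CorrectionTarget,
    x1: float,
    l: float,
    alpha: float = 45.0,
) -> OsteotomyPlan:
    """Plan the wedge: correction angle from the radiograph, gaps from the
    3-triangle formulas, slope effect from the fitted wedge model."""
    theta = geometry.miniaci_correction_angle(coronal, hinge, target)
    inputs = TriangleInputs(x1=x1, theta=theta, l=l, alpha=alpha)
    y1 = gap_posteromedial(inputs)
    y2 = gap_anteromedial(inputs, y1)
    if y1 > 0 and l > 0:
        model = fit_wedge(noyes_gap_profile(inputs), hinge_point=(0.0, 0.0, 0.0))
        dpts = slope_change(model)
    else:
        # a single measurement station (l = 0) pins no axis; the plan itself
        # is a pure valgus opening
        dpts = 0.0
    return OsteotomyPlan(theta, inputs, GapPlan(y1, y2), dpts)


# ---------------------------------------------------------------------------
# worked-example fixture: 27 intraoperative gap computations


def load_table2() -> pd.DataFrame:
    """The packaged fixture of 27 printed intraoperative gap computations.

    Columns: ``patient_id, y1_mm, y2_mm, x1_mm, l_mm``.
    """
    with resources.files("htoplan.data").joinpath("table2.csv").open("rb") as fh:
        return pd.read_csv(fh)


def audit_table2(
    table: pd.DataFrame | None = None,
    alpha: float = 45.0,
    tol_mm: float = 0.55,
) -> pd.DataFrame:
    """Re-derive every printed Y2 from (Y1, X1, L) under a common cortex angle.

    Adds the model prediction, the residual against the printed value, a
    ``within_tol`` flag, and the per-row implied cortex angle (NaN where no
    admissible angle exists, with the reason in ``alpha_status``).
    """
    if table is None:
        table = load_table2()
    rows = []
    for rec in table.itertuples(index=False):
        inputs = TriangleInputs(
            x1=rec.x1_mm, theta=0.0, l=rec.l_mm, alpha=alpha
        )
        y2_model = rec.y1_mm * inputs.x2 / inputs.x1
        resid = y2_model - rec.y2_mm
        try:
            a_imp = implied_alpha(rec.y1_mm, rec.y2_mm, rec.x1_mm, rec.l_mm)
            status = "ok"
        except InconsistentRowError:
            a_imp = float("nan")
            status = "no_admissible_alpha"
        rows.append(
            {
                "patient_id": rec.patient_id,
                "y1_mm": rec.y1_mm,
                "y2_printed_mm": rec.y2_mm,
                "y2_model_mm": y2_model,
                "y2_model_rounded_mm": round_half_mm(y2_model),
                "residual_mm": resid,
                "within_tol": abs(resid) <= tol_mm,
                "implied_alpha_deg": a_imp,
                "alpha_status": status,
            }
        )
    return pd.DataFrame(rows)
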