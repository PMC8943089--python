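"""Radiographic measures: worked examples, invariances, planning oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from htoplan import geometry
from htoplan.errors import (
    DegenerateGeometryError,
    InvalidLandmarksError,
    PlanningInfeasibleError,
)
from htoplan.geometry import CorrectionTarget, LandmarkSet

from conftest import make_coronal, make_sagittal


# ---------------------------------------------------------------------------
# weight-bearing line


@pytest.mark.parametrize(
    "ankle, expected",
    [((0.0, 0.0), 50.0), ((20.0, 0.0), 62.5), ((-20.0, 0.0), 37.5)],
)
def test_wbl_percent_examples(ankle, expected):
    """Symmetric limb crosses at 50 %; lateral/medial ankle shifts of 20 mm
    move the crossing to 62.5 / 37.5 % (hand line-line intersection)."""
    assert geometry.wbl_percent(make_coronal(ankle=ankle)) == pytest.approx(expected)


def test_wbl_outside_plateau_not_clamped():
    lms = make_coronal(ankle=(-90.0, 0.0))
    assert geometry.wbl_percent(lms) < 0.0


def test_wbl_parallel_line_is_degenerate():
    lms = make_coronal(head=(0.0, 500.0), ankle=(80.0, 500.0), knee=(0.0, 400.0))
    with pytest.raises(DegenerateGeometryError):
        geometry.wbl_percent(lms)


def test_wbl_monotone_in_lateral_ankle_shift(rng):
    shifts = np.sort(rng.uniform(-60, 60, size=25))
    vals = [geometry.wbl_percent(make_coronal(ankle=(s, 0.0))) for s in shifts]
    assert np.all(np.diff(vals) > 0)


# ---------------------------------------------------------------------------
# angles


def _tilted_plateau(tau_deg, knee=(0.0, 400.0), half=40.0):
    a = math.radians(tau_deg)  # positive: medial edge lowered (varus sense)
    lat = (knee[0] + half * math.cos(a), knee[1] + half * math.sin(a))
    med = (knee[0] - half * math.cos(a), knee[1] - half * math.sin(a))
    return med, lat


@pytest.mark.parametrize("tau, expected", [(0.0, 90.0), (5.6, 84.4)])
def test_mpta_from_plateau_tilt(tau, expected):
    """Vertical mechanical axis: MPTA = 90 - plateau tilt (varus sense)."""
    med, lat = _tilted_plateau(tau)
    lms = make_coronal(medial=med, lateral=lat)
    assert geometry.mpta(lms) == pytest.approx(expected, abs=1e-9)


def test_mpta_axis_tilted_three_degrees():
    a = math.radians(3.0)
    ankle = (-400.0 * math.sin(a), 400.0 - 400.0 * math.cos(a))
    lms = make_coronal(ankle=ankle)
    assert geometry.mpta(lms) == pytest.approx(87.0, abs=1e-9)


def test_mpta_medial_and_lateral_angles_are_supplementary(rng):
    for _ in range(25):
        med, lat = _tilted_plateau(rng.uniform(-10, 10))
        lms = make_coronal(ankle=(rng.uniform(-40, 40), 0.0), medial=med, lateral=lat)
        axis = lms.p("ankle_center") - lms.p("knee_center")
        lat_dir = lms.p("plateau_lateral_edge") - lms.p("plateau_medial_edge")
        lateral_angle = math.degrees(
            math.acos(
                np.dot(axis, lat_dir) / np.linalg.norm(axis) / np.linalg.norm(lat_dir)
            )
        )
        assert geometry.mpta(lms) + lateral_angle == pytest.approx(180.0, abs=1e-9)


def test_jlca_examples():
    lms = make_coronal()
    assert geometry.jlca(lms) == pytest.approx(0.0, abs=1e-12)
    a = math.radians(2.5)
    # femoral tangent rotated 2.5 degrees against a horizontal plateau
    cm = (-36.0 * math.cos(a), 403.0 - 36.0 * math.sin(a))
    cl = (36.0 * math.cos(a), 403.0 + 36.0 * math.sin(a))
    tilted = make_coronal(condyle_medial=cm, condyle_lateral=cl)
    assert geometry.jlca(tilted) == pytest.approx(2.5, abs=1e-9)
    mirrored = make_coronal(
        condyle_medial=(cm[0], 2 * 403.0 - cm[1]),
        condyle_lateral=(cl[0], 2 * 403.0 - cl[1]),
    )
    assert geometry.jlca(mirrored) == pytest.approx(2.5, abs=1e-9)
    assert geometry.jlca(tilted, signed=True) == pytest.approx(
        -geometry.jlca(mirrored, signed=True), abs=1e-9
    )


@pytest.mark.parametrize(
    "pts_deg",
    [0.0, 7.7, -3.0],
)
def test_pts_brazier_vertical_cortex(pts_deg):
    """Vertical posterior cortex: the slope equals the plateau drop angle."""
    a = math.radians(pts_deg)
    sag = make_sagittal(anterior=(-25.0 + 50 * math.cos(a), 50 * math.sin(a)))
    assert geometry.pts_brazier(sag) == pytest.approx(pts_deg, abs=1e-9)


def test_pts_cortex_and_tangent_rotating_together_cancel():
    sag = make_sagittal().transformed(rotation_deg=5.0)
    assert geometry.pts_brazier(sag) == pytest.approx(0.0, abs=1e-9)


def test_missing_landmark_and_degenerate_edges_rejected():
    pts = dict(make_coronal().points)
    del pts["ankle_center"]
    with pytest.raises(InvalidLandmarksError, match="ankle_center"):
        LandmarkSet("coronal", pts)
    pts = dict(make_coronal().points)
    pts["plateau_medial_edge"] = pts["plateau_lateral_edge"]
    with pytest.raises(InvalidLandmarksError):
        LandmarkSet("coronal", pts)


# ---------------------------------------------------------------------------
# similarity invariance (all measures are ratios/angles)


@settings(derandomize=True, max_examples=60)
@given(
    angle=st.floats(-180, 180),
    tx=st.floats(-500, 500),
    ty=st.floats(-500, 500),
    scale=st.floats(0.2, 5.0),
    ankle_x=st.floats(-50, 50),
    tau=st.floats(-8, 8),
)
def test_measures_invariant_under_similarity_transform(
    angle, tx, ty, scale, ankle_x, tau
):
    med, lat = _tilted_plateau(tau)
    lms = make_coronal(ankle=(ankle_x, 0.0), medial=med, lateral=lat)
    moved = lms.transformed(rotation_deg=angle, translation=(tx, ty), scale=scale)
    for fn in (geometry.wbl_percent, geometry.mpta, geometry.mldfa, geometry.jlca):
        a, b = fn(lms), fn(moved)
        assert b == pytest.approx(a, rel=1e-9, abs=1e-7)
    sag = make_sagittal(anterior=(-25.0 + 50 * math.cos(0.12), 50 * math.sin(0.12)))
    sag_moved = sag.transformed(rotation_deg=angle, translation=(tx, ty), scale=scale)
    assert geometry.pts_brazier(sag_moved) == pytest.approx(
        geometry.pts_brazier(sag), rel=1e-9, abs=1e-7
    )


# ---------------------------------------------------------------------------
# correction-angle planning


def _wbl_grid(lms, hinge, angles_deg):
    """Vectorised WBL for many candidate rotations (independent oracle)."""
    h = np.asarray(hinge, float)
    ankle = lms.p("ankle_center")
    a = np.radians(angles_deg)
    d = ankle - h
    rot = np.stack(
        [
            h[0] + d[0] * np.cos(a) - d[1] * np.sin(a),
            h[1] + d[0] * np.sin(a) + d[1] * np.cos(a),
        ],
        axis=1,
    )
    head = lms.p("femoral_head_center")
    m = lms.p("plateau_medial_edge")
    dd = lms.p("plateau_lateral_edge") - m
    w = rot - head
    denom = dd[0] * w[:, 1] - dd[1] * w[:, 0]
    num = (head[0] - m[0]) * w[:, 1] - (head[1] - m[1]) * w[:, 0]
    return 100.0 * num / denom


def test_miniaci_zero_when_already_on_target():
    lms = make_coronal(ankle=(20.0, 0.0))  # WBL exactly 62.5 %
    assert geometry.miniaci_correction_angle(lms) == pytest.approx(0.0, abs=1e-9)


def test_miniaci_matches_dense_grid_oracle():
    """Planned angle agrees with a 0.001-degree brute-force grid search."""
    lms = make_coronal(ankle=(-25.0, 0.0))
    hinge = np.array([35.0, 395.0])
    beta = geometry.miniaci_correction_angle(lms, hinge)
    grid = np.arange(0.0, 20.0, 0.001)
    signed = geometry.correction_rotation_deg(lms, hinge)
    vals = _wbl_grid(lms, hinge, np.sign(signed) * grid)
    best = grid[np.argmin(np.abs(vals - 62.5))]
    assert beta == pytest.approx(best, abs=0.001)
    after = geometry.apply_correction(lms, hinge, signed)
    assert geometry.wbl_percent(after) == pytest.approx(62.5, abs=0.1)


def test_miniaci_fixed_point_over_random_geometries(rng):
    """Applying the planned rotation reproduces the target crossing, and the
    brute-force grid never finds a smaller admissible rotation."""
    for _ in range(120):
        ankle_x = rng.uniform(-60, -5)
        tau = rng.uniform(0, 8)
        med, lat = _tilted_plateau(tau)
        lms = make_coronal(ankle=(ankle_x, 0.0), medial=med, lateral=lat)
        hinge = geometry.default_hinge(lms)
        signed = geometry.correction_rotation_deg(lms, hinge)
        after = geometry.apply_correction(lms, hinge, signed)
        assert geometry.wbl_percent(after) == pytest.approx(62.5, abs=0.1)
        grid = np.arange(0.0, 25.0, 0.005)
        vals = _wbl_grid(lms, hinge, np.sign(signed) * grid)
        best = grid[np.argmin(np.abs(vals - 62.5))]
        assert abs(signed) == pytest.approx(best, abs=0.005)


def test_miniaci_mirrored_deformity_has_opposite_sense():
    lms = make_coronal(ankle=(-25.0, 0.0))
    mirrored = make_coronal(
        ankle=(25.0, 0.0), medial=(40.0, 400.0), lateral=(-40.0, 400.0)
    )
    hinge = np.array([35.0, 395.0])
    hinge_m = np.array([-35.0, 395.0])
    s1 = geometry.correction_rotation_deg(lms, hinge, CorrectionTarget())
    s2 = geometry.correction_rotation_deg(mirrored, hinge_m, CorrectionTarget())
    assert abs(s1) == pytest.approx(abs(s2), abs=1e-6)
    assert s1 * s2 < 0


def test_miniaci_unreachable_target_raises():
    # hinge 1 mm from the ankle: rotation barely moves the WBL
    lms = make_coronal(ankle=(-25.0, 0.0))
    with pytest.raises(PlanningInfeasibleError):
        geometry.miniaci_correction_angle(lms, np.array([-24.0, 0.0]))
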