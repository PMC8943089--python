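"""Synthetic two-arm cohorts of opening-wedge HTO knees.

The generator emulates the radiographic structure of a retrospective
two-arm comparison: a *noyes* arm planned and executed with the 3-triangle
gap method and a *conventional* arm opened under fluoroscopic control.  Each
knee is a full landmark geometry, so every sampled angle can be re-measured
by :mod:`htoplan.geometry` and every downstream statistic can be computed
without any real radiographs.

Model, per knee
---------------
1. **Pre-operative state.**  True (noise-free) MPTA, WBL%, JLCA and PTS are
   drawn from configured Gaussians (JLCA truncated at zero); coronal and
   sagittal landmark sets are constructed to reproduce the sampled values
   exactly.  The configured SDs are on the *measured* scale; true values are
   sampled with SD ``sd*sqrt(icc)`` so that adding measurement noise
   restores the configured spread.
2. **Surgery.**  The wedge is planned against the 62.5 % WBL target; the
   *achieved* post-operative WBL is drawn from an arm-specific truncated
   normal (the latent execution distribution, calibrated so the measured
   means/SDs land on the study's printed values, including the systematic
   undercorrection) and realised geometrically by rotating the distal
   fragment about a lateral hinge.  The slope effect of the execution is an
   arm-specific Gaussian slope change applied through the sagittal landmark
   geometry: near zero for the noyes arm (the method's point), systematically
   positive for the conventional arm.
3. **Measurement noise.**  Inter-rater reliability enters as Gaussian noise
   with variance ``var_true*(1/icc - 1)`` per measure (default ICC 0.68).
   Part of the noise (default 60 % of its variance) is a per-knee offset
   shared between the pre- and post-operative readings -- a systematic
   rater/technique effect -- and the rest is independent per timepoint.

Seeding: one root seed; every knee consumes its own deterministic
substreams (derived from ``[seed, arm_index, knee_index, stage]``), so
changing the cohort size never reshuffles earlier knees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats as sps

from . import geometry, triangle
from .errors import ConfigError, PlanningInfeasibleError
from .geometry import CorrectionTarget, DeformityMeasures, LandmarkSet

__all__ = [
    "Dist",
    "ArmParams",
    "CohortParams",
    "KneeRecord",
    "default_params",
    "noise_sd",
    "build_coronal_landmarks",
    "build_sagittal_landmarks",
    "generate_preop",
    "apply_surgery",
    "add_measurement_noise",
    "generate_cohort",
    "write_cohort",
    "sample_postop_wbl",
    "wbl_from_mpta",
    "forward_regression_sample",
    "expected_moments",
]

ARMS = ("noyes", "conventional")


@dataclass(frozen=True)
class Dist:
    """A (mean, sd) pair."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("sd cannot be negative")


@dataclass(frozen=True)
class ArmParams:
    """Distributional parameters of one treatment arm.

    Pre-operative distributions are on the measured (reported) scale.  The
    post-operative WBL is parameterised by the latent truncated normal
    ``(postop_wbl_mu, postop_wbl_sigma)`` on ``postop_wbl_range``;
    ``62.5 - postop_wbl_mu`` is the latent undercorrection shortfall and
    ``postop_wbl_sigma`` the coronal execution scatter in %WBL.
    """

    preop_wbl: Dist
    preop_mpta: Dist
    preop_jlca: Dist
    preop_pts: Dist
    age: Dist
    bmi: Dist
    female_fraction: float
    postop_wbl_mu: float
    postop_wbl_sigma: float
    postop_wbl_range: Tuple[float, float]
    slope_change: Dist
    jlca_change: Dist

    def __post_init__(self) -> None:
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must lie in [0, 1]")
        lo, hi = self.postop_wbl_range
        if not lo < hi:
            raise ConfigError("postop WBL range must satisfy lo < hi")
        if self.postop_wbl_sigma <= 0:
            raise ConfigError("postop WBL sigma must be positive")
        for d in (self.preop_wbl, self.preop_mpta, self.preop_jlca, self.preop_pts):
            if d.sd <= 0:
                raise ConfigError("preop SDs must be positive")


@dataclass(frozen=True)
class CohortParams:
    """Everything the generator needs for a two-arm cohort."""

    n_per_arm: int = 27
    icc: float = 0.68
    shared_noise_fraction: float = 0.6
    femur_length_mm: float = 450.0
    tibia_length_mm: float = 365.0
    plateau_width_mm: float = 75.0
    osteotomy_width_mm: float = 60.0
    gap_point_distance_mm: float = 20.0
    cortex_angle_deg: float = 45.0
    target: CorrectionTarget = field(default_factory=CorrectionTarget)
    noyes: ArmParams = None  # type: ignore[assignment]
    conventional: ArmParams = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ConfigError("n_per_arm must be at least 2")
        if not 0.0 < self.icc <= 1.0:
            raise ConfigError("icc must lie in (0, 1]")
        if not 0.0 <= self.shared_noise_fraction <= 1.0:
            raise ConfigError("shared_noise_fraction must lie in [0, 1]")
        for L in (self.femur_length_mm, self.tibia_length_mm, self.plateau_width_mm):
            if L <= 0:
                raise ConfigError("anthropometric lengths must be positive")
        if self.noyes is None:
            object.__setattr__(self, "noyes", _DEFAULT_NOYES)
        if self.conventional is None:
            object.__setattr__(self, "conventional", _DEFAULT_CONVENTIONAL)

    def arm(self, name: str) -> ArmParams:
        if name not in ARMS:
            raise ConfigError(f"unknown arm {name!r}")
        return self.noyes if name == "noyes" else self.conventional


# Latent post-op WBL (mu, sigma) solved at design time so the truncated true
# moments, after adding ICC-0.68 measurement noise, reproduce the reported
# measured means/SDs: noyes (49.1, 11.4) on [22, 73], conventional
# (52.8, 15.7) on [30, 94].
_DEFAULT_NOYES = ArmParams(
    preop_wbl=Dist(19.5, 10.2),
    preop_mpta=Dist(84.4, 2.7),
    preop_jlca=Dist(1.8, 1.3),
    preop_pts=Dist(6.2, 4.0),
    age=Dist(43.7, 12.1),
    bmi=Dist(26.9, 5.5),
    female_fraction=23 / 27,
    postop_wbl_mu=49.2748,
    postop_wbl_sigma=10.3733,
    postop_wbl_range=(22.0, 73.0),
    slope_change=Dist(0.0, 1.2),
    jlca_change=Dist(0.0, 0.6),
)
_DEFAULT_CONVENTIONAL = ArmParams(
    preop_wbl=Dist(17.3, 7.6),
    preop_mpta=Dist(84.5, 2.6),
    preop_jlca=Dist(2.5, 1.8),
    preop_pts=Dist(8.9, 4.2),
    age=Dist(43.3, 11.7),
    bmi=Dist(26.1, 4.7),
    female_fraction=22 / 27,
    postop_wbl_mu=41.3874,
    postop_wbl_sigma=23.8194,
    postop_wbl_range=(30.0, 94.0),
    slope_change=Dist(2.1, 1.5),
    jlca_change=Dist(-0.6, 0.9),
)


def default_params(**overrides) -> CohortParams:
    """The default study conditions; keyword overrides replace top-level fields."""
    return replace(CohortParams(), **overrides) if overrides else CohortParams()


def noise_sd(sigma_true: float, icc: float) -> float:
    """Measurement-noise SD giving reliability ``icc``: ``sigma_true*sqrt(1/icc - 1)``."""
    if not 0.0 < icc <= 1.0:
        raise ConfigError("icc must lie in (0, 1]")
    return sigma_true * math.sqrt(1.0 / icc - 1.0)


@dataclass
class KneeRecord:
    """One knee: demographics, landmarks, true and measured pre/post measures."""

    id: str
    arm: str
    index: int
    age: float
    bmi: float
    sex: str
    true_pre: Optional[DeformityMeasures] = None
    true_post: Optional[DeformityMeasures] = None
    meas_pre: Optional[DeformityMeasures] = None
    meas_post: Optional[DeformityMeasures] = None
    planned_correction_deg: float = float("nan")
    achieved_correction_deg: float = float("nan")
    y1_mm: float = float("nan")
    y2_mm: float = float("nan")
    landmarks_pre: Optional[Dict[str, LandmarkSet]] = None
    landmarks_post: Optional[Dict[str, LandmarkSet]] = None


# ---------------------------------------------------------------------------
# landmark construction


def _condyle_points(
    med_edge: np.ndarray, lat_edge: np.ndarray, jlca_deg: float
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Femoral condylar tangent points above the plateau, converging medially
    by ``jlca_deg`` (the femoral tangent rises toward lateral)."""
    mid = 0.5 * (med_edge + lat_edge)
    half = lat_edge - mid
    a = math.radians(jlca_deg)
    R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    half_rot = R @ half
    up = np.array([-half[1], half[0]])
    up = 3.0 * up / np.linalg.norm(up)  # small proximal offset; angle-neutral
    lat_c = mid + 0.9 * half_rot + up
    med_c = mid - 0.9 * half_rot + up
    return tuple(med_c), tuple(lat_c)


def build_coronal_landmarks(
    wbl_pct: float,
    mpta_deg: float,
    jlca_deg: float = 0.0,
    femur_mm: float = 450.0,
    tibia_mm: float = 365.0,
    plateau_mm: float = 75.0,
) -> LandmarkSet:
    """Coronal landmarks reproducing the given WBL%, MPTA and JLCA exactly.

    Knee centre at the origin, femoral head directly proximal; the plateau is
    tilted (medial edge distal for varus) until the re-measured MPTA matches,
    and the ankle centre is placed on the head-to-target line so the WBL
    crossing is exact.  The implied femorodiaphyseal alignment absorbs any
    residual between the two, which is what allows independently configured
    MPTA and WBL marginals.
    """
    knee = np.zeros(2)
    head = np.array([0.0, femur_mm])
    w2 = plateau_mm / 2.0

    def build(tau_deg: float) -> LandmarkSet:
        a = math.radians(tau_deg)
        lat = knee + w2 * np.array([math.cos(a), math.sin(a)])
        med = knee - w2 * np.array([math.cos(a), math.sin(a)])
        q = med + (wbl_pct / 100.0) * (lat - med)
        s = (-tibia_mm - head[1]) / (q[1] - head[1])
        ankle = head + s * (q - head)
        med_c, lat_c = _condyle_points(med, lat, jlca_deg)
        return LandmarkSet(
            "coronal",
            {
                "femoral_head_center": tuple(head),
                "knee_center": tuple(knee),
                "ankle_center": tuple(ankle),
                "plateau_medial_edge": tuple(med),
                "plateau_lateral_edge": tuple(lat),
                "femoral_condyle_medial": med_c,
                "femoral_condyle_lateral": lat_c,
            },
        )

    # MPTA(tau) ~ 90 - tau + (small ankle-direction term); fixed-point solve
    tau = 90.0 - mpta_deg
    for _ in range(60):
        err = geometry.mpta(build(tau)) - mpta_deg
        if abs(err) < 1e-10:
            break
        tau += err
    return build(tau)


def build_sagittal_landmarks(pts_deg: float) -> LandmarkSet:
    """Sagittal landmarks with a vertical posterior cortex and the plateau
    tangent dropping ``pts_deg`` posteriorly."""
    a = math.radians(pts_deg)
    post = np.array([-25.0, 0.0])
    ant = post + 50.0 * np.array([math.cos(a), math.sin(a)])
    return LandmarkSet(
        "sagittal",
        {
            "plateau_tangent_posterior": tuple(post),
            "plateau_tangent_anterior": tuple(ant),
            "posterior_cortex_proximal": (0.0, -10.0),
            "posterior_cortex_distal": (0.0, -90.0),
        },
    )


# ---------------------------------------------------------------------------
# generation stages


def _knee_rng(seed: int, arm_index: int, knee_index: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), arm_index, knee_index, stage])


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    return sps.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def generate_preop(
    params: CohortParams, seed: int, arms: Tuple[str, ...] = ARMS
) -> List[KneeRecord]:
    """Draw the pre-operative cohort (true values + landmark geometry)."""
    records: List[KneeRecord] = []
    ricc = math.sqrt(params.icc)
    for arm_index, arm_name in enumerate(ARMS):
        if arm_name not in arms:
            continue
        arm = params.arm(arm_name)
        for i in range(params.n_per_arm):
            rng = _knee_rng(seed, arm_index, i, 0)
            age = arm.age.mean + arm.age.sd * rng.standard_normal()
            bmi = arm.bmi.mean + arm.bmi.sd * rng.standard_normal()
            sex = "f" if rng.random() < arm.female_fraction else "m"
            wbl = arm.preop_wbl.mean + arm.preop_wbl.sd * ricc * rng.standard_normal()
            mpta = arm.preop_mpta.mean + arm.preop_mpta.sd * ricc * rng.standard_normal()
            jl_sd = arm.preop_jlca.sd * ricc
            jlca = float(
                _truncnorm(arm.preop_jlca.mean, jl_sd, 0.0, np.inf).ppf(rng.random())
            )
            pts = arm.preop_pts.mean + arm.preop_pts.sd * ricc * rng.standard_normal()
            coronal = build_coronal_landmarks(
                wbl,
                mpta,
                jlca,
                params.femur_length_mm,
                params.tibia_length_mm,
                params.plateau_width_mm,
            )
            sagittal = build_sagittal_landmarks(pts)
            rec = KneeRecord(
                id=f"{arm_name}-{i:03d}",
                arm=arm_name,
                index=i,
                age=age,
                bmi=bmi,
                sex=sex,
                true_pre=geometry.measure_all(coronal, sagittal),
                landmarks_pre={"coronal": coronal, "sagittal": sagittal},
            )
            records.append(rec)
    return records


def apply_surgery(
    record: KneeRecord, params: CohortParams, rng: np.random.Generator
) -> KneeRecord:
    """Plan and execute the osteotomy on one knee.

    The wedge is planned against the configured target (gap heights from the
    3-triangle formulas); the achieved coronal result is a draw from the
    arm's latent execution distribution, realised as a rotation of the
    distal fragment about the lateral hinge; the slope effect is the arm's
    slope-change draw applied through the sagittal geometry.  All post-op
    true measures are re-measured from the transformed landmarks.
    """
    if record.landmarks_pre is None or record.true_pre is None:
        raise ConfigError("record has no pre-operative state")
    arm = params.arm(record.arm)
    coronal = record.landmarks_pre["coronal"]
    hinge = geometry.default_hinge(coronal)

    plan = triangle.plan_osteotomy(
        coronal,
        hinge,
        params.target,
        x1=params.osteotomy_width_mm,
        l=params.gap_point_distance_mm,
        alpha=params.cortex_angle_deg,
    )

    lo, hi = arm.postop_wbl_range
    achieved_wbl = float(
        _truncnorm(arm.postop_wbl_mu, arm.postop_wbl_sigma, lo, hi).ppf(rng.random())
    )
    beta = geometry.correction_rotation_deg(coronal, hinge, achieved_wbl)
    post_coronal = geometry.apply_correction(coronal, hinge, beta)

    dpts = arm.slope_change.mean + arm.slope_change.sd * rng.standard_normal()
    post_sagittal = build_sagittal_landmarks(record.true_pre.pts + dpts)

    djlca = arm.jlca_change.mean + arm.jlca_change.sd * rng.standard_normal()
    post_jlca = max(record.true_pre.jlca + djlca, 0.0)
    med_c, lat_c = _condyle_points(
        post_coronal.p("plateau_medial_edge"),
        post_coronal.p("plateau_lateral_edge"),
        post_jlca,
    )
    post_coronal = post_coronal.replace_point(
        "femoral_condyle_medial", med_c
    ).replace_point("femoral_condyle_lateral", lat_c)

    record.true_post = geometry.measure_all(post_coronal, post_sagittal)
    record.landmarks_post = {"coronal": post_coronal, "sagittal": post_sagittal}
    record.planned_correction_deg = plan.theta_deg
    record.achieved_correction_deg = abs(beta)
    record.y1_mm = plan.gaps.y1
    record.y2_mm = plan.gaps.y2
    return record


_NOISED = ("wbl_percent", "mpta", "mldfa", "jlca", "pts")


def _true_sds(params: CohortParams, arm: ArmParams) -> Dict[str, float]:
    ricc = math.sqrt(params.icc)
    return {
        "wbl_percent": arm.preop_wbl.sd * ricc,
        "mpta": arm.preop_mpta.sd * ricc,
        "mldfa": arm.preop_mpta.sd * ricc,  # same metrology as MPTA
        "jlca": arm.preop_jlca.sd * ricc,
        "pts": arm.preop_pts.sd * ricc,
    }


def add_measurement_noise(
    record: KneeRecord,
    params: CohortParams,
    rng: np.random.Generator,
    icc: float | None = None,
) -> KneeRecord:
    """Attach measured pre/post values: true + reliability-limited noise.

    Per measure the total noise variance is ``var_true*(1/icc - 1)``;
    ``shared_noise_fraction`` of it is a per-knee offset common to both
    timepoints, the rest independent per timepoint.  With ``icc = 1`` the
    measured values equal the true ones exactly.
    """
    icc = params.icc if icc is None else icc
    if not 0.0 < icc <= 1.0:
        raise ConfigError("icc must lie in (0, 1]")
    arm = params.arm(record.arm)
    sds = _true_sds(params, arm)
    lam = params.shared_noise_fraction

    def noised(true: DeformityMeasures, shared: Dict[str, float]) -> DeformityMeasures:
        vals = {}
        for m in _NOISED:
            tot = noise_sd(sds[m], icc)
            indep = tot * math.sqrt(1.0 - lam)
            vals[m] = getattr(true, m) + shared[m] + indep * rng.standard_normal()
        return DeformityMeasures(**vals)

    shared = {
        m: noise_sd(sds[m], icc) * math.sqrt(lam) * rng.standard_normal()
        for m in _NOISED
    }
    if icc == 1.0:
        record.meas_pre = record.true_pre
        record.meas_post = record.true_post
        return record
    if record.true_pre is not None:
        record.meas_pre = noised(record.true_pre, shared)
    if record.true_post is not None:
        record.meas_post = noised(record.true_post, shared)
    return record


def generate_cohort(
    params: CohortParams | None = None, seed: int = 0
) -> List[KneeRecord]:
    """Full pipeline: pre-op draw, surgery, measurement noise; deterministic
    per (params, seed) and stable per knee under cohort-size changes."""
    params = params or default_params()
    records = generate_preop(params, seed)
    for rec in records:
        arm_index = ARMS.index(rec.arm)
        apply_surgery(rec, params, _knee_rng(seed, arm_index, rec.index, 1))
        add_measurement_noise(rec, params, _knee_rng(seed, arm_index, rec.index, 2))
    return records


def write_cohort(records: List[KneeRecord], path) -> None:
    """Write a cohort to CSV (one row per knee; lossless round trip)."""
    from .io import write_cohort as _write

    _write(records, path)


# ---------------------------------------------------------------------------
# distribution-level helpers (acceptance-scale computations)


def sample_postop_wbl(
    n: int,
    rng: np.random.Generator,
    mean: float = 49.1,
    sd: float = 11.4,
    lo: float = 22.0,
    hi: float = 73.0,
) -> np.ndarray:
    """Draws from a reported post-operative WBL distribution: a normal with
    the printed mean/SD truncated to the printed range."""
    return _truncnorm(mean, sd, lo, hi).rvs(size=n, random_state=rng)


def wbl_from_mpta(
    mpta_deg: float,
    femur_mm: float = 450.0,
    tibia_mm: float = 365.0,
    plateau_mm: float = 75.0,
) -> float:
    """Geometric forward model: WBL% of a limb whose entire coronal deformity
    is tibial (plateau horizontal, femoral head above the knee centre)."""
    lms = build_coronal_landmarks(
        wbl_pct=50.0,  # placeholder; ankle is re-derived from MPTA below
        mpta_deg=90.0,
        jlca_deg=0.0,
        femur_mm=femur_mm,
        tibia_mm=tibia_mm,
        plateau_mm=plateau_mm,
    )
    phi = math.radians(mpta_deg - 90.0)
    ankle = np.array([tibia_mm * math.sin(phi), -tibia_mm * math.cos(phi)])
    return geometry.wbl_percent(lms.replace_point("ankle_center", ankle))


def forward_regression_sample(
    n: int,
    rng: np.random.Generator,
    mpta_mean: float = 90.7,
    mpta_sd: float = 2.3,
    icc: float = 0.68,
    femur_mm: float = 450.0,
    tibia_mm: float = 365.0,
    plateau_mm: float = 75.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """(measured MPTA, WBL%) sample for the alignment regression.

    True post-operative MPTA is Gaussian; the WBL follows from the landmark
    geometry; reliability-limited noise (variance ``sd^2*(1/icc-1)``) is
    added to the MPTA reading, which attenuates the regression slope by the
    factor ``icc``.
    """
    mpta_true = mpta_mean + mpta_sd * rng.standard_normal(n)
    wbl = np.array(
        [wbl_from_mpta(m, femur_mm, tibia_mm, plateau_mm) for m in mpta_true]
    )
    mpta_meas = mpta_true + noise_sd(mpta_sd, icc) * rng.standard_normal(n)
    return mpta_meas, wbl


# ---------------------------------------------------------------------------
# configured-law moments (for parameter-recovery checks)


def _trunc_moments(mean, sd, lo, hi) -> Tuple[float, float]:
    d = _truncnorm(mean, sd, lo, hi)
    m, v = d.stats(moments="mv")
    return float(m), float(np.sqrt(v))


def expected_moments(params: CohortParams | None = None) -> Dict[str, Dist]:
    """Expected measured-scale (mean, sd) of every configured quantity,
    under the generator's own sampling law (truncations included)."""
    params = params or default_params()
    out: Dict[str, Dist] = {}
    for name in ARMS:
        arm = params.arm(name)
        nz = {
            "wbl": noise_sd(arm.preop_wbl.sd * math.sqrt(params.icc), params.icc),
            "mpta": noise_sd(arm.preop_mpta.sd * math.sqrt(params.icc), params.icc),
            "jlca": noise_sd(arm.preop_jlca.sd * math.sqrt(params.icc), params.icc),
            "pts": noise_sd(arm.preop_pts.sd * math.sqrt(params.icc), params.icc),
        }
        out[f"{name}.age"] = arm.age
        out[f"{name}.bmi"] = arm.bmi
        out[f"{name}.preop_wbl"] = Dist(arm.preop_wbl.mean, arm.preop_wbl.sd)
        out[f"{name}.preop_mpta"] = Dist(arm.preop_mpta.mean, arm.preop_mpta.sd)
        out[f"{name}.preop_pts"] = Dist(arm.preop_pts.mean, arm.preop_pts.sd)
        jm, js = _trunc_moments(
            arm.preop_jlca.mean, arm.preop_jlca.sd * math.sqrt(params.icc), 0.0, np.inf
        )
        out[f"{name}.preop_jlca"] = Dist(jm, math.hypot(js, nz["jlca"]))
        wm, ws = _trunc_moments(
            arm.postop_wbl_mu, arm.postop_wbl_sigma, *arm.postop_wbl_range
        )
        out[f"{name}.postop_wbl"] = Dist(wm, math.hypot(ws, nz["wbl"]))
        # measured pre/post slope difference: true change + independent noise
        indep = nz["pts"] * math.sqrt(1.0 - params.shared_noise_fraction)
        out[f"{name}.delta_pts"] = Dist(
            arm.slope_change.mean,
            math.hypot(arm.slope_change.sd, math.sqrt(2.0) * indep),
        )
    return out
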