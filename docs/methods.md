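# Methods

This note documents the models implemented in `htoplan`, the defaults and
why they were chosen, the numerical choices, and what the synthetic cohort
does and does not emulate.

## Radiographic measures

All measures are functions of named 2-D landmark coordinates (mm); pixel
data and landmark detection are out of scope. The coordinate convention is
x toward lateral (coronal) / anterior (sagittal), y toward proximal, but
every measure is a ratio of distances or an angle between lines and is
therefore exactly invariant under translation, rotation and uniform scaling
of the landmarks (property-tested to 1e-9 relative).

* **WBL%** — intersection of the femoral-head-to-ankle line with the
  infinite line through the plateau edges, parameterised medial (0 %) to
  lateral (100 %). Values outside [0, 100] are reported raw, never clamped,
  because over/under-correction classification needs them. A WBL parallel
  to the plateau line raises a degenerate-geometry error.
* **MPTA / mLDFA** — angle between the mechanical axis segment and the
  joint-line tangent, computed with the `atan2(|cross|, dot)` form (well
  conditioned near 0° and 180°, where `arccos` of a normalised dot product
  loses half the available precision). Convention: varus tibia (medial
  plateau edge distal) gives MPTA < 90°.
* **JLCA** — unsigned magnitude by default, since radiographic reports
  quote magnitudes; a signed variant (positive = converging medially,
  decided by which side of the plateau midpoint the tangents intersect) is
  available behind a flag.
* **PTS** — Brazier construction: angle between the medial plateau tangent
  and the perpendicular to the posterior tibial cortex, positive for a
  posteriorly dropping plateau; wrapped into (−90°, 90°].

### Correction-angle planning

The planner rotates the ankle centre about a hinge until the WBL crosses
the plateau at the target (default 62.5 %, with a 3–5° valgus band kept as
metadata). The rotation sense (valgus) is detected from the local
derivative, so left and right knees need no special-casing; the angle is
solved with Brent's method on [0°, 45°] to 1e-10°, and infeasibility (no
admissible rotation reaches the target) is a typed error. The default
hinge sits 10 mm medial and 15 mm distal to the lateral plateau edge,
measured along landmark-derived directions so planning commutes with
similarity transforms; the literature does not fix a numeric hinge
position, so it is configurable.

## The 3-triangle gap model

Inputs: X₁ (coronal tibial width at the posteromedial gap point), L
(distance between the two gap points along the medial osteotomy side), α
(anteromedial cortex angle vs the coronal plane) and the planned valgus
angle θ. The model is

Y₁ = X₁ tan θ, X₂ = X₁ − L cos α, Y₂ = Y₁ X₂ / X₁.

The published description of Y₂ is partially circular; the
similar-triangles reading above is adopted because it reproduces the bulk
of the published 27-row worked table. Gaps are additionally rounded to the
0.5 mm grid used intraoperatively (raw values always retained).

* **Default α = 45°.** No value is printed with the table; 45° reproduces
  20 of the 27 rows within 0.55 mm. The remaining rows
  (5, 11, 12, 14, 19, 20, 23) deviate by more; inverting the formula
  (`implied_alpha`) shows rows 5, 12, 14 and 23 admit *no* cortex angle at
  all (implied cos α > 1), i.e. they cannot arise from the model for any α,
  while the others are consistent with per-patient cortex angles between
  ~33° and ~63°. The audit reports both diagnostics; whether those rows
  reflect measured per-patient angles or transcription artifacts cannot be
  decided from the printed data.

### Wedge-rotation model

The osteotomy is modelled as a rigid rotation of the proximal fragment by
ω about an in-plane axis through the hinge (zero-width lateral bridge; no
hinge-fracture mechanics, no plate or bone material model). Gap convention:
the vertical separation of the cut surfaces measured at a fixed station at
in-plane distance *s* from the axis is `s·tan ω` — the convention that makes
the Y₁ = X₁ tan θ formula exact. `fit_wedge` solves the resulting linear
system for the axis direction and tan ω (least squares for >2 stations)
and inverts with `arctan`, so gap profiles synthesised from an explicit 3-D
rotation are recovered exactly; collinear stations raise a typed error and
an all-zero profile returns the zero-opening model. `slope_change` and
`coronal_change` apply the exact Rodrigues rotation to the anterior and
medial plateau directions and report their elevation angles: the slope
component is positive when the anterior tangent rises (plateau drops
posteriorly, slope increases).

The package's formal statement of slope preservation: for any valid plan
the fitted wedge of the (Y₁, Y₂) profile has slope change 0 (±0.1°) and
valgus component θ (±0.1°), while the equal-gap profile always yields a
positive slope change matching a brute-force rotation oracle within 0.05°
(tested over 1000 random geometries).

## Synthetic cohort

The generator emulates the *radiographic* structure of a two-arm
retrospective comparison at n = 27 knees per arm; it does not emulate
clinical follow-up (recurrent varus, conversion to arthroplasty, outcome
scores) or image acquisition.

**Pre-operative state.** MPTA, WBL%, JLCA, PTS, age and BMI are sampled as
independent Gaussian marginals (JLCA truncated at 0); coronal landmarks are
built to satisfy the sampled MPTA (plateau tilt, solved by fixed-point
iteration to 1e-10°) and WBL (ankle placed on the head-to-target line)
simultaneously, with the implied femorodiaphyseal alignment absorbing the
difference. Independence is a deliberate simplification: the reported
marginal SDs are mutually inconsistent with full rigid coupling (an MPTA SD
of 2.7° would force a WBL SD near 13 %), so the configured marginals take
precedence and cross-correlations are not calibrated. Consequence: the
within-cohort regression of post-op WBL on MPTA is flatter in generated
cohorts than in the geometric forward model below.

**Surgery.** The wedge is planned against the 62.5 % target (correction
angle, Y₁, Y₂ recorded per knee). The achieved post-operative WBL is a draw
from an arm-specific latent truncated normal realised geometrically by
rotating the distal fragment about the hinge; its (μ, σ) were solved
numerically so that the truncated true moments, after measurement noise,
reproduce the reported measured moments — noyes μ = 49.2748, σ = 10.3733 on
[22, 73] (measured ≈ 49.1 ± 11.4); conventional μ = 41.3874, σ = 23.8194 on
[30, 94] (measured ≈ 52.8 ± 15.7, with ~10 % over-corrections emerging from
the truncation shape). Both arms therefore undercorrect relative to the
62.5 % plan, as observed clinically. The slope effect is an arm-specific
Gaussian slope change applied through the sagittal landmarks —
conventional +2.1° ± 1.5° (systematic slope increase), noyes 0.0° ± 1.2°
(the method preserves the slope in expectation; execution scatter remains).
The noyes mean is a design choice: a mean as large as the reported
between-visit difference (+1.5°) is arithmetically incompatible with the
reported *non*-significance being reproducible at n = 27 (it would be
rejected in ~a third of replicates), and the mechanism's noise-free limit
is exactly zero. JLCA changes are Gaussian (conventional −0.6° ± 0.9°,
noyes 0 ± 0.6°), floored at zero.

**Measurement noise.** Reliability is the variance ratio var(true)/
var(measured) = ICC (default 0.68); noise SD per measure is
`σ_true·√(1/ICC − 1)` with σ_true = σ_configured·√ICC, so measured moments
match the configured (reported) ones. 60 % of the noise variance is a
per-knee offset shared between the pre- and post-operative readings (a
systematic rater/technique effect), the rest independent per timepoint.
The split is not identifiable from a single reliability coefficient; a
purely independent noise model would put a ±3.9° floor on paired PTS
differences, which is incompatible with any reproducible within-arm paired
significance at these sample sizes.

**Seeding.** One root seed; per-knee generators are derived from
`[seed, arm, knee, stage]`, so identical seeds give byte-identical cohorts
and growing a cohort never reshuffles existing knees.

**Geometric forward model.** For the alignment regression a separate
single-cause model is used: the whole coronal deformity is tibial (plateau
horizontal, femoral head above the knee), so post-operative WBL is a pure
function of MPTA. With femur 450 mm, tibia 365 mm and plateau 75 mm
(defaults chosen as typical adult values; they are not reported in the
source data) the noise-free slope is 4.69 % per degree; regressing on an
MPTA reading with reliability 0.68 attenuates it by exactly that factor to
≈ 3.19 % per degree — which is how the reported ≈ 3.2 %/° arises.

## Statistics

* Pooled two-sample t by default (Welch behind a flag); two-sided
  throughout; zero-variance-equal-means returns p = 1 by convention.
* Accuracy band 50–75 % with **inclusive** bounds (the source wording fixes
  no boundary policy); `classify_accuracy` partitions the line into
  under/within/over.
* Pearson chi-square **without** Yates correction — the only variant whose
  p (0.574) is consistent with the reported 0.58 for the 12/26 vs 10/26
  band comparison.
* Propensity matching: logistic model of arm on covariates, greedy 1:1
  nearest-neighbour without replacement, treated processed in descending
  score order, no caliper (neither order nor caliper is specified in the
  source; the greedy rule is deterministic and idempotent). Perfect
  separation falls back to standardized Euclidean matching with a warning;
  standardized mean differences before/after are reported as diagnostics.
* Post-hoc power by noncentral t. Note: a power of 0.78 at 27 + 27 knees
  requires d ≈ 0.77; the routine makes the reported "moderate effect size
  (d = 0.03)" visibly incompatible with that power (it gives ≈ 0.05).
* No multiple-testing adjustment (none is applied in the emulated design).

## Problem sizes and tolerances

The test suite runs the slope-preservation property at 1000 random
geometries, the accuracy-band shares at 100 000 truncated-normal draws, the
regression at 5000 knees, parameter recovery at 20 seeded cohorts of 500
knees per arm (each configured mean/SD within 2 SE at the nominal ~5 %
exception rate, compared against the sampler's own truncated-law moments),
and the significance pattern at 50 seeded replicates of 27 knees per arm.
Gap formulas are exact; wedge fits agree with rotation oracles to below
0.05°; planner fixed points reproduce their target to below 0.1 percentage
points.

## Known limitations

* Landmarks are inputs; no image processing, DICOM/PACS or detection.
* mLDFA is measured but drives no femoral-osteotomy planning.
* Pre-operative measures are independent marginals (see above), so joint
  pre-operative correlation structure and the cohort-level regression slope
  are not calibrated quantities.
* The wedge model has a point hinge and rigid fragments: no lateral-hinge
  fracture, plate mechanics, or bone-healing behaviour.
* Reported study-scale patient results (per-table means and p-values)
  serve as calibration constants of the generator; they are not themselves
  recomputable from real data here.
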