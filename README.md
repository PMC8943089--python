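# htoplan

Planning geometry and cohort analytics for **medial opening-wedge high
tibial osteotomy (HTO)** — the valgus-producing cut used to unload the
arthritic medial compartment in young, active patients.

The package is aimed at orthopaedic researchers and surgical-planning
engineers who need three things in one tested toolbox:

1. **Radiographic metrology.** From named 2-D landmarks (mm) on a long-leg
   coronal view and a lateral knee view it computes the weight-bearing-line
   crossing (WBL%, Dugdale convention, medial edge = 0 %), the medial
   proximal tibial angle (MPTA), the mechanical lateral distal femoral angle
   (mLDFA), the joint-line convergence angle (JLCA) and the posterior tibial
   slope (PTS, Brazier construction). It also solves the Miniaci correction
   angle: the rotation of the distal fragment about a lateral hinge that
   places the WBL at the 62.5 % target.

2. **The 3-triangle intraoperative gap method.** For a planned valgus angle
   θ the vertical gap at the posteromedial cortex is

   Y₁ = X₁ · tan θ,

   and at a second point L millimetres more anterior along an anteromedial
   cortex inclined α to the coronal plane (tibial width X₂ = X₁ − L·cos α),

   Y₂ = Y₁ · X₂ / X₁  ≤  Y₁.

   Because both gaps are proportional to the distance from the lateral
   hinge, the opening is a pure valgus rotation about an anteroposterior
   axis and the posterior slope is preserved; opening *equal* gaps tilts
   the hinge axis and increases the slope. `fit_wedge`/`slope_change`
   quantify this by inverting any measured gap profile to its rigid
   opening (axis direction + angle) and decomposing it into valgus and
   slope components. A packaged fixture of 27 published intraoperative gap
   computations is audited row by row (`triangle.audit_table2`).

3. **A synthetic two-arm cohort and the comparison pipeline.** A generator
   emulates a retrospective study (a *noyes* arm executed by predefined
   gaps vs a *conventional* arm opened under fluoroscopy) at full landmark
   level, with inter-rater measurement noise at a configurable reliability
   (ICC, default 0.68). The statistics layer provides propensity-score
   nearest-neighbour matching (age, BMI, WBL, JLCA, MPTA, PTS), pooled and
   paired t-tests, the 50–75 % accuracy band with a Pearson chi-square,
   OLS of post-operative WBL% on MPTA, and noncentral-t post-hoc power.

## Worked example

```sh
$ htoplan plan --landmarks demo_coronal.json --x1 60
correction angle  θ = 9.49°
posteromedial gap Y1 = 10.03 mm (use 10.0)
anteromedial gap  Y2 = 7.66 mm (use 7.5)
predicted slope change ΔPTS = 0.00°
```

For a varus limb whose WBL crosses at 19.5 % the planner needs a 9.49°
valgus rotation to reach the 62.5 % target. With a 60 mm tibial width,
gap points 20 mm apart and a 45° anteromedial cortex the surgeon opens
10.0 mm posteromedially but only 7.5 mm anteromedially; the fitted wedge
confirms the profile is a pure valgus rotation (ΔPTS = 0.00°).

The same from Python:

```python
from htoplan import cohort, geometry, triangle

lms = cohort.build_coronal_landmarks(wbl_pct=19.5, mpta_deg=84.4, jlca_deg=1.8)
plan = triangle.plan_osteotomy(lms, None, geometry.CorrectionTarget(),
                               x1=60, l=20, alpha=45)
print(plan.gaps.y1_rounded, plan.gaps.y2_rounded)   # 10.0 7.5
```

End-to-end cohort study:

```sh
htoplan simulate --n 27 --seed 1 --out cohort.csv
htoplan compare --cohort cohort.csv --out report.json
```

## Layout

| module | contents |
|---|---|
| `htoplan.geometry` | landmark sets, WBL/MPTA/mLDFA/JLCA/PTS, correction-angle planning |
| `htoplan.triangle` | Y₁/Y₂ gap formulas, implied-α audit, wedge fit and slope decomposition |
| `htoplan.cohort` | synthetic two-arm cohort generator, forward alignment model |
| `htoplan.stats` | matching, t-tests, accuracy bands, chi-square, regression, power |
| `htoplan.io` / `htoplan.cli` | landmark + cohort file formats, `htoplan` command |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
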