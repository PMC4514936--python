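# Methods

## Problem and measurement model

In orthognathic surgery a Le Fort I osteotomy detaches the maxilla, which is
then repositioned according to a virtual 3D plan and held by a CAD/CAM
occlusal splint wired to the mandible. How faithfully the executed surgery
reproduces the plan is measured from nine fiducial bone screws — three each
in the skull, maxilla and mandible — whose 3D coordinates are known at two
timepoints: the virtual plan and the post-operative CT, fused on the skull
(the only structure the surgery does not move).

All coordinates are millimetres in a right-handed frame: `x` medio-lateral
(+ toward the specimen's left), `y` antero-posterior (+ anterior), `z`
supero-inferior (+ superior). The sign conventions are fixed and documented
rather than configurable; angle signs follow the right-hand rule about the
corresponding axis.

### Pose differences

Each region's three screws form a *fiducial triad*. Its barycenter (the
component-wise mean) is the region's rigid-body landmark; the vectors from
barycenter to each screw carry its orientation. For a planned/post-operative
triad pair:

* **translation** = post-operative barycenter − planned barycenter
  (components and Euclidean magnitude);
* **rotation** = the proper rotation `R` minimising
  `Σᵢ ‖R v_plan,i − v_ppop,i‖²` over the three barycenter-to-screw vectors —
  the orthogonal Procrustes / Kabsch solution with reflections excluded.
  It is the standard least-squares estimator for corresponding landmark
  sets and is exactly solvable; the per-vector RMS misfit after rotation is
  reported as `residual_rmse`.

Angles are extracted from `R` as pitch (about x), roll (about y) and yaw
(about z) using the Euler factorisation `R = Rx(pitch)·Ry(roll)·Rz(yaw)`
(z–y–x sequence, yaw applied first). At surgical magnitudes (≲ 10°) the
sequence choice is second order. Gimbal lock (`|roll| → 90°`) is flagged but
not fatal — at these magnitudes it indicates corrupt input. A second
convention, `paper_literal`, evaluates single-axis two-argument arctangent
formulas on the rotated +y axis; it is retained for traceability with the
original study's printed formulas, but it cannot encode rotation about y and
its yaw formula is degenerate (returns 90°) at the identity, so `standard`
is the default everywhere.

### Agreement statistics

For each region × axis (mm) and region × angle (degrees) the signed
per-specimen differences `d₁..d_n` are summarised by:

* **RMSD** = `sqrt((1/n) Σ dᵢ²)` — note the `1/n` denominator, so
  `rmsd² = mean² + sd²·(n−1)/n` with the sample (n−1) SD. Accuracy is
  classified against inclusive cutoffs of 2 mm (translational) and 4°
  (rotational).
* **Bland–Altman limits of agreement** `mean ± 1.96·sd` (1.96 fixed, not
  t-based), each limit with a 95% CI of half-width `t · sqrt(3·sd²/n)`.
  The t quantile's degrees of freedom are selectable (`n−1`, the
  convention and the default, or `n`, which matches the published CI widths
  slightly better); both are within 0.05 of the published tables.

Inverting the limit formulas (`mean = (U+L)/2`, `sd = (U−L)/3.92`) and
applying the RMSD identity yields the RMSD implied by a limits table —
`check_consistency` uses this to cross-validate table pairs. On the
published reference tables this confirms every overall cell to the printed
precision, and flags the splint *rotational* cells, which duplicate the
overall mandible rotational cells and cannot follow from the splint limits;
those cells are treated as a documented inconsistency, not a target.

### Error decomposition

Because the maxilla is positioned through the splint seated on the mandible,
the maxillary repositioning error is the sum of the mandibular (condylar
seating) error and the intrinsic splint error, per specimen and component:

    MxRE = MdRE + SE,  hence  SE = MxRE − MdRE.

Subtraction happens on the signed per-specimen components *before* any
aggregation — subtracting aggregate RMSDs is not equivalent (the published
tables themselves rule it out). For rotations the subtraction of Euler
angles is the small-angle approximation of the exact relative rotation
`R_mx·R_mdᵀ` (also provided); the discrepancy is second order in the angles,
under 0.1° when each rotation stays within a few degrees and roughly 0.5°
near 10°.

### Screw deformation (inter-points discrepancy)

Deformation is the non-rigid remainder of a triad's motion: after the
best-fit rigid transform (Kabsch rotation about the barycenter plus
barycenter translation) maps the planned triad onto the post-operative one,
the per-screw, per-axis residuals are attributed to screw bending. Their
RMSD across screws and specimens gives the per-region, per-axis deformation
table, and its ratio to the overall RMSD on the same axis gives the
deformation share. This is the standard fiducial-registration-error
construction; the alternative reading (changes in pairwise inter-screw
distances, also exposed via `inter_point_distances`) is scalar per pair and
cannot be resolved per axis. Note that a 6-dof rigid fit on 9 coordinates
absorbs part of any noise: isotropic noise of SD σ leaves per-axis residual
RMSDs of roughly 0.5–0.6 σ (measured empirically; stable across seeds).

### Registration frames

The default frame is skull-fixed, mirroring the imaging protocol. A
mandible-fixed mode re-expresses each specimen's post-operative triads
through the rigid transform that maps the post-operative mandible back onto
its planned pose, so maxilla differences isolate the splint error. Under the
additive generative model below this removal is exact for translational
mandibular error and first-order for rotational error (a mandibular rotation
about the mandible's own barycenter displaces the maxilla by
`(R−I)·(b_mx − b_md)`, which the mandible-frame correction cancels only to
first order).

## Synthetic studies

No raw landmark data accompany the published study, so the generator
produces complete studies with known ground truth:

* **Template geometry**: fixed screw coordinates per region (nasion /
  infraorbital rims; anterior nasal spine / upper first molar roots; mental
  midline / lower first molar roots), inter-screw distances all > 20 mm.
  Fixed constants, not random, so every downstream tolerance is conditioned
  on reproducible geometry.
* **Planned maxillary movement**: 5 mm advancement with 4 mm (left
  pterygo-maxillary), 3 mm (left naso-maxillary) superior and 3 mm (right
  pterygo-maxillary) inferior repositioning. The plan prescribes buttress
  displacements, not a transform, so the proper rigid motion least-squares
  fitted (Kabsch) to the three displaced buttress points is taken as the
  planned transform of the maxilla template.
* **Error model**: per specimen, the mandibular error and the splint error
  are each drawn as independent axis-wise normal translations (mm) and Euler
  rotations (degrees) — matching the axis-wise normality the Bland–Altman
  analysis assumes. The mandible receives the mandibular draw; the maxilla
  receives the *component-wise sum* of the two draws, applied as one rigid
  motion about its own planned barycenter. This additive parameter-space
  composition realises `MxRE = MdRE + SE` exactly (matrix composition would
  leave an `O(θ·t)` cross term); the skull receives no transform.
* **Deformation noise**: independent normal noise per screw coordinate with
  per-region, per-axis SDs, default largest on the mandible antero-posterior
  axis (the screws loaded by the maxillo-mandibular wiring).

Default error-model means/SDs are calibrated to land in the ranges of the
published aggregate tables (means and SDs read off the limits rows via
`mean=(U+L)/2`, `sd=(U−L)/3.92`); deformation SDs (skull 0.15/0.25/0.20,
maxilla 0.25/0.20/0.20, mandible 0.55/1.20/0.45 mm) reproduce the published
*pattern* qualitatively. No claim is made of matching any printed value —
the generator supplies study-scale realism and exact ground truth, not a fit.

What the generator does **not** emulate: CT acquisition and segmentation
error, surface-registration error, correlated (non-axis-wise) error
structure, screw-bending mechanics, or occlusal constraints coupling the
error draws. Passing tests therefore demonstrate correctness of the
geometry, statistics and decomposition under the stated generative model,
not clinical performance on real scans.

## Numerical choices

* Triads are rejected as degenerate when their triangle area ≤ 1 mm²
  (default, configurable): screws sit centimetres apart, so near-collinear
  triads indicate data-entry errors.
* Screw labels must match between timepoints (same physical screw); a
  mismatch is an input error, never silently re-matched.
* `atan2` is used wherever an arctangent of a ratio appears, for correct
  quadrants.
* Rotation-estimate invariants (`RᵀR = I`, `det R = +1`, unit rotated axis)
  are enforced at 1e−9; noise-free rigid round trips recover translations
  and angles to 1e−9; the decomposition additivity is exact to 1e−12.
* Report CSVs store full precision; the text rendering rounds half-up to
  2 decimals, the precision of the published tables.

## Problem sizes used in the shipped analyses and tests

The shipped drivers analyse one simulated 10-specimen study (seed 42).
Monte-Carlo checks use 500 replicate studies of n = 10 for parameter
recovery (empirical Bland–Altman limits compared with their exact
finite-sample expectation `μ ± 1.96·c₄(n)·σ`, where `c₄(n) =
sqrt(2/(n−1))·Γ(n/2)/Γ((n−1)/2)` corrects for `E[s] < σ`; tolerance 3
Monte-Carlo standard errors), 10,000 replicates for limit coverage, and a
20-instance comparison of the Kabsch estimator against a dense Euler-grid +
local-refinement rotation search (agreement within 0.1°). These sizes give
Monte-Carlo standard errors well below the tolerances they are tested
against.

## Known limitations

* The Euler sequence used by the original analysis software is unknown;
  exact re-derivation of its printed angles is not claimed (order effects
  are second order at ≤ ~8°).
* The published splint rotational RMSD cells are internally inconsistent
  with the splint limits table and are excluded from numerical targets.
* Whether the original deformation residuals were computed before or after
  the barycenter-based pose fit is unstated; the rigid-remainder definition
  used here is recorded as an interpretation.
* The mandible-fixed analysis mode is supported but no published numbers
  exist for it to be checked against.
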