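# Methods

This note documents the models, conventions and numerical choices behind
`airwaymorph`, and what the synthetic cohort does and does not emulate.

## Reference frame

The averaged Frankfort horizontal plane is the leave-one-out average over
{Orbitale_L, Orbitale_R, Porion_L, Porion_R}: each three-point plane's
normal is sign-aligned with an approximate superior direction (by default
the direction from the porion midpoint toward nasion, which lies above the
Frankfort plane), the four aligned normals are averaged and renormalized,
and the plane is anchored at the centroid of the four points.  This
estimator was chosen because it reproduces the exactly coplanar case, is
rotation-equivariant, and is the simplest average consistent with the
leave-one-out construction; proprietary "plane averaging" tools do not
publish their formula.  Degeneracy thresholds: triangle area > 1e-9 mm²,
mean-normal magnitude > 1e-9, nasion–opisthion axis at least 1e-6 away
(relative) from the Frankfort normal.  These sit far below anatomical
scales (tens of mm) and far above double-precision noise.

The canonical frame is +x right, +y anterior, +z superior, origin at the
triple-plane intersection, so the three reference planes become the
coordinate planes and all signed offsets (tongue-to-palate, hyoid depth)
have fixed anatomical meaning.

## Measurement bundle

Measurements are **data, not code**: a declarative spec (kind, operands,
laterality, units, sign) evaluated against the canonical landmark set and
optional closed meshes.  The shipped bundle follows the main published
definitions (HAD: Hyoid–Pog; HPD: Hyoid–anterior C3; IPA: Go_L–Pog–Go_R;
gonial angle: S_Co–Go–Pog; ramus width: Pia–Aia; bigonial: Go_L–Go_R;
tongue offsets as perpendicular distances to the coronal plane through ANS
and the axial plane through the mid-palate).  Definitions that are not
published in full are flagged `provisional` and implemented as reasonable
operand chains: body total length as the Go → mid-body → Pog path, body
width as the inter-mid-body distance, hyoid craniocaudal position as depth
below the Frankfort plane.  Users can override any operand mapping from a
TOML file.  Bilateral measures default to the left/right mean (the
published tables print one value per subject); per-side values are always
retained (`__L`/`__R` rows) because hemifacial asymmetry is part of the
clinical spectrum.  Whether the original analysis averaged sides or
measured one side is not stated; the averaging default is recorded here as
our choice.

Airway compartments are bounded by axial planes through the
vomer/ANS midpoint (naso/oropharynx), the anterior-inferior C2 point
(oro/hypopharynx) and the anterior-inferior C4 point (hypopharyngeal
floor).  Volumes integrate the closed mesh between two parallel planes by
the divergence theorem with the flux field chosen parallel to the planes,
so the flat cut faces contribute nothing: only mesh triangles clipped to
the slab (Sutherland–Hodgman) are integrated.  This is exact for
polyhedra and requires no re-meshing or triangulation engine.  Areas are
midsagittal cross-sections: the closed mesh is sectioned into planar
polygons and clipped against the slab band in section coordinates
(shapely); a `total_surface` interpretation would be an alternative
reading of "airway area" — the midsagittal section is the default because
it is the quantity a sagittal cephalogram approximates.  Units follow
clinical convention: mm, degrees, cm² (areas ÷100), cm³ (volumes ÷1000).

Missing landmarks never abort a subject: frame construction fails loudly
(the subject is excluded with a logged reason), but measurement evaluation
degrades per measurement — a row is flagged unavailable, and a bilateral
mean falls back to the available side with an `unilateral` note.

## Normative growth model and Δ scores

"Regression with logarithmic transformation" is read as the log–log power
law `ln v = α + β ln(age_months)`, i.e. `v = e^α · age^β`, because
craniofacial dimensional growth is concave and saturating and power laws
are the standard parametric choice; the alternative reading (value linear
in ln age) is available as `model="log_age_only"`.  Fits are OLS with
residual SD on n−2 degrees of freedom; ages are months and must be
positive (inputs are clamped to ≥ 1 month upstream).  The deviation score
is `Δ = predicted(control fit, age) − observed`, so a subject whose angle
is 7.1° *wider* than the age-expected control value scores Δ = −7.1°.
One textual ambiguity is worth recording: the source analysis mentions a
"logistic regression equation of each parameter" between the growth
regression and the Δ computation; the only reading consistent with
"differences between estimated values according to the regression
equation and measurement value" and with the growth-curve figures is Δ
against the control growth curve, which is what this package implements.

## Screening statistics

* **Two-group tests**: Shapiro–Wilk at α = 0.05 per group; Welch's t if
  both pass, two-sided Mann–Whitney U otherwise.  The gate and both
  normality p values are recorded so every table is auditable.  Constant
  samples are treated as non-normal (Shapiro is undefined on them).
* **Logistic regression**: maximum likelihood (Newton/IRLS, tolerance
  1e-8, ≤ 100 iterations) via statsmodels; Wald 95% intervals
  `exp(β ± 1.96·SE)`.  Perfect separation, singular information matrices
  and non-convergence raise typed errors; the pipeline records them per
  predictor instead of failing the run.
* **ROC**: AUC is the Mann–Whitney probability (ties ½).  Candidate
  cutoffs are midpoints of adjacent sorted unique scores; the Youden index
  J = sensitivity + specificity − 1 picks the cutoff, ties broken toward
  the smallest threshold.  If the raw AUC is below 0.5 the orientation is
  flipped and reported (`direction="less"`, cutoff on the original
  scale).  The 95% CI uses the DeLong placement-variance estimator by
  default (a seeded 2000-rep bootstrap is a config option).  Whether the
  published −7.1° cutoff was Youden-derived is not stated; Youden is the
  default because a single (sensitivity, specificity) pair was printed.
* **Combined score**: "adding" ΔHAD to ΔIPA means the linear predictor of
  the two-predictor logistic fit — the standard construction, recorded
  here because no combination rule is published.
* No multiple-testing correction and no cross-validation are applied,
  mirroring the study design; all screening performance is therefore
  *apparent* (resubstitution) performance and will be optimistic on new
  data.

## Reliability

Bland–Altman is computed on each observer's Euclidean distance from the
landmark to a per-scan origin (bias, SD with n−1 denominator, limits
bias ± 1.96 SD), on 18 named landmarks over 40 scans (720 pairs) split
across both cohorts.  The origin is never defined in the source; we use
the centroid of the four Frankfort landmarks (averaged over observers),
record the rule in the output, and always report the full 3D placement
error alongside, since a radial scalar can hide tangential disagreement.

## Synthetic cohort

The generator defines the study conditions; its defaults are calibrated
once to the published cohort summaries and are not tuning knobs.

* **Demographics**: 42 subjects per group; age log-uniform over 4–200
  months (populating both dentition strata, ≤ 60 and > 60 months); sex
  Bernoulli(½); difficult-airway prevalence 10/84 ≈ 11.9%.
* **Growth**: each measurement follows `a · age^b` with `a` anchored so
  the control expectation at the 60-month reference age equals the
  published control central value, and `b` derived from the two dentition
  strata where printed (e.g. ramus height 0.21, HAD 0.137, HPD 0.077) or
  set to class defaults otherwise (volumes ≈ 0.4–0.57, areas 0.30,
  angles 0).
* **Group effects**: multiplicative deficits for dimensions (e.g. HAD
  ×0.845, ramus width ×0.86), additive offsets for angles (IPA +9.6°,
  gonial +7.1°) — directions and magnitudes from the published group
  contrasts.
* **Variation**: a shared per-subject log-normal size factor (SD 0.12,
  weighted by each measure's length-dimensionality, so volumes scale ×3
  on the log scale) plus independent per-measurement log noise (SD 0.08);
  angles get additive per-group SDs matching the printed ones (IPA 4.8
  control / 9.6 hypoplasia).
* **Back-propagation**: hypoplasia acts in measurement space and is
  realized by constructing landmarks constraint-by-constraint (bigonial +
  IPA fix the mandibular arch; gonial angle + ramus height place the
  condylion; HAD + craniocaudal depth place the hyoid; the menton depth is
  solved by bracketed root-finding so the hyoid's mandibular-plane
  distance is exact; mid-body points are solved so body width and total
  length are exact).  Geometrically impossible noise draws (≈ 1–3% of
  subjects: body length below the minimal path, hyoid above the gonial
  plane, hyoid unreachable from any mandibular plane) are clamped to the
  feasible boundary and the clamped value *becomes* the latent truth, so
  the invariant "latent values equal noise-free landmark measurements to
  1e-6" holds for every subject.
* **Labels**: Bernoulli(expit(b₀ + ln(1.11)·IPA + ln(0.83)·HAD)) on true
  (noise-free) measurements; b₀ is calibrated to the target prevalence on
  a fixed internal 20 000-draw sample (deterministic).
* **Observers**: two, each seeing truth + isotropic N(0, 0.9² mm) per
  axis, chosen so the inter-observer 3D error averages ≈ 2 mm
  (0.9·√2·2√(2/π) ≈ 2.03), the reported digitization noise scale.
* **Meshes**: the pharynx is a closed polygonal tube (64 segments) of
  per-compartment near-cylinders joined by 0.5 mm frustum blends so no
  boundary plane ever coincides with mesh faces; radii are solved (hybrid
  Newton on log-radii, residual < 1e-8 relative) against the *polygonal*
  cross-section area so mesh compartment volumes equal the latent targets
  to float precision.  Oral cavity and tongue are boxes whose dimensions
  realize both the target volume and midsagittal area exactly.  These are
  calibration solids, not anatomy.

**What passing tests do not show.**  The published oropharyngeal areas and
volumes are mutually inconsistent for any tube-like solid (15 cm²
sagittal area vs 2.6 cm³ at a few-mm compartment height), so the three
pharyngeal areas are geometric consequences of the volume-matched tube
rather than calibrated quantities, and the template-fidelity fixture
covers only the directly constrained measurements.  Real anatomy has
curved, branching, non-convex airways, correlated regional deformity,
left–right asymmetry and age-dependent measurement error — none of which
the generator attempts.  Tests passing on synthetic cohorts validate the
*statistical machinery and geometry*, not clinical performance.

## Problem sizes and determinism

Unit and property tests run on cohorts of 12–84 subjects, icospheres of
~20 000 faces, 200-seed recovery studies and 1000-rep permutation nulls;
the simulate-then-refit odds-ratio round trips use 840 subjects × 50
seeds per predictor.  These sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping the full suite around a
minute.  All randomness flows through `numpy.random.SeedSequence` spawns
from a single seed: cohorts are bit-reproducible, the pipeline report is
byte-identical across runs with the same config, and the acceptance
script is a pure function of `--seed`.

## Known limitations

* The measurement operand chains marked provisional are plausible
  reconstructions, not published definitions.
* Logistic fits on 84 subjects with ~10 events are fragile by nature;
  separation is detected and reported rather than papered over.
* The Δ-score screening is evaluated in-sample, as in the source design.
* The generator's feasibility clamps slightly truncate the extreme lower
  tail of body length (and rare hyoid geometries); group means shift by
  far less than the configured effects.
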