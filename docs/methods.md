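# Methods

## Problem and model

The package quantifies how well skin-surface landmarks over the spinous
processes represent the internal spinal column, for subjects lying in the
lateral decubitus position. Three landmark sources per subject are compared
pairwise in two anatomical planes:

| profile | source | role |
|---|---|---|
| SCP | MRI spinous processes (T1–L5) | internal reference |
| FMP | MRI skin fiducial markers | external markers, same session |
| 3MP | surface-scan markers | external markers, separate session |

All coordinates use one fixed convention: millimetres, +z cephalad,
+y posterior, +x subject-left. The anatomical frame has its origin at the
L1 skin marker; the antero-posterior axis is the substrate normal (the
sagittal plane is parallel to the lying surface); the cephalo-caudal axis is
the unit vector from the PSIS mid-point toward L1 projected into the
substrate plane; the lateral axis completes a right-handed triad.

Each projected source is reduced to a planar profile v(z) by ordinary
least-squares fitting of a degree-7 polynomial (numpy's domain-mapped basis,
so the fit is solved in a variable scaled to [−1, 1] for conditioning). The
fit RMSE against the original landmark coordinates is reported per profile —
it is computed against the source points, not the resampled stations.
Profiles are evaluated at 20 mm stations anchored at the most cephalad point
of the fitted domain (for a pair of profiles, of the overlap of their
domains, so stations match exactly); stations step caudally while they
remain inside the domain.

Distance between two profiles is the matched-station value difference, not
a closest-point distance: RMSD = rms of (v_b − v_a) over shared stations,
with the mean and SD of the absolute differences alongside. Regional RMSDs
split stations at the mid-point between the T12 and L1 markers (a boundary
station joins the region whose defining marker is nearer); thoracic and
lumbar station sets are disjoint.

Curvature at each station uses the plane-parametric-curve formula
k = |x′y″ − y′x″| / (x′² + y′²)^{3/2} with x the cephalo-caudal coordinate
and y the in-plane value, derivatives estimated by finite differences over
the station sequence — central three-point stencils in the interior,
second-order one-sided stencils at the two endpoints. Endpoint curvature
values are included in the KS samples. An analytic mode
(`curvature_analytic`) differentiates the fitted polynomial exactly and
serves as the truncation-error oracle in the tests; on a 200 mm-radius arc
sampled at 20 mm the finite-difference error at interior stations is below
0.1%.

### Statistics

* **KS tests.** Phase 1 compares the two curvature samples across stations;
  phase 2 compares the sampled coordinate values, following the study
  design's explicit distinction. D is the maximum ECDF difference
  (right-continuous, ties by the ECDF convention); the p-value is exact
  (scipy's exact two-sample null distribution, equal to full permutation
  enumeration for continuous data) when n₁·n₂ ≤ 10⁴, otherwise asymptotic:
  the Kolmogorov distribution evaluated at D·√(n₁n₂/(n₁+n₂)). Before the KS
  comparison the pipeline rounds coordinates to 1 nm and curvature to
  10⁻¹² mm⁻¹, so profiles equal up to floating-point noise yield D = 0
  exactly. Significance is p < α with α = 0.05; no multiple-testing
  correction is applied (the report records the number of tests performed).
  Note the exact two-sample test is discrete and therefore conservative at
  small n: its achievable level at n₁ = n₂ = 23 stations is below the
  nominal 0.05.
* **Correlations.** Pearson r with two-sided p from the t distribution on
  n − 2 df, over the per-plane overall/thoracic/lumbar RMSDs and BMI, age
  and gender (coded Female = 1, Male = 2 — a point-biserial correlation).
  |r| ≥ 0.5 is labelled strong, 0.3–0.49 moderate, otherwise low.
  Zero-variance variables produce explicitly flagged undefined entries.
* **Reliability.** ICC(2,1) — two-way random effects, absolute agreement,
  single measures — computed from the ANOVA mean squares per coordinate
  axis between two observer-selection sessions; a consistency variant
  (ICC(3,1)) is available behind a flag. Reliability reports in this field
  rarely state which ICC form their statistics software computed, so the
  absolute-agreement form — the stricter of the two — is the default.
  ICC > 0.81 is reported as "almost perfect agreement".
* **BMI.** weight/height² with classes underweight (< 18.5), healthy
  (18.5–24.9) and overweight (25–29.9); boundaries are inclusive upward
  (18.5 → healthy, 25.0 → overweight). Group contrasts report
  100·(mean(to) − mean(from))/mean(from).

### Rigid alignment

Scan markers are brought into the MRI frame by least-squares rigid
superposition (Kabsch via scipy's `Rotation.align_vectors`; rotation +
translation, no scaling) over the shared labels, with the residual RMS
attached to the transform. If the shared labels are collinear the rotation
about the line is unconstrained; it is resolved by composing the rotation
about that line which minimises the deviation of the mapped
antero-posterior axis from the frame's AP axis, with a warning.

## Synthetic cohort generator

The generator emulates the measurement structure of a 50-subject
lateral-lying MRI + 3DSS validation cohort. Parameters, defaults and
provenance:

* **Skeleton.** Inter-spinous gaps 27 mm (thoracic) and 33 mm (lumbar),
  T1–L5 chain length 462 mm — typical adult values; studies of this design
  do not publish per-level spacings. The sagittal curve is a single quintic
  fixed by Hermite conditions: +kyphosis amplitude (default 28 mm) with zero
  slope at the T7 station, −lordosis amplitude (20 mm) with zero slope at
  L3, zero at the inflection level (T12) and at T1. Building the shape from
  a degree-≤5 polynomial makes the degree-7 fit exact by construction, so
  fit-RMSE properties stay analytic, and pinning the apex at a station makes
  the configured amplitude recoverable exactly. The coronal deviation is the
  same double-arc at small amplitude (default 6 mm, lumbar counter-bow 0.6×,
  random side per subject): a varying-curvature postural S-curve. A
  constant-curvature bow (e.g. a parabola) would give a degenerate
  point-mass curvature distribution that a KS test always separates from any
  noisy counterpart, which is an artefact, not anatomy.
* **Skin markers.** Posterior offset per level = 1.5 mm + 0.9 mm per BMI
  unit + noise, truncated at +0.1 mm so markers are strictly posterior;
  lateral offset = 5.17 mm left bias + noise with SD 2.83 mm (the
  point-to-point statistics reported for this study design, used here as
  generator truth). The per-level noise has the configured marginal SD but
  is spatially correlated along the spine (squared-exponential kernel,
  length 250 mm): the adipose layer deforms smoothly, and uncorrelated
  per-level noise would make the polynomial chase noise and distort the
  curvature comparison for every subject. The marginal distribution per
  level is unaffected by the correlation length, so pooled offset statistics
  (e.g. the left-lateral fraction Φ(bias/SD)) are preserved.
* **Posture misalignment.** Scan markers = fiducials + a quadratic-in-z
  field applied to the lateral (8 mm) and antero-posterior (2 mm) axes with
  per-subject random signs, plus 1 mm isotropic repositioning noise. The
  quadratic basis is orthogonalised against constant and linear trends over
  the stations and normalised to unit maximum, so rigid alignment absorbs
  essentially none of it and the configured amplitude is the post-alignment
  discrepancy. The lateral/AP asymmetry mirrors the empirical finding that
  sagittal posture is reproducible across modalities while coronal posture
  is not.
* **Demographics.** BMI ~ truncated normal (22.82, 3.22) on [16, 31] so all
  three weight classes appear; exact 50/50 gender split via a
  low-discrepancy assignment that is independent of cohort size; integer
  ages ~ N(23.48, 2.79) clipped to [18, 35]; heights ~ N(1.63/1.75, 0.06)
  by gender, weight derived from BMI.
* **Observer sessions.** Designated subjects carry session-2 duplicates of
  their MRI selections with 0.5 mm isotropic noise, feeding the ICC
  analysis.
* **Seeding.** All randomness derives from one master seed through
  per-subject, per-stage seed sequences: identical (config, seed) gives a
  byte-identical cohort, and adding a subject never perturbs earlier ones.

Amplitude defaults (coronal 6 mm, correlation length 250 mm, lateral posture
8 mm) were calibrated once, coarsely, so the default cohort lands in the
ranges such studies report (sagittal skin-to-bone RMSD ≈ 22 mm, phase-1
curvature KS non-significant for essentially all subjects, phase-2 coronal
non-significance near 60–70%), and then frozen.

## What the generator does and does not emulate

Passing tests demonstrate that the pipeline recovers the structure the
generator encodes — BMI-driven posterior offsets, curvature-preserving
smooth soft-tissue artefact, posture-driven coronal irreproducibility,
near-perfect observer reliability — at realistic magnitudes and sample
sizes. They do not certify performance on real images. Known gaps:

* Between-subject adipose variance beyond BMI is not modelled, so the
  BMI–sagittal-RMSD correlation is stronger (r ≈ 0.9) than observed in real
  cohorts (≈ 0.6).
* Lateral offsets are BMI-independent, so the coronal RMSD does not
  correlate with BMI as real data suggest it does, and posture misalignment
  is BMI-independent, so phase-2 non-significance shows no gradient across
  weight classes.
* All subjects share the same skeletal curve; inter-individual shape
  variation enters only through soft tissue. Real spines vary in kyphosis,
  lordosis and segment lengths.
* Landmarks only: no surface meshes, images or palpation/selection error
  models beyond isotropic noise.

## Numerical choices and degenerate inputs

* Polynomial fits require at least degree + 2 distinct-z points; duplicate
  z values are rejected.
* Station matching between sampled profiles uses a 10⁻⁶ mm tolerance on z;
  regional RMSD needs at least 3 stations in the region.
* Exact zeros in signed lateral differences count as *not* left.
* The left-lateral station fraction and signed statistics attach only to
  coronal comparisons.
* A landmark set expressed in its scanner's own frame is exempt from the
  cephalo-caudal monotonicity invariant, which is a property of the
  anatomical convention.
* Frame construction rejects coincident L1/PSIS-mid-point inputs and
  L1–PSIS lines parallel to the substrate normal.
* ICC of two identical sessions is defined as 1 even when the
  between-target variance is zero.
* Subjects without a scan set are retained for phase 1 and excluded, with a
  log message, from phase 2.

## Problem sizes used in tests

The simulation-based tests use 50-subject cohorts: 100 seeded replicates
for the BMI-slope power and null checks, three seeds per rung of a
four-rung posture-amplitude ladder, and 4000 null replicates at n = 60 per
sample for the KS type-I calibration (a sample size at which the discrete
exact test admits a level close to the nominal 0.05). The acceptance script
analyses one 50-subject cohort plus 20 replicate cohorts for the power
estimate.
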