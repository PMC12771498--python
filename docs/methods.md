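# Methods

This note documents the models, conventions and design choices behind
`dprfeas`, in the spirit of a package reference manual: what is computed, how
the unavoidable ambiguities were resolved, and what the synthetic cohort does
and does not establish about clinical data.

## Geometry and sampling conventions

All volumes live on regular grids with a voxel-center convention: the
physical coordinate of index $(i,j,k)$ is `origin + index * spacing`
(0-based, mm).  Axes are $(x, y, z)$ = left–right, posterior–anterior,
inferior–superior.  Masks are strictly binary; membership is decided at the
voxel center with no partial-volume weighting, which keeps every metric
exactly reproducible by brute-force enumeration.

Masks are resampled with nearest-neighbour interpolation only (they must
stay binary); dose is the physical field and is never resampled for metric
evaluation — when mask and dose disagree on lattice, the *mask* moves to the
dose grid, and the relative-volume denominator is the resampled mask's
volume so numerator and denominator stay consistent.  The one place dose is
interpolated is the virtual couch shift, where the whole field is rigidly
translated with trilinear interpolation.

Registrations between fraction frames are translation-only, computed as the
displacement of an anchor structure's centroid (prostate by default,
configurable).  Online prostate matching is dominated by translation, and
nothing in the pipeline requires rotations; user-supplied full rigid
transforms (orthonormal, det +1) are accepted throughout.  Margin expansion
(CTV→PTV) is an ellipsoidal, direction-dependent dilation: a voxel joins the
expanded set when it lies within the margin ellipsoid of any input voxel,
with independent margins per axis direction.  The default margins, 5 mm
isotropic with 3 mm posterior, are a package default chosen as typical for
MR-guided prostate SBRT — they are **not** a protocol value from any
specific study.

## Dose-volume metrics

* `v_dose` uses an inclusive comparison (`dose >= threshold`), so a uniform
  dose exactly at threshold scores 100 %.  Treatment planning systems do not
  agree on this convention; it is fixed here and stated so results are
  interpretable.
* `d_percent` is the exact order statistic: with $n$ in-structure voxels,
  $D_{p\%}$ is the $\lceil p n / 100 \rceil$-th largest voxel dose — the
  largest dose received by at least $p\%$ of the volume, with lower-value
  tie-breaking and no interpolation.  Interpolated variants differ by less
  than the voxel-dose granularity; the chosen form matches a brute-force
  oracle bit for bit, which the test suite exploits.
* No claim of numerical parity with any commercial system is made anywhere;
  interpolation conventions inside such systems are not public.

## Criteria A, B, C

Constraint rows carry optimal / mandatory / marginal bounds with inclusive
satisfaction (a value exactly at a bound satisfies it, consistent with
strict inequalities defining the unacceptable region).  Targets compare with
$\ge$, OARs with $\le$.  The urethra hot-volume row cannot render a plan
unacceptable (it has no unacceptable region) and is encoded with
`can_be_unacceptable=False`.

**Marginal budget.**  Marginal target coverage is allowed for one fraction
per course.  The budget is charged along the *delivered* sequence: when a
fraction's approved plan needed marginal coverage, later candidates see an
exhausted budget.  Candidate repository plans are evaluated against the
budget state produced by the delivered fractions but do not themselves
consume it (they were not delivered).  A `budget_mode="fresh"` switch
evaluates every fraction against an unused budget instead, since the
fraction-by-fraction accounting of a retrospective what-if analysis is
genuinely ambiguous; "delivered" is the default as the conservative reading
of a once-per-course allowance.

**Criteria B derivation.**  For each target metric the new mandatory bound
is $\min(P_{25}, A)$ over the pooled benchmark values; for each OAR metric
$\max(P_{75}, A)$.  Percentiles use linear interpolation between order
statistics — the convention under which the published cohort summary
statistics reproduce exactly — and the pool must hold at least four values
per metric.  If a relaxed target bound crosses the marginal bound, the
marginal bound is clamped down to preserve the row ordering (not exercised
by the shipped tables).  The shipped `criteria_b_study.json` carries the two
clinically observed relaxations (PTV $D_{98\%}$ 32.38 Gy; rectum $V_{36}$
3.04 cm³).

**Criteria C tolerance.**  "Equivalent or better" is implemented with a
relative tolerance of $10^{-6}$ per metric, purely to keep float noise from
flipping verdicts.  The candidate's statistics are evaluated on the daily
anatomy while the approved plan's are evaluated on the verification anatomy,
exactly as the two pipelines produce them; no attempt is made to harmonize
the anatomy source, because in a reuse workflow the verification image of a
skipped replanning session would not exist.

## Benchmark (CCPB)

The benchmark copies verification contours onto the approved plan's dose
without motion compensation — it deliberately measures what intrafraction
motion did to the delivered plan.  For fractions whose online coverage check
(default: PTV$_{psv}$ $V_{36.25} \ge 90\%$ on the verification anatomy,
configurable) failed, a virtual couch shift is applied first: the dose field
is translated by the anchor structure's planning→verification displacement.
This is a deliberately simple surrogate for segment-aperture morphing and
segment-weight re-optimization in a commercial online optimizer; dose is
never recomputed, only rigidly moved, and density overrides are out of
scope.  The shift errors out if it would push the half-maximum dose region
off the grid.

## Repository assessment

At fraction $n$ the repository is the reference plan plus the online plans
of fractions $1..n-1$ (an excluded, corrupted fraction contributes neither
an assessment nor a plan).  Backward propagation registers the daily
structure set to the stored plan's frame and nearest-neighbour-resamples
every contour onto the plan's dose grid.  If propagation fails — a contour
pushed entirely off the stored plan's grid by extreme motion — the plan is
marked unassessable for that fraction and conservatively counted not
acceptable.  All acceptable plans are reported; no ranking among them is
implemented.

Cohort aggregation reports, per patient, $N$ and % of assessable fractions
with at least one acceptable plan per criteria set, then cohort
median/IQR/mean/SD of both (linear-interpolation quartiles, sample SD with
$n-1$).  Reports round percentages to integers and counts/bounds to two
decimals; CSV files retain raw values.  The same aggregation restricted to
single candidates — the offline reference plan everywhere, or the
per-fraction reference (offline plan at fraction 1, the fraction-1 online
plan thereafter) — quantifies what the repository adds over one-plan reuse.

## Synthetic cohort

The generator emulates the *design* of a nine-patient, five-fraction
prostate cohort at 36.25 Gy, not any patient population.  Defaults: 2.5 mm
isotropic grid over a 100×118×128 mm pelvic volume; ellipsoidal prostate
(~30 cm³), seminal vesicles, bladder, rectum tube 1–2 mm behind the PTV,
bowel, and an intra-prostatic urethra; per-patient variation of ±4 % radius
and 2 mm OAR position.

**Dose surrogate.**  Conformal and geometric: prescription inside the PTV
with a smooth interior boost rising to $(1+b)\,\mathrm{Rx}$ ($b = 0.2$,
ramp $\sigma_{in} = 1.5$ mm) so the CTV clears the 40 Gy coverage goal as a
real SBRT hotspot does; outside, the prescription isodose keeps 1 mm of
flash beyond the PTV (robust plans do not collapse at the PTV surface) and
then falls off as a Gaussian with $\sigma = 4$ mm.  Every quantity the
analysis consumes is a dose-volume statistic of a static field, so beams,
heterogeneity and optimizer behaviour need no modelling.  A calibration
self-check asserts that the reference plan on its own anatomy satisfies the
clinical goals; violating geometry raises a configuration error naming the
failing metrics.

**Motion model.**  Interfraction: a global rigid translation (SD 3 mm/axis,
removed by prostate-anchored registration) plus per-organ displacements
relative to the prostate, each the sum of a systematic random walk across
fractions (bladder/rectum/bowel 2 mm, seminal vesicles 2 mm per axis per
fraction) and an independent day-to-day component (3 mm and 2.5 mm
respectively).  The walk is what makes recent plans genuinely better than
the reference — without it, the reference plan would be statistically as
good as yesterday's plan and a repository would add nothing.  Intrafraction:
a 1.5 mm/axis drift (optionally biased) applied to all organs between daily
and verification anatomy.  Bladder and rectum radii jitter by 10 % per
fraction (filling).  Swelling patients scale prostate (and urethra) radii by
$(1+r)^{k/3}$ at fraction $k$ (volume factor $(1+r)^k$); the default cohort
designates one patient with $r = 0.5$.  All magnitudes are scenario
parameters chosen to produce a mixed acceptability pattern — some fractions
reusable, some not — at defaults; they are not estimates of any measured
population, which is why the acceptance checks assert combinatorial,
calibration and monotonicity properties rather than specific cohort
percentages.

**What the synthetic cohort does not show.**  Organs are rigid ellipsoids:
no deformation, no rotation, no contouring uncertainty, no dose-calculation
error, no imaging.  Passing tests demonstrate that the *analysis machinery*
is correct and that its qualitative behaviour (repository superset benefit,
motion sensitivity, swelling failure mode) is right; they do not predict
clinical reuse rates.

**Problem sizes.**  The shipped tests and the acceptance script run the full
nine-patient cohort at 2.5 mm resolution (a few seconds to simulate, ~10 s
to assess 130 propagations) and use smaller cohorts (1–2 patients, 3–5
fractions) for property sweeps across seeds; these sizes were chosen as
comfortably sufficient for the combinatorial and monotonicity properties
being checked.

## Numerical details and edge cases

* Percentile convention everywhere: NumPy's default linear interpolation.
* Empty structure on the dose grid → `ValueError("undefined metric")`; an
  ellipsoid without a single voxel center → `"empty structure"`.
* Nearest-neighbour resampling of a sub-voxel translation erodes/accretes a
  one-voxel surface shell; the tests bound this by the surface voxel count
  and the assessment treats it as genuine (a stored plan really is evaluated
  through a lattice).
* Seeds: each patient draws from `default_rng([seed, patient_index])`, so a
  cohort is reproducible patient-by-patient and byte-identical CSV outputs
  across reruns are asserted in the tests.
* The NIfTI interface accepts only axis-aligned, positive-diagonal affines;
  DICOM-RT import is limited to axis-aligned orientations and regular slice
  spacing, with RTSTRUCT polygons rasterized by point-in-polygon tests at
  voxel centers.

## Known limitations

Rigid, translation-only propagation; a geometric dose surrogate with no
claim of dosimetric realism beyond conformal falloff; acceptability reduced
to dose-volume constraints (clinical review weighs dose distributions and
patient-specific context); no plan ranking when several candidates pass; and
the Criteria-C comparison inherits the daily-vs-verification anatomy
asymmetry of the underlying workflow.
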