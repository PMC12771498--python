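# dprfeas — feasibility of treatment-plan reuse in online adaptive radiotherapy

Online adaptive radiotherapy (oART) generates a fresh, anatomy-of-the-day
treatment plan at every fraction — and then throws it away.  For a
hypofractionated prostate course on an MR-linac this makes every session slow
and resource-hungry.  `dprfeas` implements the analysis behind a simple
question: *at each fraction, would any of the previously generated plans (the
offline reference plan plus every online plan so far — the Dynamic Plan
Repository, DPR) have been dosimetrically acceptable for today's anatomy?*
If yes, the session could skip replanning entirely.

The package is aimed at medical-physics researchers studying plan-reuse and
plan-of-the-day strategies.  It provides the full pipeline as a library with
a thin CLI: dose-volume metrics, criteria grading, the empirical benchmark,
backward contour propagation, cohort aggregation, and a synthetic cohort
generator so the whole analysis runs end to end from a seed.

## The method

For a course with fractions $n = 1 \dots N$ (prescription 36.25 Gy in five
fractions):

* **Metric panel.**  For structure $s$ and dose $D$,
  $V_{x\,\mathrm{Gy}}(s)$ is the volume of $s$ (absolute cm³ or % of $s$)
  receiving $\ge x$ Gy, and $D_{p\%}(s)$ is the largest dose $d$ such that at
  least $p\%$ of $s$ receives $\ge d$ (an exact voxel order statistic).  The
  panel covers CTV/PTV coverage (CTV$_{psv}$ $V_{40}$, PTV$_{psv}$
  $V_{36.25}$, PTV$_{psv}$ $D_{98\%}$) and bladder, rectum, bowel and urethra
  sparing.
* **Benchmark (CCPB).**  Each fraction's *approved* plan is re-evaluated on
  the verification anatomy acquired just before delivery (with a virtual
  couch shift first when the online coverage check had failed).  Pooling
  these statistics over the cohort gives the Current Clinical Practice
  Benchmark.
* **Criteria A / B / C.**  A: every OAR metric meets its mandatory clinical
  goal and targets meet theirs, with *marginal* target coverage allowed for
  at most one fraction per course.  B: the same rule against empirically
  relaxed bounds — for targets $\min(P_{25}, \text{goal})$, for OARs
  $\max(P_{75}, \text{goal})$ of the pooled benchmark.  C: B, plus a
  candidate is accepted when the approved plan itself violated B and the
  candidate is equivalent-or-better on every metric.  By construction
  $A \Rightarrow B \Rightarrow C$.
* **Repository assessment.**  At fraction $n$ the repository holds
  $\mathrm{DPR}_0$ (reference) and $\mathrm{DPR}_{1..n-1}$.  The day's
  contours are registered (translation on the prostate centroid) and copied
  backwards onto each stored plan's dose, the panel is evaluated, and each
  plan is graded under A/B/C.  Per patient, the result is the number and
  percentage of fractions with at least one acceptable stored plan; across
  patients, median/IQR (linear-interpolation quartiles) and mean/SD
  (sample SD).

## Worked example

`examples/04_assess_course.py` simulates one five-fraction course and asks,
at every fraction, which stored plans would have been acceptable:

```
                    Tx1             Tx2             Tx3             Tx4             Tx5
plan_id
DPR_0      unacceptable    unacceptable    unacceptable    unacceptable    unacceptable
DPR_1    not_applicable    acceptable_A    acceptable_A    unacceptable    acceptable_A
DPR_2    not_applicable  not_applicable    unacceptable    unacceptable    unacceptable
DPR_3    not_applicable  not_applicable  not_applicable    acceptable_A    acceptable_A
DPR_4    not_applicable  not_applicable  not_applicable  not_applicable    acceptable_A
DPR_5    not_applicable  not_applicable  not_applicable  not_applicable  not_applicable

fractions with >=1 acceptable stored plan: A 4/5, B 4/5, C 4/5
```

Rows are stored plans, columns fractions.  The offline reference plan
(`DPR_0`) is never good enough for this patient's drifting anatomy, but
recently generated online plans often are — four of five fractions could have
reused a stored plan at full clinical goals.  `not_applicable` marks plans
that did not exist yet.

The other examples cover the metric panel (`01`), criteria grading (`02`),
benchmark pooling and the Criteria-B derivation (`03`) and the cohort-level
summary with reference-only comparisons (`05`).  The CLI mirrors the same
stages on files:

```bash
dprfeas simulate --out cohort/ --seed 1
dprfeas run --manifest cohort/manifest.json --out results/
```

## Layout

```
src/dprfeas/
  geometry.py    grids, masks, margins, rigid transforms, registration
  metrics.py     V_xGy / D_p% extraction
  criteria.py    constraint tables, grading, A/B/C, marginal budget
  ccpb.py        verification benchmark, virtual couch shift, pooling
  dpr.py         repository build, backward propagation, aggregation
  synthetic.py   seeded pelvic cohort generator
  io.py          NIfTI + manifest + CSV interchange
  dicom_rt.py    RTDOSE / RTSTRUCT import
  pipeline.py    stage orchestration
  cli.py         thin command-line front end
```
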