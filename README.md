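# spiroqc

Automated quality assurance for spirometry — the forced-expiration test at
the core of respiratory diagnostics. A maneuver is only as good as its
execution: a hesitant start inflates the back-extrapolated volume, a cough
in the first second corrupts FEV₁, glottic closure or an early stop
truncates FVC, and the ATS/ERS 2019 technical standard prescribes exactly
which of these faults make an index *unacceptable*, merely *usable*, or
worthless. Applying those rules consistently requires both quantitative
checks and trained visual inspection of the flow–volume and volume–time
curves — expertise that is scarce in primary care, where most spirometry is
now performed.

`spiroqc` implements the full rule set as code:

* **Indices** — back-extrapolated time zero and volume (BEV), FEV₁, FVC,
  PEF, time-to-peak-flow, forced expiratory time, end-of-test plateau, and
  the three-way end-of-forced-expiration (EOFE) rule.
* **Artifact detection & localization** — deterministic signal-domain
  detectors for cough, glottic closure, mouthpiece/device flutter, extra
  breath, early termination, hesitant start and variable flow, each
  reporting a time interval and a volume landmark on both curve
  representations.
* **Acceptability / usability / grading** — per-maneuver verdicts for FEV₁
  and FVC separately, session grades A–F/U from counts of acceptable
  maneuvers and the repeatability of the two largest values
  (A: ≥3 acceptable, Δ ≤ 0.150 L … U: usable only, F: nothing usable),
  plus operator warnings and patient instructions from a message catalog.
* **Simulator** — a two-phase (rise + exponential decay) forced-expiration
  generator with seven injectable artifact classes and exact ground-truth
  labels, so the whole pipeline is testable with no patient data.
* **Evaluation statistics** — balanced accuracy, sensitivity, specificity,
  PPV, NPV; exact-match grade accuracy; and chi-squared comparison of
  quality proportions across groups (e.g. monthly batches of a quality
  programme).

## Worked example

Simulate a small labeled cohort, assess it, and score the assessments
against the generator's ground truth:

```sh
$ spiroqc simulate --n 4 --seed 3 --profile 0.5 --out demo
$ spiroqc assess demo/sim*.json --format text
sim0001: FEV1 grade A, FVC grade A
  m1: FEV1 2.47 L, FVC 2.72 L [AA] clean
  ...
sim0003: FEV1 grade A, FVC grade B
  m1: FEV1 3.41 L, FVC 3.75 L [AA] clean
  m2: FEV1 3.39 L, FVC 3.73 L [AA] clean
  m3: FEV1 2.79 L, FVC 3.08 L [AU] glottic_closure@1.33s
  ! Glottic closure detected: FVC is underestimated in this maneuver.
```

Session `sim0003` carries an injected glottic closure: maneuver m3's flow
ceases abruptly at 1.33 s, so its FVC (3.08 L, ~0.65 L short of its
siblings) is *usable but not acceptable* (`[AU]`), the session's FVC grade
drops to B (two acceptable maneuvers, Δ ≤ 0.150 L), and the operator is
warned. FEV₁ is untouched — the closure happened after the first second —
so the FEV₁ grade stays A.

```sh
$ spiroqc evaluate --truth demo/truth.json demo/sim*.json
fvc_acceptable: balanced 100.0 | sens 100.0 spec 100.0 | ...
FEV1 grade accuracy: 100.0%
FVC grade accuracy: 100.0%
```

The same operations are available as a library (`read_session`,
`compute_indices`, `scan_artifacts`, `assess_session`, `grade_session`,
`generate_cohort`, `confusion_metrics`, `monthly_quality_comparison`);
every threshold lives in `QCConfig` and can be overridden from a JSON
config file. The session file schema is documented in
`spiroqc.session`.

## Scope

`spiroqc` judges maneuver *quality*, not lung function: no predicted
values, z-scores, or obstruction/restriction interpretation; no BTPS
correction; no vendor PDF or device-driver I/O (sessions are structured
JSON or two-column CSV); no leak criterion. See `docs/methods.md` for the
model, thresholds, and known limitations.
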