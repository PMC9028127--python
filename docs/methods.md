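# Methods

This note documents the quantitative model behind `spiroqc`: what each
operation computes, the thresholds and their defaults, what the simulator
does and does not emulate, the numerical choices, and the design decisions
taken where the standard or common practice leaves room.

## Data model

A maneuver is a uniform 0.01-s grid with cumulative exhaled volume (L,
BTPS assumed) and expiratory flow (L/s, positive during expiration).
Time 0 is the recording start, *not* the back-extrapolated time zero —
raw data stay raw, and t₀ is computed downstream. When a file carries
both channels the flow channel wins and a |flow − dV/dt| mismatch above
0.05 L/s (after 5-sample smoothing, interior samples only) is warned
about, not rejected: differencing a volume channel amplifies
quantization and sensor noise, and the two channels of real devices are
never numerically identical. A missing flow channel is reconstructed by
centered finite differences.

Irregularly sampled imports are resampled with monotone cubic (PCHIP)
interpolation. Shape preservation matters (volume is monotone outside
artifacts), and at typical coarse export intervals (0.05 s) PCHIP lands
within ~1e-4 L of a smooth underlying curve where linear interpolation
errs by several mL — material against the 1 mL-scale tolerances used
elsewhere. On the canonical grid itself all lookups (FEV₁ at t₀ + 1 s,
BEV at t₀) are linear: at 0.01-s resolution the quadratic interpolation
error is below 1 mL for physiological curvature.

## Indices

* **Back-extrapolation.** t₀ is the V = 0 intercept of the tangent at
  the maximal smoothed volume slope (moving average, `smooth_window` = 5
  samples; raw differencing at 0.01 s is noise-dominated and the
  standard's "steepest slope" prescribes no smoother). BEV is the
  measured volume at t₀. The construction is exact on piecewise-linear
  curves: a hesitation of slope s₁ followed by a blast of slope s₂
  through (t₁, V₁) yields t₀ = t₁ − V₁/s₂ identically.
* **End of expiration.** The last sample whose smoothed flow exceeds the
  zero-flow floor (`zero_flow_floor` = 0.025 L/s), before any sustained
  (≥ 0.2 s) inspiratory segment. The floor prevents FET inflation by
  sensor drift; the inspiration cutoff stops the clock when the subject
  demonstrably stopped exhaling. FET = that time minus t₀.
* **Plateau.** True iff volume changes ≤ 0.025 L over the trailing 1-s
  window of the *recorded* expiration (up to a sustained inspiration, if
  any — deliberately not truncated at the flow floor, since a subject
  holding a true plateau exhales below the floor for seconds). The
  onset is the earliest time such that every trailing window ending at
  or after it complies; onset times refer to the window's end. On
  V = 4(1 − e^{−t/0.4}) this gives onset ≈ 3.0 s, the closed-form
  crossing of 4e^{−t/0.4}(e^{2.5} − 1) = 0.025.
* **EOFE.** Met by plateau, or FET ≥ 15 s, or FVC within 0.150 L of the
  session's best FVC among the *other* usable maneuvers. Excluding
  self-comparison is deliberate: the best maneuver (or a singleton
  session) must not confirm its own end-of-test by tautology.
* **FEV₁** is V(t₀ + 1 s) − V(t₀) by interpolation (not nearest sample)
  and is *absent* when the record ends earlier — surfaced as a failed
  `fev1_measurable` criterion, not a crash. FVC is max cumulative
  volume minus V(t₀); PEF and tPEF come from the raw flow channel after
  t₀ (smoothing would clip a genuine sharp peak).

## Artifact detection

The detectors replace image-based visual inspection with signal-domain
rules. All fractional thresholds are relative to a *local flow
envelope* so they are scale-free across subjects; each finding carries a
time interval, the volume at onset (localizing it on the flow–volume
loop), and a score in [0, 1] — the observed amplitude as a multiple of
its threshold, mapped by min(1, ratio/2). The score is a documented
monotone surrogate for confidence, not a calibrated probability.

* **Envelope.** A 0.3-s running median of smoothed flow for flutter and
  general use. The cough detector instead references a short (0.08 s)
  *trailing maximum*: a median window long enough to bridge a ~0.12-s
  dip is dragged down by the dip plus the decay and hides the
  transient, while a trailing maximum cannot be captured by the dip and
  never looks ahead (a rising flow is never below its own reference).
  The apparent "dips" a trailing maximum creates on clean monotone
  decay are rejected by the rebound requirement below.
* **Cough**: drop ≥ 25% of the reference with recovery ≥ 15% within
  0.5 s, during expiration, transient length ≤ 0.5 s (longer sustained
  oscillation is flutter territory). The reported interval is extended
  one reference-lookback before the threshold crossing so it covers the
  physical onset.
* **Glottic closure**: flow falls from above 10% of PEF to below the
  zero-flow floor within 0.1 s and stays there ≥ 0.25 s (or to the end
  of the record), with no plateau already established; at most one
  finding, its onset sharpened on the raw flow channel.
* **Flutter**: 5–15 Hz band-passed flow (3rd-order Butterworth,
  filtfilt) whose oscillation amplitude (RMS tracker scaled to peak)
  reaches 15% of the envelope for ≥ 0.3 s where the envelope is at
  least 0.3 L/s (below that, relative amplitude is meaningless).
* **Extra breath**: flow below −0.05 L/s for ≥ 0.15 s with expiratory
  flow (≥ 0.1 L/s for ≥ 0.1 s) resuming afterwards; a terminal
  inspiration is not an extra breath — the recording simply ended.
* **Early termination**: flagged over the final 1-s window iff neither
  plateau nor long FET holds and no glottic closure explains the stop;
  the session-level repeatability branch is resolved later by the QC
  layer.
* **Start-of-test**: hesitant start iff BEV > max(0.100 L, 5% FVC);
  otherwise variable flow iff tPEF > 0.15 s.
* **Scan**: union of all detectors sorted by onset; overlapping
  cough/flutter findings resolved in favor of the higher score (ties to
  the cough, the briefer explanation).

Detectors are pure functions — bit-reproducible, time-translation
invariant, with no learned parameters.

## Acceptability, usability, grading

The decision table ships as data (`spiroqc/data/decision_table.json`):
criterion id → affected index, phase window, and whether failure voids
acceptability only or usability too. Union-of-failures: any failed
criterion from either the rule checks or the detectors voids the
affected verdict. Key rows: BEV over limit voids usability of both
indices; cough/closure/flutter overlapping [t₀, t₀+1 s] void FEV₁
usability; extra breath or flutter anywhere voids FVC usability; a
closure at any time, or an unexplained early termination, voids FVC
acceptability. Two deliberate choices where practice varies: flutter
counts against both indices (a corrupted flow channel corrupts both),
and an early-termination finding only voids FVC acceptability when the
EOFE rule *including* the repeatability branch is unmet — otherwise the
repeatability branch could never rescue anything, because the finding
fires exactly when plateau and FET fail.

Because the repeatability branch is session-relative, assessment is
two-pass: all maneuvers are assessed without session context to collect
usable FVCs, then re-assessed with each maneuver's distance to the best
other usable FVC.

Grades per index: A (≥3 acceptable, top-two Δ ≤ 0.150 L), B (2, Δ ≤
0.150), C (≥2, Δ ≤ 0.200), D (≥2, Δ ≤ 0.250), E (≥2 with Δ > 0.250, or
exactly 1), U (0 acceptable, ≥1 usable), F (nothing usable). Pediatric
tiers (age ≤ 6 years: 0.100/0.150/0.200 L) sit behind the subject-age
switch and default to adult tiers when age is absent. Deltas use only
acceptable maneuvers' values. Note the tier table is *not* monotone in
maneuver quality: a newly acceptable maneuver with a higher value can
inflate the top-two delta and worsen the letter (acceptable values
[4.0, 3.9] grade B; adding an acceptable 4.5 gives Δ = 0.5, grade E).
This is a property of the standard's table, reproduced faithfully and
frozen in a test.

Messages: one operator warning and one patient instruction per distinct
failed criterion id (deduplicated across maneuvers, sorted by id), plus
a repeat-maneuver prompt when either index grades below C. The catalog
is data (`messages.json`) and the mapping is a pure function of the set
of failed ids.

## Simulator

The clean template is two-phase: flow rises to PEF over `rise_time`
(default 0.08 s) as a sin² ramp — same junction volume as a linear ramp
(PEF·rise/2) and identical tangent closed forms, but without the slope
discontinuity a real pneumotach never records — then decays
exponentially toward FVC. The decay constant is fixed by flow
continuity at the junction, τ' = (FVC − V_junction)/PEF; an explicit
`tau` is honored as the decay constant, in which case the realized FVC
follows from continuity (the (FVC, PEF, τ) triple is over-determined).
Gaussian flow noise (default SD 0.02 L/s, a plausible digitization/
sensor level at 100 Hz) is added last; volume is always the running
integral of flow, so the two channels are consistent by construction.

Artifact injectors transform the flow channel: multiplicative sin² dip
(cough, strong regime magnitude ≥ 0.35), zeroed flow plus a short flat
tail (closure), multiplicative 10-Hz sinusoid (flutter, strong ≥ 0.2),
an inspiratory sin² bump inhaling a prescribed volume then resumed
decay (extra breath), a low-slope prefix exhaling a prescribed volume
(hesitant start), and truncation (early termination). Ground truth —
(kind, onset) labels, noise-free index values, and the QC flags the
injection is *designed* to produce — is computed from the generator's
own closed forms and noise-free series, never from the analysis
pipeline. Expected session grades apply the grading tiers to those
intended flags and values.

One cohort seed fans out to per-maneuver substreams by a stable hash of
(session id, maneuver id), so datasets are bit-identical for a fixed
seed and independent of generation order. The default cohort draws FVC
uniformly on 2.5–5.5 L, three maneuvers per session, one artifact
maneuver in a violation session; the default artifact mix is uniform
over the six injectable kinds — real artifact prevalence varies by
setting and no claim of realism is made for the mix. Slower decays
(PEF/FVC 1.3–1.6 instead of 2.2) are used for closure, extra-breath and
termination injections so their timing constraints (e.g. flow still
above 10% PEF at closure) hold across the FVC range.

What the simulator does **not** emulate: pediatric physiology, disease
loops (obstructive concavity, restriction), device-specific noise
spectra, BTPS drift, and leak. Passing tests therefore demonstrate
that the rule set and detectors are implemented correctly and behave
sensibly on physiologically shaped curves — not that detection
performance transfers to any particular device or population.

## Evaluation statistics

Balanced accuracy is defined as (sensitivity + specificity)/2 exactly —
an identity asserted on every computed result. Ratios with zero
denominators are reported as `None` and listed in `undefined`, never
silently zeroed: with imbalanced classes a silent zero masquerades as
poor performance. Display rounding is half-up to one decimal, the
convention of clinical tables (94.25 → 94.3; banker's rounding would
disagree). Group proportions are compared with Pearson's chi-squared
test on the k×2 table, *without* continuity correction — at the count
sizes this package targets the correction is immaterial, and the
uncorrected statistic matches the textbook 2×2 formula used as the test
oracle; p-values below 1e-4 display as "< .0001".

The detection benchmark (200 single-artifact maneuvers with clean
mates, strong-regime strengths, seeded) reports per-kind recall and the
clean-curve false-positive rate; at the shipped defaults recall is
≥ 0.95 for every kind with a clean false-positive rate ≤ 0.05. Problem
sizes throughout (200-maneuver benchmark, 60-session cohorts) were
chosen as the smallest that make binomial noise negligible against the
0.95/0.05 margins.

## Known limitations

* Detector thresholds are surrogates for visual criteria, validated
  against this package's own simulator, not against annotated patient
  curves; the scores are uncalibrated.
* The session schema is a reconstruction of the numeric intermediate
  form device reports reduce to; no vendor format is parsed.
* Artifact classes outside the seven-kind taxonomy (notably leak) are
  out of scope.
* The FVC-repeatability EOFE branch depends on which maneuvers are
  usable and is therefore only as good as the usability verdicts
  feeding it.
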