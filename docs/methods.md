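# Methods

This note documents the models, rules and numerical choices behind
`labharbor`, in the order data flow through the package.

## The registry schema

A REDCap project is defined by its data dictionary (DD): one CSV row
per field, giving the variable name, instrument (form), field type and
text-validation rule. The packaged default dictionary defines:

- a repeating **labs** instrument with 35 number-validated value fields
  (sodium through absolute eosinophil count, grouped into four panels:
  electrolytes/renal/glucose, general chemistries, liver function,
  hematological), plus one shared collection-date field (M/D/Y) and one
  collection-time field (HH:MM) per instance;
- non-repeating **subject_status** (death date, last follow-up date) and
  **patient_characteristics** (diagnosis date) instruments.

Two composition choices were genuinely open and are fixed as follows:

- **Which labs are stored.** The full clinical panel runs to 40+ tests
  once rare differential components and derived indices are included.
  The packaged instrument stores 35 primitive fields and treats derived
  indices (e.g. the neutrophil-to-lymphocyte ratio) as analysis-time
  arithmetic on stored fields, not as data. Rare differential
  components (basophils, immature granulocytes, nucleated RBCs, LDH)
  are left to site-specific extension. The default dictionary is a
  working fixture meant to be edited; nothing downstream assumes the
  specific 35.
- **Instance semantics.** One repeating-instrument instance = one
  collection event (record id + date + time), so all labs drawn
  together share an instance and its date/time, and a repeat draw on
  the same day opens the next instance. This is what lets the same lab
  be captured more than once per day without overwriting.

The DD-CSV itself does not record which instruments repeat (REDCap
keeps that in project settings), so the reader marks a form named
`labs` as repeating by default, with an override parameter. Unknown
DD-CSV columns are carried opaquely so foreign dictionaries round-trip
byte-identically.

### Value validation

Validation mirrors what REDCap's import tool enforces:

- **number** — a plain decimal numeral: optional sign, digits, one
  optional decimal point. No exponents, no thousands separators, no
  comparator prefixes: `<0.01` is *not importable* and is excluded with
  a reason rather than truncated. This is deliberate: silently reading
  `<0.01` as `0.01` would fabricate a measurement.
- **date_mdy** — a real calendar date in month/day/4-digit-year.
  Two-digit years are rejected at parse time (a century guess at a PHI
  boundary is not acceptable); ISO dates are accepted on *input* and
  rendered as M/D/Y at the CSV boundary only.
- **time_hm** — HH:MM, 24-hour. A missing time is allowed (untimed
  draw) and sorts before any timed draw on the same date.

Values are stripped of surrounding whitespace before checking, because
EHR exports pad cells.

## Harmonization rules

- **Test-name matching** is exact after case-folding and internal-
  whitespace collapse. No fuzzy matching: a near-miss spelling surfaces
  as an `unmapped_test` exclusion for a human to add to the lookup
  table. Fuzzy matches that guess wrong on clinical data are silent
  corruption.
- **Units** must be in the lookup entry's allowed set (compared
  case-insensitively). There is no automatic unit conversion; the
  lookup's `scale_factor` enables explicit, audited conversions (e.g.
  calcium mmol/L → mg/dL at 4.008). A result exported with no unit is
  excluded by default; a site that trusts unit-less feeds can allow the
  empty unit explicitly.
- **De-identification** replaces patient keys with registry record ids
  through an injective crosswalk. Strict mode aborts on an unknown key;
  the diagnostic carries the source row number, never the key. Lenient
  mode itemizes unknowns. Exclusion exports likewise carry source-row
  provenance instead of keys so they can sit beside shareable outputs.
- **Instance assignment** ranks each record's collection events
  chronologically (untimed first, then clock time); when one field
  appears twice at a single event — two results in one exported cell —
  the later-source-ordered result opens a follow-on instance at the
  same timestamp, because one instance cannot hold two values of one
  field. Two *different* values colliding at the same field, event and
  source position cannot be represented and raise an integrity error.
  Assignment is invariant to input row order.
- **Conservation** is the pipeline's master invariant: on every run,
  raw parsed values = imported values + itemized exclusions. Nothing is
  dropped silently at any stage.
- **Aggregation** of per-site import CSVs is plain concatenation,
  guarded by exact header equality and disjoint record-id sets (use a
  site prefix). **LOINC annotation** emits exactly one code per covered
  field after import; the packaged map uses common serum/blood codes
  and is configuration to be reviewed, not an assertion about any
  particular registry.

## The survival screen

Overall survival is days from diagnosis to death, censored at the last
follow-up visit when no death occurred. Death before diagnosis is a
data error; a missing diagnosis date excludes the subject with a logged
reason.

**Baseline selection.** For each subject and lab, the baseline value is
the draw nearest the diagnosis date within a window of 90 days before
to 30 days after (configurable). Ties in distance go to the earlier
draw, then the earlier clock time. Subjects with no in-window draw are
absent for that lab (complete case per lab). The window and tie rule
are package defaults, documented rather than claimed canonical.

**The Cox fit.** Each lab is screened with a univariable Cox
proportional-hazards model on the untransformed per-unit value (a
hazard ratio of 1.0444 for BUN means a 4.4% hazard increase per mg/dL).
The partial likelihood uses the **Efron correction** for tied event
times — ties are unavoidable with day-resolution survival, and Efron is
the more accurate of the two standard corrections; the choice matters
and is therefore stated. Maximization is Newton iteration from β = 0
with step-halving (the likelihood is concave; halving only guards
against overshoot), convergence at |Δβ| < 1e-9, at most 50 iterations.
The covariate is centered internally for numerical stability (the
estimate is location-invariant). SE comes from the observed
information; HR = exp(β̂), 95% CI = exp(β̂ ± 1.96·SE), p is two-sided
Wald. Degenerate inputs (constant covariate, no events) raise; a
monotone likelihood (|β̂| > 20, perfect separation) or non-convergence
returns a *flagged* result, never a silent number. No multiplicity
correction is applied by default — the screen is hypothesis-generating
and reports raw p-values; corrections can be layered on by the caller.

Correctness is established two independent ways in the test suite: on
small no-tie datasets the Newton estimate matches an exhaustive grid
search of the textbook partial likelihood to 1e-5, and across 100
simulated cohorts it matches scikit-survival's Efron fit to better than
1e-6 (scikit-survival is a cross-check only, not a dependency of the
fit).

## The synthetic cohort generator

The generator exists so that every pipeline stage is testable with no
real patient data and known ground truth.

- **Lab values** are drawn per field from Normal distributions centered
  on adult reference-interval midpoints (e.g. potassium ~ N(4.2, 0.4)
  mmol/L), rounded to field-typical decimals and floored at zero. These
  are plausibility scaffolding, not clinical claims.
- **Survival** follows an exponential proportional-hazards model:
  subject i's event time has rate h0·exp(Σ_f β_f·(x_if − μ_f)), where
  x_if is the subject's *baseline* value of lab f and μ_f its reference
  mean. Defaults: h0 = 1/730 per day (median ≈ 2 years at the reference
  profile), censor rate 0.3. Censoring is an independent exponential
  whose per-subject rate is tuned so P(censored) equals the configured
  rate exactly (for competing exponentials, P = μ/(λ+μ)). The draw
  carrying the hazard-driving panel is the one the baseline-selection
  rule will pick, so analysis sees the true covariate.
- **Draw schedule**: one baseline draw within −30..+5 days of
  diagnosis, plus a Poisson(2) number of extra draws in −90..+120 days;
  at the configured rate a subject gains a same-day repeat draw to
  exercise the repeating-instrument logic.
- **Corruption** is planted at render time, per value: "refused" and
  "canceled" tokens (1% each by default) and off-dictionary unit
  variants (1%) such as mEq/dL for mmol/L. Every planted corruption is
  recorded in a manifest keyed the same way the exclusion report is, so
  accounting can be checked item-for-item. With all rates zero the
  render is lossless and the pipeline reproduces the ground-truth
  import table exactly.
- **Cell-level error injection** (`inject_errors`) emulates *manual*
  abstraction errors on a finished table: digit typos and value
  transpositions (valid numbers, wrong values — detectable only by
  comparison against an independent dataset) and malformed dates
  (caught by import validation). Exactly k cells are perturbed without
  replacement.

What the generator does **not** emulate: longitudinal lab trajectories
(draws are independent), correlated panels, disease-specific
epidemiology, informative censoring, missing-not-at-random patterns,
and free-text outside-hospital reports. Passing tests therefore
demonstrate the pipeline's transformation, accounting and inference
machinery — not that any particular clinical association is real.

## Verification sizes and calibration

Test and acceptance runs use desk-scale cohorts chosen to finish in
seconds while leaving every code path exercised: 8–30 subjects for
round-trip and accounting checks (a 30-subject cohort is ~3000 lab
values), 20 seeds for round-trip and de-identification scans, 500
subjects for the effect-detection check. Confidence-interval
calibration uses 1000 replicates of n = 300 with a binary covariate at
true HR 2.0: 1000 keeps the Monte Carlo standard error of the coverage
estimate near 0.7%, small against the 93–97% acceptance band (at 200
replicates the estimate itself is noisy enough to fail a correctly
calibrated fit one run in five). Measured coverage is ≈95% both for
the effect covariate and for an independent null covariate.

## Known limitations

- The panel-cell grammar ("NAME VALUE [UNIT]" tokens, `;`-separated) is
  a configurable default; sites whose exports use other intra-cell
  syntaxes must supply their own `PanelGrammar` or pre-split upstream.
- Unit checking is set-membership, not dimensional analysis; UCUM
  algebra is out of scope by design.
- The Cox stage is univariable only: no multivariable adjustment,
  time-varying covariates, or competing risks.
- The REDCap boundary is the CSV: live API upload is a thin optional
  stub (`labharbor.redcap`) whose payload construction is tested but
  whose network call is not; all package tests run against files.
- Agreement comparison keys on (record, field, date, time); datasets
  that disagree on collection *time* for the same physical draw will
  show paired missing-key discrepancies rather than a value comparison.
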