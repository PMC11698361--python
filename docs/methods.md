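# Methods

## Staging model

AKI is staged hour by hour along four independent pathways — urine output
(UO), relative creatinine elevation, absolute creatinine elevation, and
dialysis — and the overall stage at an hour is the maximum over the
pathways. Staging is *causal*: every criterion is evaluated over trailing
windows ending at (and including) the current hour, so a stage asserts
"the criterion is satisfied by the history up to now" and appending future
data can never rewrite past stages. This property is enforced by tests.

### Urine-output probe

At hour `t` the probe examines every trailing window of contiguous defined
hours ending at `t` and computes the *mean* per-kg flow over the window
(recorded ml divided by the subject's weight). The highest satisfied
criterion wins:

* stage 1 — some window of length ≥ 6 h with mean flow < 0.5 ml/kg/h;
* stage 2 — some window of length ≥ 12 h with mean flow < 0.5 ml/kg/h;
* stage 3 — some window of length ≥ 24 h with mean flow < 0.3 ml/kg/h, or
  some window of length ≥ 12 h with mean flow at or below the anuria
  threshold (default 0.0 ml/kg/h, i.e. strict anuria; configurable, must
  stay below 0.3).

Mean-over-window semantics (rather than every-hour-below) is the clinical
reading of "UO below x for n hours": a single borderline hour inside an
oliguric stretch does not reset the clock. The stage-1 band "6–12 h" needs
no explicit upper bound: once a qualifying window reaches 12 h the stage-2
criterion takes over. Hours with fewer than 6 defined trailing hours are
stage 0 (insufficient duration), while hours whose own measurement is
missing are *undefined* — absence of evidence is not stage 0. A missing
hour breaks all windows; evaluation restarts from scratch after a gap.

Flow comparisons are strict ("below"), durations inclusive ("at least").
Every comparison carries an epsilon guard (default 1e-9): a value within
epsilon of a threshold counts as exactly at the threshold, so that
floating-point noise from back-distribution cannot flip a stage. The
anuria comparison is inclusive (≤ threshold), so strict anuria (0.0) works
with exact zeros.

### Creatinine probes

Relative: the ratio r = SCr / baseline maps to stages via half-open bands
0 ≤ r < 1.5 → 0, 1.5 ≤ r < 2 → 1, 2 ≤ r < 3 → 2, r ≥ 3 → 3 (epsilon-
tolerant at each edge; the 3-fold boundary is read as ratio ≥ 3.0 exactly).
Absolute: SCr ≥ 4 mg/dl is stage 3 regardless of any baseline — the
"irrespective of baseline" reading is implemented as printed, without the
stricter additional acute-rise precondition some KDIGO commentaries apply;
otherwise a rise of ≥ 0.3 mg/dl over the baseline is stage 1. A stage is
undefined where the creatinine is missing, or (below the 4 mg/dl level)
where no baseline is defined.

### Dialysis probe

Active renal replacement therapy at an hour is stage 3, otherwise 0.
Status records are carried forward indefinitely; before the first record
the status is inactive, so this probe is always defined and the overall
stage of a staged hour is in practice never undefined.

### Aggregation

Overall stage = max over the *defined* components; undefined components
are ignored when at least one component is defined, and only an hour with
all four components undefined has an undefined overall stage. A defined
stage is therefore never masked by missing evidence elsewhere.

## Baselines

Window baselines take the min, mean or first value of either a fixed
window at the start of the series or a rolling trailing window; rolling
windows cover `[t − W, t)` — they *exclude* the current hour, so a rising
creatinine is compared against its past. Hours with an empty window have
no baseline (hour 0 never has a rolling baseline). The defaults reproduce
the validation configuration: relative criterion against a rolling
7-day (168 h) window, absolute criterion against a rolling 48 h window,
statistic `min` for both. The minimum is the deliberately sensitive
choice — the reference is the best recent kidney function — and both the
statistic and the window length are configurable.

The Cockcroft–Gault path computes an expected creatinine under an assumed
GFR (default 75 ml/min) by inverting the clearance formula; clearance and
expected-SCr are exact algebraic inverses (tested to 1e-12 relative). With
a height available, weight is replaced by the adjusted body weight
ABW = IBW + 0.4 · (actual − IBW), with IBW per the Devine estimate
(50 kg male / 45.5 kg female + 2.3 kg per inch over five feet); patients
lighter than their IBW keep their actual weight. This baseline is a last
resort for cohorts without usable creatinine history.

## Preprocessing

Timestamps are floored to the hour; within one hour, urine volumes are
summed, the last creatinine value wins, and dialysis flags are OR-ed.
Hour 0 is the floor of the subject's earliest observation across all
three signals (no admission time exists in the data model), and the grid
runs to the last observed hour without extrapolation.

Urine back-distribution divides a recorded volume evenly over the hours
from just after the previous record to the record's own hour, provided
the span does not exceed the gap limit (default 6 h, spans of exactly the
limit are filled — the bound is read as inclusive). Hourly shares are
computed as consecutive differences of the cumulative fractions
`volume · (i / span)`: they telescope, so the distributed hourly volumes
sum to the recorded volume *exactly* in IEEE arithmetic while remaining
equal to within an ulp (a naive share-plus-residual scheme loses exact
conservation in a few percent of random cases). The first record of a
stay has no predecessor and lands on its own hour only. Creatinine is
carried forward until the next draw or until the gap limit (default 72 h,
chosen so typical daily draws keep the 7-day rolling baseline usable)
elapses. Beyond a limit, hours stay missing, probes emit undefined stages
there, and trailing windows restart after the gap. Preprocessing can be
disabled entirely, in which case records are placed on the grid verbatim;
for already-hourly, gap-free input both paths are the identity (tested).

Creatinine supplied in µmol/l is converted to mg/dl with the standard
factor 88.42 µmol/l per mg/dl.

## Metrics

Predictions and expert annotations are inner-joined on (subject, hour).
Accuracy is reported per category (UO, absolute SCr, relative SCr,
dialysis, overall) both as multiclass accuracy and as one-vs-rest accuracy
per stage. Hours where the prediction is undefined are excluded and
reported as counts — an expert annotation has no "undefined". Any-AKI
diagnostics binarize the overall stage at ≥ 1; the ROC-AUC uses the
ordinal predicted stage (0–3) as the score, with ties receiving half
credit (the scikit-learn trapezoidal ROC is cross-checked in tests against
an independently coded Mann–Whitney rank statistic). A reference with only
one class leaves sensitivity or specificity and the AUC as NaN with a
`degenerate_reference` flag rather than raising, so a partial report is
still produced.

## Synthetic data and the oracle

The generator emits piecewise-constant trajectories — segments of
(duration, per-kg urine flow, creatinine, dialysis status) — in the raw
record format an ICU chart produces: urine-bag volumes aggregated over
read intervals of 1–4 h drawn from a seeded RNG, creatinine drawn at
segment starts plus a fixed interval (default 24 h, typical daily draws),
dialysis recorded at status changes, and record timestamps jittered within
the hour to exercise flooring. Read intervals never cross a segment
boundary and the first read covers a single hour, so the piecewise-
constant ground truth is exactly recoverable by preprocessing — which the
round-trip tests demand. Defaults describe a generic adult ICU patient
(70 kg, 60 years). All randomness flows from the spec seed; generation is
byte-reproducible.

What the generator does *not* emulate: creatinine kinetics (real SCr rises
and decays smoothly), diuresis dynamics, measurement error, charting
artifacts, or inter-subject covariance. Passing tests therefore establish
that the staging rules are implemented correctly on well-formed input, not
that the pipeline is robust to every real-world charting pathology.

`oracle_stage` is a deliberately naive, loop-based reimplementation of the
full staging semantics (exhaustive scan over every admissible trailing
window, linear rescans for baselines) sharing no code with the probes or
baselines modules. The central equivalence test demands exact stage
agreement between the pipeline and the oracle on 1000 randomly sampled
trajectories of up to 72 h whose rate and creatinine grids deliberately
straddle the thresholds. An extended check — re-running classification and
validation on a published expert-annotated ICU dataset — requires an
external download and sits outside the desk-scale suite.

## Numerical and edge-case choices

* Epsilon guard 1e-9 on all threshold comparisons (see above).
* Stage series are nullable integers in output CSVs; undefined stages are
  empty fields, never 0.
* Demographics weight is a single static value per subject; whether it is
  actual, ideal or adjusted body weight is the caller's choice.
* Ages below 18 produce a warning, not a rejection: the paediatric
  GFR-based stage-3 criterion is out of scope, and staging an adolescent
  with adult rules is flagged but not forbidden.
* Subjects failing classification are reported and skipped; a cohort run
  fails only if every subject fails.
* Problem sizes in the test suite (trajectories ≤ 72 h, cohorts of 4–15
  subjects, 1000-trajectory equivalence sweeps) keep the whole suite
  around a quarter of a minute while still covering every window-length
  regime the criteria distinguish.
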