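# Methods

This note documents the models and procedures `daymark` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Answer coding and calendar grids

Each of the 11 daily questions maps its ordinal answer labels onto a fixed
0–100 grid (five-alternative items onto {0, 25, 50, 75, 100};
three-alternative items — Exercise, Socialized, Angry — onto {0, 50, 100}),
with higher values always the more positive outcome. Per patient, records
are laid out on a gapless calendar grid spanning the first to the last day
with any record (questionnaire or breathalyzer). Leading and trailing
inactive runs therefore never enter a panel, while interior gaps are kept —
they are the signal the imputation exploits. Days carry at most one
sobriety status; multiple tests collapse with precedence
`alcohol_detected > no_alcohol > all_omitted`, so a single detected test
marks the day.

## Biomarker construction

Two steps per index and patient:

1. **Raw daily value.** The mean of the day's available answers within the
   index's item subset. For silent days, counting days since the last
   answered day: gap 1 → ⅔ of the last observed raw value, gap 2 → ⅓,
   gap ≥ 3 → 0. The decay encodes the monitoring premise that sustained
   non-compliance signals a worsening state; it deliberately makes the
   missingness informative rather than ignorable.
2. **Exponential smoothing.** S_0 = x_0 and S_t = α·x_t + (1−α)·S_{t−1}
   with α ∈ (0, 1). Default α = 0.32; the historical alternative 0.21
   (used for breathalyzer-based monitoring) responds so sluggishly that the
   index dips only on missing data, not on answer variation, and is kept
   available but not default.

When a panel begins with unanswered days the series starts at the first
observed raw value ("days since last answered day" is undefined before any
answer); those lead days carry no biomarker value rather than an invented
prior. Gap counting uses calendar days. Arithmetic is double precision;
equality tests use 1e-9. Each panel is treated as one treatment period; if
an application splits a patient into several periods, the construction
should be restarted per period (the decay anchor must not cross a period
boundary).

## Factor discovery

PCA is computed on the correlation matrix of complete patient-days (all 11
questions answered), so eigenvalues sum to 11 and the eigenvalue > 1 rule
is scale-free. Loadings are scaled so each component's squared loadings sum
to its eigenvalue. Varimax rotation uses Kaiser row-normalization
(gradient-projection routine, tolerance 1e-6, max 1 000 iterations) with
column signs fixed so each factor's largest-magnitude loading is positive.
Each question is assigned to the factor with its largest absolute rotated
loading (ties to the lowest factor index); factors merge into named indices
via a configurable map, by default factors 1 and 3 → WeBe-i, factor 2 →
MotSC-i. Discovery always retains at least two components even when only
one eigenvalue exceeds 1, since a rotation and a two-index split are
otherwise undefined.

## Events, labels, eligibility

A day is *bad* when alcohol was detected or all scheduled tests were
omitted — non-compliance counts as relapse-indicating, mirroring how the
sobriety index treats omissions. Within a panel, a day with no sobriety
record at all is treated as all-omitted (inside a treatment span, nothing
performed means everything omitted). An exacerbation event (EE) is a
maximal run of ≥ 2 bad days. Day t's forecast label is 1 iff an EE *starts*
within [t+lo, t+hi], for look-ahead ranges (1, 3) or (5, 7); labels are
undefined where the horizon leaves the panel. A forecast is only issued
(eligibility) when the day is ≥ 7 days into the period, outside any EE, and
the same-day sobriety index is ≥ 40; days with a missing index are
ineligible.

The sobriety index here is an approximation built from the same gap-decay +
smoothing machinery as the questionnaire indices (no-alcohol = 100,
detected = 0, omitted = missing). An externally computed monitoring index
supplied in the input's `ami` column is preferred when complete.

## Forecaster

The classifier is a single-layer LSTM (32 hidden units, dropout 0.2 on the
final hidden state, sigmoid head) over left-padded 7–93-day feature
windows; a boolean mask freezes hidden and cell state on padded steps.
Implemented directly in numpy with backpropagation through time, verified
against finite differences; Adam at 1e-3, weighted binary cross-entropy
with class weights inversely proportional to prevalence, batch size 64, up
to 100 epochs with early stopping on validation loss (patience 10, best
weights restored). One global seed drives the patient split, weight
initialization and minibatch shuffling; identical hyperparameters are used
for all three feature sets — the comparison between feature sets is the
point, so none is tuned.

Missing raw answers are fed as 0 next to a per-question answered indicator;
the indicator disambiguates a true 0 answer from silence. Splits are by
patient (default 70/15/15 by rounded fraction, or exact counts), never by
day, so no patient contributes to more than one partition.

For desk-scale runs (tests, the acceptance script) the package uses batch
128, max 12 epochs, patience 3: on the standard synthetic cohort validation
loss plateaus within a handful of epochs, and the shorter schedule keeps a
full study under two minutes on one CPU while leaving held-out AUC
unchanged in the first decimal.

## Evaluation

AUC is the rank-based area under the ROC curve (ties counted ½). The
operating point reported alongside it maximizes the Matthews correlation
coefficient over all achievable thresholds (midpoints between consecutive
sorted unique probabilities, plus 0 and 1; ties toward the smallest
threshold; prediction positive iff probability ≥ threshold). MCC uses the 0
convention when any denominator factor vanishes. Rounding to 3 decimals
happens only at reporting.

## Synthetic cohorts

Each patient follows a daily three-state latent chain — stable,
deteriorating, in-EE — with transitions stable→deteriorating 0.03,
deteriorating→EE 0.25, deteriorating→stable 0.15, EE→stable 0.35, and a
2-day minimum EE dwell. The state drives:

* the probability the patient answers at all that day (0.9 when stable,
  multiplied by 0.33 when deteriorating and 0.22 in an EE) — missingness is
  MNAR by construction;
* answer values: per-question stable means patterned on a real monitored
  cohort's marginals, shifted −30 when deteriorating and −45 in an EE (the
  motivation/self-confidence items a further −10 outside the stable state),
  Gaussian dispersion 18, snapped to the item's coded grid;
* sobriety status: while in an EE, alcohol detected with probability 0.6,
  otherwise all tests omitted; outside EEs, innocent omissions with
  probability 0.05.

Default size is 300 patients × 120 days, which one CPU handles end to end
in about two minutes.

What the generator does **not** emulate: demographic heterogeneity,
weekly/seasonal answering rhythms, multi-period treatments, gradual
(rather than step) deterioration, and the long pre-relapse prodromes real
cohorts can show. In particular the deteriorating state lasts ~2.5 days on
average, so the 1–3-day look-ahead carries most of the learnable signal
and the 5–7-day horizon is close to chance on synthetic data — passing
tests demonstrate that the pipeline recovers signal that is present and
finds none where none exists, not that real-world far-horizon forecasting
works.

## Numerical and degenerate-input conventions

* Imputation of an all-missing series is an error; a series must begin
  observed (the pipeline starts each series at the first answered day).
* PCA rejects zero-variance columns; varimax rejects k < 2 and
  zero-communality rows.
* Empty sample lists predict to empty arrays; single-class training or
  evaluation labels raise.
* Left-padding with a mask, never truncation at the recent end: the last
  window step is always the anchor day.

## Known limitations

* The sobriety index is a stand-in with the questionnaire machinery, not
  the published breathalyzer-compliance index; when a real index column is
  available it should be supplied in the sobriety CSV.
* The LSTM is deliberately small and untuned; it establishes information
  content, not a production forecaster.
* Mixed omitted/performed test days are representable only through the
  day-collapse precedence; per-test granularity is out of scope.
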