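# Methods

## The problem and the model

`shockwatch` predicts, at every hour of an ICU admission, the probability
that the patient will develop septic shock during the stay.  Ground truth
is not a chart diagnosis but a deterministic rule cascade evaluated
hourly on physical-unit values (see README for the full criteria):
sepsis = ≥2 SIRS criteria + suspected infection; severe sepsis = sepsis +
organ dysfunction; septic shock = severe sepsis + SBP <90 mmHg despite
adequate fluid resuscitation.  An admission is outcome-positive if any
hour reaches `septic_shock`; the first such hour is the onset.

The classifier is a stacked LSTM: gated recurrence lets the model carry
information across many hours, which matters because the discriminative
signal (a slow physiological deterioration) accumulates over long windows.
The network reads the standardized hourly grid and emits one probability
per hour through an affine+sigmoid head on the top layer's hidden state.
Training replicates the admission-level outcome at every hour of the
(onset-truncated) sequence as the per-hour target.

## Rule-evaluation conventions

- All thresholds are strict or inclusive exactly as printed (`>` strict,
  `≥` inclusive): SBP of exactly 90 mmHg is *not* hypotension; exactly
  20 mL/kg/24 h *is* adequate resuscitation.
- "Concurrent" means within the same hour bin; criteria are evaluated on
  the imputed hourly grid in physical units (standardization feeds the
  model only).
- Infection suspicion is an input — half-open hour intervals per
  admission — never inferred by the rule core.  Real-data adapters can
  populate it from antibiotic/culture heuristics upstream.
- "Total fluid replacement" is cumulative since admission; the trailing
  24-hour window is computed from raw bolus timestamps, not from the hourly
  grid, because window semantics are physical.
- The urine-output criterion conditions on the same fluid-adequacy
  predicate as the shock rule (one definition, one code path).
- The two acute-lung-injury branches are implemented as the PaO₂/FiO₂
  ratio plus the pneumonia flag only, without requiring a separate
  lung-injury diagnosis.

## Feature pipeline

Defaults (all configurable through the range-table YAML):

- ~30 model features: 8 vitals, 16 labs, 3 trailing-window quantities
  (fluids/24 h, cumulative fluids, urine mL/kg/2 h), age and weight
  broadcast per hour, and 3 binary chronic-condition flags.
- Clinical ranges are plausibility bounds for discarding impossible
  recordings (e.g. heart rate outside [20, 300]/min); bounds are
  inclusive.  They are configuration, not ground truth.
- Binning: events map to the closest whole hour; ties at .5 round half
  up (2.5 h → hour 3).  Multiple events in a bin are averaged
  (symmetric, order-independent).
- Imputation: zero-order hold within the admission, then population mean
  for hours before a feature's first observation.  ZOH is idempotent and
  never crosses admission boundaries.
- Standardization `x̂ = (x − x̄)/s` for non-binary features; `x̄`, `s`
  are mean and sample SD (ddof = 1) over *observed* values of the
  training folds only, applied unchanged to validation/test.  Computing
  them per rotation prevents fold-to-fold leakage.  The rule labeling,
  by contrast, imputes with full-cohort statistics: verdicts are ground
  truth, not model output, so leakage is not a concern there.

## Network and training

| parameter | full scale | desk scale | notes |
|---|---|---|---|
| layers × units | 4 × 100 | 2 × 16 | |
| dropout (inter-layer) | 0.4 | 0.2 | inverted; inference-off |
| epochs | 1,000 | 30 | |
| batches/epoch | 40 × 50 random | full pass, batch 32 | |
| positive weight | 3 | 3 | weighted BCE per hour |
| optimizer | Adam, lr 1e-3 | Adam, lr 5e-3 | β=(0.9, 0.999) |
| gradient clip | global norm 5 | same | |
| validation AUROC | every 10 epochs | same | training log CSV |

Choices the architecture leaves open, resolved as follows:

- **Target construction**: per-hour probability trained against the
  admission outcome replicated at each hour, with positive admissions'
  inputs truncated at shock onset (inclusive) — post-onset hours would
  leak the outcome.  This is what gives first-alarm (HBO) semantics.
- **Output head**: minimal — one affine map + sigmoid on the top hidden
  state.
- **Dropout variant**: applied to non-recurrent (inter-layer) connections,
  fresh mask per timestep; optional variational recurrent dropout
  (`recurrent_dropout_p`) with one mask per sequence.
- **Variable lengths**: pad-and-mask; the loss runs over real hours only,
  and zero gradients propagate exactly through padding.
- **Initialisation**: Glorot-uniform weights, zero biases except the
  forget gate at +1; states start at zero each sequence.
- **Determinism**: one global seed fans out to named substreams
  (generator / folds / per-fold training / bootstrap), so each component
  is independently reproducible.  The desk-scale learning rate (5e-3) is
  higher than the full-scale default because 30 epochs over a few hundred
  short sequences need faster convergence.

The LSTM forward pass, BPTT, Adam and dropout are implemented directly in
numpy; the per-gate reference cell (`lstm_cell_step`) is retained as a
separate code path and the vectorized stack is tested against it (and
against an element-by-element re-derivation in the test suite) to 1e-10.

## Evaluation

- 5% stratified validation holdout, then six stratified folds of the
  remainder; six model instances each train on five folds and predict the
  sixth, so every admission is scored by the one model that never saw it.
  A fold whose class proportion deviates more than 5 points from the
  global proportion is rejected (with ~19+ admissions per fold this is
  attainable; tiny cohorts fail fast instead of silently unbalancing).
- Admission score = max per-hour probability (alarm semantics).
- AUROC = midrank Mann–Whitney formulation (ties count ½), which equals
  the trapezoidal area under the empirical ROC; both equalities are
  asserted in tests against brute-force pair counting and scikit-learn.
- CIs: percentile bootstrap of the six fold-level metrics (the pooled
  point estimate can fall slightly outside this interval, since pooling
  compares scores across folds while the bootstrap resamples fold means;
  both the pooled value and the fold values are reported).
- Operating threshold for HBO: per fold, the largest threshold reaching a
  target sensitivity (default 0.85) on the validation holdout.  HBO =
  onset hour − first hour with probability ≥ threshold, counting alarms
  at or before onset only; positives never alarmed are excluded from the
  median/IQR (they are reported as a count).
- Pre-onset curve: for each offset h = 1..48, the positive class score is
  the probability the model emitted at hour `onset − h` (using only data
  available then, by causality of the recurrence); negatives contribute
  their admission score.  Positives with onset < h are skipped at that
  offset.  This construction directly measures how reliability changes
  as onset approaches; a max-over-window construction would be constant
  in h because the near-onset maximum dominates every window.

## Synthetic cohort: what it emulates and what it does not

The generator produces per-admission hourly trajectories as baseline
physiology (per-admission offset + AR(1) noise) over a 36–96 h stay, with
MCAR per-feature-hour missingness (default rate 0.3; alternatively labs
observed every k hours, a block regime under which ZOH behaves
differently), timestamped fluid boluses and hourly urine volumes, and
admission statics (age 18–95, weight 50–140 kg, chronic-condition flags
at plausible prevalences).

Positive admissions follow the nesting of the criteria: an
infection-suspicion interval opens, at least two SIRS variables ramp
linearly toward pathological targets over the 36 h before the chosen
onset, lactate crosses 2 mmol/L, a 3 × 500 mL resuscitation series
crosses the fluid-adequacy rule, and SBP — held at ≥92 mmHg until onset so
the shock rule cannot fire early — drops below 90 at onset.  Negatives
either lack infection intervals or have their SIRS variables clamped to
mid-normal within them, so they can never satisfy the sepsis gate.  Every
admission is verified through the *labeling module itself* and resampled
(bounded retries) on disagreement, so requested prevalence is realized
exactly by count.

What passing tests on this cohort establish: every rule branch is
reachable and correctly ordered; the pipeline's imputation/standardization
contracts hold under realistic missingness; the LSTM can recover a
temporally accumulating signal through the full protocol; the evaluation
machinery measures what it claims.  What they do **not** establish:
performance on real ICU data.  The generator's deterioration is a clean
monotone ramp with engineered separability — real cohorts have
treatment-confounded, censored, heterogeneous trajectories, and absolute
AUROC/HBO numbers on synthetic data say nothing about clinical
performance.

## Problem sizes

The shipped study condition for end-to-end checks is 300 admissions at
30% shock prevalence with the desk-scale preset under six-fold CV (about
two minutes on one CPU); unit and property tests use cohorts of 4–120
admissions and models of 1–3 layers × 4–16 units.  The full-scale
configuration is constructed and stepped in tests but not trained to
convergence there.

## Known limitations

- Sepsis-2/SIRS definitions only; no SOFA/Sepsis-3 mode.
- No censoring model: treatment that delays or prevents criterion
  fulfilment is assumed learnable from data rather than modelled.
- Feature-specific imputation look-back windows are not supported; ZOH
  carries values indefinitely within an admission.
- The exact clinical-range table and ~30-feature list are shipped
  defaults (editable configuration), not a canonical standard.
- Single-threaded determinism: bitwise reproducibility assumes a fixed
  BLAS thread count.
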