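# shockwatch

Early detection of septic shock from hourly ICU time series.

Septic shock — severe sepsis with hypotension that persists despite
adequate fluid resuscitation — kills a large fraction of the patients who
develop it, and every hour of earlier treatment improves survival.
`shockwatch` implements a complete early-warning pipeline for this problem
on the Sepsis-2 (SIRS-era) operational definitions:

1. **Rule-based hourly labeling.** Every admission-hour is assigned a state
   in `negative < sepsis < severe_sepsis < septic_shock`:
   - *sepsis*: ≥2 SIRS criteria (temperature <36 or >38 °C; heart rate
     >90/min; respiratory rate >20/min or PaCO₂ <32 mmHg; WBC <4,000 or
     >12,000 cells/µL) concurrent with suspected infection;
   - *severe sepsis*: sepsis plus ≥1 organ dysfunction (SBP <90 mmHg;
     lactate >2.0 mmol/L; urine output <0.5 mL/kg/2 h despite adequate
     fluids; creatinine >2.0 mg/dL absent chronic renal disease; bilirubin
     >2.0 mg/dL absent chronic liver disease; platelets <100,000/µL;
     INR >1.5; PaO₂/FiO₂ <200 with pneumonia or <250 without);
   - *septic shock*: severe sepsis plus SBP <90 mmHg despite adequate
     fluid resuscitation (≥20 mL/kg over 24 h or ≥1,200 mL total).
2. **Feature pipeline.** Long-format event tables → hourly grids: age
   filter (≥15 y), clinical-range outlier removal, nearest-hour binning,
   zero-order-hold imputation with population-mean fallback, and
   per-feature standardization `x̂ = (x − x̄)/s` fitted on training folds
   only.
3. **Stacked LSTM classifier** (pure numpy, hand-written BPTT) computing,
   per layer and hour,

       f_t = σ(W_f x_t + U_f h_{t−1} + b_f)        (forget gate)
       i_t = σ(W_i x_t + U_i h_{t−1} + b_i)        (input gate)
       o_t = σ(W_o x_t + U_o h_{t−1} + b_o)        (output gate)
       c_t = f_t ∘ c_{t−1} + i_t ∘ tanh(W_c x_t + U_c h_{t−1} + b_c)
       h_t = o_t ∘ tanh(c_t)

   with an affine+sigmoid head emitting a per-hour probability that the
   admission develops septic shock.  Full-scale defaults: 4 layers × 100
   units, dropout 0.4, 1,000 epochs of 40 mini-batches × 50 samples,
   positive class weight 3.  A desk-scale preset (2 × 16 units, 30 epochs)
   runs the whole protocol on a laptop CPU in minutes.
4. **Evaluation protocol.** 5% validation holdout + six-fold stratified
   cross-validation; pooled ROC/AUROC with percentile-bootstrap CIs over
   fold results; hours-before-onset (HBO) of the first alarm at a
   validation-calibrated threshold; and the AUROC at each of the 48 hours
   preceding onset.
5. **Synthetic cohort generator** that emits hourly vitals/labs, fluid
   boluses and urine output with configurable missingness and a chosen
   number of admissions engineered to satisfy the shock criteria — every
   stage of the pipeline is testable without credentialed EHR data.  Real
   extracts in the same CSV dialect are a drop-in replacement.

## Worked example

```python
import json
import shockwatch as sw

events, metas = sw.generate_cohort(
    sw.CohortConfig(n_admissions=120, shock_fraction=0.3, seed=5))
report = sw.run_cross_validation(
    events, metas, sw.ModelConfig.desk_scale(), sw.EvalConfig(), seed=5)
print(json.dumps(report.summary(), indent=2))
```

prints (about a minute on one CPU):

```json
{
  "n_admissions": 114,
  "n_positive": 34,
  "auroc": 0.9220588235294118,
  "auroc_ci_95": [0.8829059829059829, 0.9671550671550672],
  "fold_aurocs": [0.9, 0.9286, 0.8333, 1.0, 0.9231, 0.9744],
  "hbo_median_hours": 7.5,
  "hbo_iqr_hours": [4.75, 10.0],
  "n_hbo": 16,
  "...": "..."
}
```

Reading this: of 120 generated admissions, 6 form the 5% validation
holdout and 114 rotate through six test folds; 34 of those develop septic
shock under the hourly rules.  The pooled test AUROC of 0.92 says a random
shock-positive admission outscores a random negative one 92% of the time;
the CI comes from bootstrapping the six fold-level AUROCs.  The median
first alarm fires 7.5 hours before shock onset (IQR 4.75–10) among the 16
positives alarmed at the validation-calibrated threshold.  The
`report.preonset` table shows discrimination rising steeply as onset
approaches (AUROC 0.89 one hour before onset versus chance twelve hours
out — the generator's deterioration ramp is what the model is tracking).

## Command line

```bash
shockwatch simulate --n 100 --shock-fraction 0.2 --seed 3 --out cohort
shockwatch label     --events cohort/events.csv --meta cohort/meta.csv --out labels
shockwatch featurize --events cohort/events.csv --meta cohort/meta.csv --out grids
shockwatch evaluate  --events cohort/events.csv --meta cohort/meta.csv --out eval
```

Event CSV columns: `admission_id` (opaque id), `feature` (name from the
range table), `time_hours` (float hours since admission), `value`
(physical units).  Metadata CSV columns: `admission_id`, `age` (years),
`weight` (kg), `stay_hours`, `infection_suspected` (semicolon-joined
`start-end` hour intervals), `flag_chronic_renal`, `flag_chronic_liver`,
`flag_pneumonia` (0/1), `outcome_label` (0/1 or empty).  Every command
writes a `manifest.json` (seed, config hash, versions) beside its outputs.

## Scope notes

The rules implement the SIRS-era (Sepsis-2) definitions, not Sepsis-3 /
SOFA.  Treatment-induced censoring of trajectories is deliberately not
modelled.  The synthetic generator targets criteria-satisfaction and a
learnable deterioration signal, not physiological realism — see
`docs/methods.md` for what that does and does not establish.
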