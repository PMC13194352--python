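# asdscreen

Acoustic–electrocardiographic timing indices for screening **secundum
atrial septal defect (ASD)** in children, from synchronized wearable
phonocardiogram (PCG) + single-lead ECG recordings.

A persistent left-to-right atrial shunt overloads the right ventricle and
delays pulmonary valve closure, so the second heart sound splits widely
and the split barely moves with respiration — the classic auscultatory
sign of ASD. This package turns that sign into numbers. It is written
for biomedical-signal and biostatistics researchers who want a fully
testable, end-to-end reimplementation of the screening analysis: because
no raw recordings from the source cohort are publicly available, the
package ships a synthetic-data generator with exact timing ground truth,
so every stage of the pipeline can be validated without any download.

## The five indices

From each artifact-free sinus beat at end-expiration, with Q onset from
the ECG and the S1/S2 burst fiducials from the PCG envelope
(A2 = aortic, P2 = pulmonic component of S2):

| index | definition |
|---|---|
| S2 splitting (ms) | A2 peak → P2 peak |
| S1–S2 (ms) | S1 peak → S2 (A2) peak ≈ mechanical systole |
| S1–S2/RR (%) | (S1–S2) / RR × 100, the systolic fraction |
| EMAT (ms) | Q onset (ECG) → first S1 peak (PCG) |
| EMAT/RR (%) | EMAT / RR × 100 |

Per-beat values are averaged over 30 consecutive clean end-expiration
beats per subject (mean of ratios, not ratio of means).

The cohort analysis reproduces the published statistical battery:
Shapiro–Wilk and Levene checks, pooled-variance Student *t* (raw and
summary-statistic forms), Pearson χ² without continuity correction,
Pearson correlation, age-stratified interaction tests, non-parametric
(Mann–Whitney) AUC = P(score_ASD > score_control) + ½ P(tie) with
Hanley–McNeil SE and AUC ± 1.96·SE confidence intervals, Youden-index
cut-offs (J = sensitivity + specificity − 1, rule "score ≥ cut-off ⇒
positive"), repeated stratified 10-fold cross-validated AUC, stratified
bootstrap bias-corrected AUC (2·AUC_full − mean AUC_boot, 1,000
resamples), and multivariable logistic regression with Wald χ² and
per-unit odds ratios.

## Worked example

`examples/01_simulate_and_extract.py` synthesizes one ASD subject
(wide fixed splitting, 39.65 ms target) and runs the full pipeline:

```
recording: 76.5 s, 110 beats, 30 beats averaged
index          recovered     truth   error
s2_split_ms        39.86     39.58    0.28
s1s2_ms           238.82    238.65    0.17
s1s2_rr_pct        34.30     34.50   -0.20
emat_ms            96.92     96.64    0.28
emat_rr_pct        13.92     13.97   -0.05
```

Timing indices come back within a fraction of a millisecond of the
generator's ground truth on clean recordings.
`examples/03_roc_diagnostics.py` runs the diagnostic battery on a
simulated 50-vs-50 cohort:

```
s2_split_ms:
  AUC 0.790 (SE 0.045, 95% CI 0.701-0.879)
  cut-off >= 36.52: sensitivity 0.66, specificity 0.80, Youden J 0.46
  cross-validated AUC 0.786, bootstrap bias-corrected AUC 0.789
...
multivariable logistic regression (outcome: ASD):
  s2_split_ms: OR 1.12 per unit (95% CI 1.04-1.19, p = 0.0013)
  s1s2_rr_pct: OR 1.43 per unit (95% CI 1.17-1.75, p = 0.00054)
```

Each simulated cohort is one random draw, so its AUCs scatter around the
population value (≈ 0.83 for S2 splitting) with an SE of ≈ 0.04.

## Command line

```bash
asdscreen simulate --seed 1 --out run/ --n-per-group 50 --waveforms
asdscreen extract  --data run/ --out run/
asdscreen analyze  --table run/extracted_indices.csv --out run/
# or: asdscreen all --seed 1 --out run/
```

`simulate` writes WAV phonocardiograms, CSV ECG traces, JSON ground
truth, and the cohort table; `extract` recovers per-subject indices
(excluded subjects are listed in `rejects.csv` with reasons); `analyze`
writes the group-comparison, ROC, logistic and forest-plot tables plus a
JSON diagnostic report. Every run records seed, config hash and package
version in `manifest.json`, and identical configurations reproduce
byte-identical outputs.

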