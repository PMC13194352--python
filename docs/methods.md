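# Methods

## Signal model

**ECG (500 Hz).** Each beat is a sum of Gaussian bumps anchored to the R
peak: P (amp 0.15, −160 ms, σ 25 ms), Q (−0.10, −24 ms, σ 6 ms),
R (1.0, 0 ms, σ 8 ms), S (−0.25, +18 ms, σ 6 ms), T (0.30, +220 ms,
σ 45 ms). Widths keep most spectral energy inside the 0.5–40 Hz
acquisition band. The declared Q-onset ground truth is the tangent-method
onset of a Gaussian limb, center − 2σ (28 ms before R). RR intervals are
60000/HR ms with multiplicative Gaussian jitter (relative SD
`rr_jitter_fraction`, truncated at ±3σ).

**PCG (2,000 Hz).** Heart sounds are decaying sinusoids with a fast
Gaussian attack: envelope `exp(−u²/2σ_a²)` for u<0, `exp(−u/τ)` for u≥0.
S1: 60 Hz carrier, σ_a 3 ms, τ 15 ms, amplitude 1.0. A2/P2: 110 Hz,
σ_a 1.5 ms, τ 7 ms, amplitudes 0.60/0.42 (S1-dominant, as at the mitral
recording site). A2 and P2 multiply one shared carrier, so the combined
S2 envelope is exactly the sum of the two component envelopes and has
local maxima at the placed fiducials. Placements invert the index
definitions: S1 peak = Q onset + EMAT; A2 = S1 peak + S1–S2; P2 = A2 +
instantaneous split. White Gaussian noise is added at a stated SNR
(default 30 dB re. overall signal RMS).

**Respiration.** The instantaneous split is
`s2_split_ms + resp_mod_ms·sin(φ)` with respiratory phase φ; the
end-expiration convention is φ = π (where sin φ = 0, so gated beats carry
the nominal split). Controls default to `resp_mod_ms = 10`; ASD subjects
to 0.5 ms (fixed splitting) — the physiology fixes only this contrast,
not the magnitudes. Burst amplitudes are optionally modulated as
`1 − depth·cos(φ)` (default depth 0.10), which lets respiratory phase be
re-estimated from the acoustic channel alone (per-beat envelope peaks →
detrend → Hilbert phase).

A composed subject records ≥ 75 s with free 4-s breathing cycles and a
≥ 35 s end-expiratory hold, so that a run of 30 *consecutive* gated
beats exists — the acquisition protocol this emulates (30 consecutive
end-expiration beats) presumes such a pause. Beat-to-beat index
variability defaults to 2 ms SD (no published within-subject value
exists; the parameter is exposed without any fidelity claim). Artifact
bursts are 1 s of noise with envelope ≈ 5× the S1 peak, injected at a
Poisson rate and logged in the ground truth.

**Index-level cohorts.** Per-subject indices, demographics, and optional
echocardiographic covariates are drawn from group normal marginals (the
published means ± SDs; the reference cohort is 50 ASD / 50 control
children aged 4–12). ASD-size and RVEDVI marginals are synthetic
stand-ins (12 ± 4 mm, 95 ± 15 mL/m²; values typical for hemodynamically
significant pediatric secundum ASD) because only their correlations with
the indices are published (r = 0.72/0.76 for S2 split, 0.65/0.69 for
S1–S2/RR). Unpublished pairs needed to make that correlation matrix
jointly positive semidefinite are set once: index–index r = 0.50,
size–RVEDVI r = 0.70. Waveform cohorts take split/EMAT/S1–S2/HR targets
per subject; the ratio indices then emerge from the waveform rather than
being drawn, so only index-level cohorts exactly reproduce the published
ratio marginals.

All randomness derives from one integer seed via
`numpy.random.SeedSequence`; equal seeds give byte-identical output.

## Preprocessing

Zero-phase (forward–backward) Butterworth filtering so group delay
cannot bias timing: PCG 20 Hz high-pass (order 4) + 950 Hz low-pass
guard (the nominal 20–1,000 Hz band is unrealizable, 1,000 Hz being
Nyquist); ECG 0.5–40 Hz with an order-6 low-pass section so 50/60 Hz
power-line tones are attenuated ≥ 20 dB despite the nearby edge.

Artifact rejection works on contiguous 1-s windows of the PCG with two
thresholds (both configurable, defaults 30 % and 10 dB):

* **Amplitude variation** — the smoothed envelope's excess over the
  recording-median per-beat envelope peak,
  `max(0, max_env/median_beat_peak − 1)`. (A max−min definition inside
  the window would reject every clean window of a burst–gap signal,
  since each window spans both a burst and near-silence.)
* **SNR** — 10·log10 of burst-region power over noise power, the noise
  reference being the lowest-envelope quartile; for a structureless
  recording the two coincide and SNR ≈ 0 dB, rejecting it. The SNR rule
  is applied to the PCG (heart-sound quality is the binding constraint);
  which channel it governs is configurable.

End-expiration gating flags beats with |φ − π| ≤ tolerance (default
π/4). Phase comes from ground truth, an auxiliary phase channel, or the
acoustic amplitude-modulation estimator; with no phase obtainable the
gate degrades to all-pass with a warning.

## Delineation

* **R peaks**: 80 ms-integrated squared derivative, adaptive threshold,
  200 ms refractory, parabolic sub-sample refinement of the local ECG
  maximum.
* **Q onset**: tangent method in a 120 ms pre-R window — the steepest
  point of the Q downstroke extrapolated back to the local baseline
  (median of the isoelectric segment 110–60 ms before R). On a Gaussian
  Q limb this convention equals center − 2σ, matching the generator's
  declared anchor; the 40 Hz acquisition low-pass widens the limb
  slightly, leaving a sub-millisecond onset bias on clean signals.
* **S1/S2 bursts**: Shannon-style smoothed Hilbert envelope (σ 4 ms);
  S1 = dominant peak in [R, R+200 ms], S2 = dominant peak in
  [R+200 ms, R+0.6·RR]; onsets at the 10 %-of-peak-height crossing;
  beats with either sound below 15 % of the cohort-median S1 height are
  flagged invalid, not raised. The S1 peak is re-picked on a fine
  envelope (σ 0.75 ms) to remove the asymmetric-burst smoothing shift.
* **A2/P2**: within the S2 window (onset − 20 ms to onset + 120 ms), the
  two most prominent fine-envelope maxima (prominence ≥ 6 % of the
  window maximum, separation ≥ 2 ms), ordered in time; a single
  resolvable peak ⇒ split 0 with coincident fiducials.
* **Beat selection**: the earliest run of 30 consecutive beats that are
  valid ∧ artifact-free ∧ end-expiration-gated; if none exists, the
  longest qualifying run with a warning; none at all ⇒ the subject is
  excluded.

RR for the ratio indices is the beat's own interval (current R to next
R); the alternative convention is a one-line change upstream. "S2 peak"
in S1–S2 means the A2 peak (first component), configurable in principle.

## Statistics

Pooled-variance (Student) t rather than Welch: variance homogeneity is
asserted upstream by Levene, and with equal group sizes the two
statistics coincide anyway. The summary-statistic and raw-vector forms
agree to numerical precision (tested at 1e-9). χ² is Pearson without
Yates continuity correction — the correction would halve the published
sex statistic to 0 — with Fisher's exact fallback when any expected
count is below 5. The age × group interaction is the Wald test of the
product term in an ordinary linear model (no model is published for it).
All p-values are two-sided.

AUC is the mid-rank Mann–Whitney estimator (ties count ½), equal to the
trapezoidal area under the empirical ROC; its SE uses the Hanley–McNeil
exponential approximation (a DeLong SE is provided as an alternative)
and the CI is AUC ± 1.96·SE clipped to [0, 1]. Youden cut-offs are
reported as midpoints between adjacent distinct scores (the published
quarter-value cut-offs, 31.75 ms and 35.25 %, are characteristic of the
midpoint convention), with the positive rule "score ≥ cut-off" and
J-ties broken toward higher sensitivity. Cross-validated AUC is the fold
mean over *repeated* (10×) stratified 10-fold splits: with 50 + 50
subjects a single 10-fold split leaves 5 + 5 per fold and the fold-mean
wanders by ±0.05 between seeds; repetition stabilizes it while keeping
the estimator's slight downward small-sample shift (consistent with the
published CV AUC sitting just below the full-sample AUC). The bootstrap
is stratified (cases and controls resampled separately, so every
resample keeps both classes at n = 50/50), with bias-corrected estimate
2·AUC_full − mean(AUC_boot) and 2.5/97.5 percentile CI. Logistic
regression is Newton/IRLS maximum likelihood (convergence |ΔlogL| <
1e-8) with SEs from the observed information; zero-variance covariates
are dropped and reported; perfect separation raises a diagnostic error
rather than diverging.

## Numerical choices and degenerate inputs

Sub-sample peak times by parabolic interpolation throughout; times are
real-valued ms on a shared clock starting at 0, so indices are invariant
to resampling (tested against a 4,000 Hz PCG). Requested splits below
0.5 ms (the two-sample resolution at 2 kHz) warn but generate. Flat ECG
yields zero R peaks; a constant sample is rejected by the normality/
variance tests; zero-variance t is 0 (equal means) or signed infinity
(flagged); zero-margin 2×2 tables are errors.

## What the generator does and does not emulate

It emulates: identifiable P–QRS–T morphology, burst heart sounds with
controllable A2–P2 separation, respiratory split modulation present in
controls and absent in ASD, end-expiratory gating, amplitude artifacts,
additive wideband noise, and cohort marginals/correlations matching the
published tables. It does **not** emulate murmurs, S3/S4, ectopy or
non-sinus rhythm, baseline wander or electrode motion, frequency-
dependent chest attenuation, pediatric growth effects, or any
dynamical-system ECG realism. Passing round-trip tests therefore shows
the pipeline recovers the intended timing structure under controlled
conditions — not that it would survive every failure mode of real
pediatric recordings, where the published device relied on manual
review (replaced here by per-beat validity flags).

## Known limitations

* **Split resolution floor.** With ~110 Hz S2 energy, envelope methods
  cannot resolve A2–P2 separations below ≈ 8 ms; a 5 ms split reports 0.
  The estimator is linear (slope ≈ 1.04, intercept ≈ −1.7 ms) over the
  5–60 ms sweep used in validation, and the clinical operating range
  (cohort means 28–40 ms) sits well above the floor.
* **EMAT bias.** The acquisition low-pass slightly widens the Q limb,
  biasing the tangent onset and hence EMAT by ~1 ms on clean signals —
  inside the ±2 ms recovery budget but the largest systematic error in
  the pipeline.
* **Published rounding.** Some published test statistics (t for age,
  height, HR, EMAT, EMAT/RR; the Wald χ² values; the lower OR CI for
  S1–S2/RR) are not exactly recoverable from the rounded summaries they
  derive from; recomputed values are asserted instead where the
  discrepancy is established rounding (e.g., exp(0.456 − 1.96·0.121) =
  1.24 against a printed 1.25).
* **Problem sizes in validation.** The test suite uses 30–110-beat
  recordings, 20-subject waveform cohorts, 1,000-replicate Monte-Carlo
  checks at the 50 + 50 cohort size, and 100,000-draw moment checks for
  the cohort generator — sizes chosen to make sampling error negligible
  relative to each tolerance.
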