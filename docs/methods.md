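# Methods

This note documents the generative model behind the synthetic sessions, the
two coupling estimators, the statistical machinery, the numerical choices,
and the limits of what the test suite demonstrates.

## Synthetic session model

Each session is one subject performing one task: `n_trials` repetitions of
a 10 s rest + 5 s contraction timeline, sampled at 1200 Hz with 53 EEG and
4 bipolar sEMG channels (hand extensor/flexor, tibialis anterior, soleus).

**EEG background.**  Every channel carries unit-variance 1/f ("pink")
noise plus a shared low-rank spatial mixture (4 pink sources with random
mixing weights).  The low-rank term makes the 53-column regression design
correlated, as scalp EEG is; there is no forward-model (volume-conduction)
realism beyond that.

**Cortical drives.**  During contraction windows, each task has a small set
of coupled sensorimotor EEG channels (hand tasks around C3, foot tasks
around Cz).  Each coupled channel carries its own independent band-limited
drive — zero-phase band-pass-filtered Gaussian noise in the alpha (8–14 Hz),
beta (15–30 Hz) or gamma (30–80 Hz) range, bands assigned cyclically —
added at `injection_sd` times the background amplitude.  Band-limited noise
rather than sinusoids keeps coherence below 1 and frequency-resolved.

**Muscle transmission.**  Task-related sEMG channels receive the sum of the
delayed drives, `Σ_b gain_b · s_b(t − delay)`, with a conduction delay of
15 ms (typical cortico-muscular latency; hand and foot are not
distinguished).  In the default `"modulated"` mode the delayed drive also
amplitude-modulates a broadband 5–200 Hz carrier before white noise is
added, giving a realistically broadband sEMG spectrum while the additive
term keeps a linear, coherence-visible pathway.  The `"linear"` mode drops
the carrier (pure additive transmission + noise) and is the regime in which
support recovery is provable; oracle tests use it with `injection_sd = 1`.
Non-task channels receive independent noise scaled to the task channels'
variance, so channel variance carries no label information.

**Default operating point.**  `injection_sd = 0.2`, `gain = 0.3` per band.
These place the emulated study in the weak-coupling regime characteristic
of cortico-muscular data: pooled 40-segment coherence peaks around 0.2–0.35
against a confidence limit of 0.074, while single-trial coherence almost
never exceeds its own (much higher) 4-segment limit.  In this regime
single-trial M_sCoh features classify task vs non-task sEMG channels near
chance while the sparse features remain clearly informative — the contrast
the package exists to measure.  Stronger settings make both features
informative and the comparison uninteresting.

**Determinism.**  Every sample is a pure function of
`(config, seed, subject_id, task_id)`; identical inputs give bit-identical
sessions.

## Preprocessing

EEG is band-passed 2–100 Hz, sEMG 5–200 Hz (never rectified — rectification
introduces nonlinearity and complicates coherence interpretation), both
with 4th-order zero-phase (forward–backward) Butterworth filters; a
zero-phase 50 Hz IIR notch removes line interference.  Zero-phase filtering
matters because both estimators are sensitive to relative EEG–EMG timing.
Epochs keep the central 3 s of each 5 s contraction (1 s truncated at head
and tail), indexed 0-based with half-open intervals.  Artifact correction
is a no-op hook: synthetic sessions contain no eye/muscle artifacts; real
data should pass through an established artifact pipeline first.

## Coherence features (M_sCoh)

Auto-/cross-spectra are averaged over 0.75 s non-overlapping Hann segments
(4 per trial; 80 when pooling a 20-trial task) and squared coherence is
thresholded at the analytic confidence limit `CL = 1 − (1−α)^(1/(N−1))`,
the exact per-bin null 95th percentile for independent signals (the null
coherence with N segments is Beta(1, N−1), so `P(C > CL) = 1 − α`
exactly; the Monte-Carlo calibration in the acceptance script reproduces
it to three decimals).  The per-channel feature averages the *clamped*
excess `max(Cxy − CL, 0)` over the in-band bins and normalizes by the bin
count; only significant excesses count, and an all-null band yields
exactly 0.  Single-trial features recompute CL at that trial's segment
count (N = 4 ⇒ CL ≈ 0.632) — a deliberately honest account of how little
evidence 4 segments provide.  Band edges use half-open inclusion
`[f_min, f_max)`; the "total" band is 5–100 Hz, the intersection of the
EEG and sEMG passbands.

## Sparse features (contribution degree)

Each (trial, sEMG channel) pair defines `y = Xβ + ε` with the 53 EEG
columns centred and scaled to unit Euclidean norm (penalty fairness across
channels of unequal variance; CD is reported on this standardized scale).
The solver minimizes `‖y − Xβ‖₂² + λ‖β‖₁` — no 1/(2n) factor, so the
all-zero KKT condition is `λ ≥ 2·max_j |X_jᵀy|` and the orthonormal-design
solution is the soft threshold at λ/2.  Cyclic coordinate descent on the
53×53 Gram matrix (numba-compiled) runs until the relative objective
change per sweep vanishes (10⁻¹⁴, capped at 10⁴ sweeps); at exit the
objective matches an independent projected-gradient solver to ~10⁻¹³ and
the closed-form oracle to machine precision.  `sklearn_alpha` converts λ
to scikit-learn's 1/(2n) convention for cross-checks.

λ is selected per fit by 5-fold cross-validated prediction error over a
30-point logarithmic grid spanning 3 decades down from λ_max, with seeded
fold assignment and warm-started paths; ties pick the sparser λ.  CD keeps
the positive part of β̃; `absolute=True` exposes |β̃| instead, since
discarding negative couplings is an interpretive choice, not a
mathematical necessity (see Limitations).

## Classification and evaluation

Feature tables hold one row per (subject, task, trial, sEMG channel) with
53 predictors and the task-related label (binary mode), or one row per
trial with the 4 channels' vectors concatenated (212 predictors) and the
task id as label (multitask mode).  The 80/20 split stratifies jointly by
label and subject.  The model search draws seeded hyperparameter
configurations round-robin across seven classifier families, scores each
by k-fold cross-validated error, and refits the winner on all training
rows; the budget (default 14–28 candidates) bounds total fits.  Metrics
come straight from the confusion counts: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy (TN+TP)/total, in percent; multiclass
evaluation reports macro one-vs-rest sensitivity/specificity plus overall
accuracy.  Leave-one-subject-out trains one model per held-out subject and
audits by id that no held-out row enters training.

## Group statistics

Task-related vs non-task coupling values are compared with a paired
Wilcoxon signed-rank test: zero differences excluded, mid-ranks for ties,
two-sided p from the exact permutation distribution for n ≤ 25 (dynamic
programming over doubled ranks, valid under ties) and from the normal
approximation with tie and continuity corrections otherwise.  Z is signed
by W⁺, so swapping the columns flips its sign.

Pairing units: the default pairs every (subject, EEG channel) after
averaging trials and sEMG channels within condition — informative for
effect description, but the 53 pairs within one subject share trials and
are statistically dependent.  Calibration studies therefore pair at the
subject level (`unit="subject"`), where pairs are independent by
construction; on zero-coupling replicate studies this rejects at the
nominal ~5% (the exact test's attained level at n = 12 subjects), which
the acceptance script verifies over 400 replicates.

## Problem sizes used by the tests and the acceptance script

Chosen so the whole suite runs on one CPU in minutes: null calibration
2000 white-noise pairs × 80 segments; oracle checks 50 short signals and
20–30 small LASSO problems; support recovery 100 single trials; the
classification comparison a 5 subjects × 4 tasks × 10 trials study (800
feature rows); type-I calibration 400 replicate studies of 12 subjects at
a reduced 400 Hz sampling rate and shortened rest (the tested properties
are invariant to both).  Unit tests shrink further wherever the property
under test allows it.

## Known limitations

* **Zero-lag readout vs conduction delay.**  The regression uses
  instantaneous regressors, and a band-limited drive decorrelates with its
  15 ms-delayed copy by the factor `∫S(f)cos(2πf·0.015)df`: ≈ +0.50 for
  alpha, ≈ −0.48 for beta, ≈ +0.12 for gamma.  A beta-band coupling
  therefore appears as a *negative* coefficient, which the positive-part
  CD discards, and a broadband gamma drive is strongly attenuated.  Full
  support recovery of all coupled channels from the positive-part CD is
  consequently not achievable at a 15 ms delay — the strongest channel is
  still identified in ≳95% of single trials, and the unsigned support
  (|β̃|) recovers ~99% of coupled channels.  Delayed or directed regressor
  models would remove this limitation but are out of scope.
* **Prediction-optimal λ is not a support estimator.**  With n ≈ 3600 ≫
  p = 53, CV-minimal λ is small and the selected support dense; support
  precision from the CV-λ CD is accordingly low even when the ranking is
  correct.  The package reports the feature vector, not a support
  estimate.
* The generator has no volume-conduction forward model, no motor-unit
  firing statistics and no force signal; passing tests demonstrate
  estimator correctness and the weak-coupling contrast, not physiological
  completeness.
* EDF interchange is not provided; the documented HDF5 layout is the
  canonical format (16-bit EDF quantization would anyway be lossy for the
  simulated floats).
* Per-band significance tests are reported without multiple-testing
  correction across bands.
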