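# Methods

`conflictstop` implements, end to end, the analysis chain of a
conflict-modulated response-stopping study: a Simon task combined with a
stop-signal task, recorded with 60-channel EEG.  Because such recordings
are not publicly deposited, every stage is exercised against a synthetic
data generator with known ground truth; this note documents the models,
the generator, the numerical choices, and what passing tests do and do
not establish about real data.

## Behavioral model

### Task and staircase

A session has 936 trials in 9 blocks of 80 go + 24 stop trials, each
split evenly over congruency (stimulus side matches / mismatches the
responding hand) and stimulus position.  On stop trials the stimulus
changes color after the stop-signal delay (SSD).  The SSD is tracked
with a one-up/one-down staircase per congruency condition: +50 ms after
a correct rejection, −50 ms after a failed stop, clamped to
[50, 1000] ms, starting at 250 ms.  This staircase converges on the
delay at which stopping succeeds half the time, which is what makes the
mean-method SSRT estimator valid.  A speed-up warning rule (mean RT of
the last 50 responded trials above 450 ms) is logged but does not alter
simulated behavior, since no behavioral model of the warning exists.

### Race model

Trial outcomes follow the independent-horse-race account: a go process
and, on stop trials, a stop process race; a response is emitted iff the
go finishing time beats SSD + stop finishing time.  Finishing times are
ex-Gaussian (normal + exponential), one parameter set per congruency:

| process | congruent (μ, σ, τ) | incongruent (μ, σ, τ) | mean |
|---|---|---|---|
| go   | 400, 50, 93.7  | 400, 50, 121.57 | 493.7 / 521.6 ms |
| stop | 220, 20, 49.86 | 220, 20, 59.01  | 269.9 / 279.0 ms |

Defaults are tuned so the condition means approximate the study-scale
values: a ~28 ms congruency cost on go RT and a ~9 ms cost on the stop
latency.  Go misses (probability 0.01) and wrong-effector errors (0.02)
are small and condition-independent.  The race is context-independent
(go and stop finishing times independent), the standard assumption under
which mean-method SSRT = mean correct-go RT − mean SSD is consistent.
At session scale (108 stop trials/condition) the estimator recovers the
generative stop latency within ±20 ms; the residual positive bias
(~5–10 ms) comes from the skewed stop distribution and staircase
start-up transients and is inherent to the mean method.

### Exclusion rules

Three screens, applied to per-subject condition summaries: stopping
probability outside [0.25, 0.75] in either condition; SSRT difference
(incongruent − congruent) above 50 ms; and Tukey fences
(Q1 − 1.5·IQR, Q3 + 1.5·IQR, computed across subjects per measure per
condition over {go RT, go accuracy, SSRT, p(respond|stop)}), excluding a
subject flagged in more than one measurement.  The Tukey rule is
cohort-relative and therefore not idempotent; the other two are.
Congruency contrasts are two-sided Wilcoxon signed-rank tests, exact for
n ≤ 25 pairs, continuity-corrected normal approximation above.  An
all-zero difference vector returns p = 1 (degenerate input, not an
error).  Full repeated-measures ANOVA is out of scope by design: the
contrasts are what the bespoke chain consumes.

## Synthetic EEG

### Signal model

Stop-trial epochs span −200…+995 ms around letter onset (307 samples at
256 Hz; 1200 ms is not an integer sample count, so the grid is the
half-open `t_i = −200 + i·1000/256`).  Epoching on letter onset (rather
than the variable stop-signal onset) is a documented choice; the
generator takes the event as configurable in principle, and the windows
below are stated relative to letter onset.

Each epoch is a sum over K = 4 sources of `topography × activation(t)`
plus noise.  Group topographies are mutually orthonormal spatially
smooth patterns; per-subject topographies are small seeded jitters of
them (scale 0.05, renormalized).  Orthogonality matters: with
correlated topographies, one source's condition effect leaks into the
others' spatial axes with arbitrary sign and the per-window effect
sizes are no longer the generative values.  Activations are a shared
deterministic waveform (Gabor-like bumps at well-separated latencies,
time-ensemble variance 12, exactly orthogonalized across sources) plus
the condition effect: ±effect_size/2 (incongruent minus congruent
= +effect_size) inside the source's window.  Default windows and
standardized effects — (85–245 ms, 0.5), (300–700 ms, 0.8),
(90–420 ms, 0.6), (110–430 ms, 0.6) — emulate early-attentional through
response-related discriminability with peak single-source AUC around
0.64–0.71.

Separated latencies are essential, not cosmetic: temporally overlapping
deterministic waveforms are statistically *dependent* even when
decorrelated, and independent-component estimation cannot separate
them.

### Noise model

Noise has two parts, both scaled by `noise_sd` (default 1):

1. a **white Gaussian floor** of SD `noise_sd` per channel and sample —
   the only noise along the signal axes, so the trialwise
   discriminability along a source axis is exactly
   `effect_size / noise_sd` and closed-form oracles
   (AUC = Φ(d/√2)) hold exactly;
2. **structured background EEG**: 16 spatially smooth sources with
   iid Laplacian (super-Gaussian) activations and geometrically decaying
   gains (total variance 1900·noise_sd², ratio 0.8), constructed
   orthogonal to the signal topographies and drawn *separately per
   condition*.

The background serves three purposes.  It gives the data a realistically
decaying spatial eigenspectrum, so the 98% PCA retention rule lands near
20 dimensions as in real scalp recordings.  It makes the retained
subspace non-Gaussian, hence identifiable by ICA — purely white
Gaussian noise leaves a rotation-invariant subspace in which fixed-point
ICA neither converges nor recovers topographies.  And its
condition-specificity emulates the empirical fact that only a handful of
components match across separately decomposed conditions: the four
signal sources pair at |r| ≈ 1 while background components pair below
threshold.  What it does not emulate: temporal autocorrelation, ocular
and muscle artifacts, volume-conducted topography overlap between
conditions, and channel-specific noise scales.  Passing tests therefore
show the chain is correct under its assumptions, not that real EEG meets
them.

## Group ICA (C = WX)

Per condition: epochs from all subjects are concatenated along time
(channels × Σ trials·samples), the per-channel mean removed, and the
covariance eigendecomposed.  `n_retained` = min(k_max = 20, smallest k
whose cumulative eigenvalue fraction ≥ 0.98).  FastICA (symmetric
fixed-point, tanh contrast, tol 1e-4, max 1000 iterations, seeded) runs
on the whitened scores; the unmixing is composed with the PCA projection
so `W` acts on raw centered channel data.  Sign/scale indeterminacy is
resolved by unit-norm topographies (columns of `A = pinv(W)`) with a
positive peak entry; activations absorb scale.  Back-reconstruction is
the direct projection `C_s = W X_s`, exact under the shared-unmixing
model (the partitioned group-ICA variant would differ only by a
per-subject reweighting).  Non-convergence raises an error naming the
seed.  Congruent and incongruent fits share no state.

## Component matching

Decompositions of the two conditions come back with arbitrary order,
scale and sign, so components are paired by the Pearson correlation of
their topographies, in absolute value (ICA sign is arbitrary).  Greedy
clustering: templates are visited in random order; an unconsumed
template claims, per condition, up to 3 unconsumed components with
|r| ≥ 0.85 to it; each cluster emits its best cross-condition pair; a
consumed component is unavailable to later clusters.  The pass is
repeated over 40 seeded template orders and the most recurrent pairing
kept (ties: higher total |r|, then lower indices), making the outcome
insensitive to component order.  `sign_flip` records r < 0.  On the
default ground truth this yields exactly four pairs, one per true
source, identical to the exhaustive assignment maximizing total |r|.

## Decoding

Per subject and pair, each condition's trials are back-projected to
channel space (`A_k × C_{s,k}`, rank-1 by construction; the paired
component of the other condition's decomposition serves its trials).
Classes are balanced by seeded under-sampling of the majority class;
stratified 5-fold cross-validation; per time sample, the 60 channel
amplitudes (standardized by training-fold statistics, per channel per
time) feed a linear maximum-margin classifier (L2-regularized
squared-hinge SVM, C = 1, no hyperparameter search); performance is the
rank-based AUC of decision values, averaged over test folds.  Temporal
generalization evaluates each trained classifier at every test time in
the same split, so the matrix diagonal reproduces the time course
exactly.  On rank-1 data the 60 features are informationally equivalent
to the 1-D activation; the classifier is run on the 60 channels as the
method prescribes, and the equivalence is exploited only to verify
calibration.

Two calibration facts, established empirically and worth knowing when
interpreting real analyses of this design:

* decoding the raw 60-channel epochs attenuates AUC below the
  closed-form oracle (≈0.64–0.69 instead of 0.76 at d = 1 here),
  because weight estimation against 16 strong background directions
  from ~10² trials is noisy;
* decoding back-projections from *separately fitted* per-condition
  decompositions can dramatically inflate AUC (≈0.96 here) and spread
  significance over the whole epoch: the two conditions' rank-1 data
  lie along slightly different estimated topographies, and a linear
  classifier can separate the two lines via the strong shared ERP,
  independently of any condition effect.  The same mechanism plausibly
  contributes to very long significant windows in real cross-condition
  component decoding.

Chance-level calibration (grand-mean AUC 0.5) holds on every route.

## Group inference

AUC − 0.5 is tested per sample across subjects with the Wilcoxon
signed-rank statistic, standardized as `z = Σ sign·rank / √(Σ rank²)`
(tie-robust; zeros dropped).  Sample p-values are exact for ≤ 25
subjects — the sign-flip null of the rank sum is enumerated by dynamic
programming, so midrank ties are handled exactly — and normal above.
Clusters form among same-sign samples with p < 0.05 (two-sided),
adjacency in 1-D, 4-connectivity in 2-D; cluster mass is the summed z.
The null distribution is the maximal cluster mass under random
per-subject sign flips of AUC − 0.5 — the exact exchangeability scheme
for a one-sample test against chance (trial-label permutation with
decoder refits would cost ~10³ more compute for the same control here).
Because sign flips leave the ranks of |AUC − 0.5| untouched, each
permutation is a single matrix product; 2-D runs over 307² pixels are
cheap.  Cluster p = (1 + #{null ≥ observed}) / (1 + n_perm), flooring
p at 1/(n_perm+1).  Empirical family-wise error over 200 null
replicates stays within the binomial band of the nominal 0.05.

## Brain–behavior regression

For each pair with a significant diagonal cluster, the per-subject mean
AUC over that cluster's extent is regressed onto the subject's SSRT
congruency effect (incongruent − congruent, ms).  The regressor is a
feed-forward network for scalar input: 5 tanh hidden units plus a
linear bypass, `f(x) = c0 + c1·x + Σ v_j tanh(w_j x + b_j)`, trained
full-batch by L-BFGS (analytic gradients, 5 seeded restarts, best
training loss kept) on inputs and targets standardized with
training-fold statistics.  Weight decay (α = 0.5) applies to the hidden
weights only, so an uninformative input collapses the fit toward the
least-squares line (leave-one-out RMSE ≈ target SD, the mean-predictor
level) while an exactly linear relationship passes through unshrunk
(LOO RMSE ≈ 0).  A plain tanh network cannot do both: saturation makes
it extrapolate flat at the cohort's extreme subjects, which is exactly
where leave-one-out evaluates it.  Leave-one-out integrity is verified
by poisoning: perturbing a held-out target leaves its own prediction
bit-identical.  RMSE gets a 95% subject-bootstrap CI (1000 resamples);
pairs are compared by paired t-tests on per-subject squared errors,
with identical error vectors reported as degenerate (t = 0, p = 1).

## Pipeline, determinism, problem sizes

The orchestrator runs simulate → behavior → group ICA (both
conditions) → matching → decoding → inference → brain–behavior, writing
every stage's outputs plus a manifest with config hash, per-stage
derived seeds (`SeedSequence([master, stage_index])`), durations and
sha256 checksums.  Re-runs skip stages whose outputs verify; a
downstream stage refuses to run when an upstream checksum no longer
matches.  All randomness flows from the master seed; two runs with the
same config are byte-identical.

Default problem sizes are chosen to exercise every stage at full
fidelity while staying desk-scale: the pipeline default is 12 subjects
with the full 936-trial design; tests use 6–20 subjects, 40–108 stop
trials per condition, 200–500 permutations, and 100–200 replicate
simulations for calibration properties.  The task design itself (trial
counts, staircase, windows, thresholds such as the 0.85 matching
criterion and 98% retention) is never scaled.

## Known limitations

* The mean-method SSRT estimator is the only one implemented (no
  integration method, no trigger-failure modeling).
* The generator's background is temporally white; spectra and
  autocorrelation of real EEG are not emulated, so time-domain
  smoothness of real AUC curves (which widens cluster nulls) is absent.
* Source localization, preprocessing (filtering, artifact rejection)
  and go-trial EEG are out of scope.
* The cross-decomposition inflation described under *Decoding* means
  absolute AUC values from matched-pair back-projections should be
  interpreted relative to carefully constructed nulls, not chance.
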