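# Methods

## Behavioural model

Each of the six stimuli (A–F) carries an expected value Q ∈ [0, 1],
initialised at Q0 = 0.5 — the chance expectation of a binary outcome; the
task description is silent on the starting value, and the midpoint is the
conventional neutral choice. After feedback r ∈ {1, 0} the chosen
stimulus updates by

    Q ← Q + α_gain (r − Q)   if r = 1
    Q ← Q + α_loss (r − Q)   if r = 0

so positive and negative prediction errors have separate step sizes.
Choice between the two presented stimuli is a softmax on their values
with inverse temperature β ∈ [0, 100]; we compute it as a logistic of
β(Q_a − Q_b), which is the same function without overflow risk. Misses
produce no update and contribute nothing to the likelihood. With rewards
in {0, 1} and Q0 ∈ [0, 1], values can never leave the unit interval (the
update is a convex combination), and transfer trials — which deliver no
feedback — leave the value vector frozen at its end-of-learning state.

Derived per-trial quantities: Q_chosen, Q_unchosen, the signed
prediction error r − Q_chosen and its magnitude, and ΔValue. During
learning ΔValue is Q_chosen − Q_unchosen; in transfer it is
Q(optimal) − Q(suboptimal) from end-of-learning beliefs, with optimality
defined by the scheduled reinforcement ranking (A > B, …; for novel
pairs, the member with the higher scheduled probability).

## Hierarchical estimation

Subject parameters live on an unbounded probit scale, z ~ N(μ_z, σ_z)
per parameter, with α = Φ(z) and β = 100·Φ(z). The β scaling is our
reading of the stated 0–100 bound combined with the probit transform;
the transform is applied as the conventional latent-normal-with-Φ-link.
Priors are μ_z ~ N(0, 1) and σ_z ~ U(1, 1.5). The σ prior is unusually
narrow — it forces substantial group spread — and is kept as the default
deliberately; `sigma_bounds=(0.01, 3)` is available for recovery studies
with tighter cohorts.

Sampling uses emcee's affine-invariant ensemble sampler with
differential-evolution proposals (80% DEMove, 20% DESnookerMove), which
handle the strong posterior correlation between learning rates and the
inverse temperature far better than the stretch move once the parameter
count reaches tens of dimensions (6 hyperparameters + 3 per subject).
The log posterior is vectorised over walkers and subjects, so one
ensemble evaluation propagates every walker through every subject's
trial sequence. Walkers double as chains for arviz's split-R̂ and ESS;
because walkers interact, these diagnostics are conservative — R̂ above
1.1 triggers a warning rather than an error, and hyper-level R̂ in the
1.2–1.6 range is common at the default budgets even when recovery checks
pass. Walkers start in a ball (SD 0.25 on the probit scale) around
per-subject maximum-likelihood estimates (multi-start Nelder–Mead),
which removes most burn-in while keeping the ensemble overdispersed.
Defaults: walkers = max(2·dim, 64), 1000 warmup steps, 500 retained
draws; the recovery studies in the test suite use 2500 warmup and
thinning of 3. Non-centred parameterisation is unnecessary for a
gradient-free ensemble sampler, so subject z's are sampled directly.

Posterior-predictive learning curves re-simulate each subject with its
posterior-mean parameters through a fresh schedule and bin
optimal-choice accuracy in blocks of 16 trials per pair.

The good-learner criterion is accuracy strictly above 60% on all three
trained pairs (a subject at exactly 60% on any pair is excluded).

## Synthetic data generator

The generator emulates the printed task: 300 learning trials (equal
counts of AB, CD, EF; pair-level reinforcement 80:20 / 70:30 / 60:40),
360 transfer trials (24 per pair, optimal member left on 12 of 24),
onset jitters {0, 500, 1000, 1500} ms, 4 s trials, and 20% null trials
modelled as gaps with no regressor. Cohort defaults (μ_z = −0.5, −0.9,
−1.2; σ_z = 1.1) give median learning rates around 0.31/0.18 and a
median β near 12 — a moderately heterogeneous adult cohort in which
roughly half to three-quarters of subjects pass the good-learner filter.
Agents respond on every trial by default; a configurable miss rate and
an optional log-normal response-time column exist for robustness checks.

ROI series are built as baseline + Σ amplitude·HRF(t − onset) + AR(1)
Gaussian noise at 0.5 Hz, with a canonical double-gamma HRF (peak 6 s,
undershoot 16 s, peak-normalised). Stimulus-locked amplitudes are
b0 + b_Qc·Q_chosen + b_Qu·Q_unchosen; feedback-locked amplitudes are
c0 + c_s·RPE + c_u·|RPE|. Default weights plant the structure the
deconvolution stage is meant to find: the value contrast in dorsal
striatum and visual regions, signed-RPE modulation in striatal and
visual regions, and unsigned-RPE modulation negative in the accumbens
and positive in the FFA. Single-trial transfer betas are
w_roi · s · |ΔValue| + N(0, σ_beta) with s = ±1 for optimal/suboptimal
choices; coupling the magnitude to |ΔValue| makes easy choices more
separable, which is what gives the negative uncertainty–ΔValue slope
downstream. What the generator does **not** emulate: voxel-level
structure, scanner drift beyond AR(1), motion, physiological noise,
inter-regional correlation beyond shared event structure, and any
mechanistic response-time process. Passing tests therefore demonstrate
correctness of the estimators under the stated generative assumptions,
not robustness to everything real fMRI data contains.

## FIR deconvolution

Series preprocessing: third-order Savitzky–Golay baseline over a 120 s
window, percent-signal-change about that baseline (when the series mean
is near zero the residual is already in change units and is left
unscaled), then linear interpolation from 0.5 Hz to 3 Hz. Linear
interpolation preserves the original samples and lets the design exploit
the 500 ms onset jitters.

The design matrix holds one indicator column set per event type (delta
at the onset sample, shifted over lags) and one per modulator (delta
scaled by the modulator value). Modulators are mean-centred and, by
default, z-scored within event type; centring makes modulation estimates
invariant to constant offsets and z-scoring makes coefficients
comparable across regions. The FIR window is 48 taps (16 s at 3 Hz) —
longer than the 0–8 s window of interest, to avoid truncation bias.
Stimulus and feedback streams are estimated simultaneously in one ridge
fit; when two event types never overlap in time the Gram matrix is block
diagonal and the simultaneous fit equals separate fits.

The ridge solution is the closed form (XᵀX + λI)⁻¹Xᵀy via Cholesky;
λ = 0 falls back to least squares and rank-deficient designs are
rejected with guidance to set λ > 0. The penalty is chosen by 5-fold
cross-validation over *contiguous* time blocks (preserving noise
autocorrelation) on a 20-point log grid spanning 1e−4 to 1e5.

Group inference regresses the per-subject modulation estimates on an
intercept at each time point and flags coefficients with p < α inside
0–8 s, α = 0.0125 — 0.05 Bonferroni-corrected over the four modulator
families tested in that window (chosen value, unchosen value, signed and
unsigned prediction error), not over individual time points. The value
contrast ΔValue = (Q_chosen modulation − Q_unchosen modulation) is
tested the same way as a per-subject difference time course. Contiguous
significant runs are reported as intervals. An optional
decision-duration correction (boxcar of response time for stimulus
events) exists but is off by default, as no single convention is
canonical.

## Random-forest decoding

Per-subject transfer beta tables are concatenated into one fixed-effects
matrix; rows are shuffled with a recorded seed; misses are dropped.
subject_id and trial_sign enter as integer-coded features (tree splits
on integer codes approximate native categorical splits). The matrix
splits 2/3 training, 1/3 validation.

Each of the (default 2000) trees grows on a class-balanced bootstrap:
equal counts drawn with replacement from each class, so the forest
cannot learn the optimal-choice base rate. Rows absent from a tree's
bootstrap are its OOB sample; aggregated OOB votes give the training
error. mtry (features considered per split) defaults to ⌊√p⌋ and can be
tuned by a stepwise ×1.5 search accepting steps that improve OOB error
by more than 5% relative — mirroring the standard R tuning procedure.

Permutation importance permutes one feature column over the training
rows and re-aggregates OOB votes; importance is the mean accuracy drop
over repeats (default 10), and negative values are meaningful (the
feature hurt). Validation predictions use the majority vote; an exact
0.5 tie resolves to "suboptimal" for determinism. AUC is computed from
vote shares — the only continuous score a majority-vote forest provides.
Prediction uncertainty is the disagreement share 1 − max(v, 1 − v) ∈
[0, 0.5]; ΔValue is regressed on it by OLS and summarised by slope and
adjusted R². Ablations remove or isolate the striatal
(caudate/putamen/accumbens), frontal (vmPFC/M1/DLPFC/preSMA) and
perceptual (FFA/OC) groups; difficulty splits take the easiest and
hardest thirds of |ΔValue| (the tercile cut is our choice; no canonical
value exists).

## Pipeline and reproducibility

Stages (simulate → fit-q → deconvolve → decode) exchange artifacts on
disk: TSV for event tables, CSV for matrices and tidy statistics, JSON
for reports, YAML for configuration. Every stage derives its seed
deterministically from the global seed and the stage name; no global
random state is mutated, so re-running a configuration reproduces every
output byte for byte. A manifest records the configuration hash, stage
seeds and outputs, including partial completion on failure.

The deconvolution stage of the bundled pipeline processes the first
subject's series (the generator writes one subject's ROI series by
default); multi-subject group GLMs are driven through the library
(`group_modulation_glm` on pooled per-subject fits), as in the test
suite.

## Problem sizes in the test suite

Recovery and control studies run at sizes chosen to make the checks
informative while keeping the suite practical to iterate on: hierarchical
recovery uses 20 subjects × 300 trials with 2500 warmup steps and 500
retained draws; forest controls use matrices of 800–5000 rows with
300–500 trees and 1–3 importance repeats; FIR recovery uses 80–100
events over ~10 minutes of simulated signal. The full-scale defaults
(2000 trees, 43 subjects) remain the package defaults.

## Known limitations

- The ensemble sampler's walkers-as-chains R̂ is conservative and slow to
  fall below 1.1 on the hyperparameters; treat the warning as a prompt
  to lengthen the run, and prefer the recovery checks as ground truth
  when validating changes.
- β is weakly identified for near-random responders (α → 0 flattens the
  likelihood in β); hierarchical pooling mitigates but cannot remove
  this.
- The decoder's integer coding of categorical features can only
  approximate arbitrary category partitions; with ≤ 3 trial-sign levels
  and ordered subject codes this is benign, but a native categorical
  tree learner would be preferable for many-level categoricals.
- The FIR stage assumes linear time-invariant responses; overlapping
  nonlinear saturation is not modelled.
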