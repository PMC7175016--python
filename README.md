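# valsight

Model-based analysis of value learning and its neural readout, built for
computational cognitive neuroscientists studying probabilistic selection
tasks. The package covers the full analysis chain for experiments in which
participants (N ≈ 43 in the motivating design) learn to choose between
face pairs AB, CD, EF reinforced 80:20, 70:30 and 60:40, then face all 15
pair combinations (12 novel) in a feedback-free transfer phase:

1. **Task simulation** (`valsight.task`, `valsight.simulate`) — trial
   schedules with jittered onsets and null trials, and Q-learning agents
   with separate learning rates for gains and losses:

   Q_i(t+1) = Q_i(t) + α_gain·[r − Q_i(t)] if r = 1, else
   Q_i(t) + α_loss·[r − Q_i(t)], with softmax choice
   P(A) = exp(βQ_A) / (exp(βQ_A) + exp(βQ_B)), 0 ≤ β ≤ 100.

2. **Hierarchical Bayesian estimation** (`valsight.hierarchical`) —
   probit-scale subject parameters z ~ N(μ_z, σ_z) with priors
   μ_z ~ N(0, 1), σ_z ~ U(1, 1.5), sampled with emcee's ensemble MCMC;
   `HierarchicalQModel(records).fit()` returns a results object with
   `summary()`, split-R̂/ESS diagnostics, subject-level estimates and
   posterior-predictive learning curves.

3. **FIR deconvolution** (`valsight.fir`) — simultaneous ridge-penalised
   finite-impulse-response estimation of stimulus- and feedback-locked
   ROI responses and their trial-by-trial modulation by Q_chosen,
   Q_unchosen and signed/unsigned reward prediction error, with
   Savitzky–Golay detrending (120 s window), 0.5→3 Hz upsampling,
   cross-validated penalty, and per-timepoint group GLMs at a
   Bonferroni-corrected α = 0.0125 over the 0–8 s window.

4. **Random-forest decoding** (`valsight.forest`) — optimal vs.
   suboptimal transfer choices decoded from single-trial ROI betas
   pooled across subjects (fixed-effects matrix, shuffled rows, 2/3–1/3
   split). Trees grow on class-balanced bootstraps; out-of-bag votes
   give the training error, OOB permutation importance ranks the nine
   regions, and per-trial vote shares feed an uncertainty-versus-ΔValue
   regression, region-group ablations and difficulty splits.

A synthetic-data generator (`valsight.signals`) plants known value and
prediction-error modulation in ROI time series and label-coupled
structure in trial betas, so every stage can be validated against ground
truth.

## Worked example

```python
import valsight as vs

cfg = vs.TaskConfig()                      # 300 learning / 360 transfer trials
hyper = vs.GroupHyperParams()              # cohort heterogeneity on probit scale
records, qtraces, cohort = vs.simulate_cohort(hyper, cfg, n_subjects=12, seed=7)

summary = vs.behavior_summary(records)
good = vs.filter_good_learners(summary)    # accuracy > 60% on AB, CD and EF
print(f"{len(good)} of 12 simulated subjects are good learners")

betas = vs.synthesize_trial_betas(records, qtraces, vs.RoiSignalConfig(), seed=8)
matrix = vs.assemble_matrix(
    [g for _, g in betas.groupby("subject_id")], seed=9)
report, extras = vs.decode(matrix, n_trees=500, seed=10)
print(f"OOB error {report.oob_error:.3f}, "
      f"validation accuracy {report.validation_accuracy:.3f}, "
      f"AUC {report.auc:.3f}")
print(report.importance.head(3)[["feature", "importance", "rank"]])
```

Output from this exact snippet:

```
6 of 12 simulated subjects are good learners
OOB error 0.319, validation accuracy 0.657, AUC 0.688
      feature  importance  rank
0  trial_sign    0.050417     1
1  subject_id    0.030278     2
2     putamen    0.016007     3
```

Half of the simulated cohort clears the good-learner criterion; the
forest decodes about two in three held-out choices, with the OOB error
(0.32) close to the held-out error (0.34). The trial-sign covariate
ranks first — choices between two formerly-positive options succeed at
different rates than mixed pairs, so the category itself is predictive —
followed by the subject identifier and then the putamen, the region
with the largest planted label coupling.

The same pipeline is scriptable from the shell:

```bash
valsight run-all --config cfg.yaml --seed 7 --out results/
```

## Layout

- `src/valsight/` — library (`task`, `simulate`, `signals`, `qlearning`,
  `hierarchical`, `fir`, `forest`, `io`, `pipeline`, `cli`)
- `tests/` — pytest suite, including property-based checks and
  end-to-end synthetic reproductions
- `docs/methods.md` — modelling assumptions, parameter choices and
  limitations
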