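# Methods

## Scope and model

`ovauq` evaluates predictive uncertainty for multi-class classification
decomposed one-vs-all: a C-class problem becomes C binary tasks, each with
its own independently trained predictor (no shared backbone). Every
uncertainty-quantification technique is reduced to one common contract: it
emits a `ProbabilitySample`, a (T × n) matrix of positive-class
probabilities from T stochastic forward passes, and everything downstream
(summaries, confusion matrices, calibration) consumes only that matrix.
The techniques differ only in where the stochasticity in the parameters ω
comes from:

| technique    | source of ω draws                                | T |
|--------------|--------------------------------------------------|---|
| `mc_dropout` | dropout masks kept active at inference           | `n_passes` |
| `ensemble`   | M independently initialized/trained networks     | M (deterministic passes) |
| `emc`        | both: each member sampled with MC dropout        | M × (T/M) |
| `bayes`      | full weight draws from mean-field Gaussian posteriors, pooled over M members | M × (T/M) |

Averaging the T rows approximates the Bayesian posterior-predictive mean;
the entropy of the averaged binary distribution is the predictive entropy
used for certainty decisions.

## Reference predictors

The reference network is a rectifier MLP with hidden widths (128, 64, 32),
dropout rate 0.5 after each hidden activation (inverted dropout), a single
logistic output unit, and a 150-dimensional input, giving per-layer
parameter counts 19,328 / 8,256 / 2,080 / 33 = 29,697 total; a 5-member
ensemble holds 148,485. Training is mini-batch Adam (learning rate 1e-3,
batch 64, 15 epochs by default) on binary cross-entropy, with He
(variance-scaled) initialization; all randomness — initialization, batch
shuffling, dropout masks — flows from explicit integer seeds, and every
sampler is bit-reproducible under a fixed seed.

The Bayesian predictor places an independent Gaussian posterior
N(μ, softplus(ρ)²) on every weight and trains by stochastic variational
inference (Bayes by backprop): one reparameterized weight draw per
mini-batch, cross-entropy gradient plus the KL divergence to a standard
normal prior weighted 1/n_batches (divided by the batch size to match the
mean-reduced likelihood). ρ is initialized to −5 (σ ≈ 0.007) so training
starts near-deterministic; σ can be scaled or zeroed after training
(ρ = −∞ encodes exactly zero variance, making the sampler deterministic —
a useful degenerate check). This is a plain full-weight-sampling
variational network; variance-reduction tricks for the per-example
gradient noise (e.g. decorrelated perturbations) are deliberately out of
scope, since the predictive contract is the only thing the metrics
consume.

Ensemble diversity comes from the member seed alone (initialization and
shuffle order); there is no bagging. In `emc`/`bayes` sampling, one shared
random generator is threaded through the members in sequence, so a
one-member ensemble is exactly equivalent to the single-model sampler.

## Metric conventions

Decisions the underlying formulas leave open, fixed package-wide:

- **Entropy units and normalization.** Natural log (nats). Certainty
  thresholding always uses entropy normalized by ln C (C = 2 per OvA
  task), so the default threshold 0.30 is scale-free in the class count.
- **Certainty tie-break.** An instance is uncertain iff normalized entropy
  is *strictly* greater than the threshold; boundary instances are certain.
- **Decision rule.** Predicted label is 1 iff μ ≥ 0.5 (ties positive).
- **0/0 ratios.** Any metric with a zero denominator (e.g. USen when no
  instance is both incorrect and flagged) returns 0 and the metric name is
  recorded in the report's `degenerate` field instead of raising, so
  parameter sweeps never abort.
- **ECE binning.** M = 10 equal-width bins on [0, 1]; the first bin is
  closed at 0, the rest are left-open `(lo, hi]`; binary confidence is
  max(μ, 1−μ); empty bins contribute zero.
- **UF1.** Defined as the harmonic mean of UPre and USen, by analogy with
  the traditional F1.
- **Uncertainty-aware AUC.** The AUC-ROC of the stochastic sampler's μ
  against the true binary labels (the baseline AUC uses the deterministic
  single-pass probabilities), so the delta table differences two AUCs of
  the same construction on different predictive distributions.
- **Percentage uncertainty.** |traditional − uncertainty-aware| on the
  0–100 scale, rounded to one decimal for reporting; internal values keep
  full precision. The absolute value is forced by published cells where
  the uncertainty-aware metric exceeds the traditional one.
- **AUC implementation.** Delegated to scikit-learn's `roc_auc_score`
  (rank/Mann–Whitney with ½ tie credit); tests verify it against an
  exhaustive pair-counting oracle.

One cell of the published percentage-uncertainty tables (task 2,
MC dropout, UPrec) contradicts its own published inputs
(|89.9 − 56.5| = 33.4 vs a printed 31.0); the package reproduces the other
35 of 36 cells exactly and records that cell as known-inconsistent in
`ovauq.reference.KNOWN_INCONSISTENT_CELLS`.

## Pipeline choices

- **Oversampling.** Minority classes are topped up to the majority count
  with verbatim duplicates drawn with replacement (seeded). Balancing is
  applied *before* the train/test split, mirroring dataset-level balancing;
  the duplicate-leakage caveat is noted in `ova_pipeline`'s docstring —
  held-out metrics on duplicated rows are slightly optimistic.
- **Split.** Stratified 80/20 with a seed derived from the run seed; the
  split, member seeds and sampling seeds are all derived deterministically
  from the manifest, so a `RunManifest` fully reproduces `metrics.csv`.
- **Baseline.** The "traditional" reference is the same architecture
  evaluated with dropout off in a single deterministic pass
  (`technique="baseline"`); the delta table differences each technique's
  uncertainty-aware metrics against it per task.

## Synthetic data

`make_features` draws class-conditional spherical Gaussians (σ = 1) in d
dimensions with class means placed at mutual Euclidean distance
`separation` on scaled coordinate axes, so inter-class overlap — the
aleatoric difficulty — is one knob: separation 0 is chance level, 10σ is
near-perfectly separable. Defaults mirror the study conditions: d = 150
and pre-balancing class counts (732, 619, 526) for Normal / COVID-19 /
Pneumonia. What it does **not** emulate: covariance structure, heavy
tails, or class-dependent anisotropy of real extracted image features —
passing tests on these fixtures validates the machinery, not clinical
performance. `make_calibrated` draws μ ~ Uniform(0,1), y ~ Bernoulli(μ),
which is calibrated by construction; its empirical ECE at n = 50,000 is
well below 0.01, the large-n check that the binning is implemented
correctly.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline at the
study scale (3 × 732 balanced instances, 150 features, all four
techniques, T = 50, M = 5, 15 epochs); smaller unit-test fixtures use
~300-instance datasets with 12 features and narrower nets, sized so that
Adam at learning rate 1e-3 gets enough steps to converge. Probabilities
are computed with a numerically stable sigmoid; cross-entropy adds 1e-12
inside the logs; the KL gradient term 1/σ is clipped near σ = 0.
Brute-force oracle comparisons (ECE, Brier, AUC, confusion tallies) agree
to 1e-12 at n = 500.

## Known limitations

- Oversampling before splitting leaks duplicated rows across the split
  (see above); applications with scarce positives should balance after
  splitting and re-derive the expected counts.
- The MC-dropout reference net keeps the training dropout rate (0.5) at
  inference, which on easy, low-dimensional synthetic data inflates
  predictive entropy and can push many *correct* predictions past the
  0.30 certainty threshold — visible as low UAcc with high accuracy. This
  mirrors how dropout-based uncertainty behaves when the rate is not
  re-tuned for inference.
- The Bayesian predictor is mean-field: it cannot represent weight
  correlations, and its posterior width depends on the KL weighting
  convention chosen above.
- Metrics assume binary OvA tasks throughout; joint multi-class
  calibration is out of scope.
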