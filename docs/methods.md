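# Methods

This note documents the models implemented in `mmaae`, the synthetic
benchmark they are exercised on, the numerical choices made where the
design was open, and the limitations we have measured.

## Problem setting

Instances are 166-dimensional feature vectors extracted from six
sensor modalities — phone accelerometer (Acc, 26 features), gyroscope
(Gyro, 26), watch accelerometer (WAcc, 46), location (Loc, 6), audio
(Aud, 28) and binary phone-state indicators (PS, 34) — collected
minute-by-minute from users going about their lives. Because features
of one modality are computed from one sensor, they go missing as a
block: watch non-wear removes all 46 WAcc features at once, disabling
location services removes all 6 Loc features. Labels describe the
behavioral context (51 binary labels; several can hold at once) and
are sparse: a user confirms a few labels and leaves the rest
unreported, which is *not* the same as negative.

## Data model and preprocessing

Continuous features are min–max scaled to [0,1] with statistics
computed over *observed entries of the training split only*; values
outside the training range at test time are clipped to [0,1] (the
reconstruction loss needs targets in the unit interval). Features
whose observed training values all lie in {0,1} are detected as binary
and passed through; constant features map to 0. Missing entries are
filled with the sentinel −1 after scaling. The missingness mask is
authoritative; the sentinel is a derived encoding, which avoids
ambiguity if a raw feature could be −1. Normalization is idempotent:
applying a fitted normalizer to an already-normalized dataset is the
identity.

Labels live in a ternary matrix (1 positive / 0 negative / unreported);
on disk unreported entries are empty CSV cells, distinct from 0.

Evaluation uses user-grouped k-fold cross-validation: users are
partitioned into k near-equal test groups and every model component —
normalizer, autoencoder, imputers, weight matrix, classifier — is
fitted on training-fold users only. A leakage guard raises if any user
appears on both sides.

## Reconstruction model

A three-layer encoder and decoder (128 units per layer, 128-d latent,
leaky-rectifier hidden activations with slope 0.2, Xavier-uniform
weights, zero biases, sigmoid decoder output) trained with per-feature
binary cross-entropy between the clean input and the reconstruction of
its corrupted version. The structured corruption applies, in order:

1. masked noise: exactly ⌊0.05·n⌋ randomly chosen feature positions
   set to 0 per row (masking value 0, distinct from the sentinel);
2. modality drops: k ~ Uniform{3,…,5} whole blocks set to −1 (never
   all six — an all-missing input carries no information);
3. input dropout: remaining entries zeroed independently with
   probability 0.2. Sentineled blocks are exempt so dropped blocks
   stay exactly −1.

A discriminator (two 128-unit hidden layers, sigmoid output) is
trained to separate standard-normal prior draws from latent codes, and
the encoder is updated on the non-saturating generator loss. The three
updates run sequentially per minibatch (batch 64), with separate Adam
optimizers per loss stream: reconstruction learning rate 5e−4,
adversarial 3e−4, L2 weight decay 1e−5 on encoder weights. Training
runs at most 30 epochs with early stopping (patience 5) on the
reconstruction loss of an internal 80/20 validation split whose
corrupted view is fixed once, so the stopping criterion is a
deterministic function of the epoch.

Two numerical stabilizers are applied to the adversarial game and can
be switched off in `TrainConfig`:

* the adversarial Adam streams use first-moment decay β₁ = 0.5
  (momentum 0.9 destabilizes the two-player dynamics);
* Gaussian *instance noise* is added to both discriminator inputs
  (fake codes get z + σε; prior draws are scaled to the matching total
  variance), with σ annealed 1.0 → 0.1 over the first half of
  training. Instance noise removes the discriminator's incentive to
  win on the geometry of the latent manifold rather than on
  distributional statistics, and it is exactly mean-preserving.

## Context classifier

A 64-unit hidden layer plus C sigmoid outputs, stacked either on the
trained encoder (fine-tuned end-to-end, with structured noise applied
to each training batch) or on frozen embeddings / raw features. The
loss is the instance-weighted binary cross-entropy: for label c with
N_obs reported entries, N_pos positives and N_neg negatives, positive
entries weigh N_obs/(2·N_pos), negative entries N_obs/(2·N_neg),
unreported entries exactly 0. This two-sided form makes a balanced,
fully observed label weight-neutral, and the weighted positive and
negative masses are each N_obs/2. Labels observed in one class only
get all-zero weights and are flagged. Weights are recomputed per fold
from training data only. Predictions threshold at 0.5 with ties going
to 1. Early stopping monitors macro balanced accuracy on the internal
validation split; when the classifier is trained under corruption the
validation inputs are corrupted once with a fixed stream so model
selection favors robustness under the operating input distribution.

To use partially missing training instances, the noisy split is
imputed with the trained autoencoder and concatenated with the clean
split; instance weights are computed from this combined set.

## Imputation baselines

* **PCA-75**: principal components fitted on the clean training split;
  an incomplete vector is mean-prefilled, projected to 75 components
  and inverse-transformed, and missing positions take the
  inverse-transform values (single pass — this is the classical
  baseline whose restorations hug the feature means). A `lstsq` mode
  solves the exact least-squares completion on the component subspace
  instead (component scores solved in variance-weighted coordinates so
  zero-variance directions cannot inject noise); on data lying exactly
  in a rank-≤75 affine subspace it restores a dropped block to machine
  precision. PCA itself comes from scikit-learn (full SVD solver for
  determinism).
* **Constant fills**: per-feature training mean or median, or leaving
  the sentinel −1 in place ("fill −1").
* No imputation method ever modifies an observed entry (bit-exact).

Drop-and-restore evaluation sentinels an entire observed modality on
held-out clean instances, restores it, and reports RMSE over the
hidden block only.

## Synthesis model and TSTR

The label-conditioned AAE uses a 128-unit hidden layer, a 10-d latent
code (dropout 0.2 on z during training), and a decoder that consumes z
concatenated with the C-length label vector (unreported entries 0).
Input is clean and noise-free; learning rates are 1e−3
(reconstruction), 1e−3 (adversarial) and 5e−4 (classification stream,
reserved for classifier extensions). Sampling decodes prior draws
with dropout 0.75 on decoder hidden layers; conditioning labels are
always copied from a real split because independently sampled
multi-labels can describe impossible contexts. Binary-block outputs
may optionally be snapped to {0,1} at 0.5.

TSTR trains a fresh one-hidden-layer (64 units, plain rectifier)
classifier on synthetic data and evaluates on real held-out users;
TRTS is the reverse; both use the identical metric code path as the
real–real reference, and a null control conditions the generator on
all-zero labels (its TSTR must be at chance).

## The synthetic benchmark

Every instance mixes a user-level and an instance-level factor vector,
f = √w·u + √(1−w)·e with w = 0.5 and 12 factors, so instances cluster
by user and held-out-user evaluation is genuinely harder than a random
split. Each modality is a fixed, seed-determined nonlinear map of f —
a random projection through a 10-unit tanh layer, squashed by a
sigmoid into [0,1] — plus Gaussian noise (SD 0.15); the PS block is
thresholded at 0.5 into {0,1}. Setting `nonlinearity=0` replaces the
map with a purely affine one for studying linear baselines. Labels
are drawn from a logistic model on the factors (unit-norm weight
vectors scaled by 2.5) with intercepts calibrated by bisection to
per-label target prevalences, log-spaced from 2% to 30% by default;
label entries are hidden completely at random at rate 0.3.

Block-wise missingness follows the dominant real-world causes: relative
missing propensities Acc:Gyro:Aud:PS:WAcc:Loc = 1:1:1:1:8:14, scaled so
the overall fully-clean fraction is 0.5, plus whole-user watch non-wear
at rate 0.1. Concentrating the loss on the watch and location blocks
matters beyond realism: phone-block sentinels are then essentially
absent from training data, which is what makes the fill(−1) baseline
collapse when phone modalities are dropped at test time while the
noise-trained classifier does not.

The default population is 60 users with 240–420 instances each
(~20,000 instances). The test suite and the acceptance script run a
reduced draw of the same population — 30 users, 160–220 instances each
(~5,700 instances), with the reconstruction/classifier training at the
default 30-epoch cap — which keeps a full pipeline fit under a minute
on one CPU.

What the generator does *not* emulate: raw time series and the
feature-extraction step; heavy-tailed or multimodal feature marginals;
label correlations beyond what the shared factors induce; informative
(non-random) label missingness; per-user sensor calibration drift.
Passing tests therefore demonstrate the machinery and the direction of
the comparisons under factor-driven data, not performance levels on
any real recording.

## Numerical choices

* Losses are computed from pre-activation logits
  (softplus-parameterized binary cross-entropy) for stability; the
  public probability-space loss clamps predictions to [1e−7, 1−1e−7].
* The generator loss is the non-saturating −log D(z) form.
* Adam uses (β₁, β₂) = (0.9, 0.999) everywhere except the adversarial
  streams (0.5, 0.999); weight decay applies to weight matrices only,
  never biases.
* Prediction ties at exactly 0.5 classify as positive.
* Labels with undefined sensitivity or specificity in a fold are
  excluded from macro averages and flagged.
* All randomness flows through seeded numpy Generators; training,
  generation and the CLI are byte-reproducible given config and seed.

## Known limitations

* **Latent prior matching is partial at this scale.** With the 128-d
  latent, the adversarially trained encoder's held-out latent SDs
  approach the prior and the run is consistently closer to (0, 1)
  moments than an identically seeded run without adversarial phases,
  but a substantial fraction of per-dimension means equilibrate away
  from 0 (typically 0.3–1.3). The cause is structural: the aggregated
  posterior of a deterministic encoder on ~12-factor data lies on a
  low-dimensional manifold in the 128-d latent space, and a minibatch
  discriminator separates it from the prior by geometry rather than by
  moments, so the generator receives little pressure on individual
  means. Instance noise and reduced adversarial momentum mitigate but
  do not remove this at the training volumes used here. The
  acceptance suite measures this honestly; downstream results
  (imputation, classification, synthesis) do not depend on exact
  moment matching.
* The classifier treats labels as conditionally independent; label
  co-occurrence structure is not modeled.
* Single imputation only: no uncertainty estimates on restored values.
* The synthesis model's TRTS scores run below TSTR (synthetic test
  sets are harder than synthetic training sets are useful), which
  matches the general experience that generated data is an imperfect
  substitute for real evaluation data.
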