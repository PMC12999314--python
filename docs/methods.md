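# Methods

This note documents the models and procedures implemented in `ppifern`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Problem

Given two protein sequences, predict whether the proteins physically
interact, using only sequence-derived evolutionary information.  The
pipeline has four stages: evolutionary profiles, fixed-size
featurization, unsupervised-then-supervised representation learning, and
semi-naive Bayes classification, evaluated under stratified k-fold
cross-validation.

## Evolutionary profiles (PSSM)

Each protein of length L is represented by an L×20 position-specific
scoring matrix: integer log-odds scores of observing each amino acid at
each position, as produced by iterative profile search against a large
sequence database.  Profile generation itself is out of scope; the
package parses the standard ASCII profile dialect (both the 40-column
log-odds + percentages layout and the minimal 20-column one, always
taking the first 20 numeric columns) and remaps columns to a fixed
canonical residue order so feature indices are comparable across files.

## Fixed-size cross-product features

Proteins differ in length, so the L×20 profile P is reduced to the
20×20 cross-product PᵀP — a length-independent summary of co-occurring
substitution propensities — flattened row-major to 400 values per
protein.  A pair is the 800-vector concatenation A‖B in pair-table
order.

Two preprocessing switches surround the cross-product
(`FeaturizationSettings`), both on by default:

* **logistic squashing** x → 1/(1+e⁻ˣ) applied elementwise before the
  product.  Raw log-odds products are unbounded and their scale grows
  with score magnitude; squashing bounds every feature in [0, 1], which
  the sigmoid autoencoder and the fern threshold sampler both assume.
  It also breaks the sign-blindness of the raw cross-product (PᵀP is
  invariant to P → −P; σ(P)ᵀσ(P) is not), so more of the profile is
  identifiable from the feature.
* **length normalization** dividing PᵀP by L, making features
  comparable across protein lengths (duplicating every profile row
  leaves the feature unchanged).

Raw mode (`none`/`none`) preserves the literal cross-product and is used
by the exactness oracles.  The pair-combination rule is plain
concatenation; no swap augmentation is applied by default.

## Stacked denoising autoencoder (SDAE)

Each layer is a denoising autoencoder with untied weights: corrupt the
input (default: mask a uniformly random ⌊0.3·dim⌋ subset of coordinates
to zero; additive Gaussian noise is available), encode
h = σ(Wₑx + bₑ), decode y = σ(W_d h + b_d), and minimize the mean
squared reconstruction error against the *clean* input.  Layers are
pretrained greedily — layer k trains on the clean encodings of layers
1..k−1 — then a 2-class softmax head is attached and head plus all
encoder layers are fine-tuned by cross-entropy.  The head is discarded
at prediction time: the features delivered to the classifier are the
deepest encoder outputs after fine-tuning, so they lie in (0, 1).

Training is plain seeded mini-batch gradient descent (no momentum or
adaptive rates): dependency-light and bitwise-reproducible.  Corruption
is applied only during training, never at encode time.  Weights are
initialized uniform(−r, r), r = √(6/(fan_in+fan_out)), biases at zero.

Defaults: hidden sizes (512, 256, 128) on the 800-d pair input, batch
64, learning rate 0.5, 15 pretraining and 100 fine-tuning epochs.  The
learning rate deserves comment: on deep logistic-sigmoid stacks,
gradient magnitudes are attenuated by factors of h(1−h) ≤ ¼ per layer,
and the label signal here is an interaction between the two 400-d
halves, which a linear readout cannot express.  Small rates (~0.01)
leave the fine-tuned head near chance within any reasonable epoch
budget; rates in the 0.5–1 range with ≥100 fine-tuning epochs reliably
converge.  End-to-end experiments in the tests and the acceptance
script use a reduced configuration — hidden sizes (128, 64), 10
pretraining epochs, 300 fine-tuning epochs, learning rate 1.0 — chosen
so a full 5-fold run completes in about a minute on one CPU core while
matching the larger stack's accuracy on the synthetic benchmark.

## Random ferns classifier

A fern is an ordered set of S binary tests; the joint outcome indexes
one of K = 2^S bins.  M ferns are trained by counting outcome/class
co-occurrences N_{k,ci}; scoring multiplies, across ferns, the smoothed
outcome probability

    p_{k,ci} = (Nr + N_{k,ci}) / (K·Nr + N_{ci}),

with a uniform class prior, accumulated in the log domain (at M = 50 a
raw product of 50 probabilities would underflow).  The additive count
Nr (default 1) keeps unseen outcomes at positive probability; the
smoothed probabilities over all K outcomes sum exactly to 1 for any
counts.  Prediction is the score argmax with ties broken toward the
negative class; probabilities are the exp-normalized scores.

Binary tests on continuous features are strict thresholds
f = [x[dim] > θ], with dim uniform over the feature dimensions and θ
uniform within that dimension's training range (a degenerate range pins
θ to the constant, so the test never fires).  A pairwise-comparison
variant f = [x[d₁] > x[d₂]] is available via `test_kind="pairwise"`.
Each fern samples its S tests independently, which is statistically
equivalent to drawing N = S·M tests and partitioning them into M groups.
Defaults S = 20, M = 50, i.e. 1000 binary features.  K = 2^20 per fern
makes dense tables infeasible, so tables are sparse over observed
outcomes; memory scales with training-set size, not K.

Within one fern, the S tests are modelled jointly (the full 2^S outcome
is the random variable); independence is assumed only *between* ferns.
This semi-naive structure is what lets the classifier pick up
interactions between feature dimensions — including between the two
protein halves of a pair vector — that a fully naive per-feature model
would miss.

## Evaluation

Confusion-based metrics use the standard definitions (positive class
= 1): accuracy, sensitivity, precision, and Matthews correlation with
numerator TN·TP − FN·FP.  Any metric with a zero denominator is
reported as 0 so reports are always total.  AUC is the rank-based
Mann–Whitney statistic (ties counted ½), invariant under monotone score
transforms; ROC points sweep all distinct thresholds.  Cross-validation
uses seeded stratified folds (sizes within one of each other; a
`stratify=False` switch restores plain random splits), retrains the
entire pipeline — SDAE included — inside every fold, and reports
per-metric mean and sample standard deviation (k−1 denominator) over
the k held-out folds.  Nothing fitted ever sees a held-out fold:
feature ranges, encoder weights and fern tables are all recomputed per
fold (verified by a leakage test that perturbs only test-fold rows).

## Synthetic benchmark

The generator emulates the statistical shape of the real inputs so the
whole chain is testable without downloads.  Protein i carries a latent
trait vector z_i (dimension r = 5) with **nonnegative** entries (folded
standard normals).  A fixed mixing matrix B (r×20, standard normal
entries) maps traits to residue-score channels; every profile row is

    row_t = signal · (z_i B) + ε_t,   ε_t ~ N(0, noise_sd²),

rounded to integers.  Pair candidates are distinct unordered pairs; the
latent interaction score is s = signal·(z_a · z_b); positives are the
top-ranking and negatives the bottom-ranking candidates of a pool
oversampled by a factor of 2 (the ambiguous middle is discarded),
hitting the requested class balance exactly.  With signal = 0, profiles
carry no trait information and labels are uniform — the null generator.

Three design points matter:

* **Folded traits.**  The cross-product feature is invariant to a global
  sign flip of a protein's profile, so zero-mean traits would make the
  sign of z_a·z_b unrecoverable *in principle* and planted labels
  unlearnable by any method.  Nonnegative traits make z identifiable
  from the feature, so pipeline accuracy measures signal recovery, not
  generator luck.
* **Signal scales the profile, noise is additive.**  Separability of the
  features is therefore genuinely monotone in `signal`, with signal = 0
  exactly at chance.  Because a protein of length L averages noise over
  L rows, recovery saturates quickly at realistic lengths; the
  monotonicity property is asserted in a graded regime (short profiles,
  higher noise) where the probe is off its ceiling.
* **Shared mixing matrix.**  B has its own seed (`mixing_seed`), fixed
  by default and decoupled from the dataset seed: it plays the role of
  shared biochemistry, so two datasets drawn with different seeds are
  disjoint in proteins and pairs yet live in the same feature geometry.
  That is what makes train-on-A / test-on-B transfer experiments
  meaningful.

Defaults — 200 proteins of length 50–150, latent dimension 5, signal
3.0, noise 1.0, 1000 pairs at 50 % positives — are the study conditions
for all end-to-end checks.

What passing the synthetic benchmark does **not** show: real
interaction data have homology structure, hub proteins, heavy class
imbalance in the wild, and profile quality that varies with database
coverage; none of these are emulated.  Accuracy numbers on this
benchmark characterize the implementation (signal present → recovered;
signal absent → chance), not expected performance on biological data.

## Numerical and degenerate-input conventions

* Sigmoid pre-activations are clipped at ±500 before exponentiation.
* Masking corruption zeroes exactly ⌊rate·dim⌋ coordinates per sample.
* Fern score ties predict the negative class; `argmax` order makes this
  deterministic.
* Metrics with empty denominators are 0; AUC with a single class
  present is 0.5.
* Model bundles serialize to canonical JSON (sorted keys, `repr`-exact
  floats), so save→load→save is byte-identical and loaded bundles
  reproduce predictions bit-for-bit.
* One global seed fans out to per-component seeds by CRC-32 of
  `"{seed}:{component}"`, so components are independently yet
  reproducibly seeded.

## Known limitations

* The optimizer is deliberately plain SGD; convergence depends on the
  learning-rate guidance above, and very deep stacks (>3 layers) may
  need per-case tuning.
* Only binary classification is supported; multi-class ferns and
  incremental fitting are out of scope.
* Profile generation (the iterative database search) is not included;
  inputs must be pre-computed profiles or synthetic ones.
* The pair representation is order-dependent (A‖B as listed in the pair
  table).  An optional swap-augmentation flag exists at the API level
  for training-data symmetrization but is off by default.
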