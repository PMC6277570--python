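# Methods

## Model and training procedure

The classifier is a fully connected network: descriptor vector →
hidden ReLU layer(s) → single sigmoid unit giving a = P(drug-like | x).
Training happens in two stages.

**Autoencoder pre-training.** Each hidden layer is first trained as an
autoencoder — encoder with the configured activation, linear decoder —
minimising the mean squared reconstruction error plus an L2 penalty on
the weights. Multiple hidden layers are pre-trained greedily, each layer
on the codes of the previous one (a stacked autoencoder). The intuition:
2D descriptors are strongly inter-correlated with low intrinsic
dimension, and reconstruction forces the hidden representation to
capture that structure before any label is seen. Pre-training acts as a
regulariser; reconstruction quality itself is not the goal, and on
descriptor-like data deep stacks reconstruct poorly, which is why the
default is a single hidden layer.

**Supervised fine-tuning.** The encoder weights initialise the
classifier's hidden layers; the output layer is drawn fresh from the
truncated normal. The loss is the class-weighted binary cross-entropy

    L = − Σ_k [ w·y_k·log a_k + (1 − w)(1 − y_k)·log(1 − a_k) ],

a sum over samples; mini-batch training uses the batch mean (sum divided
by batch size) so that optimiser step sizes do not scale with the batch.
At w = 0.5 the loss is exactly half the standard cross-entropy. With an
`eval_set` supplied, training stops early when held-out accuracy has not
improved for `early_stop_patience` epochs, and the best-accuracy
snapshot is restored.

**Weight tuning.** Even after balancing the training set, validation
specificity typically exceeds sensitivity, because synthetic minority
rows only interpolate the information already present in the training
positives. Raising w counters this. The scan trains one model per grid
point (21 points, 0.5 to 1.0 in 20 equal intervals), every point from
the same autoencoder-derived initialisation and seed so that only w
varies, and selects the weight where the SE and SP curves on the
validation set cross — linearly interpolated between adjacent grid
points, with a fall-back to the grid point minimising |SE − SP| (ties
to the smaller w) when the curves never cross. An optional refinement
pass rescans a 5× finer sub-grid around the first selection (off by
default). The grid endpoint w = 1.0 is trained as the limiting case
w → 1 (clipped by 1e−9), since the loss itself requires w ∈ (0, 1).

## Experiment protocol

All rows are split 9:1 into a training pool and a validation set,
stratified so that each side preserves the class ratio to within one row
(at 1:59 imbalance an unstratified draw can miss the positive class
entirely). The training pool is partitioned into 5 stratified CV folds.
Per fold: z-score statistics are fit on the fold-training rows;
balancing (duplication or SMOTE) is applied to the fold-training rows
only; the autoencoder is pre-trained on the balanced fold-training set;
the classifier fine-tunes with early stopping monitored on the fold-test
accuracy; evaluation happens on the fold-test rows and on the validation
set. Fold metrics are aggregated by unweighted arithmetic mean.

Balancing *within* each fold departs from the historical protocol of
balancing the whole training pool before folding: pre-fold SMOTE places
synthetic copies of fold-test rows inside fold-training sets and
inflates fold-test scores. The historical variant remains available
(`run_cv(..., leaky_balance=True)`, CLI `--leaky-balance`) for fidelity
comparisons. Validation rows never influence standardisation statistics,
SMOTE neighbourhoods, pre-training or early stopping; inside the weight
scan, early stopping therefore uses an internal 10% split of the
training rows rather than the validation set.

Columns that are constant within a fold's training rows cannot be
z-scored and are dropped for that fold (global constant columns are
removed beforehand by `drop_constant_columns`).

## Parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `hidden_dims` | (512,) | one hidden layer of 512 units — the tuned setting for ~700-descriptor tables; deeper stacks are supported but not better here |
| `activation` | relu | hidden activation |
| `l2` | 1e-4 | weight-decay coefficient on all weight matrices (not biases) |
| `dropout` | 0.14 | inverted dropout on hidden activations, in both pre-training and fine-tuning; inference is deterministic |
| `batch_size` | 128 | mini-batch size |
| `optimizer` | adam | Adam (β₁ 0.9, β₂ 0.999, lr 1e-3); plain SGD available |
| `init_std` | 0.05 | truncated-normal initialiser scale; draws beyond ±2σ are redrawn |
| `pos_weight` | 0.5 | loss weight w; 0.5 = unweighted |
| `threshold` | 0.5 | decision threshold on the sigmoid output; ties count positive |
| `early_stop_patience` | 10 | epochs without held-out ACC improvement before stopping |
| SMOTE `k` | 5 | minority nearest-neighbour count, reduced to minority−1 for tiny classes |
| `validation_fraction` | 0.1 | the 9:1 split |
| `fold_count` | 5 | CV folds |

## Evaluation

ACC = (TP+TN)/total, SE = TP/(TP+FN), SP = TN/(TN+FP), MCC with the
convention MCC = 0 when any denominator factor is zero (computed in log
space so large counts cannot overflow), and the Mann–Whitney AUC with
ties counting one half. SE is reported as missing — distinct from 0 —
when no positives were evaluated. Confusion counts call positive at
probability ≥ threshold.

## Synthetic data

The generator draws latent factors z ~ N(±δ/2·𝟙, I_r) — positives
shifted by +δ/2 in every latent coordinate, negatives by −δ/2, so the
latent Mahalanobis separation is δ√r — and maps them through a fixed
random loading matrix A (r × p) with isotropic ambient noise σ.
Constant columns and missing entries can be injected. With σ = 0 the
matrix has rank exactly r, which the autoencoder-vs-PCA test exploits.
A closed-form Bayes accuracy (optimal linear rule under the shared
Gaussian covariance AᵀA + σ²I) accompanies each table as an oracle.

The generator reproduces what the method *exploits* — correlated
features, low intrinsic dimension, imbalance, dirty entries — not real
descriptor marginals (integer counts, heavy tails, block correlation).
Passing tests therefore demonstrate correctness of the machinery, not
expected accuracy on real compound collections.

## The built-in benchmark

`druglike.benchmark` fixes a desk-scale analogue of the hardest
drug/non-drug-like setting: 200 positives vs 10,000 negatives (1:50),
100 features, r = 10, δ = 3, σ = 0.5, five seeded replicates. The
network for this benchmark is 32 hidden units with 5 pre-training and at
most 15 fine-tuning epochs (patience 3): the task's Bayes accuracy is
essentially 1, so a compact model keeps the benchmark honest about the
pipeline rather than about capacity. On this benchmark the full pipeline
reaches median validation accuracy above 0.95 with |SE − SP| ≤ 0.05 at
the selected weight, SMOTE matches or beats duplication in fold-test
sensitivity, and median SE (SP) is non-decreasing (non-increasing) in w.
Because the task is close to separable, several of these trends are flat
at the ceiling rather than strictly monotone.

## Numerical conventions

- Probabilities are clipped to [1e−7, 1 − 1e−7] before logarithms.
- z-score uses the population standard deviation (divide by n); fitting
  on fewer than two rows, or on a zero-variance column, is an error
  naming the columns.
- Constant-column detection is exact equality, not near-constancy.
- SMOTE nearest-neighbour ties break by row index (stable sort over
  exact distances), so a fixed seed fixes the output bit-for-bit.
- Missing-value tokens recognised in delimited input: `NA`, `N/A`,
  `NaN`, empty field, ±`inf`/`infinity`.
- The linear-autoencoder-vs-PCA equivalence is asserted as: AE
  reconstruction MSE ≤ PCA MSE + 10% of the total data variance. On
  noise-free rank-r data the PCA floor is zero, so a ratio test against
  it is ill-defined; normalising the excess by the data variance makes
  the criterion meaningful (the trained AE lands about four orders of
  magnitude below the bound).
- Model parameters serialise to a directory of named float64 arrays
  (`arrays.npz`) plus JSON metadata (dims, activations, role);
  round-trips are bit-identical.

## Known limitations

- No structure standardisation (neutralise / tautomerise / aromatise) is
  bundled; the cleaning pipeline exposes a `normalizer` hook and is
  otherwise a documented fidelity gap relative to workflows built on
  commercial standardisers.
- Descriptor computation (Mold2/PaDEL) is out of scope; the package
  starts from a numeric matrix.
- CPU-only numpy training: appropriate at the tens-of-thousands-of-rows
  scale, not for millions.
- Only plain exhaustive grid enumeration is provided for hyperparameter
  sweeps (`tuning.iter_grid`); no Bayesian search.
- Reported accuracies on synthetic benchmarks say nothing quantitative
  about proprietary compound corpora.
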