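# druglike

Drug-likeness classification from 2D molecular descriptors with
autoencoder-pretrained neural networks and a class-weighted loss.

## The problem

Most candidate compounds never become drugs, often for reasons summarised
as poor *drug-likeness*. Binary classifiers that separate drug-like from
non-drug-like compounds using large descriptor tables are a standard early
filter in drug discovery, but the available compound collections are
heavily imbalanced — marketed drugs versus purchasable screening compounds
can reach a 1:59 ratio — and a model trained naively collapses onto the
majority class.

This package implements, end to end, a workflow for building such
classifiers from 2D descriptor matrices (e.g. Mold2 output, ~700 numeric
descriptors per molecule):

1. **Chemical curation** (`druglike.moldata`) — SDF reading, removal of
   hydrocarbons and molecules with elements outside
   {C, H, O, N, P, S, Cl, Br, I, Si}, removal of multi-fragment records,
   and InChI-based deduplication (a molecule present in both sets is
   dropped from the negative set).
2. **Matrix post-processing** (`druglike.matrixprep`) — rows with
   missing/non-finite descriptor values and constant descriptor columns
   are removed; features are z-scored with statistics fit on training
   rows only.
3. **Imbalance correction** (`druglike.balance`) — minority duplication
   or SMOTE (synthetic rows `x_i + u·(x_nn − x_i)` interpolated towards
   one of the k nearest minority neighbours), applied to training rows
   only.
4. **Modelling** (`druglike.network`) — an autoencoder is trained to
   reconstruct the standardised descriptors (layerwise for stacked
   variants); its encoder initialises a fully connected classifier with a
   single sigmoid output, fine-tuned with the class-weighted binary
   cross-entropy

   L = −Σₖ [ w·yₖ·log aₖ + (1−w)·(1−yₖ)·log(1−aₖ) ],

   where aₖ is the predicted probability that compound k is drug-like and
   w ∈ (0,1) weights the positive-sample loss.
5. **Weight tuning** (`druglike.tuning`) — w is scanned from 0.5 to 1.0
   in 20 intervals; the selected weight is the intersection of the
   sensitivity (SE) and specificity (SP) curves on the validation set.
6. **Evaluation** (`druglike.metrics`) — ACC, SE, SP, MCC and the
   rank-based AUC.
7. **Orchestration** (`druglike.pipeline`) — stratified 9:1
   train/validation split, per-fold balancing, 5-fold cross-validation,
   fold averaging.

The estimators (`Autoencoder`, `DrugLikenessClassifier`, `ZScoreScaler`)
follow scikit-learn conventions (`fit`/`transform`/`predict_proba`,
`get_params`, trailing-underscore fitted attributes).

Because the classical benchmark corpora (MDDR, WDI, ACD, ZINC subsets)
are proprietary, the package ships a synthetic-data generator
(`druglike.synthdata`) producing descriptor tables with the statistical
structure the method exploits — correlated features of low intrinsic
dimension, controllable class separation and imbalance, missing values
and constant columns — so that every stage is testable at desk scale.

## Worked example

```python
from druglike import SynthSpec, generate, make_split, run_cv, TrainingConfig

matrix, truth = generate(SynthSpec(n_pos=100, n_neg=2000, n_features=50,
                                   latent_dim=5, class_shift=3.0,
                                   noise_sd=0.5, seed=7))
print("Bayes accuracy of the generating model:", round(truth["bayes_accuracy"], 4))

plan = make_split(matrix.n_rows, matrix.labels, seed=7)          # 9:1, stratified
cfg = TrainingConfig(hidden_dims=(16,), ae_epochs=5, max_epochs=20,
                     early_stop_patience=5, seed=7)
result = run_cv(matrix, plan, cfg, balance_method="smote")
print("fold-test mean:", {k: round(v, 4) for k, v in result.fold_mean.items()})
print("validation mean:", {k: round(v, 4) for k, v in result.validation_mean.items()})
```

prints

```
Bayes accuracy of the generating model: 0.9996
fold-test mean: {'acc': 0.9878, 'se': 1.0, 'sp': 0.9872, 'mcc': 0.8891, 'auc': 0.9999}
validation mean: {'acc': 0.981, 'se': 1.0, 'sp': 0.98, 'mcc': 0.838, 'auc': 0.9997}
```

The 1:20-imbalanced task has a Bayes (optimal-rule) accuracy of 0.9996;
after SMOTE balancing and autoencoder-initialised training, the averaged
five-fold models recover nearly all of it on the untouched validation
set, with sensitivity 1.0 despite only ~10 positives per validation
draw. The MCC is lower than the ACC because the validation set keeps the
original imbalance.

The same workflow is available from the shell:

```sh
druglike simulate --n-pos 100 --n-neg 2000 --seed 7 --out sim/
druglike run --matrix sim/matrix.csv --method smote --seed 7 --out results/
druglike tune-weight --train train.csv --val val.csv --out scan.json
```

(`druglike clean`, `postprocess`, `balance`, `train`, `evaluate` cover
the individual stages; see `druglike --help`.)

## Documentation

`docs/methods.md` describes the model, its assumptions, every tunable
parameter with its default, what the synthetic generator does and does
not emulate, and the package's numerical conventions.
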