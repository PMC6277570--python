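"""druglike: drug-likeness classification from 2D molecular descriptors.

Curates compound sets, post-processes descriptor matrices, corrects
class imbalance by duplication or SMOTE, pre-trains an autoencoder to
initialise a fully connected classifier trained with a class-weighted
cross-entropy, tunes the positive-loss weight to the SE/SP crossing, and
evaluates with ACC/SE/SP/MCC/AUC.
"""

__version__ = "0.1.0"

from .balance import (
    BalanceResult,
    DuplicateOverSampler,
    SMOTEOverSampler,
    oversample_duplicate,
    smote,
)
from .errors import DataError, DruglikeError, TrainingError
from .matrixprep import (
    ColumnStats,
    DescriptorMatrix,
    ZScoreScaler,
    drop_constant_columns,
    drop_error_rows,
    postprocess,
    read_matrix,
    zscore_apply,
    zscore_fit,
)
from .metrics import ConfusionCounts, EvalReport, auc, confusion, evaluate, mean_report, score
from .network import (
    Autoencoder,
    DrugLikenessClassifier,
    NetworkParams,
    TrainingConfig,
    init_truncated_normal,
    predict,
    train_autoencoder,
    transfer_weights,
    weighted_bce,
)
from .pipeline import ExperimentResult, SplitPlan, make_split, run_cv
from .synthdata import SynthSpec, bayes_accuracy, generate
from .tuning import WeightScan, default_grid, iter_grid, scan_weights, select_weight

__all__ = [
    "Autoencoder",
    "BalanceResult",
    "ColumnStats",
    "ConfusionCounts",
    "DataError",
    "DescriptorMatrix",
    "DrugLikenessClassifier",
    "DruglikeError",
    "DuplicateOverSampler",
    "EvalReport",
    "ExperimentResult",
    "NetworkParams",
    "SMOTEOverSampler",
    "SplitPlan",
    "SynthSpec",
    "TrainingConfig",
    "TrainingError",
    "WeightScan",
    "ZScoreScaler",
    "auc",
    "bayes_accuracy",
    "confusion",
    "default_grid",
    "drop_constant_columns",
    "drop_error_rows",
    "evaluate",
    "generate",
    "init_truncated_normal",
    "iter_grid",
    "make_split",
    "mean_report",
    "oversample_duplicate",
    "postprocess",
    "predict",
    "read_matrix",
    "run_cv",
    "scan_weights",
    "score",
    "select_weight",
    "smote",
    "train_autoencoder",
    "transfer_weights",
    "weighted_bce",
    "zscore_apply",
    "zscore_fit",
]
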