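"""Experiment orchestration: 9:1 split, per-fold balancing, 5-fold CV.

The full protocol for one dataset pair:

1. split all rows 9:1 into a training pool and a held-out validation
   set (stratified, seeded);
2. partition the training pool into 5 cross-validation folds;
3. per fold — fit z-score statistics on the fold-training rows, balance
   the fold-training rows (duplication or SMOTE), pre-train the
   autoencoder, fine-tune the classifier with early stopping on the
   fold-test accuracy, and evaluate on both the fold-test rows and the
   validation set;
4. average the five indexes across the folds ("the average value is the
   final judgement").

Balancing inside each fold (rather than once before folding) keeps
synthetic copies of fold-test rows out of fold-training sets; the
historical protocol of balancing the whole training pool before CV
remains available behind ``leaky_balance=True`` for fidelity
experiments.  Validation rows never touch standardisation statistics,
SMOTE neighbourhoods, pre-training or early stopping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .balance import DuplicateOverSampler, SMOTEOverSampler
from .errors import DataError
from .matrixprep import DescriptorMatrix, ZScoreScaler
from .metrics import EvalReport, evaluate, mean_report
from .network import (
    DrugLikenessClassifier,
    TrainingConfig,
    train_autoencoder,
    transfer_weights,
)

VALIDATION = -1  # assignment code for validation rows


@dataclass
class SplitPlan:
    """Deterministic assignment of every row to validation or a CV fold."""

    seed: int
    validation_fraction: float
    fold_count: int
    assignment: np.ndarray  # -1 = validation, else fold index 0..fold_count-1
    stratified: bool

    @property
    def validation_rows(self) -> np.ndarray:
        return np.flatnonzero(self.assignment == VALIDATION)

    @property
    def train_rows(self) -> np.ndarray:
        return np.flatnonzero(self.assignment != VALIDATION)

    def fold_test_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def fold_train_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero((self.assignment != VALIDATION) & (self.assignment != fold))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "seed": self.seed,
            "validation_fraction": self.validation_fraction,
            "fold_count": self.fold_count,
            "stratified": self.stratified,
            "assignment": self.assignment.tolist(),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        d["assignment"] = np.asarray(d["assignment"], dtype=int)
        return cls(**d)


def make_split(
    n_rows: int,
    labels,
    seed: int = 0,
    validation_fraction: float = 0.1,
    fold_count: int = 5,
    stratified: bool = True,
) -> SplitPlan:
    """Assign rows 9:1 to train/validation and the train rows to CV folds.

    Stratified by default so that the validation set and every fold
    preserve the class ratio to within one row per stratum — essential
    at 1:59 imbalance, where an unstratified 10% draw can miss the
    positive class entirely.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != n_rows:
        raise DataError("labels length does not match n_rows")
    if n_rows < 2 * fold_count:
        raise DataError(f"need at least {2 * fold_count} rows for {fold_count} folds")
    rs = seed % (2**31)
    try:
        train_idx, val_idx = train_test_split(
            np.arange(n_rows), test_size=validation_fraction,
            stratify=labels if stratified else None, random_state=rs,
        )
    except ValueError as exc:
        raise DataError(f"cannot satisfy a stratified split: {exc}") from exc

    assignment = np.full(n_rows, VALIDATION, dtype=int)
    splitter = (StratifiedKFold if stratified else KFold)(
        n_splits=fold_count, shuffle=True, random_state=rs)
    try:
        for fold, (_, test) in enumerate(splitter.split(train_idx, labels[train_idx])):
            assignment[train_idx[test]] = fold
    except ValueError as exc:
        raise DataError(f"cannot build {fold_count} stratified folds: {exc}") from exc
    return SplitPlan(seed, validation_fraction, fold_count, assignment, stratified)


@dataclass
class ExperimentResult:
    """Per-fold and aggregated evaluation of one full experiment."""

    fold_reports: list
    fold_mean: dict
    validation_reports: list
    validation_mean: dict
    config: dict
    plan: SplitPlan
    balance_method: str
    fold_details: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fold_reports": [r.to_dict() for r in self.fold_reports],
            "fold_mean": self.fold_mean,
            "validation_reports": [r.to_dict() for r in self.validation_reports],
            "validation_mean": self.validation_mean,
            "config": self.config,
            "balance_method": self.balance_method,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _make_sampler(method: str, seed: int, smote_k: int):
    if method == "duplicate":
        return DuplicateOverSampler(seed=seed)
    if method == "smote":
        return SMOTEOverSampler(k=smote_k, seed=seed)
    raise DataError(f"unknown balance method {method!r}")


def run_cv(
    matrix: DescriptorMatrix,
    plan: SplitPlan,
    cfg: TrainingConfig,
    balance_method: str = "smote",
    smote_k: int = 5,
    leaky_balance: bool = False,
) -> ExperimentResult:
    """Run the cross-validated experiment on a post-processed labeled matrix.

    Returns per-fold reports on the fold-test rows, per-fold reports on
    the 10% validation set, and their unweighted means.  ``fold_details``
    records, for each fold, the row indices and fitted statistics used —
    the raw material for leakage audits.
    """
    if matrix.labels is None:
        raise DataError("run_cv requires a labeled matrix")
    X, y = matrix.values, matrix.labels
    val = plan.validation_rows
    if leaky_balance:
        return _run_cv_leaky(matrix, plan, cfg, balance_method, smote_k)

    fold_reports, val_reports, details = [], [], []
    for fold in range(plan.fold_count):
        tr = plan.fold_train_rows(fold)
        te = plan.fold_test_rows(fold)
        for name, rows in (("fold-train", tr), ("fold-test", te)):
            if len(np.unique(y[rows])) < 2:
                raise DataError(f"{name} rows of fold {fold} contain a single class")

        # columns constant within this fold's training rows cannot be z-scored
        keep = X[tr].std(axis=0) > 0
        scaler = ZScoreScaler().fit(X[np.ix_(tr, np.flatnonzero(keep))])
        Xtr = scaler.transform(X[np.ix_(tr, np.flatnonzero(keep))])
        Xte = scaler.transform(X[np.ix_(te, np.flatnonzero(keep))])
        Xval = scaler.transform(X[np.ix_(val, np.flatnonzero(keep))])

        fold_seed = cfg.seed + fold
        sampler = _make_sampler(balance_method, fold_seed, smote_k)
        Xb, yb, flags = sampler.fit_resample(Xtr, y[tr])

        fold_cfg = replace(cfg, seed=fold_seed)
        ae_params, _ = train_autoencoder(Xb, fold_cfg)
        init = transfer_weights(ae_params, fold_cfg)
        clf = DrugLikenessClassifier.from_config(fold_cfg, init_params=init)
        clf.fit(Xb, yb, eval_set=(Xte, y[te]))

        fold_reports.append(evaluate(y[te], clf.predict_proba(Xte)[:, 1], cfg.threshold))
        val_reports.append(evaluate(y[val], clf.predict_proba(Xval)[:, 1], cfg.threshold))
        details.append({
            "fold": fold,
            "train_rows": tr,
            "test_rows": te,
            "early_stop_rows": te,
            "col_mask": keep,
            "scaler_mean": scaler.mean_,
            "scaler_sd": scaler.sd_,
            "n_synthetic": int(flags.sum()),
            "balance_input_rows": tr,
        })

    return ExperimentResult(
        fold_reports=fold_reports,
        fold_mean=mean_report(fold_reports),
        validation_reports=val_reports,
        validation_mean=mean_report(val_reports),
        config=cfg.to_dict(),
        plan=plan,
        balance_method=balance_method,
        fold_details=details,
    )


def _run_cv_leaky(matrix, plan, cfg, balance_method, smote_k):
    """Historical protocol: balance the whole training pool, then fold it.

    Synthetic copies of fold-test rows end up in fold-training sets, so
    fold-test scores are optimistically biased; kept only for fidelity
    comparisons.  The validation set is still untouched.
    """
    X, y = matrix.values, matrix.labels
    tr, val = plan.train_rows, plan.validation_rows
    keep = X[tr].std(axis=0) > 0
    cols = np.flatnonzero(keep)
    scaler = ZScoreScaler().fit(X[np.ix_(tr, cols)])
    Xtr = scaler.transform(X[np.ix_(tr, cols)])
    Xval = scaler.transform(X[np.ix_(val, cols)])
    sampler = _make_sampler(balance_method, cfg.seed, smote_k)
    Xb, yb, flags = sampler.fit_resample(Xtr, y[tr])

    splitter = StratifiedKFold(n_splits=plan.fold_count, shuffle=True,
                               random_state=cfg.seed % (2**31))
    fold_reports, val_reports, details = [], [], []
    for fold, (itr, ite) in enumerate(splitter.split(Xb, yb)):
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        ae_params, _ = train_autoencoder(Xb[itr], fold_cfg)
        init = transfer_weights(ae_params, fold_cfg)
        clf = DrugLikenessClassifier.from_config(fold_cfg, init_params=init)
        clf.fit(Xb[itr], yb[itr], eval_set=(Xb[ite], yb[ite]))
        fold_reports.append(evaluate(yb[ite], clf.predict_proba(Xb[ite])[:, 1], cfg.threshold))
        val_reports.append(evaluate(y[val], clf.predict_proba(Xval)[:, 1], cfg.threshold))
        details.append({"fold": fold, "n_synthetic_in_fold_train": int(flags[itr].sum())})

    return ExperimentResult(
        fold_reports=fold_reports,
        fold_mean=mean_report(fold_reports),
        validation_reports=val_reports,
        validation_mean=mean_report(val_reports),
        config=cfg.to_dict(),
        plan=plan,
        balance_method=f"{balance_method} (leaky)",
        fold_details=details,
    )
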