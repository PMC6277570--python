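"""Positive-loss-weight scan and SE/SP-crossing selection.

A classifier trained on a balanced training set still tends to over-fit
the majority side of the *original* distribution: on the held-out
validation set its specificity exceeds its sensitivity.  Raising the
positive-sample weight ``w`` of the loss shifts the balance back.  The
scan trains one model per grid point (default: 21 points from 0.5 to 1.0,
i.e. 20 equal intervals), records the five evaluation indexes on the
validation set, and selects the weight where the SE and SP curves
intersect — interpolating the crossing linearly between adjacent grid
points, or falling back to the grid point with the smallest |SE − SP|
when the curves never cross.

Every grid point is trained from the *same* autoencoder-derived
initialisation and seed, so differences along the grid isolate the
effect of ``w``.  Early stopping inside the scan uses an internal split
of the training rows, never the validation set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import DataError
from .metrics import EvalReport, evaluate
from .network import (
    Autoencoder,
    DrugLikenessClassifier,
    NetworkParams,
    TrainingConfig,
    train_autoencoder,
    transfer_weights,
)

#: w = 1.0 (the grid endpoint) is trained as the limiting case w -> 1
_W_CLIP = 1e-9


def default_grid() -> np.ndarray:
    """21 weights from 0.5 to 1.0 in steps of 0.025 (20 intervals)."""
    return np.linspace(0.5, 1.0, 21)


@dataclass
class WeightScan:
    """Result of one weight scan: the grid, one report per grid point,
    and the selected weight with the rule that produced it."""

    grid: np.ndarray
    reports: list
    selected_w: float
    selection_rule: str  # {"crossing_interpolated", "min_abs_gap"}
    selected_report: EvalReport | None = None

    def to_dict(self) -> dict:
        return {
            "grid": [float(w) for w in self.grid],
            "reports": [r.to_dict() for r in self.reports],
            "selected_w": self.selected_w,
            "selection_rule": self.selection_rule,
            "selected_report": None if self.selected_report is None
            else self.selected_report.to_dict(),
        }


def _select(grid: np.ndarray, se: np.ndarray, sp: np.ndarray) -> tuple[float, str]:
    gap = se - sp
    for i in range(len(grid)):
        if gap[i] == 0:
            return float(grid[i]), "crossing_interpolated"
        if i + 1 < len(grid) and gap[i] * gap[i + 1] < 0:
            frac = gap[i] / (gap[i] - gap[i + 1])
            return float(grid[i] + frac * (grid[i + 1] - grid[i])), "crossing_interpolated"
    best = int(np.argmin(np.abs(gap)))  # argmin takes the first = smallest w on ties
    return float(grid[best]), "min_abs_gap"


def select_weight(scan: WeightScan) -> float:
    """Re-derive the selected weight from a completed scan."""
    if len(scan.grid) == 0:
        raise DataError("cannot select a weight from an empty scan")
    se = np.array([r.se for r in scan.reports], dtype=float)
    sp = np.array([r.sp for r in scan.reports], dtype=float)
    w, _ = _select(np.asarray(scan.grid, dtype=float), se, sp)
    return w


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DataError("weight grid is empty")
    if (grid <= 0).any() or (grid > 1).any():
        raise DataError("weight grid must lie in (0, 1]")
    if grid.size > 1 and not (np.diff(grid) > 0).all():
        raise DataError("weight grid must be strictly increasing")
    return grid


def _train_at(w, X_core, y_core, es_set, X_val, y_val, cfg, init):
    w_eff = min(float(w), 1.0 - _W_CLIP)
    clf = DrugLikenessClassifier.from_config(cfg, init_params=init, pos_weight=w_eff)
    clf.fit(X_core, y_core, eval_set=es_set)
    probs = clf.predict_proba(X_val)[:, 1]
    return clf, evaluate(y_val, probs, cfg.threshold)


def scan_weights(
    X_train,
    y_train,
    X_val,
    y_val,
    cfg: TrainingConfig,
    grid=None,
    ae: Autoencoder | NetworkParams | None = None,
    refine: bool = False,
    early_stop_fraction: float = 0.1,
) -> WeightScan:
    """Train one model per weight grid point and select the SE/SP crossing.

    Parameters
    ----------
    X_train, y_train
        Balanced, standardised training rows.
    X_val, y_val
        Untouched validation rows (standardised with training statistics).
    cfg
        Shared training configuration; its seed fixes the initialisation
        reused at every grid point.
    grid
        Weight values to scan; defaults to :func:`default_grid`.
    ae
        Optional pre-trained autoencoder (or its encoder params).  When
        omitted, one is trained on ``X_train`` first.
    refine
        When True, a second scan on a 5x finer sub-grid around the first
        selection refines the selected weight (off by default).
    early_stop_fraction
        Fraction of training rows held out internally for early
        stopping; 0 disables early stopping inside the scan.
    """
    grid = _validate_grid(default_grid() if grid is None else grid)
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if ae is None:
        ae_params, _ = train_autoencoder(X_train, cfg)
    else:
        ae_params = ae.params_ if isinstance(ae, Autoencoder) else ae
    init = transfer_weights(ae_params, cfg)

    if early_stop_fraction > 0:
        core_idx, es_idx = train_test_split(
            np.arange(len(y_train)), test_size=early_stop_fraction,
            stratify=y_train, random_state=cfg.seed % (2**31),
        )
        X_core, y_core = X_train[core_idx], y_train[core_idx]
        es_set = (X_train[es_idx], y_train[es_idx])
    else:
        X_core, y_core, es_set = X_train, y_train, None

    reports = []
    for w in grid:
        _, rep = _train_at(w, X_core, y_core, es_set, X_val, y_val, cfg, init)
        reports.append(rep)

    se = np.array([r.se for r in reports], dtype=float)
    sp = np.array([r.sp for r in reports], dtype=float)
    selected_w, rule = _select(grid, se, sp)

    if refine and len(grid) > 1:
        step = float(np.min(np.diff(grid)))
        lo = max(selected_w - step, float(grid[0]))
        hi = min(selected_w + step, float(grid[-1]))
        sub = np.unique(np.clip(np.arange(lo, hi + step / 10, step / 5), grid[0], grid[-1]))
        sub_reports = []
        for w in sub:
            _, rep = _train_at(w, X_core, y_core, es_set, X_val, y_val, cfg, init)
            sub_reports.append(rep)
        sub_se = np.array([r.se for r in sub_reports], dtype=float)
        sub_sp = np.array([r.sp for r in sub_reports], dtype=float)
        selected_w, rule = _select(sub, sub_se, sub_sp)

    _, selected_report = _train_at(selected_w, X_core, y_core, es_set,
                                   X_val, y_val, cfg, init)
    return WeightScan(grid=grid, reports=reports, selected_w=selected_w,
                      selection_rule=rule, selected_report=selected_report)


def iter_grid(param_grid: dict):
    """Exhaustive hyper-parameter grid: yields one dict per combination.

    A deliberately plain helper for small sweeps (hidden sizes, dropout,
    ...); no search strategy beyond full enumeration is provided.
    """
    keys = sorted(param_grid)
    for combo in itertools.product(*(param_grid[k] for k in keys)):
        yield dict(zip(keys, combo))
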