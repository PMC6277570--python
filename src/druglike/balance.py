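"""Training-set balancing by minority duplication or SMOTE.

Drug-likeness datasets are heavily imbalanced (down to ~1:59 positives to
negatives), and a classifier trained on the raw ratio collapses onto the
majority class.  Two over-sampling schemes bring the training classes to
a 1:1 ratio:

* **duplication** — minority rows are copied (sampled with replacement)
  until the counts match;
* **SMOTE** — synthetic minority rows are interpolated between a minority
  row and one of its *k* nearest minority neighbours:
  ``x_new = x_i + u * (x_nn - x_i)`` with ``u ~ Uniform(0, 1)``.

Balancing is applied to training rows only, never to validation rows.
Original rows are kept bit-identical and synthetic rows are appended
after them, flagged, so downstream leakage audits can tell them apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DataError
from .matrixprep import DescriptorMatrix


@dataclass
class BalanceResult:
    """Outcome of one balancing run.

    ``matrix`` holds the original rows first and the appended
    duplicated/synthetic rows after them; ``synthetic_flags`` marks the
    appended rows.
    """

    matrix: DescriptorMatrix
    synthetic_flags: np.ndarray
    method: str
    seed: int


class DuplicateOverSampler:
    """Balance classes by copying minority rows (random over-sampling).

    Appended rows are exact copies of minority rows, sampled uniformly
    with replacement under the given seed.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit_resample(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(X_out, y_out, synthetic_flags)`` with equal class counts."""
        X, y, minority, deficit = _check_classes(X, y)
        rng = np.random.default_rng(self.seed)
        min_idx = np.flatnonzero(y == minority)
        picks = rng.integers(0, len(min_idx), size=deficit)
        X_new = X[min_idx[picks]]
        return _append(X, y, X_new, minority)


class SMOTEOverSampler:
    """Balance classes with the synthetic minority over-sampling technique.

    Each synthetic row interpolates between a randomly chosen minority
    row and one of its ``k`` nearest minority neighbours (Euclidean
    distance, neighbours searched among minority rows only, self
    excluded).  ``k`` is reduced to ``minority_size - 1`` for tiny
    classes; a minority class of one row is an error — use duplication.
    Nearest-neighbour ties are broken by row index so a fixed seed gives
    a fixed output.
    """

    def __init__(self, k: int = 5, seed: int = 0):
        self.k = k
        self.seed = seed

    def fit_resample(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(X_out, y_out, synthetic_flags)`` with equal class counts."""
        if self.k < 1:
            raise DataError("k must be >= 1")
        X, y, minority, deficit = _check_classes(X, y)
        min_idx = np.flatnonzero(y == minority)
        n_min = len(min_idx)
        if deficit and n_min < 2:
            raise DataError(
                "SMOTE needs at least two minority rows; use duplication over-sampling instead"
            )
        if deficit == 0:
            return _append(X, y, X[:0], minority)

        k_eff = min(self.k, n_min - 1)
        neigh = _knn_indices(X[min_idx], k_eff)

        rng = np.random.default_rng(self.seed)
        base = rng.integers(0, n_min, size=deficit)
        which = rng.integers(0, k_eff, size=deficit)
        u = rng.random(deficit)
        x_i = X[min_idx[base]]
        x_nn = X[min_idx[neigh[base, which]]]
        X_new = x_i + u[:, None] * (x_nn - x_i)
        return _append(X, y, X_new, minority)


def _check_classes(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise DataError("X and y lengths differ")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("cannot balance a single-class dataset")
    minority = 1 if n_pos < n_neg else 0
    deficit = abs(n_pos - n_neg)
    return X, y, minority, deficit


def _append(X, y, X_new, minority):
    flags = np.concatenate([np.zeros(len(X), dtype=bool), np.ones(len(X_new), dtype=bool)])
    X_out = np.vstack([X, X_new])
    y_out = np.concatenate([y, np.full(len(X_new), minority, dtype=int)])
    return X_out, y_out, flags


def _knn_indices(P: np.ndarray, k: int, chunk: int = 1024) -> np.ndarray:
    """Indices of the k nearest neighbours of each row of P among the rows
    of P, self excluded, ties broken by row index (stable sort)."""
    n = len(P)
    out = np.empty((n, k), dtype=int)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(P[start:stop], P)
        d[np.arange(start, stop) - start, np.arange(start, stop)] = np.inf
        out[start:stop] = np.argsort(d, axis=1, kind="stable")[:, :k]
    return out


def _balance_matrix(m: DescriptorMatrix, sampler, method: str, seed: int) -> BalanceResult:
    if m.labels is None:
        raise DataError("balancing requires a labeled matrix")
    X_out, y_out, flags = sampler.fit_resample(m.values, m.labels)
    n_new = int(flags.sum())
    new_ids = np.array([f"{method}_{i}" for i in range(n_new)], dtype=object)
    out = DescriptorMatrix(
        values=X_out,
        row_ids=np.concatenate([m.row_ids, new_ids]),
        col_names=m.col_names.copy(),
        labels=y_out,
    )
    return BalanceResult(matrix=out, synthetic_flags=flags, method=method, seed=seed)


def oversample_duplicate(m: DescriptorMatrix, seed: int = 0) -> BalanceResult:
    """Balance a labeled matrix by duplicating minority rows ("copy the
    minority class" scheme)."""
    return _balance_matrix(m, DuplicateOverSampler(seed=seed), "duplicate", seed)


def smote(m: DescriptorMatrix, k: int = 5, seed: int = 0) -> BalanceResult:
    """Balance a labeled matrix with SMOTE interpolation."""
    return _balance_matrix(m, SMOTEOverSampler(k=k, seed=seed), "smote", seed)
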