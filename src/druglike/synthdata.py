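"""Synthetic descriptor matrices with controllable class structure.

Real drug-likeness descriptor tables have three statistical features the
modelling stack relies on: strong correlation between descriptors (low
intrinsic dimensionality), class imbalance that can reach ~1:59
(drugs vs. purchasable compounds), and dirty entries (missing values,
constant columns).  The generator emulates exactly these with a Gaussian
latent-factor model:

.. math::

    z \\sim \\mathcal{N}(\\pm\\,\\delta/2 \\cdot \\mathbf{1},\\; I_r),
    \\qquad x = zA + \\varepsilon,\\quad
    \\varepsilon \\sim \\mathcal{N}(0, \\sigma^2 I)

with a fixed random loading matrix :math:`A \\in \\mathbb{R}^{r \\times p}`.
Positive (drug-like) rows are shifted by :math:`+\\delta/2` in every
latent coordinate and negative rows by :math:`-\\delta/2`, so the
between-class Mahalanobis separation in latent space is
:math:`\\delta\\sqrt{r}`.  With ``noise_sd = 0`` the matrix has rank
exactly ``latent_dim``, which the autoencoder-vs-PCA tests exploit.

The generator does *not* emulate real Mold2 marginals (counts,
heavy-tailed indices, discreteness); conclusions about real descriptor
data require real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .matrixprep import DescriptorMatrix


@dataclass
class SynthSpec:
    """Parameters of one synthetic two-class descriptor table.

    ``class_shift`` is the per-latent-coordinate mean separation between
    the classes, in units of the latent standard deviation; ``noise_sd``
    is the isotropic ambient noise added on top of the loadings.
    """

    n_pos: int
    n_neg: int
    n_features: int = 700
    latent_dim: int = 10
    class_shift: float = 3.0
    noise_sd: float = 0.5
    n_constant_cols: int = 0
    na_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise DataError("both class sizes must be >= 1")
        if self.latent_dim < 1 or self.latent_dim > self.n_features - self.n_constant_cols:
            raise DataError("latent_dim must be in [1, n_features - n_constant_cols]")
        if not (0 <= self.na_fraction < 1):
            raise DataError("na_fraction must be in [0, 1)")
        if self.n_constant_cols < 0 or self.n_constant_cols >= self.n_features:
            raise DataError("n_constant_cols must be in [0, n_features)")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be non-negative")


def generate(spec: SynthSpec) -> tuple[DescriptorMatrix, dict]:
    """Generate a labeled synthetic descriptor matrix.

    Returns the matrix (rows shuffled, labels attached) and a ground-truth
    dictionary holding the loading matrix, latent factors, the spec and
    the Bayes accuracy of the optimal linear rule, for use as oracles in
    tests.
    """
    rng = np.random.default_rng(spec.seed)
    r, p = spec.latent_dim, spec.n_features - spec.n_constant_cols
    n = spec.n_pos + spec.n_neg

    loadings = rng.normal(size=(r, p))
    labels = np.concatenate([np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg, dtype=int)])
    shift = np.where(labels == 1, spec.class_shift / 2.0, -spec.class_shift / 2.0)
    latent = rng.normal(size=(n, r)) + shift[:, None]
    values = latent @ loadings
    if spec.noise_sd > 0:
        values = values + rng.normal(scale=spec.noise_sd, size=values.shape)

    if spec.n_constant_cols:
        consts = rng.normal(size=spec.n_constant_cols)
        values = np.hstack([values, np.broadcast_to(consts, (n, spec.n_constant_cols)).copy()])

    if spec.na_fraction > 0:
        mask = rng.random(values.shape) < spec.na_fraction
        values[mask] = np.nan

    order = rng.permutation(n)
    values, labels, latent_ord = values[order], labels[order], latent[order]

    matrix = DescriptorMatrix(
        values=values,
        row_ids=np.array([f"mol_{i:06d}" for i in range(n)], dtype=object),
        col_names=np.array([f"d{j:04d}" for j in range(values.shape[1])], dtype=object),
        labels=labels,
    )
    truth = {
        "spec": spec,
        "loadings": loadings,
        "latent": latent_ord,
        "bayes_accuracy": bayes_accuracy(spec, loadings),
    }
    return matrix, truth


def bayes_accuracy(spec: SynthSpec, loadings: np.ndarray) -> float:
    """Closed-form accuracy of the optimal linear rule on balanced classes.

    Both classes are Gaussian with shared covariance
    :math:`\\Sigma = A^\\top A + \\sigma^2 I` and mean difference
    :math:`\\Delta\\mu = \\delta\\,\\mathbf{1}^\\top A`; the Bayes error of the
    resulting LDA rule is :math:`\\Phi(-m/2)` with
    :math:`m^2 = \\Delta\\mu\\,\\Sigma^{-1}\\Delta\\mu^\\top`.
    """
    from scipy.stats import norm

    p = loadings.shape[1]
    dmu = spec.class_shift * np.ones(loadings.shape[0]) @ loadings
    sigma = loadings.T @ loadings + max(spec.noise_sd, 1e-12) ** 2 * np.eye(p)
    m2 = float(dmu @ np.linalg.solve(sigma, dmu))
    return float(norm.cdf(np.sqrt(m2) / 2.0))
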