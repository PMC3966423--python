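"""ML-kNN: Bayesian k-nearest-neighbour multilabel classifier.

For each label q, the classifier estimates the prior P(H_q) from training
prevalence and, from each training instance's k nearest neighbours
(Euclidean distance, self excluded), the likelihood of observing j of k
neighbours with the label given that the instance does / does not carry it.
A query is scored with the posterior P(H_q | j of its k neighbours carry q)
by Bayes' rule.  Counts are Laplace-smoothed with strength s (default 1).

Distance ties are broken by ascending training index, so predictions are
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .br import ScoreMatrix
from .data import DimensionError, MultiLabelDataset, ValidationError

__all__ = ["MLkNNModel", "fit_mlknn", "predict_mlknn"]


@dataclass
class MLkNNModel:
    train_features: np.ndarray      # (n, p)
    train_labels: np.ndarray        # (n, Q)
    label_names: list[str]
    k: int
    smoothing: float
    priors: np.ndarray              # (Q,) P(H_q)
    # posterior_tables[c, q, j]: P(j of k neighbours carry q | H_q is c), c in {0,1}
    posterior_tables: np.ndarray    # (2, Q, k+1)


def _k_nearest(X_query: np.ndarray, X_train: np.ndarray, k: int, exclude_self: bool) -> np.ndarray:
    """Indices of the k nearest training rows per query; ties by train index."""
    d = cdist(X_query, X_train, metric="euclidean")
    if exclude_self:
        np.fill_diagonal(d, np.inf)
    # stable argsort on distance keeps ascending index among exact ties
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def fit_mlknn(ds: MultiLabelDataset, k: int = 10, smoothing: float = 1.0) -> MLkNNModel:
    """Estimate priors and neighbour-count likelihood tables.

    priors: P(H_q) = (s + #train with q) / (2s + n).
    posterior tables: per label, the smoothed distribution of
    j = #neighbours carrying q among each training instance's k nearest
    (self excluded), split by whether the instance itself carries q.
    """
    ds.validate()
    X, Y = ds.features, ds.labels
    n, Q = Y.shape
    if n <= k:
        raise ValidationError(f"need n > k neighbours: n={n}, k={k}")
    if smoothing <= 0:
        raise ValidationError("smoothing must be positive")

    s = float(smoothing)
    priors = (s + Y.sum(axis=0)) / (2 * s + n)

    neigh = _k_nearest(X, X, k, exclude_self=True)          # (n, k)
    counts = Y[neigh].sum(axis=1).astype(int)               # (n, Q): j per instance/label

    tables = np.empty((2, Q, k + 1))
    for q in range(Q):
        has = Y[:, q] == 1
        for c, mask in ((1, has), (0, ~has)):
            hist = np.bincount(counts[mask, q], minlength=k + 1).astype(float)
            tables[c, q] = (s + hist) / (s * (k + 1) + hist.sum())
    return MLkNNModel(X.copy(), Y.copy(), list(ds.label_names), k, s, priors, tables)


def predict_mlknn(model: MLkNNModel, X: np.ndarray) -> ScoreMatrix:
    """Posterior P(H_q | neighbour count) for every query and label."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.train_features.shape[1]:
        raise DimensionError(
            f"query width {X.shape[1]} != training width {model.train_features.shape[1]}"
        )
    neigh = _k_nearest(X, model.train_features, model.k, exclude_self=False)
    counts = model.train_labels[neigh].sum(axis=1).astype(int)   # (m, Q)

    m, Q = counts.shape
    scores = np.empty((m, Q))
    for q in range(Q):
        j = counts[:, q]
        a = model.priors[q] * model.posterior_tables[1, q, j]
        b = (1.0 - model.priors[q]) * model.posterior_tables[0, q, j]
        scores[:, q] = a / (a + b)
    return ScoreMatrix(scores, list(model.label_names))
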