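"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops over sets, deliberately sharing no
code with the package, so agreement is evidence of correctness rather than
of consistency.
"""

from __future__ import annotations

import numpy as np


def ranks_bruteforce(scores: np.ndarray) -> list[dict[int, int]]:
    """Per-instance label -> rank maps, descending score, ties by label index."""
    out = []
    for row in np.atleast_2d(scores):
        order = sorted(range(len(row)), key=lambda j: (-row[j], j))
        out.append({lab: pos + 1 for pos, lab in enumerate(order)})
    return out


def average_precision_bruteforce(scores: np.ndarray, Y: np.ndarray) -> float:
    vals = []
    for row_scores, row_y, rank in zip(np.atleast_2d(scores), np.atleast_2d(Y),
                                       ranks_bruteforce(scores)):
        relevant = {j for j in range(len(row_y)) if row_y[j] == 1}
        if not relevant:
            continue
        per_label = []
        for y in relevant:
            above = sum(1 for y2 in relevant if rank[y2] <= rank[y])
            per_label.append(above / rank[y])
        vals.append(sum(per_label) / len(relevant))
    return sum(vals) / len(vals)


def coverage_bruteforce(scores: np.ndarray, Y: np.ndarray, normalize: bool = True) -> float:
    vals = []
    Q = np.atleast_2d(Y).shape[1]
    for row_y, rank in zip(np.atleast_2d(Y), ranks_bruteforce(scores)):
        relevant = [j for j in range(Q) if row_y[j] == 1]
        if not relevant:
            continue
        vals.append(max(rank[y] for y in relevant) - 1)
    value = sum(vals) / len(vals)
    return value / Q if normalize else value


def ranking_loss_bruteforce(scores: np.ndarray, Y: np.ndarray) -> float:
    vals = []
    for row_scores, row_y in zip(np.atleast_2d(scores), np.atleast_2d(Y)):
        Q = len(row_y)
        relevant = [j for j in range(Q) if row_y[j] == 1]
        irrelevant = [j for j in range(Q) if row_y[j] == 0]
        if not relevant or not irrelevant:
            continue
        bad = sum(
            1
            for y1 in relevant
            for y2 in irrelevant
            if row_scores[y1] <= row_scores[y2]
        )
        vals.append(bad / (len(relevant) * len(irrelevant)))
    return sum(vals) / len(vals)


def hamming_loss_bruteforce(pred: np.ndarray, Y: np.ndarray) -> float:
    pred, Y = np.atleast_2d(pred), np.atleast_2d(Y)
    n, Q = Y.shape
    total = 0
    for i in range(n):
        p_set = {j for j in range(Q) if pred[i, j] == 1}
        y_set = {j for j in range(Q) if Y[i, j] == 1}
        total += len(p_set.symmetric_difference(y_set))
    return total / (n * Q)


def one_error_bruteforce(scores: np.ndarray, Y: np.ndarray) -> float:
    vals = []
    for row_scores, row_y in zip(np.atleast_2d(scores), np.atleast_2d(Y)):
        relevant = {j for j in range(len(row_y)) if row_y[j] == 1}
        if not relevant:
            continue
        top = min(range(len(row_scores)), key=lambda j: (-row_scores[j], j))
        vals.append(0.0 if top in relevant else 1.0)
    return sum(vals) / len(vals)


def mlknn_bruteforce_scores(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_query: np.ndarray,
    k: int,
    s: float = 1.0,
) -> np.ndarray:
    """Naive all-pairs ML-kNN: pure loops, distances squared and re-rooted."""
    n, Q = Y_train.shape

    def knn(x, exclude: int | None) -> list[int]:
        d = []
        for t in range(n):
            if t == exclude:
                continue
            dist = sum((x[c] - X_train[t, c]) ** 2 for c in range(X_train.shape[1])) ** 0.5
            d.append((dist, t))
        d.sort(key=lambda pair: (pair[0], pair[1]))
        return [t for _, t in d[:k]]

    priors = [(s + sum(Y_train[i, q] for i in range(n))) / (2 * s + n) for q in range(Q)]

    # neighbour-count histograms per label, split by label presence
    c1 = [[0] * (k + 1) for _ in range(Q)]
    c0 = [[0] * (k + 1) for _ in range(Q)]
    for i in range(n):
        neigh = knn(X_train[i], exclude=i)
        for q in range(Q):
            j = int(sum(Y_train[t, q] for t in neigh))
            (c1 if Y_train[i, q] == 1 else c0)[q][j] += 1

    def table(c, q, j):
        return (s + c[q][j]) / (s * (k + 1) + sum(c[q]))

    scores = np.zeros((len(X_query), Q))
    for m, x in enumerate(X_query):
        neigh = knn(x, exclude=None)
        for q in range(Q):
            j = int(sum(Y_train[t, q] for t in neigh))
            a = priors[q] * table(c1, q, j)
            b = (1 - priors[q]) * table(c0, q, j)
            scores[m, q] = a / (a + b)
    return scores


def random_multilabel_instance(rng: np.random.Generator, Q: int) -> tuple[np.ndarray, np.ndarray]:
    """Random scores (with occasional ties) and a non-degenerate label row."""
    scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.7, 0.9], size=Q) if rng.random() < 0.3 \
        else rng.random(Q)
    while True:
        y = (rng.random(Q) < 0.5).astype(float)
        if 0 < y.sum() < Q:
            return np.asarray(scores, dtype=float), y
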