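"""Ranking-based multilabel evaluation measures and fold aggregation.

Five measures are computed from the per-instance ordering of label scores
f(x_i, y) (rank 1 = highest score; ties broken deterministically by ascending
label index):

* **average precision** — mean over instances of the average, over relevant
  labels y, of the fraction of labels ranked at or above y that are relevant;
  1 is perfect.
* **coverage** — mean of (max rank of a relevant label − 1), reported on a
  0–1 scale by dividing by Q; 0 is perfect.  The raw 0..Q−1 value is
  available via ``normalize=False``.
* **ranking loss** — mean fraction of relevant/irrelevant label pairs that
  are reversely ordered (ties count as reversed); 0 is perfect.
* **hamming loss** — fraction of instance–label cells misclassified after
  thresholding (the normalized symmetric difference of predicted and true
  label sets).
* **one-error** — fraction of instances whose top-ranked label is not
  relevant; on single-label data it equals ordinary classification error.

Instances with an empty relevant set carry no ranking information and are
skipped by the ranking measures (ranking loss also skips full label sets);
hamming loss always uses every instance.  Skipped counts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .br import ScoreMatrix
from .data import DimensionError, ValidationError

__all__ = [
    "UndefinedMetricError",
    "MetricValue",
    "MetricReport",
    "label_ranks",
    "average_precision",
    "coverage",
    "ranking_loss",
    "hamming_loss",
    "one_error",
    "evaluate_all",
    "aggregate_folds",
]

METRIC_NAMES = ("average_precision", "coverage", "hamming_loss", "one_error", "ranking_loss")


class UndefinedMetricError(ValueError):
    """Every instance is degenerate for the requested ranking measure."""


class MetricValue(NamedTuple):
    mean: float
    std: float


@dataclass
class MetricReport:
    average_precision: MetricValue
    coverage: MetricValue
    hamming_loss: MetricValue
    one_error: MetricValue
    ranking_loss: MetricValue
    n_instances: int
    n_skipped: int

    def to_dict(self) -> dict:
        d: dict = {}
        for name in METRIC_NAMES:
            v: MetricValue = getattr(self, name)
            d[name] = {"mean": v.mean, "std": v.std}
        d["n_instances"] = self.n_instances
        d["n_skipped"] = self.n_skipped
        return d

    def format_row(self) -> str:
        """Table-style 'mean ± std' cells, metrics as columns."""
        return "\t".join(
            f"{getattr(self, m).mean:.3f} ± {getattr(self, m).std:.3f}"
            for m in METRIC_NAMES
        )


def _coerce(sm: ScoreMatrix | np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = sm.scores if isinstance(sm, ScoreMatrix) else np.atleast_2d(np.asarray(sm, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if scores.shape != Y.shape:
        raise DimensionError(f"scores {scores.shape} vs labels {Y.shape}")
    if np.any((Y != 0) & (Y != 1)):
        raise ValidationError("label matrix must be binary")
    return scores, Y


def label_ranks(scores: np.ndarray) -> np.ndarray:
    """Per-instance ranks by descending score, rank 1 = best.

    Ties are broken by ascending label index (stable sort on the negated
    scores), making ranks invariant under strictly increasing transforms.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    order = np.argsort(-scores, axis=1, kind="stable")
    ranks = np.empty_like(order)
    n, Q = scores.shape
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, Q + 1)
    return ranks


def _require_valid(mask: np.ndarray, what: str) -> None:
    if not mask.any():
        raise UndefinedMetricError(f"every instance is degenerate for {what}")


def average_precision(sm: ScoreMatrix | np.ndarray, Y: np.ndarray) -> float:
    scores, Y = _coerce(sm, Y)
    ranks = label_ranks(scores)
    valid = Y.sum(axis=1) > 0
    _require_valid(valid, "average precision")
    total = 0.0
    for i in np.flatnonzero(valid):
        rel = np.flatnonzero(Y[i] == 1)
        r = ranks[i, rel]
        # for each relevant label: relevant labels at-or-above it / its rank
        prec = np.array([(r <= rj).sum() / rj for rj in r])
        total += prec.mean()
    return total / valid.sum()


def coverage(sm: ScoreMatrix | np.ndarray, Y: np.ndarray, normalize: bool = True) -> float:
    scores, Y = _coerce(sm, Y)
    ranks = label_ranks(scores)
    valid = Y.sum(axis=1) > 0
    _require_valid(valid, "coverage")
    depth = np.where(Y[valid] == 1, ranks[valid], 0).max(axis=1) - 1.0
    value = float(depth.mean())
    return value / Y.shape[1] if normalize else value


def ranking_loss(sm: ScoreMatrix | np.ndarray, Y: np.ndarray) -> float:
    scores, Y = _coerce(sm, Y)
    sizes = Y.sum(axis=1)
    valid = (sizes > 0) & (sizes < Y.shape[1])
    _require_valid(valid, "ranking loss")
    total = 0.0
    for i in np.flatnonzero(valid):
        rel = scores[i, Y[i] == 1]
        irr = scores[i, Y[i] == 0]
        # a relevant/irrelevant pair is mis-ordered when f(rel) <= f(irr)
        total += (rel[:, None] <= irr[None, :]).mean()
    return total / valid.sum()


def hamming_loss(pred: np.ndarray, Y: np.ndarray) -> float:
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if pred.shape != Y.shape:
        raise DimensionError(f"pred {pred.shape} vs labels {Y.shape}")
    if np.any((pred != 0) & (pred != 1)):
        raise ValidationError("predictions must be binary; threshold scores first")
    if np.any((Y != 0) & (Y != 1)):
        raise ValidationError("label matrix must be binary")
    return float((pred != Y).mean())


def one_error(sm: ScoreMatrix | np.ndarray, Y: np.ndarray) -> float:
    scores, Y = _coerce(sm, Y)
    valid = Y.sum(axis=1) > 0
    _require_valid(valid, "one-error")
    top = np.argmax(scores[valid], axis=1)  # argmax takes the lowest tied index
    hit = Y[valid, :][np.arange(valid.sum()), top]
    return float(1.0 - hit.mean())


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def evaluate_all(
    sm: ScoreMatrix | np.ndarray, Y: np.ndarray, pred: np.ndarray
) -> MetricReport:
    """All five measures on one evaluation set (std fields are 0 for one fold)."""
    scores, Y = _coerce(sm, Y)
    sizes = Y.sum(axis=1)
    skipped = int(((sizes == 0) | (sizes == Y.shape[1])).sum())
    zero = 0.0
    return MetricReport(
        average_precision=MetricValue(average_precision(scores, Y), zero),
        coverage=MetricValue(coverage(scores, Y), zero),
        hamming_loss=MetricValue(hamming_loss(pred, Y), zero),
        one_error=MetricValue(one_error(scores, Y), zero),
        ranking_loss=MetricValue(ranking_loss(scores, Y), zero),
        n_instances=int(Y.shape[0]),
        n_skipped=skipped,
    )


def aggregate_folds(reports: Iterable[MetricReport]) -> MetricReport:
    """Mean ± population std of each measure across folds."""
    reports = list(reports)
    if not reports:
        raise ValidationError("aggregate_folds requires at least one report")
    agg = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name).mean for r in reports])
        agg[name] = MetricValue(float(vals.mean()), float(vals.std()))  # population std
    return MetricReport(
        **agg,
        n_instances=sum(r.n_instances for r in reports),
        n_skipped=sum(r.n_skipped for r in reports),
    )
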