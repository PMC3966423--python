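"""Cross-validation harness, hidden-width sweep, and model comparison.

Experiments follow the study protocol: ten-fold cross-validation with the
five ranking measures reported as mean ± population standard deviation over
folds, plus per-label recognition accuracy in percent (the fraction of
held-out instances whose thresholded prediction for that label equals the
truth).  Folds are derived from the experiment seed alone and are reused
across grid points and across models, so every comparison is paired.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .br import BRModel, ScoreMatrix, binarize, fit_br, predict
from .data import MultiLabelDataset, RunConfig, ValidationError
from .metrics import METRIC_NAMES, MetricReport, aggregate_folds, evaluate_all
from .mlknn import fit_mlknn, predict_mlknn

logger = logging.getLogger("mldbn")

__all__ = [
    "ExperimentSpec",
    "CVResult",
    "kfold_split",
    "per_label_accuracy",
    "majority_baseline_accuracy",
    "run_cv",
    "hid_sweep",
    "compare_models",
    "sweep_table",
    "comparison_table",
]

# a custom scorer maps (training dataset, held-out features) -> score matrix
ScorerFn = Callable[[MultiLabelDataset, np.ndarray], ScoreMatrix | np.ndarray]


@dataclass
class ExperimentSpec:
    """One cross-validated experiment.

    ``model`` is ``"br_dbn"``, ``"mlknn"``, or a callable scorer
    (training dataset, held-out features) -> scores, used to wire in oracle
    and floor scorers.
    """

    dataset: MultiLabelDataset
    model: str | ScorerFn = "br_dbn"
    config: RunConfig = field(default_factory=RunConfig)
    n_folds: int = 10
    seed: int = 0
    mlknn_k: int = 10
    name: str | None = None

    def __post_init__(self) -> None:
        n = self.dataset.n_instances
        if not (2 <= self.n_folds <= n):
            raise ValidationError(f"n_folds must lie in [2, {n}], got {self.n_folds}")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        return self.model if isinstance(self.model, str) else getattr(
            self.model, "__name__", "scorer"
        )


@dataclass
class CVResult:
    """Aggregated cross-validation outcome."""

    report: MetricReport
    fold_reports: list[MetricReport]
    label_names: list[str]
    label_accuracy_mean: np.ndarray   # (Q,), percent
    label_accuracy_std: np.ndarray    # (Q,), percent, population std over folds
    model: str


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded balanced partition of 0..n-1 into k folds (sizes differ by <= 1)."""
    if not (2 <= k <= n):
        raise ValidationError(f"need 2 <= k <= n, got k={k}, n={n}")
    order = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xF01D])).permutation(n)
    return [np.sort(part) for part in np.array_split(order, k)]


def per_label_accuracy(pred: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Recognition accuracy per label, in percent."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return 100.0 * (pred == Y).mean(axis=0)


def majority_baseline_accuracy(Y_train: np.ndarray, Y_test: np.ndarray) -> np.ndarray:
    """Per-label accuracy (percent) of always predicting the training majority class."""
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    Y_test = np.atleast_2d(np.asarray(Y_test, dtype=float))
    majority = (Y_train.mean(axis=0) >= 0.5).astype(float)
    return 100.0 * (Y_test == majority).mean(axis=0)


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, fold]).generate_state(1)[0] & 0x7FFFFFFF)


def _fit_and_score(
    spec: ExperimentSpec, train: MultiLabelDataset, X_test: np.ndarray, fold: int
) -> np.ndarray:
    if callable(spec.model):
        sm = spec.model(train, X_test)
        return sm.scores if isinstance(sm, ScoreMatrix) else np.asarray(sm, dtype=float)
    if spec.model == "br_dbn":
        cfg = dataclasses.replace(spec.config, seed=_fold_seed(spec.config.seed, fold))
        model = fit_br(train, cfg)
        return predict(model, X_test).scores
    if spec.model == "mlknn":
        return predict_mlknn(fit_mlknn(train, k=spec.mlknn_k), X_test).scores
    raise ValidationError(f"unknown model {spec.model!r}")


def run_cv(spec: ExperimentSpec, folds: list[np.ndarray] | None = None) -> CVResult:
    """k-fold cross-validation: fit on k−1 folds, score the held-out fold.

    A label that is constant within a training fold is logged and the fold is
    still evaluated.  Deterministic given the spec (folds and all per-fold
    model seeds derive from the seeds in the spec).
    """
    ds = spec.dataset
    if folds is None:
        folds = kfold_split(ds.n_instances, spec.n_folds, spec.seed)
    all_idx = np.arange(ds.n_instances)
    reports: list[MetricReport] = []
    accs: list[np.ndarray] = []
    for fold, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train = MultiLabelDataset(
            ds.features[train_idx], ds.labels[train_idx],
            ds.feature_names, ds.label_names,
        )
        for q, name in enumerate(ds.label_names):
            col = train.labels[:, q]
            if col.min() == col.max():
                logger.warning("fold %d: label %r constant in training data", fold, name)
        scores = _fit_and_score(spec, train, ds.features[test_idx], fold)
        pred = binarize(scores, spec.config.threshold)
        Y_test = ds.labels[test_idx]
        reports.append(evaluate_all(scores, Y_test, pred))
        accs.append(per_label_accuracy(pred, Y_test))
        logger.debug("fold %d/%d done (%s)", fold + 1, len(folds), spec.label)
    acc = np.vstack(accs)
    return CVResult(
        report=aggregate_folds(reports),
        fold_reports=reports,
        label_names=list(ds.label_names),
        label_accuracy_mean=acc.mean(axis=0),
        label_accuracy_std=acc.std(axis=0),
        model=spec.label,
    )


def hid_sweep(spec: ExperimentSpec, hid_values: Sequence[int]) -> dict[int, CVResult]:
    """One cross-validated run per hidden-layer width, on shared folds."""
    if not hid_values:
        raise ValidationError("hid grid must be non-empty")
    folds = kfold_split(spec.dataset.n_instances, spec.n_folds, spec.seed)
    out: dict[int, CVResult] = {}
    for h in hid_values:
        cfg = dataclasses.replace(spec.config, layer_sizes=[int(h)])
        out[h] = run_cv(dataclasses.replace(spec, config=cfg), folds=folds)
        logger.info("hid=%d: %s", h, out[h].report.format_row())
    return out


def compare_models(specs: Sequence[ExperimentSpec]) -> dict[str, CVResult]:
    """Run several models on identical data and folds; aligned metric rows."""
    if len(specs) < 2:
        raise ValidationError("compare_models needs at least two specs")
    first = specs[0]
    for other in specs[1:]:
        if other.dataset is not first.dataset and other.dataset != first.dataset:
            raise ValidationError("all specs must share the same dataset")
        if (other.n_folds, other.seed) != (first.n_folds, first.seed):
            raise ValidationError("all specs must share fold count and seed")
    folds = kfold_split(first.dataset.n_instances, first.n_folds, first.seed)
    return {spec.label: run_cv(spec, folds=folds) for spec in specs}


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def _report_cells(report: MetricReport) -> dict[str, str]:
    return {
        m: f"{getattr(report, m).mean:.3f} ± {getattr(report, m).std:.3f}"
        for m in METRIC_NAMES
    }


def sweep_table(results: dict[int, CVResult]) -> pd.DataFrame:
    """One row per hidden width, five 'mean ± std' metric columns."""
    rows = [{"hid": h, **_report_cells(r.report)} for h, r in sorted(results.items())]
    return pd.DataFrame(rows).set_index("hid")


def comparison_table(results: dict[str, CVResult]) -> pd.DataFrame:
    """One row per model, five 'mean ± std' metric columns."""
    rows = [{"model": name, **_report_cells(r.report)} for name, r in results.items()]
    return pd.DataFrame(rows).set_index("model")
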