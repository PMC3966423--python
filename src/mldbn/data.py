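"""Dataset container and file input/output.

A multilabel symptom–syndrome dataset is a pair of matrices over the same
instances: an ``n × p`` feature matrix of binary symptom indicators (stored as
reals in [0, 1] so probability-valued representations can flow through the same
container) and an ``n × Q`` label matrix of {0, 1} syndrome indicators.  The
on-disk dialect is two plain CSV files with one header row each, instances as
rows — chosen over ARFF/Mulan XML for transparency.

Missing values are not supported: incomplete records are excluded upstream, so
the reader rejects empty cells rather than imputing.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mldbn")

__all__ = [
    "ValidationError",
    "DimensionError",
    "MultiLabelDataset",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "read_config",
    "write_config",
]


class ValidationError(ValueError):
    """An input violates a dataset or configuration invariant."""


class DimensionError(ValidationError):
    """Shapes of paired inputs are inconsistent."""


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class MultiLabelDataset:
    """Paired feature and label matrices with column names.

    Parameters
    ----------
    features
        ``(n, p)`` array of reals in [0, 1]; binary 0/1 for raw symptom
        indicators.
    labels
        ``(n, Q)`` array with entries exactly 0 or 1.
    feature_names, label_names
        Unique, non-empty column names for the two matrices.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    label_names: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        self.feature_names = [str(s) for s in self.feature_names]
        self.label_names = [str(s) for s in self.label_names]
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        f, y = self.features, self.labels
        if f.ndim != 2 or y.ndim != 2:
            raise DimensionError("features and labels must be 2-D matrices")
        if f.shape[0] != y.shape[0]:
            raise DimensionError(
                f"row-count mismatch: {f.shape[0]} feature rows vs "
                f"{y.shape[0]} label rows"
            )
        if f.shape[0] < 1:
            raise ValidationError("dataset must contain at least one instance")
        if f.shape[1] < 1:
            raise ValidationError("dataset must contain at least one feature")
        if y.shape[1] < 1:
            raise ValidationError("dataset must contain at least one label")
        if not np.all(np.isfinite(f)):
            i, j = np.argwhere(~np.isfinite(f))[0]
            raise ValidationError(
                f"non-finite feature value at row {i}, column "
                f"{self.feature_names[j]!r}"
            )
        if f.min() < 0.0 or f.max() > 1.0:
            i, j = np.argwhere((f < 0) | (f > 1))[0]
            raise ValidationError(
                f"feature value {f[i, j]!r} outside [0, 1] at row {i}, column "
                f"{self.feature_names[j]!r}"
            )
        bad = (y != 0.0) & (y != 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary label value {y[i, j]!r} at row {i}, column "
                f"{self.label_names[j]!r}"
            )
        for kind, names, width in (
            ("feature", self.feature_names, f.shape[1]),
            ("label", self.label_names, y.shape[1]),
        ):
            if len(names) != width:
                raise DimensionError(
                    f"{kind}_names has {len(names)} entries for {width} columns"
                )
            if any(not n for n in names):
                raise ValidationError(f"empty {kind} name")
            if len(set(names)) != len(names):
                dup = next(n for n in names if names.count(n) > 1)
                raise ValidationError(f"duplicate {kind} name {dup!r}")

    # -- conveniences ------------------------------------------------------

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_labels(self) -> int:
        return self.labels.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiLabelDataset):
            return NotImplemented
        return (
            self.feature_names == other.feature_names
            and self.label_names == other.label_names
            and np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
        )


# ---------------------------------------------------------------------------
# Training configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Hyperparameters for pretraining and fine-tuning.

    Defaults follow the study settings: learning rate 0.1, momentum
    ("smooth") 0.5, L2 weight decay ("damping factor") 2e-4, mini-batches of
    100 instances, and 100 iterations for each of the two training phases.
    ``layer_sizes`` is the list of hidden-layer widths; a single hidden layer
    of 80 units is the selected default.  ``cd_k`` is the number of Gibbs
    steps per contrastive-divergence update (1 is the canonical choice).
    """

    layer_sizes: list[int] = field(default_factory=lambda: [80])
    learning_rate: float = 0.1
    momentum: float = 0.5
    weight_decay: float = 2e-4
    batch_size: int = 100
    pretrain_epochs: int = 100
    finetune_epochs: int = 100
    threshold: float = 0.5
    seed: int = 0
    cd_k: int = 1

    def __post_init__(self) -> None:
        self.layer_sizes = [int(h) for h in self.layer_sizes]
        self.validate()

    def validate(self) -> None:
        if not self.layer_sizes:
            raise ValidationError("layer_sizes must be non-empty")
        if any(h < 1 for h in self.layer_sizes):
            raise ValidationError(f"hidden-layer widths must be >= 1: {self.layer_sizes}")
        if not self.learning_rate > 0:
            raise ValidationError("learning_rate must be positive")
        if not (0 <= self.momentum < 1):
            raise ValidationError("momentum must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValidationError("weight_decay must be nonnegative")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be a positive integer")
        if self.pretrain_epochs < 0 or self.finetune_epochs < 0:
            raise ValidationError("epoch counts must be nonnegative integers")
        if not (0 < self.threshold < 1):
            raise ValidationError("threshold must lie in (0, 1)")
        if self.cd_k < 1:
            raise ValidationError("cd_k must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# CSV dataset IO
# ---------------------------------------------------------------------------


def _read_matrix_csv(path: Path) -> tuple[np.ndarray, list[str]]:
    """Read one CSV matrix, rejecting duplicate headers and empty cells."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh), None)
    if header is None:
        raise ValidationError(f"{path}: empty file, expected a header row")
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise ValidationError(f"{path}: duplicate column name {dup!r}")
    df = pd.read_csv(
        path, header=0, names=header, dtype=float, float_precision="round_trip"
    )
    if df.isna().any().any():
        j = df.isna().any().idxmax()
        i = int(df[j].isna().idxmax())
        raise ValidationError(
            f"{path}: missing value at row {i}, column {j!r} "
            "(missing data are not supported)"
        )
    return df.to_numpy(dtype=float), [str(h) for h in header]


def read_dataset(features_path: Path | str, labels_path: Path | str) -> MultiLabelDataset:
    """Read the two-CSV dataset dialect and validate all invariants.

    Row order is preserved.  Raises :class:`DimensionError` on row-count
    mismatch and :class:`ValidationError` (naming the offending row/column)
    on non-binary labels, missing cells, or duplicate column names.
    """
    X, feature_names = _read_matrix_csv(Path(features_path))
    Y, label_names = _read_matrix_csv(Path(labels_path))
    if X.shape[0] != Y.shape[0]:
        raise DimensionError(
            f"row-count mismatch: {features_path} has {X.shape[0]} rows, "
            f"{labels_path} has {Y.shape[0]}"
        )
    return MultiLabelDataset(X, Y, feature_names, label_names)


def write_dataset(
    ds: MultiLabelDataset, features_path: Path | str, labels_path: Path | str
) -> None:
    """Write a dataset as two CSV files that read back identically.

    Floats are written with ``repr`` round-trip precision, so
    ``read_dataset(*write_dataset(ds))`` reproduces ``ds`` bit-exactly.
    """
    ds.validate()
    pd.DataFrame(ds.features, columns=ds.feature_names).to_csv(
        features_path, index=False
    )
    pd.DataFrame(ds.labels, columns=ds.label_names).to_csv(labels_path, index=False)


# ---------------------------------------------------------------------------
# Config IO (YAML or JSON by extension)
# ---------------------------------------------------------------------------


def read_config(path: Path | str) -> RunConfig:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            d = json.load(fh)
        else:
            d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValidationError(f"{path}: expected a mapping of RunConfig fields")
    return RunConfig.from_dict(d)


def write_config(cfg: RunConfig, path: Path | str) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(cfg.to_dict(), fh, indent=2)
        else:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
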