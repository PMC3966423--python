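"""Binary relevance multilabel wrapper around per-label DBNs.

The multilabel problem with Q labels is decomposed into Q independent binary
tasks: one deep belief network is pretrained and fine-tuned per label,
ignoring label correlations by design.  Each label's training draws from its
own random stream, derived from the run seed and the label *name*, so fits
are reproducible, independent of label column order, and unaffected by
adding or removing other labels.

Model files are a single self-describing JSON container holding every weight
matrix, bias vector, layer sizes, label names and the RunConfig, behind a
format/version tag.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import DimensionError, MultiLabelDataset, RunConfig, ValidationError
from .dbn import LabelNetwork, finetune, init_network, predict_scores, pretrain_stack

logger = logging.getLogger("mldbn")

__all__ = [
    "ScoreMatrix",
    "BRModel",
    "ModelFormatError",
    "label_rng",
    "fit_br",
    "predict",
    "binarize",
    "save_model",
    "load_model",
]

_MODEL_FORMAT = "mldbn-br-model"
_MODEL_VERSION = 1


class ModelFormatError(ValueError):
    """Model file has the wrong magic tag or an incompatible version."""


@dataclass
class ScoreMatrix:
    """Real-valued scores f(x_i, y) for every instance-label pair."""

    scores: np.ndarray       # (n, Q)
    label_names: list[str]

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.label_names = [str(s) for s in self.label_names]
        if self.scores.shape[1] != len(self.label_names):
            raise DimensionError(
                f"{self.scores.shape[1]} score columns vs "
                f"{len(self.label_names)} label names"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("non-finite scores")


@dataclass
class BRModel:
    """Ordered collection of Q per-label networks."""

    networks: list[LabelNetwork]
    label_names: list[str]
    cfg: RunConfig

    def __post_init__(self) -> None:
        if not self.networks or len(self.networks) != len(self.label_names):
            raise DimensionError("need one network per label name, at least one label")
        dims = {net.input_dim for net in self.networks}
        if len(dims) != 1:
            raise DimensionError(f"networks disagree on input dimension: {dims}")

    @property
    def input_dim(self) -> int:
        return self.networks[0].input_dim


def label_rng(seed: int, label_name: str) -> np.random.Generator:
    """Per-label random stream keyed on (run seed, label name).

    Keying on the name rather than the column index makes per-label fits
    invariant to label order and to the presence of other labels.
    """
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label_name.encode("utf-8"))])
    )


# ---------------------------------------------------------------------------
# Fit / predict / threshold
# ---------------------------------------------------------------------------


def fit_br(
    ds: MultiLabelDataset,
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
) -> BRModel:
    """Train one DBN per label on the shared feature matrix.

    For each label q (independently: training never reads other label
    columns): greedy RBM pretraining on the features, network init, then
    supervised fine-tuning against label column q.  A constant label column
    is a degenerate but legal target; it is logged and trained anyway.

    The optional ``rng`` argument is accepted for interface symmetry but per
    -label streams are always derived from ``cfg.seed`` and the label name,
    by contract, so results cannot depend on fit order.
    """
    ds.validate()
    networks: list[LabelNetwork] = []
    for q, name in enumerate(ds.label_names):
        y = ds.labels[:, q]
        if y.min() == y.max():
            logger.warning(
                "label %r is constant (%g) in the training data; the network "
                "will learn a near-constant predictor", name, y[0]
            )
        stream = label_rng(cfg.seed, name)
        stack = pretrain_stack(ds.features, cfg.layer_sizes, cfg, stream)
        net = init_network(stack, stream, cfg)
        net = finetune(net, ds.features, y, cfg, stream)
        networks.append(net)
        logger.debug("fitted label %d/%d (%s)", q + 1, ds.n_labels, name)
    return BRModel(networks, list(ds.label_names), cfg)


def predict(model: BRModel, X: np.ndarray) -> ScoreMatrix:
    """Score every instance against every label; column q comes from network q."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise DimensionError(
            f"feature width {X.shape[1]} != model input dim {model.input_dim}"
        )
    cols = [predict_scores(net, X) for net in model.networks]
    return ScoreMatrix(np.column_stack(cols), list(model.label_names))


def binarize(sm: ScoreMatrix | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold scores into {0,1} labels; ties (score == threshold) map to 1."""
    if not (0 < threshold < 1):
        raise ValidationError("threshold must lie in (0, 1)")
    scores = sm.scores if isinstance(sm, ScoreMatrix) else np.asarray(sm, dtype=float)
    return (scores >= threshold).astype(float)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: BRModel, path: Path | str) -> None:
    """Write the model as a self-describing JSON container.

    Floats are serialized with repr round-trip precision, so a load/save
    cycle reproduces every weight exactly.
    """
    doc = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "label_names": model.label_names,
        "config": model.cfg.to_dict(),
        "networks": [
            {
                "weights": [W.tolist() for W in net.layer_weights],
                "biases": [b.tolist() for b in net.layer_biases],
            }
            for net in model.networks
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path: Path | str) -> BRModel:
    """Load a model container, checking the format tag and version."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or doc.get("format") != _MODEL_FORMAT:
        raise ModelFormatError(f"{path}: not a {_MODEL_FORMAT} file")
    if doc.get("version") != _MODEL_VERSION:
        raise ModelFormatError(
            f"{path}: incompatible model version {doc.get('version')!r}, "
            f"expected {_MODEL_VERSION}"
        )
    cfg = RunConfig.from_dict(doc["config"])
    networks = [
        LabelNetwork(
            [np.asarray(W, dtype=float) for W in entry["weights"]],
            [np.asarray(b, dtype=float) for b in entry["biases"]],
            cfg,
        )
        for entry in doc["networks"]
    ]
    return BRModel(networks, [str(s) for s in doc["label_names"]], cfg)
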