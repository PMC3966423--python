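"""Deep belief network: greedy layer-wise pretraining and supervised fine-tuning.

A stack of RBMs is trained bottom-up — each RBM sees the hidden-probability
representation produced by the layers beneath it — and then unrolled into a
feed-forward network with logistic units: the RBM weights and hidden biases
initialise the hidden layers, and a fresh logistic output unit is attached on
top.  Fine-tuning is plain mini-batch gradient descent with momentum and L2
weight decay on the binary cross-entropy of the output unit, updating all
layers.  Hidden activations during fine-tuning and prediction are mean-field
probabilities, not samples (the standard DBN-to-MLP conversion), so forward
passes are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .data import DimensionError, RunConfig, ValidationError
from .rbm import RBMParams, hidden_probabilities, init_rbm, train_rbm

logger = logging.getLogger("mldbn")

__all__ = [
    "LabelNetwork",
    "pretrain_stack",
    "init_network",
    "finetune",
    "predict_scores",
    "bce_loss",
    "loss_and_grads",
]

_INIT_SCALE = 0.01


@dataclass
class LabelNetwork:
    """Feed-forward logistic network with a single-output top unit.

    ``layer_weights[l]`` maps layer l to layer l+1; the final matrix has one
    output column.  ``cfg`` is a snapshot of the hyperparameters used to
    train the network.
    """

    layer_weights: list[np.ndarray]
    layer_biases: list[np.ndarray]
    cfg: RunConfig

    def __post_init__(self) -> None:
        self.layer_weights = [np.asarray(W, dtype=float) for W in self.layer_weights]
        self.layer_biases = [np.asarray(b, dtype=float) for b in self.layer_biases]
        if len(self.layer_weights) != len(self.layer_biases):
            raise DimensionError("weights and biases must pair up layer by layer")
        if not self.layer_weights:
            raise ValidationError("network must have at least one layer")
        for l, (W, b) in enumerate(zip(self.layer_weights, self.layer_biases)):
            if W.ndim != 2 or b.shape != (W.shape[1],):
                raise DimensionError(f"layer {l}: bias shape {b.shape} vs W {W.shape}")
            if l > 0 and self.layer_weights[l - 1].shape[1] != W.shape[0]:
                raise DimensionError(
                    f"layer {l}: input width {W.shape[0]} does not chain with "
                    f"previous output width {self.layer_weights[l - 1].shape[1]}"
                )
        if self.layer_weights[-1].shape[1] != 1:
            raise DimensionError("output layer must have exactly one unit")

    @property
    def input_dim(self) -> int:
        return self.layer_weights[0].shape[0]

    def copy(self) -> "LabelNetwork":
        return LabelNetwork(
            [W.copy() for W in self.layer_weights],
            [b.copy() for b in self.layer_biases],
            replace(self.cfg),
        )


# ---------------------------------------------------------------------------
# Greedy pretraining
# ---------------------------------------------------------------------------


def pretrain_stack(
    X: np.ndarray,
    layer_sizes: list[int],
    cfg: RunConfig,
    rng: np.random.Generator,
) -> list[RBMParams]:
    """Train RBMs bottom-up; RBM l sees the hidden probabilities of RBM l-1."""
    if not layer_sizes:
        raise ValidationError("layer_sizes must be non-empty")
    if any(h < 1 for h in layer_sizes):
        raise ValidationError(f"layer sizes must be >= 1: {layer_sizes}")
    rep = np.atleast_2d(np.asarray(X, dtype=float))
    stack: list[RBMParams] = []
    for depth, h in enumerate(layer_sizes):
        logger.debug("pretraining RBM %d: %d -> %d units", depth + 1, rep.shape[1], h)
        params = train_rbm(rep, h, cfg, rng)
        stack.append(params)
        rep = hidden_probabilities(rep, params)
    return stack


def init_network(
    stack: list[RBMParams], rng: np.random.Generator, cfg: RunConfig
) -> LabelNetwork:
    """Unroll a pretrained stack into a LabelNetwork.

    Hidden layers copy RBM weights and hidden biases; the output layer
    (last hidden width -> 1 logistic unit) starts at Gaussian(0, 0.01^2)
    weights with zero bias, so untrained outputs sit near 0.5.
    """
    if not stack:
        raise ValidationError("stack must be non-empty")
    weights = [p.W.copy() for p in stack]
    biases = [p.b_hid.copy() for p in stack]
    top = stack[-1].p_hid
    weights.append(rng.normal(0.0, _INIT_SCALE, size=(top, 1)))
    biases.append(np.zeros(1))
    return LabelNetwork(weights, biases, replace(cfg))


# ---------------------------------------------------------------------------
# Forward pass and backprop
# ---------------------------------------------------------------------------


def _forward(net: LabelNetwork, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer, input first, output probabilities last."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.input_dim:
        raise DimensionError(
            f"input width {X.shape[1]} != network input dim {net.input_dim}"
        )
    acts = [X]
    for W, b in zip(net.layer_weights, net.layer_biases):
        acts.append(expit(acts[-1] @ W + b))
    return acts


def predict_scores(net: LabelNetwork, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; returns the (n,) output probabilities."""
    return _forward(net, X)[-1][:, 0]


def bce_loss(net: LabelNetwork, X: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy of the logistic output on (X, y)."""
    y = np.asarray(y, dtype=float).ravel()
    s = predict_scores(net, X)
    eps = 1e-12
    return float(-np.mean(y * np.log(s + eps) + (1 - y) * np.log(1 - s + eps)))


def loss_and_grads(
    net: LabelNetwork, X: np.ndarray, y: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Mean BCE and its exact gradients for every weight matrix and bias.

    Pure data gradient — weight decay is applied by the update rule, not
    here — so the result is directly checkable against finite differences.
    """
    y = np.asarray(y, dtype=float).ravel()
    acts = _forward(net, X)
    B = acts[0].shape[0]
    if y.shape[0] != B:
        raise DimensionError(f"target length {y.shape[0]} != batch size {B}")

    # logistic + BCE: delta at the output is simply (s - y)/B
    delta = (acts[-1] - y[:, None]) / B
    gW: list[np.ndarray] = [None] * len(net.layer_weights)  # type: ignore[list-item]
    gb: list[np.ndarray] = [None] * len(net.layer_biases)  # type: ignore[list-item]
    for l in range(len(net.layer_weights) - 1, -1, -1):
        gW[l] = acts[l].T @ delta
        gb[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ net.layer_weights[l].T) * acts[l] * (1 - acts[l])

    s = acts[-1][:, 0]
    eps = 1e-12
    loss = float(-np.mean(y * np.log(s + eps) + (1 - y) * np.log(1 - s + eps)))
    return loss, gW, gb


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------


def finetune(
    net: LabelNetwork,
    X: np.ndarray,
    y: np.ndarray,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> LabelNetwork:
    """Mini-batch gradient descent on BCE for ``cfg.finetune_epochs`` epochs.

    Uses the same batch size, learning rate, momentum and weight decay as
    pretraining; all layers are updated; decay applies to weights only.
    Deterministic given the generator state.  The input network is not
    modified.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.shape[0]:
        raise DimensionError("X and y row counts differ")
    if np.any((y != 0.0) & (y != 1.0)):
        bad = y[(y != 0.0) & (y != 1.0)][0]
        raise ValidationError(f"targets must be in {{0, 1}}; found {bad!r}")

    net = net.copy()
    vel_W = [np.zeros_like(W) for W in net.layer_weights]
    vel_b = [np.zeros_like(b) for b in net.layer_biases]
    n = X.shape[0]
    lr, mom, wd = cfg.learning_rate, cfg.momentum, cfg.weight_decay

    for epoch in range(cfg.finetune_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, gW, gb = loss_and_grads(net, X[idx], y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            for l in range(len(net.layer_weights)):
                vel_W[l] = mom * vel_W[l] - lr * (gW[l] + wd * net.layer_weights[l])
                vel_b[l] = mom * vel_b[l] - lr * gb[l]
                net.layer_weights[l] += vel_W[l]
                net.layer_biases[l] += vel_b[l]
        logger.debug("finetune epoch %d mean loss %.6f", epoch + 1, epoch_loss / n)
    return net
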