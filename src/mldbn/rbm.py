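"""Restricted Boltzmann Machine with binary units.

An RBM is a two-layer undirected energy model over binary visible units v and
binary hidden units h with energy

    E(v, h) = -b_vis . v - b_hid . h - v^T W h

so both conditionals factorise into logistic units.  Training uses one-step
contrastive divergence (CD-1) with momentum and L2 weight decay: the positive
statistics come from the data and the hidden-unit probabilities, the negative
statistics from one Gibbs step (sample h0, reconstruct visible probabilities,
recompute hidden probabilities).  Probabilities rather than samples are used
wherever the update remains unbiased — the standard variance-reduction
convention; only h0 is sampled, to drive the reconstruction.

For enumerable model sizes the module also provides the exact likelihood and
its gradient, which serve as independent correctness oracles for CD.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .data import DimensionError, RunConfig, ValidationError

logger = logging.getLogger("mldbn")

__all__ = [
    "RBMParams",
    "CDState",
    "init_rbm",
    "hidden_probabilities",
    "visible_probabilities",
    "cd1_step",
    "train_rbm",
    "free_energy",
    "exact_log_likelihood",
    "exact_log_likelihood_grad",
]

# Exact enumeration over 2^p_vis visible states is the oracle's cost; this cap
# keeps it to ~10^5 states.
_ENUM_LIMIT = 16

_INIT_SCALE = 0.01  # std of Gaussian weight init; biases start at zero


@dataclass
class RBMParams:
    """One RBM layer: visible-to-hidden weights and the two bias vectors."""

    W: np.ndarray        # (p_vis, p_hid)
    b_vis: np.ndarray    # (p_vis,)
    b_hid: np.ndarray    # (p_hid,)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b_vis = np.asarray(self.b_vis, dtype=float)
        self.b_hid = np.asarray(self.b_hid, dtype=float)
        if self.W.ndim != 2:
            raise DimensionError("W must be a matrix")
        if self.b_vis.shape != (self.W.shape[0],) or self.b_hid.shape != (self.W.shape[1],):
            raise DimensionError(
                f"bias shapes {self.b_vis.shape}/{self.b_hid.shape} inconsistent "
                f"with W {self.W.shape}"
            )
        for name, a in (("W", self.W), ("b_vis", self.b_vis), ("b_hid", self.b_hid)):
            if not np.all(np.isfinite(a)):
                raise ValidationError(f"non-finite entries in {name}")

    @property
    def p_vis(self) -> int:
        return self.W.shape[0]

    @property
    def p_hid(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.b_vis.copy(), self.b_hid.copy())


@dataclass
class CDState:
    """Momentum accumulators for contrastive-divergence training."""

    velocity_W: np.ndarray
    velocity_bvis: np.ndarray
    velocity_bhid: np.ndarray
    epoch: int = 0

    @classmethod
    def zeros(cls, params: RBMParams) -> "CDState":
        return cls(
            np.zeros_like(params.W),
            np.zeros_like(params.b_vis),
            np.zeros_like(params.b_hid),
        )

    def check_shapes(self, params: RBMParams) -> None:
        if (
            self.velocity_W.shape != params.W.shape
            or self.velocity_bvis.shape != params.b_vis.shape
            or self.velocity_bhid.shape != params.b_hid.shape
        ):
            raise DimensionError("CDState shapes do not match RBMParams")


def init_rbm(p_vis: int, p_hid: int, rng: np.random.Generator) -> RBMParams:
    """Gaussian(0, 0.01^2) weights, zero biases."""
    if p_vis < 1 or p_hid < 1:
        raise ValidationError("layer sizes must be >= 1")
    W = rng.normal(0.0, _INIT_SCALE, size=(p_vis, p_hid))
    return RBMParams(W, np.zeros(p_vis), np.zeros(p_hid))


# ---------------------------------------------------------------------------
# Conditionals
# ---------------------------------------------------------------------------


def hidden_probabilities(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """P(h_j = 1 | v) = logistic(b_hid_j + sum_i v_i W_ij).

    Accepts a single visible vector or a batch of rows; expit is
    overflow-safe for arbitrarily large pre-activations.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.p_vis:
        raise DimensionError(
            f"visible vector length {v.shape[-1]} != p_vis {params.p_vis}"
        )
    return expit(v @ params.W + params.b_hid)


def visible_probabilities(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """P(v_i = 1 | h) = logistic(b_vis_i + sum_j h_j W_ij)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.p_hid:
        raise DimensionError(
            f"hidden vector length {h.shape[-1]} != p_hid {params.p_hid}"
        )
    return expit(h @ params.W.T + params.b_vis)


# ---------------------------------------------------------------------------
# Contrastive divergence
# ---------------------------------------------------------------------------


def cd1_step(
    batch: np.ndarray,
    params: RBMParams,
    state: CDState,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> tuple[RBMParams, CDState]:
    """One CD-k parameter update on a mini-batch (k = ``cfg.cd_k``, default 1).

    velocity <- momentum * velocity + lr * (positive - negative)/B
                - lr * weight_decay * W       (decay on W only)
    params   <- params + velocity

    Deterministic given the generator state.  Raises a numeric error carrying
    the epoch index if the update produces non-finite parameters.
    """
    v0 = np.atleast_2d(np.asarray(batch, dtype=float))
    B = v0.shape[0]
    state.check_shapes(params)

    h0_prob = hidden_probabilities(v0, params)
    vk = v0
    hk_prob = h0_prob
    for _ in range(cfg.cd_k):
        h_sample = (rng.random(hk_prob.shape) < hk_prob).astype(float)
        vk = visible_probabilities(h_sample, params)
        hk_prob = hidden_probabilities(vk, params)

    lr = cfg.learning_rate
    grad_W = (v0.T @ h0_prob - vk.T @ hk_prob) / B
    grad_bvis = (v0 - vk).mean(axis=0)
    grad_bhid = (h0_prob - hk_prob).mean(axis=0)

    vW = cfg.momentum * state.velocity_W + lr * grad_W - lr * cfg.weight_decay * params.W
    vbv = cfg.momentum * state.velocity_bvis + lr * grad_bvis
    vbh = cfg.momentum * state.velocity_bhid + lr * grad_bhid

    W = params.W + vW
    if not (np.all(np.isfinite(W)) and np.all(np.isfinite(vbv)) and np.all(np.isfinite(vbh))):
        raise FloatingPointError(
            f"non-finite CD update (exploding weights) at epoch {state.epoch}"
        )
    new_params = RBMParams(W, params.b_vis + vbv, params.b_hid + vbh)
    new_state = CDState(vW, vbv, vbh, epoch=state.epoch)
    return new_params, new_state


def _batches(n: int, batch_size: int, order: np.ndarray):
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_rbm(
    X: np.ndarray,
    p_hid: int,
    cfg: RunConfig,
    rng: np.random.Generator,
    return_history: bool = False,
):
    """Train one RBM by CD over ``cfg.pretrain_epochs`` epochs of mini-batches.

    Rows are shuffled each epoch; the last batch may be smaller than
    ``cfg.batch_size``.  Per-epoch mean squared reconstruction error is logged
    at DEBUG level and optionally returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if p_hid < 1:
        raise ValidationError("p_hid must be >= 1")
    n = X.shape[0]
    params = init_rbm(X.shape[1], p_hid, rng)
    state = CDState.zeros(params)
    history: list[float] = []
    for epoch in range(cfg.pretrain_epochs):
        state.epoch = epoch
        order = rng.permutation(n)
        sq_err = 0.0
        for idx in _batches(n, cfg.batch_size, order):
            v0 = X[idx]
            params, state = cd1_step(v0, params, state, cfg, rng)
            state.epoch = epoch
            # mean-field reconstruction: deterministic diagnostic, no rng use
            recon = visible_probabilities(hidden_probabilities(v0, params), params)
            sq_err += float(((v0 - recon) ** 2).sum())
        err = sq_err / (n * X.shape[1])
        history.append(err)
        logger.debug("rbm epoch %d reconstruction error %.6f", epoch + 1, err)
    if return_history:
        return params, history
    return params


# ---------------------------------------------------------------------------
# Free energy and exact oracles
# ---------------------------------------------------------------------------


def free_energy(v: np.ndarray, params: RBMParams) -> np.ndarray | float:
    """F(v) = -b_vis . v - sum_j log(1 + exp(b_hid_j + (v W)_j)).

    Marginalizes the hidden layer analytically; vectorized over rows.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    v2 = np.atleast_2d(v)
    if v2.shape[1] != params.p_vis:
        raise DimensionError("visible vector length mismatch")
    pre = v2 @ params.W + params.b_hid
    F = -v2 @ params.b_vis - np.logaddexp(0.0, pre).sum(axis=1)
    return float(F[0]) if single else F


def _all_binary_states(p: int) -> np.ndarray:
    return np.array(list(itertools.product((0.0, 1.0), repeat=p)))


def _check_enumerable(params: RBMParams) -> None:
    if params.p_vis + params.p_hid > _ENUM_LIMIT:
        raise DimensionError(
            f"exact enumeration refused: p_vis + p_hid = "
            f"{params.p_vis + params.p_hid} > {_ENUM_LIMIT}"
        )


def exact_log_likelihood(X: np.ndarray, params: RBMParams) -> float:
    """Exact average log-likelihood by summing the partition function.

    Only tractable for small models; refuses when p_vis + p_hid exceeds the
    enumeration guard.
    """
    _check_enumerable(params)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    states = _all_binary_states(params.p_vis)
    log_Z = logsumexp(-free_energy(states, params))
    return float(np.mean(-free_energy(X, params)) - log_Z)


def exact_log_likelihood_grad(X: np.ndarray, params: RBMParams) -> RBMParams:
    """Exact gradient of the average log-likelihood, as an RBMParams triple.

    d/dθ log p(v) = E_data[-dF/dθ] - E_model[-dF/dθ], with
    -dF/dW_ij = v_i P(h_j=1|v), -dF/db_vis = v, -dF/db_hid = P(h|v).
    The model expectation enumerates all visible states weighted by p(v).
    """
    _check_enumerable(params)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    states = _all_binary_states(params.p_vis)
    F = free_energy(states, params)
    log_p = -F - logsumexp(-F)
    p = np.exp(log_p)

    h_data = hidden_probabilities(X, params)
    h_model = hidden_probabilities(states, params)

    gW = X.T @ h_data / X.shape[0] - states.T @ (h_model * p[:, None])
    gbv = X.mean(axis=0) - p @ states
    gbh = h_data.mean(axis=0) - p @ h_model
    return RBMParams(gW, gbv, gbh)
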