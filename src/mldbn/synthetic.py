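"""Synthetic multilabel symptom–syndrome data with hierarchical latent structure.

Real clinical inquiry data of this kind — hundreds of binary symptom items,
a handful of co-occurring syndrome diagnoses per patient — are rarely
deposited, so this module generates datasets with the same shape and the
hierarchical structure symptoms <- syndrome factors <- syndromes:

1. **Labels.**  Each instance's Q-vector of syndromes is drawn from a
   pairwise log-linear (Ising-like) model: P(s) ∝ exp(Σ θ_q s_q +
   Σ_{q<r} C_qr s_q s_r).  The unary terms θ are calibrated by fixed-point
   iteration so marginal prevalences hit their targets exactly under the
   requested pairwise association matrix C.  Labels are therefore genuinely
   correlated, which stresses the binary-relevance assumption.
2. **Symptoms.**  Given the active syndromes, symptom i fires by noisy-OR:
   P(x_i = 1 | s) = 1 − (1 − background) Π_{q: s_q=1} (1 − loading[q, i]),
   i.e. a symptom appears unless every active cause and the background
   process independently fail to trigger it.  Syndrome factors are merged
   into the syndrome labels themselves for generation.
3. **Observation noise.**  Each recorded symptom flips with a small
   symmetric probability, emulating inquiry/entry error.

Because the full generative law is explicit and Q is small, the exact
posterior P(label | symptoms) is available by enumerating all 2^Q label
vectors (:func:`bayes_scores`); it provides the performance ceiling any
classifier can be measured against.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logit

from .br import ScoreMatrix
from .data import DimensionError, MultiLabelDataset, ValidationError

__all__ = [
    "SyntheticConfig",
    "CalibrationError",
    "label_distribution",
    "generate",
    "bayes_scores",
    "default_cg_profile",
    "write_sidecar",
]

_ENUM_Q_LIMIT = 10


class CalibrationError(RuntimeError):
    """Prevalence/association targets could not be realised."""


@dataclass
class SyntheticConfig:
    """Generative specification for one synthetic dataset.

    ``label_cooccurrence`` holds pairwise log-odds boosts (symmetric, zero
    diagonal); ``factor_loadings[q, i]`` is the probability that syndrome q
    activates symptom i through its factor.
    """

    n: int = 919
    p: int = 113
    Q: int = 6
    label_prevalence: np.ndarray = field(default_factory=lambda: np.full(6, 0.25))
    label_cooccurrence: np.ndarray = field(default_factory=lambda: np.zeros((6, 6)))
    factor_loadings: np.ndarray = field(default_factory=lambda: np.zeros((6, 113)))
    background_rate: float = 0.05
    flip_noise: float = 0.02
    seed: int = 0
    label_names: list[str] | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.label_prevalence = np.asarray(self.label_prevalence, dtype=float)
        self.label_cooccurrence = np.asarray(self.label_cooccurrence, dtype=float)
        self.factor_loadings = np.asarray(self.factor_loadings, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n < 1 or self.p < 1 or self.Q < 1:
            raise ValidationError("n, p and Q must be positive")
        if self.label_prevalence.shape != (self.Q,):
            raise DimensionError(f"label_prevalence must have shape ({self.Q},)")
        if np.any(self.label_prevalence <= 0) or np.any(self.label_prevalence >= 1):
            raise ValidationError("prevalences must lie strictly in (0, 1)")
        C = self.label_cooccurrence
        if C.shape != (self.Q, self.Q):
            raise DimensionError(f"label_cooccurrence must be {self.Q}x{self.Q}")
        if not np.allclose(C, C.T):
            raise ValidationError("label_cooccurrence must be symmetric")
        if np.any(np.diag(C) != 0):
            raise ValidationError("label_cooccurrence diagonal must be zero")
        if np.any(C < 0):
            raise ValidationError("association strengths must be nonnegative")
        L = self.factor_loadings
        if L.shape != (self.Q, self.p):
            raise DimensionError(f"factor_loadings must be {self.Q}x{self.p}")
        if np.any(L < 0) or np.any(L > 1):
            raise ValidationError("factor loadings must lie in [0, 1]")
        if not (0 <= self.background_rate < 1):
            raise ValidationError("background_rate must lie in [0, 1)")
        if not (0 <= self.flip_noise < 1):
            raise ValidationError("flip_noise must lie in [0, 1)")
        for attr, width in (("label_names", self.Q), ("feature_names", self.p)):
            names = getattr(self, attr)
            if names is not None and len(names) != width:
                raise DimensionError(f"{attr} must have {width} entries")

    def resolved_label_names(self) -> list[str]:
        return list(self.label_names) if self.label_names else [
            f"syndrome_{q + 1}" for q in range(self.Q)
        ]

    def resolved_feature_names(self) -> list[str]:
        return list(self.feature_names) if self.feature_names else [
            f"symptom_{i + 1:03d}" for i in range(self.p)
        ]

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("label_prevalence", "label_cooccurrence", "factor_loadings"):
            d[key] = np.asarray(d[key]).tolist()
        return d


# ---------------------------------------------------------------------------
# Label model: pairwise log-linear with calibrated marginals
# ---------------------------------------------------------------------------


def _all_label_vectors(Q: int) -> np.ndarray:
    if Q > _ENUM_Q_LIMIT:
        raise DimensionError(f"label enumeration refused for Q={Q} > {_ENUM_Q_LIMIT}")
    bits = (np.arange(2**Q)[:, None] >> np.arange(Q)) & 1
    return bits.astype(float)


def _marginals(theta: np.ndarray, C: np.ndarray, vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    energy = vectors @ theta + 0.5 * np.einsum("kq,qr,kr->k", vectors, C, vectors)
    energy -= energy.max()
    w = np.exp(energy)
    probs = w / w.sum()
    return probs @ vectors, probs


def _calibrate_theta(
    prevalence: np.ndarray, C: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> np.ndarray:
    """Fixed-point calibration of unary log-odds to hit target marginals."""
    vectors = _all_label_vectors(len(prevalence))
    theta = logit(prevalence).astype(float)
    for _ in range(max_iter):
        m, _ = _marginals(theta, C, vectors)
        if np.max(np.abs(m - prevalence)) < tol:
            return theta
        theta += logit(prevalence) - logit(np.clip(m, 1e-12, 1 - 1e-12))
    m, _ = _marginals(theta, C, vectors)
    raise CalibrationError(
        "prevalence calibration did not converge; residual "
        f"{np.max(np.abs(m - prevalence)):.3e} — prevalence/association targets "
        "may be infeasible"
    )


def label_distribution(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """All 2^Q label vectors and their calibrated probabilities."""
    vectors = _all_label_vectors(cfg.Q)
    theta = _calibrate_theta(cfg.label_prevalence, cfg.label_cooccurrence)
    _, probs = _marginals(theta, cfg.label_cooccurrence, vectors)
    return vectors, probs


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _symptom_probs(label_vectors: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Noisy-OR P(x_i = 1 | s) for each label vector (rows), before flip noise."""
    # log(1 - p) = log(1 - bg) + sum over active causes of log(1 - loading)
    log_fail = np.log1p(-np.clip(cfg.factor_loadings, 0.0, 1.0 - 1e-15))
    log_off = np.log1p(-cfg.background_rate) + label_vectors @ log_fail
    p = 1.0 - np.exp(log_off)
    # loadings of exactly 1 must force the symptom on for active labels
    forced = (label_vectors @ (cfg.factor_loadings == 1.0)) > 0
    p[forced] = 1.0
    return p


def generate(cfg: SyntheticConfig) -> MultiLabelDataset:
    """Draw one dataset: labels, noisy-OR symptoms, then symmetric flip noise.

    Bit-identical for identical configurations (the seed is part of the
    configuration).
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0x5D17]))
    vectors, probs = label_distribution(cfg)
    which = rng.choice(len(vectors), size=cfg.n, p=probs)
    Y = vectors[which]

    p_sym = _symptom_probs(Y, cfg)                       # (n, p)
    X = (rng.random((cfg.n, cfg.p)) < p_sym).astype(float)
    if cfg.flip_noise > 0:
        flips = rng.random((cfg.n, cfg.p)) < cfg.flip_noise
        X = np.where(flips, 1.0 - X, X)
    return MultiLabelDataset(X, Y, cfg.resolved_feature_names(), cfg.resolved_label_names())


# ---------------------------------------------------------------------------
# Exact posterior scorer (performance ceiling)
# ---------------------------------------------------------------------------


def bayes_scores(cfg: SyntheticConfig, X: np.ndarray) -> ScoreMatrix:
    """Exact P(label q = 1 | symptoms) under the generative model.

    Enumerates all 2^Q label vectors; observation likelihood includes the
    flip noise: P(x_i=1 | s) = p_i (1 − ε) + (1 − p_i) ε.
    """
    cfg.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != cfg.p:
        raise DimensionError(f"feature width {X.shape[1]} != cfg.p {cfg.p}")
    vectors, prior = label_distribution(cfg)
    eps = cfg.flip_noise
    f = _symptom_probs(vectors, cfg) * (1 - eps) + (1 - _symptom_probs(vectors, cfg)) * eps
    f = np.clip(f, 1e-300, 1.0 - 1e-16)
    # log P(x | s) for every instance (rows) x label vector (cols)
    loglik = X @ np.log(f).T + (1.0 - X) @ np.log1p(-f).T
    logpost = loglik + np.log(prior)
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    marg = post @ vectors
    return ScoreMatrix(np.clip(marg, 0.0, 1.0), cfg.resolved_label_names())


# ---------------------------------------------------------------------------
# Default chronic-gastritis-like profile
# ---------------------------------------------------------------------------

_CG_LABELS = [
    "damp_heat_spleen_stomach",
    "damp_obstruction_spleen_stomach",
    "spleen_stomach_qi_deficiency",
    "spleen_stomach_deficiency_cold",
    "liver_stagnation",
    "stagnated_heat_liver_stomach",
]

# heterogeneous prevalences with one rare syndrome (deficiency cold)
_CG_PREVALENCE = np.array([0.32, 0.28, 0.30, 0.07, 0.33, 0.22])

# (label, label, log-odds boost): the two damp syndromes co-occur most,
# qi deficiency pairs with deficiency cold, the two liver patterns pair.
_CG_ASSOC = [(0, 1, 0.9), (2, 3, 0.6), (4, 5, 0.6), (0, 5, 0.3), (1, 2, 0.3)]

# (label, first symptom, count): contiguous symptom blocks; the two
# damp-related syndromes share symptoms 13..17.
_CG_BLOCKS = [(0, 0, 18), (1, 13, 18), (2, 31, 16), (3, 47, 13), (4, 60, 16), (5, 76, 14)]


def default_cg_profile(seed: int = 0) -> SyntheticConfig:
    """Profile emulating a chronic-gastritis inquiry dataset.

    919 instances, 113 binary symptom items, 6 co-occurring syndrome labels.
    Each syndrome loads on a block of 13–18 symptoms (loadings 0.3–0.75,
    drawn once from a fixed stream so the profile is a constant); symptoms
    88–112 are background-only distractors.  The deficiency-cold syndrome is
    rare but has the strongest, most distinctive loadings, mimicking a
    pattern that is infrequent yet easy to recognise when present.
    """
    loadings = np.zeros((6, 113))
    block_rng = np.random.default_rng(np.random.SeedSequence(201403))
    for q, start, count in _CG_BLOCKS:
        lo, hi = (0.5, 0.75) if q == 3 else (0.3, 0.6)
        loadings[q, start : start + count] = block_rng.uniform(lo, hi, size=count)

    C = np.zeros((6, 6))
    for q, r, boost in _CG_ASSOC:
        C[q, r] = C[r, q] = boost

    return SyntheticConfig(
        n=919,
        p=113,
        Q=6,
        label_prevalence=_CG_PREVALENCE.copy(),
        label_cooccurrence=C,
        factor_loadings=loadings,
        background_rate=0.05,
        flip_noise=0.02,
        seed=seed,
        label_names=list(_CG_LABELS),
    )


def write_sidecar(cfg: SyntheticConfig, path: Path | str) -> None:
    """Record the true generative parameters next to an emitted dataset."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(cfg.to_jsonable(), fh, indent=2)
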