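"""Evidential multi-objective classification loss with adaptive weighting.

Four terms: cross-entropy on the Dirichlet expected probabilities, the
evidential expected cross-entropy  sum_k y_k (psi(S) - psi(alpha_k)), a
KL regularizer pulling misleading evidence toward the uniform Dirichlet,
and an alignment term (u - (1 - S))^2 coupling evidential uncertainty u
to segmentation confidence S.  The term weights follow a temperature
softmax lambda_i = exp(z_i / tau) / sum_j exp(z_j / tau) (tau = 2.0)
over per-term learning-progress statistics z_i, maintained as an EMA
(momentum 0.9) of the relative one-epoch loss decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special as sps

from .clsnet import K_CLASSES
from .nn.tensor import Tensor, as_tensor

__all__ = [
    "AdaptiveWeights",
    "edl_loss",
    "kl_uniform",
    "confidence_loss",
    "adaptive_weights",
    "compound_cls_loss",
    "TERM_NAMES",
]

TERM_NAMES = ("ce", "edl", "kl", "conf")


@dataclass
class AdaptiveWeights:
    lambdas: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    z: np.ndarray = field(default_factory=lambda: np.zeros(4))
    tau: float = 2.0
    ema_momentum: float = 0.9

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if abs(self.lambdas.sum() - 1.0) > 1e-9 or (self.lambdas < 0).any():
            raise ValueError("lambdas must be nonnegative and sum to 1")


def _alpha_tensor(pred) -> Tensor:
    """Accept a DirichletPrediction, an (N, K) / (K,) tensor or array."""
    alpha = getattr(pred, "alpha", pred)
    t = as_tensor(alpha)
    if (t.data < 1.0 - 1e-9).any():
        raise ValueError("Dirichlet concentrations must be >= 1")
    if t.ndim == 1:
        t = t.reshape(1, -1)
    return t


def _onehot(label, n: int) -> np.ndarray:
    lab = np.atleast_1d(np.asarray(label, dtype=int))
    return np.eye(K_CLASSES)[lab][:n] if len(lab) == n else np.tile(np.eye(K_CLASSES)[lab], (n, 1))


def edl_loss(pred, label) -> Tensor:
    """Expected cross-entropy under Dir(alpha): sum_k y_k (psi(S) - psi(alpha_k))."""
    alpha = _alpha_tensor(pred)
    n = alpha.shape[0]
    y = _onehot(label, n)
    s = alpha.sum(axis=1, keepdims=True)
    per = (as_tensor(y) * (s.digamma() - alpha.digamma())).sum(axis=1)
    return per.mean()


def kl_uniform(pred, label) -> Tensor:
    """KL(Dir(alpha~) || Dir(1)) with the true-class concentration reset to 1.

    Closed form: log Gamma(S~) - sum log Gamma(a~_k) - log Gamma(K)
    + sum (a~_k - 1)(psi(a~_k) - psi(S~)).
    """
    alpha = _alpha_tensor(pred)
    n = alpha.shape[0]
    y = _onehot(label, n)
    y_t = as_tensor(y)
    at = y_t + (1.0 - y_t) * alpha  # misleading evidence only
    s = at.sum(axis=1, keepdims=True)
    term = (
        s.gammaln().reshape(n)
        - at.gammaln().sum(axis=1)
        - float(sps.gammaln(K_CLASSES))
        + ((at - 1.0) * (at.digamma() - s.digamma())).sum(axis=1)
    )
    return term.mean()


def confidence_loss(pred, confidence_S) -> Tensor:
    """(u - (1 - S))^2: evidential uncertainty should mirror poor segmentation."""
    alpha = _alpha_tensor(pred)
    s_seg = np.atleast_1d(np.asarray(confidence_S, dtype=float))
    if (s_seg < 0).any() or (s_seg > 1).any():
        raise ValueError("confidence S must lie in [0, 1]")
    u = K_CLASSES / alpha.sum(axis=1)
    diff = u - as_tensor(1.0 - s_seg)
    return (diff * diff).mean()


def expected_ce(pred, label, clamp: float = 1e-7) -> Tensor:
    """Plain cross-entropy on the Dirichlet mean alpha / S."""
    alpha = _alpha_tensor(pred)
    n = alpha.shape[0]
    y = _onehot(label, n)
    p = alpha / alpha.sum(axis=1, keepdims=True)
    return -(as_tensor(y) * p.clip(clamp, 1.0).log()).sum(axis=1).mean()


def adaptive_weights(loss_history, state: AdaptiveWeights | None = None) -> AdaptiveWeights:
    """Update z (EMA of relative per-epoch improvement) and recompute lambda.

    ``loss_history`` maps each term name to its per-epoch loss series; the
    last two entries define the one-epoch relative decrease.
    """
    state = state or AdaptiveWeights()
    z = state.z.copy()
    for i, name in enumerate(TERM_NAMES):
        series = list(loss_history.get(name, []))
        if len(series) >= 2:
            prev, cur = series[-2], series[-1]
            delta = (prev - cur) / (abs(prev) + 1e-8)
            z[i] = state.ema_momentum * z[i] + (1.0 - state.ema_momentum) * delta
    lam = np.exp((z - z.max()) / state.tau)
    lam /= lam.sum()
    return AdaptiveWeights(lambdas=lam, z=z, tau=state.tau, ema_momentum=state.ema_momentum)


def compound_cls_loss(pred, label, confidence_S, weights: AdaptiveWeights | None = None):
    """lambda-weighted sum of the four terms; returns (total, breakdown)."""
    weights = weights or AdaptiveWeights()
    terms = {
        "ce": expected_ce(pred, label),
        "edl": edl_loss(pred, label),
        "kl": kl_uniform(pred, label),
        "conf": confidence_loss(pred, confidence_S),
    }
    lam = weights.lambdas
    total = None
    for i, name in enumerate(TERM_NAMES):
        piece = float(lam[i]) * terms[name]
        total = piece if total is None else total + piece
    return total, {k: v.item() for k, v in terms.items()}
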