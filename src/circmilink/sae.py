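"""Sparse autoencoder (SAE) for attribute-feature compression.

A three-layer network (input, logistic hidden, logistic output) trained to
reconstruct its input under a sparsity penalty: the Kullback-Leibler
divergence between a small target activation rho and the mean hidden
activation rho_hat_j of each unit,

    KL(rho || rho_hat_j) = rho*log(rho/rho_hat_j)
                         + (1-rho)*log((1-rho)/(1-rho_hat_j)),

added to the reconstruction cost with weight kappa:

    F_C(W, b) = F(W, b) + kappa * sum_j KL(rho || rho_hat_j).

The encoder output (hidden activations in (0,1)) is the compressed
attribute feature; the default hidden width is 128.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, glorot, minibatches, sigmoid

__all__ = [
    "SAEModel",
    "kl_sparsity",
    "mean_activation",
    "train_sae",
    "encode",
    "minmax_scale_columns",
]

_CLIP = 1e-12


class SparsityDomainError(ValueError):
    """KL divergence diverges when a mean activation reaches 0 or 1."""


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    """Summed KL(rho || rho_hat_j) over hidden units; zero iff rho_hat == rho."""
    rho_hat = np.atleast_1d(np.asarray(rho_hat, dtype=np.float64))
    if not 0.0 < rho < 1.0:
        raise SparsityDomainError(f"rho must lie strictly in (0,1), got {rho}")
    if np.any(rho_hat <= 0.0) or np.any(rho_hat >= 1.0):
        raise SparsityDomainError(
            "mean activations must lie strictly in (0,1)"
        )
    return float(
        np.sum(
            rho * np.log(rho / rho_hat)
            + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat))
        )
    )


def mean_activation(encoded: np.ndarray) -> np.ndarray:
    """Per-unit mean activation rho_hat over samples (rows)."""
    encoded = np.asarray(encoded, dtype=np.float64)
    if encoded.ndim != 2 or encoded.shape[0] == 0:
        raise ValueError("encoded must be a non-empty 2-D sample matrix")
    return encoded.mean(axis=0)


def minmax_scale_columns(X: np.ndarray) -> np.ndarray:
    """Scale each column to [0, 1]; constant columns map to 0."""
    X = np.asarray(X, dtype=np.float64)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    return (X - lo) / span


@dataclass
class SAEModel:
    """Trained sparse autoencoder weights plus its training configuration."""

    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray
    hidden_dim: int
    rho: float
    kappa: float
    training_seed: int
    cost_trace: list = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.W_enc.shape[0]


def _cost(X, W1, b1, W2, b2, rho, kappa):
    H = sigmoid(X @ W1 + b1)
    Xhat = sigmoid(H @ W2 + b2)
    recon = 0.5 * np.mean(np.sum((Xhat - X) ** 2, axis=1))
    rho_hat = np.clip(H.mean(axis=0), _CLIP, 1 - _CLIP)
    return recon + kappa * kl_sparsity(rho, rho_hat)


def train_sae(
    X: np.ndarray,
    hidden_dim: int = 128,
    rho: float = 0.05,
    kappa: float = 0.1,
    epochs: int = 100,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
) -> SAEModel:
    """Fit the SAE on a sample matrix (rows = RNAs, columns in [0, 1]).

    Minimizes reconstruction cost plus ``kappa`` times the KL sparsity
    penalty by mini-batch Adam; deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    n, d = X.shape
    if hidden_dim < 1:
        raise ValueError("hidden_dim must be >= 1")
    if hidden_dim >= d:
        warnings.warn(
            f"hidden_dim={hidden_dim} >= input width {d}: no compression",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    W1 = glorot(rng, d, hidden_dim)
    b1 = np.zeros(hidden_dim)
    W2 = glorot(rng, hidden_dim, d)
    b2 = np.zeros(d)
    params = [W1, b1, W2, b2]
    opt = Adam(params, lr=learning_rate)
    trace = [_cost(X, W1, b1, W2, b2, rho, kappa)]
    for _ in range(epochs):
        for idx in minibatches(n, batch_size, rng):
            xb = X[idx]
            nb = len(idx)
            H = sigmoid(xb @ W1 + b1)
            Xhat = sigmoid(H @ W2 + b2)
            dZ2 = (Xhat - xb) * Xhat * (1 - Xhat) / nb
            rho_hat = np.clip(H.mean(axis=0), _CLIP, 1 - _CLIP)
            dH = dZ2 @ W2.T + kappa * (
                -rho / rho_hat + (1 - rho) / (1 - rho_hat)
            ) / nb
            dZ1 = dH * H * (1 - H)
            grads = [xb.T @ dZ1, dZ1.sum(axis=0), H.T @ dZ2, dZ2.sum(axis=0)]
            opt.step(grads)
        trace.append(_cost(X, W1, b1, W2, b2, rho, kappa))
    return SAEModel(W1, b1, W2, b2, hidden_dim, rho, kappa, seed, trace)


def encode(model: SAEModel, X: np.ndarray) -> np.ndarray:
    """Hidden-layer activations H = sigma(W x + b), entries in (0, 1)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"input width {X.shape[-1]} does not match model "
            f"input width {model.input_dim}"
        )
    return sigmoid(X @ model.W_enc + model.b_enc)
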