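"""Pair assembly, negative sampling, and the fusion DNN classifier.

Each candidate (circRNA, miRNA) pair is described by the concatenation
[circ attribute | circ behavior | miRNA attribute | miRNA behavior]; a
feed-forward network with ReLU hidden layers and a sigmoid output unit is
trained under mean binary cross-entropy,

    F_cost = -(1/L) * sum_j [ y_j log(yhat_j) + (1-y_j) log(1-yhat_j) ],

with early stopping on validation AUC. Negatives are sampled uniformly from
the non-edges of the adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._nn import Adam, glorot, minibatches, relu, sigmoid
from .corpus_io import AdjacencyMatrix

__all__ = [
    "LabeledPairSet",
    "FeatureLayout",
    "DNNModel",
    "sample_negatives",
    "assemble_pair_features",
    "binary_cross_entropy",
    "train_dnn",
    "predict_scores",
    "rank_candidate_pairs",
]

_EPS = 1e-12


class CapacityError(ValueError):
    """Not enough non-edges to draw the requested number of negatives."""


class DegenerateLabelsError(ValueError):
    pass


@dataclass
class LabeledPairSet:
    pairs: list[tuple[str, str]]
    labels: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


@dataclass(frozen=True)
class FeatureLayout:
    """Segment boundaries of the concatenated pair feature vector."""

    circ_attr: int
    circ_beh: int
    mi_attr: int
    mi_beh: int

    @property
    def width(self) -> int:
        return self.circ_attr + self.circ_beh + self.mi_attr + self.mi_beh


def sample_negatives(
    adj: AdjacencyMatrix, ratio: float = 1.0, seed: int = 0
) -> LabeledPairSet:
    """Positives = all edges; negatives = uniform non-edges without replacement."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    rows, cols = np.nonzero(adj.P)
    n_pos = len(rows)
    if n_pos == 0:
        raise ValueError("adjacency has no positive pairs")
    zrows, zcols = np.nonzero(adj.P == 0)
    n_neg = int(round(ratio * n_pos))
    if len(zrows) < n_neg:
        raise CapacityError(
            f"requested {n_neg} negatives but only {len(zrows)} non-edges exist"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(zrows), size=n_neg, replace=False)
    pairs = [
        (adj.circ_index[i], adj.mi_index[j]) for i, j in zip(rows, cols)
    ] + [
        (adj.circ_index[zrows[k]], adj.mi_index[zcols[k]]) for k in pick
    ]
    labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    return LabeledPairSet(pairs, labels, seed)


def assemble_pair_features(
    attr_c: pd.DataFrame,
    beh_c: pd.DataFrame,
    attr_m: pd.DataFrame,
    beh_m: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> tuple[np.ndarray, FeatureLayout]:
    """Row per pair: [circ attr | circ behavior | mi attr | mi behavior]."""
    layout = FeatureLayout(
        attr_c.shape[1], beh_c.shape[1], attr_m.shape[1], beh_m.shape[1]
    )
    for name, frame, idx in (
        ("circ attribute", attr_c, 0),
        ("circ behavior", beh_c, 0),
        ("miRNA attribute", attr_m, 1),
        ("miRNA behavior", beh_m, 1),
    ):
        missing = {p[idx] for p in pairs} - set(frame.index)
        if missing:
            raise KeyError(
                f"ids missing from the {name} matrix: {sorted(missing)[:5]}"
            )
    circ_ids = [c for c, _ in pairs]
    mi_ids = [m for _, m in pairs]
    X = np.hstack(
        [
            attr_c.loc[circ_ids].to_numpy(float),
            beh_c.loc[circ_ids].to_numpy(float),
            attr_m.loc[mi_ids].to_numpy(float),
            beh_m.loc[mi_ids].to_numpy(float),
        ]
    ) if pairs else np.empty((0, layout.width))
    return X, layout


def binary_cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    """Mean BCE with probabilities clipped away from {0, 1}."""
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class DNNModel:
    weights: list
    biases: list
    training_seed: int
    best_epoch: int | None = None
    loss_trace: list = field(default_factory=list)

    @property
    def layer_widths(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]


def _forward(model: DNNModel, X: np.ndarray) -> np.ndarray:
    a = np.asarray(X, dtype=np.float64)
    for W, b in zip(model.weights[:-1], model.biases[:-1]):
        a = relu(a @ W + b)
    z = a @ model.weights[-1] + model.biases[-1]
    return sigmoid(z).ravel()


def predict_scores(model: DNNModel, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; scores strictly inside (0, 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model input "
            f"width {model.weights[0].shape[0]}"
        )
    return np.clip(_forward(model, X), _EPS, 1 - _EPS)


def train_dnn(
    features: np.ndarray,
    labels: np.ndarray,
    hidden_layers: tuple[int, ...] = (256, 128, 64),
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    max_epochs: int = 100,
    patience: int = 10,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
) -> DNNModel:
    """Train the fusion classifier; deterministic given ``seed``.

    When a ``(features, labels)`` validation split is supplied, training
    stops ``patience`` epochs after validation AUC last improved and the
    best-epoch weights are restored.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be 2-D and aligned with labels")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise DegenerateLabelsError(
            "training requires at least 2 samples of each class"
        )
    rng = np.random.default_rng(seed)
    widths = [X.shape[1], *hidden_layers, 1]
    Ws = [glorot(rng, a, b) for a, b in zip(widths[:-1], widths[1:])]
    bs = [np.zeros(b) for b in widths[1:]]
    opt = Adam(Ws + bs, lr=learning_rate)
    model = DNNModel(Ws, bs, seed)
    best_auc, best_epoch, best_state, stall = -np.inf, None, None, 0
    for epoch in range(max_epochs):
        for idx in minibatches(len(X), batch_size, rng):
            xb, yb = X[idx], y[idx]
            acts = [xb]
            zs = []
            a = xb
            for W, b in zip(Ws[:-1], bs[:-1]):
                z = a @ W + b
                zs.append(z)
                a = relu(z)
                acts.append(a)
            z_out = a @ Ws[-1] + bs[-1]
            p = sigmoid(z_out).ravel()
            delta = ((p - yb) / len(yb)).reshape(-1, 1)
            gWs, gbs = [None] * len(Ws), [None] * len(bs)
            gWs[-1] = acts[-1].T @ delta
            gbs[-1] = delta.sum(axis=0)
            for layer in range(len(Ws) - 2, -1, -1):
                delta = (delta @ Ws[layer + 1].T) * (zs[layer] > 0)
                gWs[layer] = acts[layer].T @ delta
                gbs[layer] = delta.sum(axis=0)
            opt.step(gWs + gbs)
        model.loss_trace.append(binary_cross_entropy(y, _forward(model, X)))
        if validation is not None:
            val_auc = roc_auc_score(
                validation[1], _forward(model, validation[0])
            )
            if val_auc > best_auc + 1e-12:
                best_auc, best_epoch, stall = val_auc, epoch, 0
                best_state = (
                    [W.copy() for W in Ws],
                    [b.copy() for b in bs],
                )
            else:
                stall += 1
                if stall >= patience:
                    break
    if best_state is not None:
        model.weights, model.biases = best_state
        model.best_epoch = best_epoch
    return model


def rank_candidate_pairs(
    model: DNNModel,
    candidates: list[tuple[str, str]],
    features: np.ndarray,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Score candidates and return the top_k, descending by score.

    Ties are broken lexicographically by (circRNA id, miRNA id).
    """
    if len(candidates) == 0:
        return pd.DataFrame(columns=["circRNA_id", "miRNA_id", "score"])
    scores = predict_scores(model, features)
    df = pd.DataFrame(
        {
            "circRNA_id": [c for c, _ in candidates],
            "miRNA_id": [m for _, m in candidates],
            "score": scores,
        }
    )
    df = df.sort_values(
        ["score", "circRNA_id", "miRNA_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    df.index = np.arange(1, len(df) + 1)
    df.index.name = "rank"
    return df
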