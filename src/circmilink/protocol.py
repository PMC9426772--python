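"""Repeated-split evaluation protocol.

Each repeat draws a fresh negative sample, makes a stratified 70/20/10
train/validation/test split of the labeled pairs, recomputes the GIP kernel
and the HOPE embedding from the training-fold edges only (validation and
test positives are removed from the similarity graph unless
``paper_faithful`` is set), trains the fusion DNN with early stopping on
validation AUC, and evaluates threshold metrics plus AUC/AUPR on the test
fold. Results are reported per repeat with mean and standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import classifier as _clf
from . import metrics as _metrics
from .corpus_io import AdjacencyMatrix
from .model import InteractionModel, compute_features, stage_seeds

__all__ = ["make_split", "run_protocol", "run_experiment_grid"]

_SKLEARN_ADAPTERS = ("rf", "lr", "svm", "gbdt")


def make_split(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
    stratified: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint train/validation/test index arrays honoring the fractions."""
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    idx = np.arange(len(labels))
    n = len(labels)
    n_val = round(n * fractions[1])
    n_test = round(n * fractions[2])
    strat = labels if stratified else None
    train, rest = train_test_split(
        idx,
        test_size=n_val + n_test,
        random_state=seed,
        stratify=strat,
    )
    rest_labels = labels[rest] if stratified else None
    val, test = train_test_split(
        rest,
        test_size=n_test,
        random_state=seed,
        stratify=rest_labels,
    )
    return train, val, test


def _training_adjacency(
    adj: AdjacencyMatrix,
    labeled: _clf.LabeledPairSet,
    train_idx: np.ndarray,
) -> AdjacencyMatrix:
    """Adjacency with every held-out positive edge zeroed."""
    P = adj.P.copy()
    circ_pos = {c: i for i, c in enumerate(adj.circ_index)}
    mi_pos = {m: j for j, m in enumerate(adj.mi_index)}
    train = set(train_idx.tolist())
    for k, (c, m) in enumerate(labeled.pairs):
        if labeled.labels[k] == 1 and k not in train:
            P[circ_pos[c], mi_pos[m]] = 0
    return AdjacencyMatrix(P, adj.circ_index, adj.mi_index)


def _fit_sklearn_adapter(name: str, X, y, seed: int):
    """Thin adapters for the classifier-comparison grid."""
    from sklearn.ensemble import (
        GradientBoostingClassifier,
        RandomForestClassifier,
    )
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import SVC

    est = {
        "rf": RandomForestClassifier(n_estimators=200, random_state=seed),
        "lr": LogisticRegression(max_iter=1000, random_state=seed),
        "svm": SVC(probability=True, random_state=seed),
        "gbdt": GradientBoostingClassifier(random_state=seed),
    }[name]
    return est.fit(X, y)


def run_protocol(
    model: InteractionModel,
    repeats: int = 5,
    base_seed: int = 0,
    shuffle_labels: bool = False,
    classifier: str = "dnn",
) -> _metrics.MetricsReport:
    """The repeated 70/20/10 evaluation; returns per-repeat metrics.

    ``shuffle_labels`` permutes the labels of the labeled pair set before
    splitting — a negative control that must score near AUC 0.5.
    ``classifier`` selects the fusion DNN (default) or one of the sklearn
    adapters ('rf', 'lr', 'svm', 'gbdt') on identical features.
    """
    if classifier != "dnn" and classifier not in _SKLEARN_ADAPTERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    cfg = model.config
    rows = []
    for rep in range(repeats):
        seeds = stage_seeds(base_seed, rep)
        labeled = _clf.sample_negatives(
            model.adjacency, cfg.negative_ratio, seeds["negatives"]
        )
        labels = labeled.labels.copy()
        if shuffle_labels:
            labels = np.random.default_rng(seeds["split"]).permutation(labels)
        tr, va, te = make_split(
            labels,
            cfg.protocol.fractions,
            seeds["split"],
            cfg.protocol.stratified,
        )
        if cfg.paper_faithful:
            sim_adj = model.adjacency
        else:
            sim_adj = _training_adjacency(
                model.adjacency,
                _clf.LabeledPairSet(labeled.pairs, labels),
                tr,
            )
        feats = compute_features(
            model.circ_records,
            model.mi_records,
            sim_adj,
            cfg,
            seeds["sae_circ"],
            seeds["sae_mi"],
        )
        X, _ = _clf.assemble_pair_features(
            feats["attr_circ"],
            feats["beh_circ"],
            feats["attr_mi"],
            feats["beh_mi"],
            labeled.pairs,
        )
        if classifier == "dnn":
            dnn = _clf.train_dnn(
                X[tr],
                labels[tr],
                hidden_layers=cfg.dnn.hidden_layers,
                learning_rate=cfg.dnn.learning_rate,
                batch_size=cfg.dnn.batch_size,
                max_epochs=cfg.dnn.max_epochs,
                patience=cfg.dnn.patience,
                validation=(X[va], labels[va]),
                seed=seeds["dnn"],
            )
            test_scores = _clf.predict_scores(dnn, X[te])
        else:
            est = _fit_sklearn_adapter(
                classifier, X[np.concatenate([tr, va])],
                labels[np.concatenate([tr, va])], seeds["dnn"],
            )
            test_scores = est.predict_proba(X[te])[:, 1]
        counts = _metrics.confusion_counts(labels[te], test_scores)
        row = _metrics.compute_metrics(counts)
        row["AUC"] = _metrics.roc_auc(labels[te], test_scores)
        row["AUPR"] = _metrics.pr_auc(labels[te], test_scores)
        row["repeat"] = rep
        row["n_test"] = len(te)
        rows.append(row)
    per_repeat = pd.DataFrame(rows)
    return _metrics.MetricsReport(
        per_repeat,
        extra={
            "repeats": repeats,
            "base_seed": base_seed,
            "classifier": classifier,
            "shuffle_labels": shuffle_labels,
        },
    )


def run_experiment_grid(
    model: InteractionModel,
    axis: str,
    values=None,
    repeats: int = 5,
    base_seed: int = 0,
) -> pd.DataFrame:
    """One evaluation row per grid value along a single axis.

    Axes: 'K' iterates (k_circ, k_mi) pairs or single K applied to both;
    'sae_dim' iterates SAE hidden widths; 'classifier' iterates the fusion
    DNN and the sklearn adapters on identical features.
    """
    import dataclasses as _dc

    defaults = {
        "K": [(2, 2), (3, 3), (4, 4), (5, 5)],
        "sae_dim": [64, 128, 256, 512],
        "classifier": ["dnn", "rf", "lr", "svm", "gbdt"],
    }
    if axis not in defaults:
        raise ValueError(f"unknown grid axis {axis!r}")
    values = list(values) if values is not None else defaults[axis]
    if not values:
        raise ValueError("empty grid")
    rows = []
    for v in values:
        cfg = model.config
        classifier = "dnn"
        if axis == "K":
            kc, km = v if isinstance(v, (tuple, list)) else (v, v)
            cfg = _dc.replace(cfg, k_circ=kc, k_mi=km)
        elif axis == "sae_dim":
            cfg = _dc.replace(cfg, sae=_dc.replace(cfg.sae, hidden_dim=int(v)))
        else:
            classifier = str(v)
        sub = InteractionModel(
            model.circ_records, model.mi_records, model.interactions, cfg
        )
        report = run_protocol(
            sub, repeats=repeats, base_seed=base_seed, classifier=classifier
        )
        row = report.mean.to_dict()
        row[axis] = str(v)
        rows.append(row)
    return pd.DataFrame(rows).set_index(axis)
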