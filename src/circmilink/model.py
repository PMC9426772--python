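"""Model/Results surface tying the pipeline stages together.

:class:`InteractionModel` is built from a sequence corpus and an interaction
table; :meth:`InteractionModel.fit` runs featurization (k-mer + GIP ->
sparse autoencoder; HOPE graph embedding), trains the fusion DNN on the
known positives plus sampled negatives, and returns an
:class:`InteractionResults` carrying scores, training diagnostics, a
summary table and candidate ranking. :meth:`InteractionModel.evaluate` runs
the repeated 70/20/10 split protocol.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifier as _clf
from . import gip as _gip
from . import hope as _hope
from . import kmer as _kmer
from . import metrics as _metrics
from . import sae as _sae
from .corpus_io import (
    AdjacencyMatrix,
    InteractionTable,
    SequenceRecord,
    build_adjacency,
    read_fasta,
    read_pairs,
)

__all__ = ["PipelineConfig", "InteractionModel", "InteractionResults"]


@dataclass
class SAEConfig:
    hidden_dim: int = 128
    rho: float = 0.05
    kappa: float = 0.1
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 64


@dataclass
class HopeConfig:
    beta: int = 64
    decay_fraction: float = 0.5


@dataclass
class DNNConfig:
    hidden_layers: tuple[int, ...] = (256, 128, 64)
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10


@dataclass
class ProtocolConfig:
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    repeats: int = 5
    stratified: bool = True

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, serializable losslessly."""

    k_circ: int = 5
    k_mi: int = 2
    kmer_mode: str = "frequency"
    gip_prior: float = 1.0
    sae: SAEConfig = field(default_factory=SAEConfig)
    hope: HopeConfig = field(default_factory=HopeConfig)
    dnn: DNNConfig = field(default_factory=DNNConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    negative_ratio: float = 1.0
    paper_faithful: bool = False
    reducer: str = "sae"

    def __post_init__(self):
        if self.reducer not in ("sae", "pca"):
            raise ValueError("reducer must be 'sae' or 'pca'")
        for dim in (self.k_circ, self.k_mi, self.sae.hidden_dim,
                    self.hope.beta):
            if dim < 1:
                raise ValueError("all dimensions must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("sae", SAEConfig),
            ("hope", HopeConfig),
            ("dnn", DNNConfig),
            ("protocol", ProtocolConfig),
        ):
            if key in d and isinstance(d[key], dict):
                payload = dict(d[key])
                for k, v in payload.items():
                    if isinstance(v, list):
                        payload[k] = tuple(v)
                d[key] = sub(**payload)
        return cls(**d)


def stage_seeds(base_seed: int, repeat: int) -> dict[str, int]:
    """Expand a base seed into independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence([int(base_seed), int(repeat)])
    state = ss.generate_state(5) % (2 ** 31)
    names = ("negatives", "split", "sae_circ", "sae_mi", "dnn")
    return {name: int(v) for name, v in zip(names, state)}


def compute_features(
    circ_records: list[SequenceRecord],
    mi_records: list[SequenceRecord],
    similarity_adj: AdjacencyMatrix,
    config: PipelineConfig,
    sae_seed_circ: int = 0,
    sae_seed_mi: int = 1,
) -> dict[str, pd.DataFrame]:
    """Attribute and behavior matrices for every RNA.

    Attribute input per RNA = [k-mer spectrum | GIP kernel row], min-max
    scaled and compressed by one SAE per molecule class (or PCA when the
    config selects it). Behavior = HOPE embedding rows of the interaction
    graph given by ``similarity_adj``.
    """
    circ_records = sorted(circ_records, key=lambda r: r.id)
    mi_records = sorted(mi_records, key=lambda r: r.id)
    order_c = {rid: i for i, rid in enumerate(similarity_adj.circ_index)}
    order_m = {rid: i for i, rid in enumerate(similarity_adj.mi_index)}
    missing = ({r.id for r in circ_records} ^ set(order_c)) | (
        {r.id for r in mi_records} ^ set(order_m)
    )
    if missing:
        raise KeyError(
            "sequence corpus and adjacency universe disagree on ids: "
            f"{sorted(missing)[:5]}"
        )

    def _attr(records, K, profiles, index, seed):
        spectra = _kmer.featurize_corpus(records, K, config.kmer_mode)
        kern = _gip.gip_kernel(profiles, config.gip_prior).matrix
        kern = pd.DataFrame(kern, index=index, columns=index)
        raw = np.hstack(
            [spectra.to_numpy(float), kern.loc[spectra.index].to_numpy()]
        )
        X = _sae.minmax_scale_columns(raw)
        dim = config.sae.hidden_dim
        if config.reducer == "pca":
            from sklearn.decomposition import PCA

            n_comp = min(dim, X.shape[0], X.shape[1])
            Z = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
            if n_comp < dim:
                Z = np.hstack([Z, np.zeros((len(Z), dim - n_comp))])
        else:
            import warnings

            with warnings.catch_warnings():
                # a short miRNA attribute block can be narrower than the
                # fixed 128-unit hidden layer; that is expected here
                warnings.filterwarnings(
                    "ignore", message="hidden_dim.*no compression"
                )
                model = _sae.train_sae(
                    X,
                    hidden_dim=dim,
                    rho=config.sae.rho,
                    kappa=config.sae.kappa,
                    epochs=config.sae.epochs,
                    learning_rate=config.sae.learning_rate,
                    batch_size=config.sae.batch_size,
                    seed=seed,
                )
            Z = _sae.encode(model, X)
        return pd.DataFrame(Z, index=spectra.index)

    attr_c = _attr(
        circ_records,
        config.k_circ,
        similarity_adj.circ_profiles(),
        similarity_adj.circ_index,
        sae_seed_circ,
    )
    attr_m = _attr(
        mi_records,
        config.k_mi,
        similarity_adj.mi_profiles(),
        similarity_adj.mi_index,
        sae_seed_mi,
    )
    behavior = _hope.embed_interaction_graph(
        similarity_adj, config.hope.beta, config.hope.decay_fraction
    )
    beh_c = behavior.loc[similarity_adj.circ_index]
    beh_m = behavior.loc[similarity_adj.mi_index]
    return {
        "attr_circ": attr_c,
        "beh_circ": beh_c,
        "attr_mi": attr_m,
        "beh_mi": beh_m,
    }


class InteractionModel:
    """circRNA-miRNA interaction predictor built from a corpus and pair table.

    Parameters
    ----------
    circ_records, mi_records : list of SequenceRecord
        The sequence corpora for the two molecule classes.
    interactions : InteractionTable
        Known positive pairs; every pair id must have a sequence.
    config : PipelineConfig, optional
        Pipeline hyperparameters (defaults follow the package defaults:
        K=5/2, SAE dim 128, HOPE beta 64, 1:1 negatives).
    """

    def __init__(
        self,
        circ_records: list[SequenceRecord],
        mi_records: list[SequenceRecord],
        interactions: InteractionTable,
        config: PipelineConfig | None = None,
    ):
        self.config = config or PipelineConfig()
        self.circ_records = sorted(circ_records, key=lambda r: r.id)
        self.mi_records = sorted(mi_records, key=lambda r: r.id)
        self.interactions = interactions
        circ_ids = [r.id for r in self.circ_records]
        mi_ids = [r.id for r in self.mi_records]
        self.adjacency = build_adjacency(interactions, circ_ids, mi_ids)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_files(cls, fasta_circ, fasta_mi, pairs, config=None):
        return cls(
            read_fasta(fasta_circ, "circRNA"),
            read_fasta(fasta_mi, "miRNA"),
            read_pairs(pairs),
            config,
        )

    @classmethod
    def from_study(cls, study, config=None):
        return cls(study.circ_records, study.mi_records, study.table, config)

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int = 0) -> "InteractionResults":
        """Train on all known positives plus sampled negatives.

        This is the candidate-ranking ("case study") mode: the similarity
        graph and the classifier see every known positive. A stratified 20%
        of the labeled pairs is held out for early stopping only.
        """
        from sklearn.model_selection import train_test_split

        seeds = stage_seeds(seed, 0)
        feats = compute_features(
            self.circ_records,
            self.mi_records,
            self.adjacency,
            self.config,
            seeds["sae_circ"],
            seeds["sae_mi"],
        )
        labeled = _clf.sample_negatives(
            self.adjacency, self.config.negative_ratio, seeds["negatives"]
        )
        X, layout = _clf.assemble_pair_features(
            feats["attr_circ"],
            feats["beh_circ"],
            feats["attr_mi"],
            feats["beh_mi"],
            labeled.pairs,
        )
        idx_tr, idx_val = train_test_split(
            np.arange(len(X)),
            test_size=0.2,
            random_state=seeds["split"],
            stratify=labeled.labels,
        )
        dnn = _clf.train_dnn(
            X[idx_tr],
            labeled.labels[idx_tr],
            hidden_layers=self.config.dnn.hidden_layers,
            learning_rate=self.config.dnn.learning_rate,
            batch_size=self.config.dnn.batch_size,
            max_epochs=self.config.dnn.max_epochs,
            patience=self.config.dnn.patience,
            validation=(X[idx_val], labeled.labels[idx_val]),
            seed=seeds["dnn"],
        )
        scores = _clf.predict_scores(dnn, X)
        return InteractionResults(
            self, dnn, feats, layout, labeled, scores, seed
        )

    def evaluate(
        self, repeats: int | None = None, base_seed: int = 0
    ) -> _metrics.MetricsReport:
        """Repeated stratified 70/20/10 split evaluation (mean +/- std)."""
        from .protocol import run_protocol

        return run_protocol(
            self,
            repeats=repeats or self.config.protocol.repeats,
            base_seed=base_seed,
        )


class InteractionResults:
    """Fitted pipeline: scores, diagnostics, ranking, and a summary table."""

    def __init__(self, model, dnn, features, layout, labeled, scores, seed):
        self.model = model
        self.dnn = dnn
        self.features = features
        self.layout = layout
        self.labeled = labeled
        self.scores = scores
        self.seed = seed

    @property
    def config(self) -> PipelineConfig:
        return self.model.config

    def training_metrics(self) -> dict:
        counts = _metrics.confusion_counts(self.labeled.labels, self.scores)
        out = _metrics.compute_metrics(counts)
        out["AUC"] = _metrics.roc_auc(self.labeled.labels, self.scores)
        out["AUPR"] = _metrics.pr_auc(self.labeled.labels, self.scores)
        return out

    def predict_pairs(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        X, _ = _clf.assemble_pair_features(
            self.features["attr_circ"],
            self.features["beh_circ"],
            self.features["attr_mi"],
            self.features["beh_mi"],
            pairs,
        )
        return _clf.predict_scores(self.dnn, X)

    def rank_candidates(self, top_k: int = 10) -> pd.DataFrame:
        """Score every non-positive (circ, mi) pair; top_k descending."""
        known = set(self.model.adjacency.pair_set())
        candidates = [
            (c, m)
            for c in self.model.adjacency.circ_index
            for m in self.model.adjacency.mi_index
            if (c, m) not in known
        ]
        X, _ = _clf.assemble_pair_features(
            self.features["attr_circ"],
            self.features["beh_circ"],
            self.features["attr_mi"],
            self.features["beh_mi"],
            candidates,
        )
        return _clf.rank_candidate_pairs(self.dnn, candidates, X, top_k)

    def summary(self) -> str:
        adj = self.model.adjacency
        tm = self.training_metrics()
        lines = [
            "circRNA-miRNA interaction model",
            "=" * 48,
            f"circRNAs: {adj.n_circ}    miRNAs: {adj.n_mi}    "
            f"positives: {int(adj.P.sum())}",
            f"K (circ/mi): {self.config.k_circ}/{self.config.k_mi}    "
            f"reducer: {self.config.reducer} -> {self.config.sae.hidden_dim}"
            f"    HOPE beta: {self.config.hope.beta}",
            f"pair feature width: {self.layout.width}    "
            f"DNN layers: {self.config.dnn.hidden_layers}    "
            f"best epoch: {self.dnn.best_epoch}",
            "-" * 48,
            "training-set metrics (labeled pairs, threshold 0.5):",
        ]
        lines.append(
            "  "
            + "  ".join(
                f"{k}={tm[k]:.4f}"
                for k in ("Acc", "Sen", "Spec", "Prec", "MCC", "AUC", "AUPR")
            )
        )
        return "\n".join(lines)
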