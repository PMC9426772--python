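"""Synthetic study generator: planted-block bipartite graphs plus sequences.

Emulates the structure of a curated circRNA-miRNA interaction resource at
desk scale. CircRNAs and miRNAs are assigned round-robin to blocks; an edge
is drawn independently with probability ``p_in`` within a block and
``p_out`` across blocks, so interaction profiles carry block signal. Each
block owns a distinct hexamer motif embedded into its members' otherwise
uniform sequences at a rate proportional to ``motif_strength``, so k-mer
spectra carry the same block signal. Sequence lengths mirror the real
asymmetry: miRNAs ~18-25 nt, circRNAs hundreds to thousands of nt.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import (
    AdjacencyMatrix,
    InteractionTable,
    SequenceRecord,
    write_fasta,
    write_pairs,
)

__all__ = [
    "StudyConfig",
    "SyntheticStudy",
    "generate_planted_bipartite",
    "generate_sequences",
    "generate_study",
    "write_study",
]

_MOTIF_LEN = 6
_BASES = np.array(list("ACGU"))


@dataclass
class StudyConfig:
    n_circ: int = 200
    n_mi: int = 100
    n_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    circ_length: tuple[int, int] = (300, 1200)
    mi_length: tuple[int, int] = (18, 25)
    motif_strength: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValueError("require 0 <= p_out <= p_in <= 1")
        if self.n_blocks > min(self.n_circ, self.n_mi):
            raise ValueError("n_blocks must not exceed min(n_circ, n_mi)")
        if not 0 <= self.motif_strength <= 1:
            raise ValueError("motif_strength must lie in [0, 1]")
        for lo, hi in (self.circ_length, self.mi_length):
            if not 0 < lo <= hi:
                raise ValueError("length ranges must be positive and ordered")
        if min(self.circ_length[0], self.mi_length[0]) < _MOTIF_LEN:
            raise ValueError(
                f"minimum sequence length must be >= motif length {_MOTIF_LEN}"
            )


@dataclass
class SyntheticStudy:
    adjacency: AdjacencyMatrix
    block_labels: dict[str, int]
    sequences: list[SequenceRecord]
    table: InteractionTable
    config: StudyConfig = field(default_factory=StudyConfig)

    @property
    def circ_records(self) -> list[SequenceRecord]:
        return [r for r in self.sequences if r.molecule_class == "circRNA"]

    @property
    def mi_records(self) -> list[SequenceRecord]:
        return [r for r in self.sequences if r.molecule_class == "miRNA"]


def generate_planted_bipartite(
    n_circ: int,
    n_mi: int,
    n_blocks: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[AdjacencyMatrix, dict[str, int]]:
    """Planted-block bipartite adjacency with round-robin block assignment."""
    if not 0 <= p_out <= p_in <= 1:
        raise ValueError("require 0 <= p_out <= p_in <= 1")
    if n_blocks > min(n_circ, n_mi):
        raise ValueError("n_blocks must not exceed min(n_circ, n_mi)")
    rng = np.random.default_rng(seed)
    circ_ids = [f"circ_{i:04d}" for i in range(n_circ)]
    mi_ids = [f"mir_{j:04d}" for j in range(n_mi)]
    circ_block = np.arange(n_circ) % n_blocks
    mi_block = np.arange(n_mi) % n_blocks
    same = circ_block[:, None] == mi_block[None, :]
    prob = np.where(same, p_in, p_out)
    P = (rng.random((n_circ, n_mi)) < prob).astype(np.int8)
    labels = {cid: int(b) for cid, b in zip(circ_ids, circ_block)}
    labels.update({mid: int(b) for mid, b in zip(mi_ids, mi_block)})
    return AdjacencyMatrix(P, circ_ids, mi_ids), labels


def _block_motifs(n_blocks: int, seed: int) -> list[str]:
    """Distinct hexamer motif per block, reproducible from the seed."""
    rng = np.random.default_rng([seed, 0xB10C])
    motifs: list[str] = []
    while len(motifs) < n_blocks:
        m = "".join(rng.choice(_BASES, size=_MOTIF_LEN))
        if m not in motifs:
            motifs.append(m)
    return motifs


def _one_sequence(
    rng: np.random.Generator, length: int, motif: str, motif_strength: float
) -> str:
    seq = rng.choice(_BASES, size=length)
    # one embedding slot per ~30 nt, each occupied with prob motif_strength
    n_slots = max(1, length // 30)
    n_copies = rng.binomial(n_slots, motif_strength)
    for _ in range(n_copies):
        start = rng.integers(0, length - _MOTIF_LEN + 1)
        seq[start : start + _MOTIF_LEN] = list(motif)
    return "".join(seq)


def generate_sequences(
    block_labels: dict[str, int],
    molecule_classes: dict[str, str],
    circ_length: tuple[int, int] = (300, 1200),
    mi_length: tuple[int, int] = (18, 25),
    motif_strength: float = 0.8,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Uniform-random RNA sequences with block motifs embedded.

    ``molecule_classes`` maps each node id to 'circRNA' or 'miRNA'; the
    length range is chosen per class.
    """
    if not 0 <= motif_strength <= 1:
        raise ValueError("motif_strength must lie in [0, 1]")
    n_blocks = max(block_labels.values()) + 1
    motifs = _block_motifs(n_blocks, seed)
    rng = np.random.default_rng([seed, 0x5E0])
    records = []
    for node_id in block_labels:
        cls = molecule_classes[node_id]
        lo, hi = circ_length if cls == "circRNA" else mi_length
        if lo < _MOTIF_LEN:
            raise ValueError(
                f"minimum length {lo} shorter than motif ({_MOTIF_LEN} nt)"
            )
        length = int(rng.integers(lo, hi + 1))
        motif = motifs[block_labels[node_id]]
        records.append(
            SequenceRecord(
                node_id, cls, _one_sequence(rng, length, motif, motif_strength)
            )
        )
    return records


def generate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Planted graph + block-correlated sequences + interaction table."""
    cfg = config or StudyConfig()
    adj, labels = generate_planted_bipartite(
        cfg.n_circ, cfg.n_mi, cfg.n_blocks, cfg.p_in, cfg.p_out, cfg.seed
    )
    classes = {cid: "circRNA" for cid in adj.circ_index}
    classes.update({mid: "miRNA" for mid in adj.mi_index})
    sequences = generate_sequences(
        labels,
        classes,
        cfg.circ_length,
        cfg.mi_length,
        cfg.motif_strength,
        cfg.seed,
    )
    table = InteractionTable.from_pairs(
        sorted(adj.pair_set()), source="synthetic"
    )
    return SyntheticStudy(adj, labels, sequences, table, cfg)


def write_study(study: SyntheticStudy, outdir) -> dict[str, Path]:
    """Write FASTA (per class), pair TSV, and a JSON truth/config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta_circ": outdir / "circRNA.fasta",
        "fasta_mi": outdir / "miRNA.fasta",
        "pairs": outdir / "interactions.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(study.circ_records, paths["fasta_circ"])
    write_fasta(study.mi_records, paths["fasta_mi"])
    write_pairs(study.table, paths["pairs"])
    sidecar = {
        "config": dataclasses.asdict(study.config),
        "block_labels": study.block_labels,
    }
    paths["truth"].write_text(json.dumps(sidecar, indent=2))
    return paths
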