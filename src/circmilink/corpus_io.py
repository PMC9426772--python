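"""Sequence and interaction-table ingestion.

Reads FASTA sequence corpora and delimited interaction pair lists, normalizes
identifiers, merges pair tables from multiple sources, and builds the binary
circRNA x miRNA adjacency matrix whose rows and columns are the interaction
profiles consumed by the Gaussian-kernel and graph-embedding stages.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "InteractionTable",
    "AdjacencyMatrix",
    "read_fasta",
    "write_fasta",
    "read_pairs",
    "merge_interaction_sources",
    "build_adjacency",
    "normalize_id",
]

_VALID_CLASSES = ("circRNA", "miRNA")


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the '>'-header convention."""


class DuplicateIdError(ValueError):
    """Raised when a corpus contains two records with the same identifier."""


class UnknownIdError(KeyError):
    """Raised when interaction pairs reference ids absent from the universe."""


def normalize_id(raw: str) -> str:
    """Canonical identifier form: surrounding whitespace removed, case-folded."""
    return raw.strip().casefold()


@dataclass(frozen=True)
class SequenceRecord:
    """One RNA sequence with its identifier and molecule class."""

    id: str
    molecule_class: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if self.molecule_class not in _VALID_CLASSES:
            raise ValueError(
                f"molecule_class must be one of {_VALID_CLASSES}, "
                f"got {self.molecule_class!r}"
            )
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")


def read_fasta(path, molecule_class: str = "circRNA") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Multi-line sequences are concatenated and upper-cased; ``U`` is left
    intact (the k-mer stage maps alphabets). Duplicate ids and header-less
    leading content raise errors.
    """
    path = Path(path)
    text = path.read_text()
    # locate the first non-blank line for a precise error message
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno} is not a '>' header; "
                    "FASTA records must start with '>'"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, molecule_class, str(rec.seq).upper())
        )
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 70) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


@dataclass
class InteractionTable:
    """A set of (circRNA id, miRNA id) pairs with per-pair source tags."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("interaction table contains duplicate pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def circ_ids(self) -> list[str]:
        return sorted({c for c, _ in self.pairs})

    @property
    def mi_ids(self) -> list[str]:
        return sorted({m for _, m in self.pairs})

    @classmethod
    def from_pairs(cls, pairs, source: str = "unknown") -> "InteractionTable":
        norm = []
        seen = set()
        prov: dict[tuple[str, str], set[str]] = {}
        for c, m in pairs:
            key = (normalize_id(c), normalize_id(m))
            if key not in seen:
                seen.add(key)
                norm.append(key)
            prov.setdefault(key, set()).add(source)
        return cls(norm, prov)


_CIRC_COL_HINTS = ("circ", "circrna", "circrna_id")
_MI_COL_HINTS = ("mi", "mirna", "mirna_id")


def read_pairs(path, source: str | None = None) -> InteractionTable:
    """Read a tab-separated pair list (circRNA_id, miRNA_id[, source]).

    A header row is auto-detected by column-name match on 'circ'/'mi'.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    first = [str(v).casefold() for v in df.iloc[0]]
    has_header = any(h in first[0] for h in _CIRC_COL_HINTS) and any(
        first[1].startswith(h) for h in _MI_COL_HINTS
    )
    if has_header:
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two tab-separated columns")
    default_source = source if source is not None else path.name
    pairs = []
    seen = set()
    prov: dict[tuple[str, str], set[str]] = {}
    for row in df.itertuples(index=False):
        key = (normalize_id(row[0]), normalize_id(row[1]))
        tag = row[2] if df.shape[1] > 2 and pd.notna(row[2]) else default_source
        if key not in seen:
            seen.add(key)
            pairs.append(key)
        prov.setdefault(key, set()).add(str(tag))
    return InteractionTable(pairs, prov)


def write_pairs(table: InteractionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("circRNA_id\tmiRNA_id\tsource\n")
        for c, m in table.pairs:
            src = ";".join(sorted(table.provenance.get((c, m), set())))
            fh.write(f"{c}\t{m}\t{src}\n")


def merge_interaction_sources(
    tables: list[InteractionTable],
) -> InteractionTable:
    """Union of pair tables with duplicates removed after id normalization.

    Provenance tags are retained as the union of source tags per pair.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    prov: dict[tuple[str, str], set[str]] = {}
    for t in tables:
        for pair in t.pairs:
            key = (normalize_id(pair[0]), normalize_id(pair[1]))
            if key not in seen:
                seen.add(key)
                pairs.append(key)
            prov.setdefault(key, set()).update(
                t.provenance.get(pair, set())
            )
    return InteractionTable(pairs, prov)


@dataclass
class AdjacencyMatrix:
    """Binary interaction matrix P (circRNAs on rows, miRNAs on columns).

    Row i is the interaction profile of circRNA ``circ_index[i]``; column j
    is the profile of miRNA ``mi_index[j]``.
    """

    P: np.ndarray
    circ_index: list[str]
    mi_index: list[str]

    def __post_init__(self):
        self.P = np.asarray(self.P)
        if self.P.ndim != 2:
            raise ValueError("P must be a 2-D matrix")
        if self.P.shape != (len(self.circ_index), len(self.mi_index)):
            raise ValueError("P shape does not match id lists")
        if not np.isin(self.P, (0, 1)).all():
            raise ValueError("P entries must be 0 or 1")

    @property
    def n_circ(self) -> int:
        return len(self.circ_index)

    @property
    def n_mi(self) -> int:
        return len(self.mi_index)

    def circ_profiles(self) -> np.ndarray:
        return self.P

    def mi_profiles(self) -> np.ndarray:
        return self.P.T

    def pair_set(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.P)
        return {
            (self.circ_index[i], self.mi_index[j])
            for i, j in zip(rows, cols)
        }


def build_adjacency(
    table: InteractionTable,
    circ_ids: list[str] | None = None,
    mi_ids: list[str] | None = None,
) -> AdjacencyMatrix:
    """Build P with P[i, j] = 1 iff (circ_ids[i], mi_ids[j]) is a known pair."""
    if circ_ids is None:
        circ_ids = table.circ_ids
    if mi_ids is None:
        mi_ids = table.mi_ids
    circ_pos = {c: i for i, c in enumerate(circ_ids)}
    mi_pos = {m: j for j, m in enumerate(mi_ids)}
    unknown = [
        (c, m)
        for c, m in table.pairs
        if c not in circ_pos or m not in mi_pos
    ]
    if unknown:
        raise UnknownIdError(
            f"pairs reference ids missing from the universe: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )
    P = np.zeros((len(circ_ids), len(mi_ids)), dtype=np.int8)
    for c, m in table.pairs:
        P[circ_pos[c], mi_pos[m]] = 1
    return AdjacencyMatrix(P, list(circ_ids), list(mi_ids))
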