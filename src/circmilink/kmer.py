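"""K-mer spectrum features.

A sequence of length l is scanned with a sliding window of K nucleotides
(stride 1), giving l - K + 1 windows; each window is indexed by its base-4
lexicographic rank over the fixed alphabet order A < C < G < T, producing a
spectrum vector of length 4**K. ``U`` is mapped to ``T`` so RNA and DNA
spellings share one index space; windows containing any other character are
skipped (counted as invalid) rather than resolved stochastically.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = ["KmerSpectrum", "kmer_vector", "featurize_corpus", "kmer_labels"]

ALPHABET = "ACGT"
_CODE = np.full(128, -1, dtype=np.int64)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
_CODE[ord("U")] = _CODE[ord("T")]


class SequenceTooShortError(ValueError):
    pass


class DegenerateSequenceError(ValueError):
    """No valid window exists, so a frequency spectrum is undefined."""


@dataclass
class KmerSpectrum:
    values: np.ndarray
    K: int
    mode: str
    n_valid_windows: int
    n_invalid_windows: int

    def __post_init__(self):
        assert len(self.values) == 4 ** self.K


def kmer_labels(K: int) -> list[str]:
    """All 4**K k-mer strings in lexicographic (index) order."""
    return ["".join(p) for p in product(ALPHABET, repeat=K)]


def kmer_vector(seq: str, K: int, mode: str = "frequency") -> KmerSpectrum:
    """Spectrum of all length-K windows of ``seq``.

    Parameters
    ----------
    seq : str
        RNA or DNA sequence; upper-cased internally, U treated as T.
    K : int
        Window length, 1 <= K <= 8.
    mode : {"count", "frequency"}
        Raw window counts, or counts divided by the number of valid windows.
    """
    if not 1 <= K <= 8:
        raise ValueError(f"K must be in [1, 8], got {K}")
    if mode not in ("count", "frequency"):
        raise ValueError(f"mode must be 'count' or 'frequency', got {mode!r}")
    seq = seq.upper()
    if len(seq) < K:
        raise SequenceTooShortError(
            f"sequence of length {len(seq)} is shorter than K={K}"
        )
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n_win = len(seq) - K + 1
    # base-4 rank of each window; windows touching an invalid character are
    # dropped, not imputed
    valid = codes >= 0
    ranks = np.zeros(n_win, dtype=np.int64)
    ok = np.ones(n_win, dtype=bool)
    for offset in range(K):
        ranks = ranks * 4 + np.where(
            valid[offset : offset + n_win], codes[offset : offset + n_win], 0
        )
        ok &= valid[offset : offset + n_win]
    counts = np.bincount(ranks[ok], minlength=4 ** K).astype(np.float64)
    n_valid = int(ok.sum())
    if mode == "frequency":
        if n_valid == 0:
            raise DegenerateSequenceError(
                "no valid window: frequency spectrum undefined"
            )
        values = counts / n_valid
    else:
        values = counts
    return KmerSpectrum(values, K, mode, n_valid, n_win - n_valid)


def featurize_corpus(records, K: int, mode: str = "frequency") -> pd.DataFrame:
    """K-mer attribute matrix (one row per record, 4**K columns).

    Row index is the record ids in input order; columns are k-mer strings.
    Errors from individual sequences are re-raised with the offending id.
    """
    rows = []
    ids = []
    for rec in records:
        try:
            rows.append(kmer_vector(rec.sequence, K, mode).values)
        except ValueError as exc:
            raise type(exc)(f"record {rec.id!r}: {exc}") from exc
        ids.append(rec.id)
    data = np.vstack(rows) if rows else np.empty((0, 4 ** K))
    return pd.DataFrame(data, index=ids, columns=kmer_labels(K))
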