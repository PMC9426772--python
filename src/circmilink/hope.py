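"""Behavior features: HOPE embedding of the interaction graph.

High-Order Proximity preserved Embedding factorizes a Katz proximity matrix

    M = (I - decay*A)^-1 (decay*A) = sum_{k>=1} decay^k A^k

by truncated SVD, M ~= N_s N_t^T, with N_s[:, i] = sqrt(sigma_i) u_i and
N_t[:, i] = sqrt(sigma_i) v_i so the product is the best rank-beta
approximation in Frobenius norm (Eckart-Young). For the undirected bipartite
interaction graph the block adjacency A = [[0, P], [P^T, 0]] is symmetric and
N_s serves as the per-node behavior vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import AdjacencyMatrix

__all__ = [
    "ProximityMatrix",
    "HopeEmbedding",
    "katz_proximity",
    "hope_embed",
    "embed_interaction_graph",
]


class DivergenceError(ValueError):
    """Katz series diverges: decay * spectral_radius(A) >= 1."""


class DegenerateGraphError(ValueError):
    pass


@dataclass
class ProximityMatrix:
    M: np.ndarray
    decay: float
    construction: str = "katz"


@dataclass
class HopeEmbedding:
    N_s: np.ndarray
    N_t: np.ndarray
    singular_values: np.ndarray
    beta: int
    node_index: list[str] | None = None


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(A, dtype=float)))))


def katz_proximity(A: np.ndarray, decay: float) -> ProximityMatrix:
    """Katz proximity M = (I - decay*A)^-1 (decay*A).

    Requires decay < 1/spectral_radius(A) for the underlying path series
    to converge.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if np.any(A < 0):
        raise ValueError("A must be non-negative")
    if decay < 0:
        raise ValueError("decay must be non-negative")
    rad = spectral_radius(A)
    if rad > 0 and decay >= 1.0 / rad:
        raise DivergenceError(
            f"decay={decay} >= 1/spectral_radius = {1.0 / rad:.6g}; "
            "Katz series diverges"
        )
    n = A.shape[0]
    M = np.linalg.solve(np.eye(n) - decay * A, decay * A)
    return ProximityMatrix(M, decay)


def hope_embed(M: ProximityMatrix | np.ndarray, beta: int) -> HopeEmbedding:
    """Rank-beta SVD factorization of the proximity matrix.

    Columns of N_s and N_t carry sqrt(sigma_i) so that N_s @ N_t.T equals the
    best rank-beta approximation of M.
    """
    mat = M.M if isinstance(M, ProximityMatrix) else np.asarray(M, float)
    alpha = mat.shape[0]
    if not 1 <= beta <= alpha:
        raise ValueError(f"beta must be in [1, {alpha}], got {beta}")
    U, s, Vt = np.linalg.svd(mat, full_matrices=False)
    root = np.sqrt(s[:beta])
    N_s = U[:, :beta] * root
    N_t = Vt[:beta].T * root
    return HopeEmbedding(N_s, N_t, s[:beta], beta)


def embed_interaction_graph(
    adj: AdjacencyMatrix,
    beta: int = 64,
    decay_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-node behavior vectors for all circRNAs and miRNAs.

    Builds the symmetric block adjacency over alpha = n_circ + n_mi nodes,
    sets decay = decay_fraction / spectral_radius(A) (guaranteeing Katz
    convergence), and returns the source embedding rows keyed by node id.
    Isolated nodes receive exact zero vectors.
    """
    P = adj.P.astype(np.float64)
    if P.sum() == 0:
        raise DegenerateGraphError("interaction matrix has no edges")
    if not 0 < decay_fraction < 1:
        raise ValueError("decay_fraction must lie in (0, 1)")
    n_c, n_m = P.shape
    alpha = n_c + n_m
    A = np.zeros((alpha, alpha))
    A[:n_c, n_c:] = P
    A[n_c:, :n_c] = P.T
    rad = float(np.max(np.abs(np.linalg.eigvalsh(A))))
    decay = decay_fraction / rad
    emb = hope_embed(katz_proximity(A, decay), min(beta, alpha))
    vectors = emb.N_s
    if emb.beta < beta:
        vectors = np.hstack(
            [vectors, np.zeros((alpha, beta - emb.beta))]
        )
    isolated = A.sum(axis=1) == 0
    vectors = vectors.copy()
    vectors[isolated] = 0.0
    index = list(adj.circ_index) + list(adj.mi_index)
    return pd.DataFrame(vectors, index=index)
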