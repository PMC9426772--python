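"""Gaussian interaction profile (GIP) kernel similarity.

The similarity between two RNAs is a Gaussian radial-basis function of the
Euclidean distance between their binary interaction profiles (rows or
columns of the adjacency matrix):

    G(i, j) = exp(-lam * ||L(i) - L(j)||^2)

with the bandwidth normalized by the mean squared profile norm,

    lam = lam' / ( (1/n) * sum_i ||L(i)||^2 ),

and the prior bandwidth lam' fixed at 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["GipKernel", "gip_bandwidth", "gip_kernel"]


class ZeroProfileError(ValueError):
    """All interaction profiles are zero, so the bandwidth is undefined."""


@dataclass
class GipKernel:
    matrix: np.ndarray
    bandwidth: float
    bandwidth_prior: float
    axis: str = "circRNA"


def gip_bandwidth(profiles: np.ndarray, prior: float = 1.0) -> float:
    """Bandwidth lam = prior / mean squared row norm of ``profiles``."""
    if prior <= 0:
        raise ValueError("bandwidth prior must be positive")
    profiles = np.asarray(profiles, dtype=np.float64)
    mean_sq_norm = float(np.mean(np.sum(profiles ** 2, axis=1)))
    if mean_sq_norm == 0.0:
        raise ZeroProfileError(
            "all interaction profiles are zero; bandwidth undefined"
        )
    return prior / mean_sq_norm


def gip_kernel(
    profiles: np.ndarray, prior: float = 1.0, axis: str = "circRNA"
) -> GipKernel:
    """Symmetric, unit-diagonal, PSD Gaussian kernel over profile rows."""
    profiles = np.asarray(profiles, dtype=np.float64)
    lam = gip_bandwidth(profiles, prior)
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    K = np.exp(-lam * sq_dists)
    np.fill_diagonal(K, 1.0)
    return GipKernel(K, lam, prior, axis)
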