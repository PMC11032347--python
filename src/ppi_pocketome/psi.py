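"""Pocket Similarity Index: Gaussian kernel over descriptor distances.

Pockets live in the standardized descriptor space; the similarity between
pockets *i* and *j* is

    PSI_ij = exp(-d_ij^2 / (2 sigma^2))

where ``d_ij`` is their Euclidean distance and ``sigma`` the (population)
standard deviation of the distances over all unordered pocket pairs.  The
kernel maps distances into (0, 1], with 1 for identical pockets; it is
strictly decreasing in distance, so similarity rankings from any anchor
pocket are sigma-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["DistanceMatrix", "PSIMatrix", "pairwise_distances", "psi",
           "psi_matrix"]


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean distance matrix with its pairwise-spread sigma."""

    pocket_ids: list[str]
    d: np.ndarray
    sigma: float

    def __len__(self) -> int:
        return len(self.pocket_ids)


@dataclass
class PSIMatrix:
    """Symmetric pocket-similarity matrix in (0, 1], unit diagonal."""

    pocket_ids: list[str]
    psi: np.ndarray

    def __len__(self) -> int:
        return len(self.pocket_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.psi, index=self.pocket_ids,
                            columns=self.pocket_ids)


def pairwise_distances(matrix: pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """All-pairs Euclidean distances between pocket descriptor rows.

    ``sigma`` is the population standard deviation over the N(N-1)/2
    unordered off-diagonal pairs (the zero diagonal is excluded so it
    cannot deflate the spread).
    """
    if isinstance(matrix, pd.DataFrame):
        ids = [str(i) for i in matrix.index]
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        ids = [f"pocket{i + 1}" for i in range(len(values))]
    if len(values) < 2:
        raise ValueError("need at least 2 pockets")
    condensed = pdist(values, metric="euclidean")
    return DistanceMatrix(pocket_ids=ids, d=squareform(condensed),
                          sigma=float(condensed.std(ddof=0)) if len(condensed) > 1
                          else float(condensed[0]))


def psi(d_ij: float | np.ndarray, sigma: float) -> float | np.ndarray:
    """Gaussian-kernel similarity for distance(s) *d_ij* at spread *sigma*."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(d_ij, dtype=float)
    out = np.exp(-(d**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def psi_matrix(dist: DistanceMatrix) -> PSIMatrix:
    """Elementwise PSI of a distance matrix, diagonal forced to 1."""
    if dist.sigma <= 0:
        raise ValueError(
            "degenerate sigma: all pockets have identical descriptors; "
            "check the descriptor matrix"
        )
    values = psi(dist.d, dist.sigma)
    np.fill_diagonal(values, 1.0)
    return PSIMatrix(pocket_ids=list(dist.pocket_ids), psi=values)
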