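"""Gene-gene similarity graph and Laplacian for the smoothness penalty.

The factorization penalizes dissimilar low-dimensional embeddings for genes
with similar mutation profiles via Tr(Z^T L_S Z), where L_S = D_S - S is the
graph Laplacian of a Gaussian-kernel similarity matrix S over gene columns.
Distances between gene profiles are weighted per sample by the learned
diagonal feature-weight matrix M, so noisy samples contribute less to
similarity as the solver learns to discount them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .exceptions import ConfigurationError


@dataclass
class SimilarityGraph:
    """Similarity matrix S, degree vector and Laplacian L_S = diag(D_S) - S."""

    similarity: np.ndarray
    degrees: np.ndarray
    laplacian: np.ndarray
    sigma: float

    @property
    def n_nodes(self) -> int:
        return self.similarity.shape[0]


def weighted_sq_distance(a, b, feature_weights) -> float:
    """Squared distance (a-b)^T diag(feature_weights) (a-b).

    With unit weights this is the squared Euclidean distance; on binary
    vectors, the Hamming distance. Nonnegative weights learn which features
    (here: samples) matter for similarity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w = np.asarray(feature_weights, dtype=float)
    if a.shape != b.shape or a.shape != w.shape:
        raise ConfigurationError(
            f"length mismatch: a {a.shape}, b {b.shape}, feature_weights {w.shape}"
        )
    if (w < 0).any():
        raise ConfigurationError("feature_weights must be nonnegative")
    d = a - b
    return float(d @ (w * d))


def gaussian_similarity(sq_dist: float, sigma: float) -> float:
    """Gaussian kernel similarity exp(-d^2 / (2 sigma^2)) in (0, 1]."""
    if sigma <= 0:
        raise ConfigurationError(f"sigma must be positive, got {sigma}")
    if sq_dist < 0:
        raise ConfigurationError(f"squared distance must be nonnegative, got {sq_dist}")
    return float(np.exp(-sq_dist / (2.0 * sigma**2)))


def _pairwise_weighted_sq_dists(columns: np.ndarray, feature_weights: np.ndarray) -> np.ndarray:
    # columns: p x m (one row per gene); scale features by sqrt(w) so plain
    # squared Euclidean distance equals the diag-metric distance.
    scaled = columns * np.sqrt(feature_weights)[np.newaxis, :]
    d2 = squareform(pdist(scaled, metric="sqeuclidean"))
    return np.maximum(d2, 0.0)


def median_bandwidth(sq_dists: np.ndarray) -> float:
    """Median-heuristic bandwidth: sqrt of the median nonzero squared distance.

    Falls back to 1.0 (with a warning) when every pairwise distance is zero.
    """
    iu = np.triu_indices_from(sq_dists, k=1)
    off = sq_dists[iu]
    nonzero = off[off > 0]
    if nonzero.size == 0:
        warnings.warn(
            "all pairwise distances are zero; falling back to sigma=1.0", stacklevel=2
        )
        return 1.0
    return float(np.sqrt(np.median(nonzero)))


def build_graph(
    X,
    feature_weights=None,
    sigma="median",
    knn: int | None = None,
) -> SimilarityGraph:
    """Build the similarity graph over gene mutation profiles.

    Parameters
    ----------
    X : MutationMatrix or ndarray (samples x genes)
        Gene profiles are the columns.
    feature_weights : length-n_samples nonnegative vector, optional
        Diagonal metric for the distance; defaults to all ones.
    sigma : positive float or "median"
        Kernel bandwidth; "median" uses the median heuristic over the
        weighted pairwise distances.
    knn : int, optional
        If set, sparsify to a symmetric k-nearest-neighbour graph (an edge
        survives if either endpoint ranks the other among its k closest).
        Off by default: the penalty is defined on the full graph.
    """
    values = X.values if hasattr(X, "values") and not isinstance(X, np.ndarray) else np.asarray(X)
    values = np.asarray(values, dtype=float)
    m, p = values.shape
    if p < 2:
        raise ConfigurationError(f"need at least 2 genes to build a graph, got {p}")
    if feature_weights is None:
        feature_weights = np.ones(m)
    feature_weights = np.asarray(feature_weights, dtype=float)
    if feature_weights.shape != (m,):
        raise ConfigurationError(
            f"feature_weights must have length {m}, got shape {feature_weights.shape}"
        )
    if (feature_weights < 0).any():
        raise ConfigurationError("feature_weights must be nonnegative")

    d2 = _pairwise_weighted_sq_dists(values.T, feature_weights)
    if sigma == "median":
        sigma_val = median_bandwidth(d2)
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ConfigurationError(f"sigma must be positive, got {sigma_val}")

    S = np.exp(-d2 / (2.0 * sigma_val**2))
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0

    if knn is not None:
        if knn < 1 or knn >= p:
            raise ConfigurationError(f"knn must be in [1, {p - 1}], got {knn}")
        keep = np.zeros_like(S, dtype=bool)
        key = -S.copy()
        np.fill_diagonal(key, -np.inf)  # self sorts first, then nearest neighbours
        order = np.argsort(key, axis=1)
        for i in range(p):
            keep[i, order[i, 1 : knn + 1]] = True
        keep = keep | keep.T
        np.fill_diagonal(keep, True)
        S = np.where(keep, S, 0.0)

    degrees = S.sum(axis=1)
    laplacian = np.diag(degrees) - S
    return SimilarityGraph(similarity=S, degrees=degrees, laplacian=laplacian, sigma=sigma_val)
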