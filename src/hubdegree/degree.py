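"""Composite weighted degree centrality over proportional-threshold sweeps.

Weighted degree of node *i* in a connectivity matrix ``A`` is the row sum
``k_i = sum_j a_ij``.  To avoid committing to a single graph sparsity, the
matrix is thresholded at a range of edge densities (default 2–10% in 1%
steps), degree is computed on each thresholded graph, and the per-density
degrees are summed into a single *composite* weighted degree per node.

Degree can additionally be split into within-network and between-network
components using a parcel-to-network assignment: the same globally
thresholded graphs are used, and each surviving edge is attributed to the
within or between component according to whether its endpoints share a
network label.  The two components sum exactly to the total.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: Edge densities 0.02, 0.03, ..., 0.10 — the default sparsity sweep.
DEFAULT_DENSITIES: tuple[float, ...] = tuple(
    round(0.02 + 0.01 * i, 2) for i in range(9)
)

__all__ = [
    "DEFAULT_DENSITIES",
    "proportional_threshold",
    "weighted_degree",
    "composite_degree",
    "partition_degree",
    "CompositeDegree",
]


def _validate_matrix(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got shape {C.shape}")
    if C.shape[0] < 2:
        raise ValueError("connectivity matrix needs at least 2 parcels")
    return C


def _validate_densities(densities: Sequence[float]) -> tuple[float, ...]:
    ds = tuple(float(d) for d in densities)
    if len(ds) == 0:
        raise ValueError("density sweep must be nonempty")
    if any(not (0.0 < d <= 1.0) for d in ds):
        raise ValueError(f"densities must lie in (0, 1], got {ds}")
    if any(b <= a for a, b in zip(ds, ds[1:])):
        raise ValueError(f"densities must be strictly increasing, got {ds}")
    return ds


def _edge_order(C: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending weight, ties by (i, j)."""
    iu, ju = np.triu_indices(C.shape[0], k=1)
    w = C[iu, ju]
    # lexsort: last key is primary
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def _edges_to_keep(density: float, n_edges: int) -> int:
    # floor with a minimum of one edge so tiny densities still yield a graph
    return max(1, math.floor(density * n_edges))


def proportional_threshold(C: np.ndarray, density: float) -> np.ndarray:
    """Keep the strongest ``density`` fraction of edges, weights preserved.

    Retains the ``m = max(1, floor(density * n(n-1)/2))`` largest
    off-diagonal edges; ties are broken deterministically by ascending
    (row, column) index.  All other entries are zeroed.
    """
    C = _validate_matrix(C)
    (density,) = _validate_densities([density])
    n = C.shape[0]
    n_edges = n * (n - 1) // 2
    if not np.any(C):
        logger.warning("proportional_threshold: all-zero matrix")
        return np.zeros_like(C)
    m = _edges_to_keep(density, n_edges)
    ii, jj, ww = _edge_order(C)
    out = np.zeros_like(C)
    out[ii[:m], jj[:m]] = ww[:m]
    out += out.T
    return out


def weighted_degree(C: np.ndarray) -> np.ndarray:
    """Row sums ``k_i = sum_j a_ij`` of a (thresholded) connectivity matrix."""
    C = _validate_matrix(C)
    return C.sum(axis=1)


def composite_degree(
    C: np.ndarray, densities: Sequence[float] = DEFAULT_DENSITIES
) -> np.ndarray:
    """Sum of weighted degree across the proportional-threshold sweep.

    Each edge contributes its weight times the number of densities at which
    it survives thresholding (proportional thresholds are nested), so the
    result is computed from edge survival counts rather than by building
    every thresholded matrix.
    """
    C = _validate_matrix(C)
    ds = _validate_densities(densities)
    n = C.shape[0]
    n_edges = n * (n - 1) // 2
    if not np.any(C):
        logger.warning("composite_degree: all-zero matrix")
        return np.zeros(n)
    ii, jj, ww = _edge_order(C)
    ranks = np.arange(n_edges)
    multiplicity = np.zeros(n_edges)
    for d in ds:
        multiplicity += ranks < _edges_to_keep(d, n_edges)
    contrib = ww * multiplicity
    k = np.zeros(n)
    np.add.at(k, ii, contrib)
    np.add.at(k, jj, contrib)
    return k


def partition_degree(
    C: np.ndarray,
    networks: Sequence,
    densities: Sequence[float] = DEFAULT_DENSITIES,
) -> tuple[np.ndarray, np.ndarray]:
    """Within- and between-network composite degree.

    The full matrix is thresholded globally at each density; surviving edges
    are then attributed to the within component when both endpoints share a
    network label and to the between component otherwise.  The identity
    ``within + between == composite_degree(C, densities)`` holds exactly.
    """
    C = _validate_matrix(C)
    ds = _validate_densities(densities)
    networks = np.asarray(networks)
    if networks.shape[0] != C.shape[0]:
        raise ValueError(
            f"parcellation has {networks.shape[0]} parcels but matrix has "
            f"{C.shape[0]}"
        )
    same = networks[:, None] == networks[None, :]
    within = np.zeros(C.shape[0])
    between = np.zeros(C.shape[0])
    for d in ds:
        Ct = proportional_threshold(C, d)
        within += (Ct * same).sum(axis=1)
        between += (Ct * ~same).sum(axis=1)
    return within, between


class CompositeDegree(BaseEstimator, TransformerMixin):
    """Transformer mapping stacked connectivity matrices to composite degree.

    Parameters
    ----------
    densities : sequence of float
        Edge-density sweep; defaults to 2–10% in 1% increments.

    ``transform`` accepts an array of shape ``(n_subjects, n_parcels,
    n_parcels)`` and returns ``(n_subjects, n_parcels)`` composite degree.
    """

    def __init__(self, densities: Sequence[float] = DEFAULT_DENSITIES):
        self.densities = densities

    def fit(self, X, y=None):
        self.densities_ = _validate_densities(self.densities)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "densities_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        return np.stack([composite_degree(c, self.densities_) for c in X])
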