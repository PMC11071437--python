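"""Per-sample niche network construction.

Every cell anchors one niche containing itself plus its k nearest
neighbours.  Two niches are connected when their anchoring cells are
mutual k-nearest neighbours.  A cell i belonging to niche j gets the
Gaussian association weight ``w_ij = exp(-d_ij^2 / sigma_j^2)`` where
``sigma_j`` is the distance from the anchor of j to its
``sigma_index``-th nearest neighbour, and the niche feature vector is
the association-weighted cell-type composition
``v_jm = sum_i w_ij I_im / sum_i w_ij``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree


@dataclass
class NicheNetwork:
    """Niche graph, association weights and composition for one sample.

    Attributes
    ----------
    sample : str
        Sample identifier.
    cell_ids : ndarray of str, shape (N,)
        Anchoring cells in input order; niche *j* is anchored at cell *j*.
    knn : ndarray of int, shape (N, k)
        Indices of each anchor's k nearest neighbours, nearest first.
    adjacency : scipy.sparse.csr_matrix, shape (N, N)
        Symmetric binary mutual-kNN adjacency, zero diagonal.
    assoc_weights : scipy.sparse.csr_matrix, shape (N, N)
        ``W[i, j] = w_ij`` for cells i belonging to niche j, else 0.
        The anchor's own weight is exactly 1.
    sigma : ndarray, shape (N,)
        Per-niche Gaussian scale, strictly positive.
    composition : ndarray, shape (N, M)
        Row-stochastic cell-type composition of each niche.
    cell_types : ndarray of str, shape (M,)
        Column labels of ``composition`` (global type order).
    """

    sample: str
    cell_ids: np.ndarray
    coords: np.ndarray
    knn: np.ndarray
    adjacency: sparse.csr_matrix
    assoc_weights: sparse.csr_matrix
    sigma: np.ndarray
    composition: np.ndarray
    cell_types: np.ndarray

    @property
    def n_niches(self) -> int:
        return len(self.cell_ids)

    def edge_list(self) -> pd.DataFrame:
        """Niche graph as an (sample, anchor_i, anchor_j) edge table."""
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        return pd.DataFrame(
            {
                "sample": self.sample,
                "anchor_i": self.cell_ids[coo.row],
                "anchor_j": self.cell_ids[coo.col],
            }
        )


def knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest other points for every point.

    Euclidean distance; ties are broken by the smaller point index so
    the result is deterministic across platforms.

    Parameters
    ----------
    coords : (N, 2) array of finite coordinates
    k : int, 1 <= k < N

    Returns
    -------
    (N, k) integer array, nearest neighbour first.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the number of points ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")

    tree = cKDTree(coords)
    # query k+1 including self, then drop self and re-sort (distance, index)
    dist, idx = tree.query(coords, k=k + 1)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        d_i, j_i = dist[i], idx[i]
        keep = j_i != i
        d_i, j_i = d_i[keep][:k], j_i[keep][:k]
        if len(j_i) < k:  # self not returned (coincident points); re-query
            d_full = np.linalg.norm(coords - coords[i], axis=1)
            d_full[i] = np.inf
            order = np.lexsort((np.arange(n), d_full))[:k]
            out[i] = order
            continue
        order = np.lexsort((j_i, d_i))
        out[i] = j_i[order]
    return out


def knn_distances(coords: np.ndarray, knn: np.ndarray) -> np.ndarray:
    """Distances matching a neighbour-index array."""
    coords = np.asarray(coords, dtype=np.float64)
    return np.linalg.norm(coords[knn] - coords[:, None, :], axis=2)


def build_adjacency(knn: np.ndarray) -> sparse.csr_matrix:
    """Mutual-kNN adjacency: ``a_ij = 1`` iff i in knn(j) and j in knn(i)."""
    n, k = knn.shape
    rows = np.repeat(np.arange(n), k)
    cols = knn.ravel()
    directed = sparse.csr_matrix(
        (np.ones(n * k, dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    mutual = directed.multiply(directed.T)
    mutual = sparse.csr_matrix(mutual, dtype=np.float64)
    mutual.setdiag(0)
    mutual.eliminate_zeros()
    return mutual


def association_weights(
    coords: np.ndarray, knn: np.ndarray, sigma_index: int
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Gaussian cell-niche association weights and per-niche scales.

    Niche j's members are its anchor (weight exactly 1) and its k
    nearest neighbours with weight ``exp(-d^2 / sigma_j^2)``.

    Returns
    -------
    W : csr_matrix, (n_cells, n_niches)
    sigma : (n_niches,) strictly positive scales
    """
    n, k = knn.shape
    if not (1 <= sigma_index <= k):
        raise ValueError(f"sigma_index ({sigma_index}) must be in [1, k={k}]")
    dist = knn_distances(coords, knn)
    sigma = dist[:, sigma_index - 1].copy()

    # degenerate segmentations: >= sigma_index coincident points
    zero = sigma <= 0
    if zero.any():
        for j in np.flatnonzero(zero):
            positive = dist[j][dist[j] > 0]
            if positive.size == 0:
                raise ValueError(
                    f"niche {j}: all {k} nearest neighbours coincide with the "
                    "anchor; cannot set a positive association scale"
                )
            sigma[j] = positive.min()

    w_members = np.exp(-(dist**2) / sigma[:, None] ** 2)
    rows = np.concatenate([knn.ravel(), np.arange(n)])  # member cells
    cols = np.concatenate([np.repeat(np.arange(n), k), np.arange(n)])  # niches
    vals = np.concatenate([w_members.ravel(), np.ones(n)])  # anchor w = 1
    W = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return W, sigma


def composition_vectors(
    weights: sparse.csr_matrix,
    cell_types: np.ndarray | pd.Series,
    categories: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Association-weighted cell-type composition of every niche.

    ``v_jm = sum_i w_ij I_im / sum_i w_ij`` — the weight fraction of
    type m among the members of niche j.

    Parameters
    ----------
    weights : (n_cells, n_niches) sparse weight matrix
    cell_types : length n_cells labels
    categories : optional fixed type ordering (for multi-sample runs)

    Returns
    -------
    V : (n_niches, M) row-stochastic composition matrix
    categories : (M,) column labels
    """
    ct = pd.Categorical(np.asarray(cell_types), categories=categories)
    if categories is None:
        categories = np.asarray(ct.categories)
    codes = ct.codes
    if (codes < 0).any():
        raise ValueError("cell type outside the provided category set")
    m = len(categories)
    onehot = sparse.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), m),
    )
    num = np.asarray((weights.T @ onehot).todense())  # (n_niches, M)
    denom = num.sum(axis=1, keepdims=True)
    if np.any(denom <= 0):
        raise RuntimeError("niche with zero total association weight")
    return num / denom, categories


def build_niche_network(
    cells: pd.DataFrame,
    sample: str,
    k_neighbors: int,
    sigma_index: int,
    categories: np.ndarray,
) -> NicheNetwork:
    """Assemble the full niche network for one sample's cells."""
    sub = cells.loc[cells["sample"] == sample]
    coords = sub[["x", "y"]].to_numpy(dtype=np.float64)
    knn = knn_indices(coords, k_neighbors)
    adjacency = build_adjacency(knn)
    weights, sigma = association_weights(coords, knn, sigma_index)
    composition, categories = composition_vectors(
        weights, sub["cell_type"].to_numpy(), categories
    )
    return NicheNetwork(
        sample=sample,
        cell_ids=sub["cell_id"].to_numpy(dtype=object),
        coords=coords,
        knn=knn,
        adjacency=adjacency,
        assoc_weights=weights,
        sigma=sigma,
        composition=composition,
        cell_types=categories,
    )
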