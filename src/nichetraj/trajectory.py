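"""Niche-cluster graph, optimal ordering and NT scores.

The niche network is collapsed onto K niche clusters through the soft
assignment C: cluster connectivity ``E_kl = sum_ij c_ik a_ij c_jl``,
normalised as ``E~_kl = E_kl / (sum_i E_ki * sum_i E_il)``.  The
trajectory is the ordering p_1..p_K of clusters maximising the chained
connectivity ``sum_k E~_{p_k, p_{k+1}}``; cluster p_k receives the
equally spaced score (k-1)/(K-1), every niche the C-weighted average of
cluster scores (the NT score), and every cell the association-weighted
average of the scores of the niches containing it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse


@dataclass
class ClusterGraph:
    """Cluster connectivity E and its normalised form E~."""

    connectivity: np.ndarray        # (K, K) E
    connectivity_norm: np.ndarray   # (K, K) E~


@dataclass
class Trajectory:
    """A one-dimensional ordering of niche clusters with scores."""

    ordering: np.ndarray            # permutation p_1..p_K of cluster indices
    cluster_scores: np.ndarray      # (K,) score of cluster k (index order)
    connectivity: np.ndarray
    connectivity_norm: np.ndarray
    reversed: bool = False

    def reverse(self) -> "Trajectory":
        """The same trajectory traversed in the opposite direction (s -> 1-s)."""
        return Trajectory(
            ordering=self.ordering[::-1].copy(),
            cluster_scores=1.0 - self.cluster_scores,
            connectivity=self.connectivity,
            connectivity_norm=self.connectivity_norm,
            reversed=not self.reversed,
        )


def cluster_graph(C: np.ndarray, A: sparse.spmatrix | np.ndarray) -> ClusterGraph:
    """Collapse the niche network onto the cluster graph.

    For multi-sample runs pass the block-diagonal union of the
    per-sample adjacencies with C stacked accordingly.  Clusters with a
    zero connectivity marginal get zero rows/columns in E~.
    """
    A = sparse.csr_matrix(A, dtype=np.float64)
    E = C.T @ (A @ C)
    row = E.sum(axis=1)   # == column sums when A symmetric
    col = E.sum(axis=0)
    denom = np.outer(row, col)
    E_norm = np.divide(E, denom, out=np.zeros_like(E), where=denom > 0)
    return ClusterGraph(connectivity=E, connectivity_norm=E_norm)


def path_score(E_norm: np.ndarray, ordering: np.ndarray) -> float:
    """Total chained connectivity along an ordering."""
    o = np.asarray(ordering)
    return float(E_norm[o[:-1], o[1:]].sum())


def _canonical(order: tuple[int, ...] | np.ndarray) -> np.ndarray:
    o = np.asarray(order, dtype=np.int64)
    return o if o[0] < o[-1] else o[::-1].copy()


def _exhaustive(E_norm: np.ndarray, active: np.ndarray) -> np.ndarray:
    best, best_score = None, -np.inf
    for perm in itertools.permutations(active.tolist()):
        if perm[0] > perm[-1]:
            continue  # each reversal class visited once
        s = path_score(E_norm, np.asarray(perm))
        if s > best_score + 1e-15 or (best is None):
            best, best_score = perm, s
    return np.asarray(best, dtype=np.int64)


def _greedy_chain(sub: np.ndarray, start: int) -> np.ndarray:
    k = sub.shape[0]
    chain = [start]
    remaining = set(range(k)) - {start}
    while remaining:
        head, tail = chain[0], chain[-1]
        cand_head = max(remaining, key=lambda c: sub[c, head])
        cand_tail = max(remaining, key=lambda c: sub[tail, c])
        if sub[cand_head, head] >= sub[tail, cand_tail]:
            chain.insert(0, cand_head)
            remaining.remove(cand_head)
        else:
            chain.append(cand_tail)
            remaining.remove(cand_tail)
    return np.asarray(chain, dtype=np.int64)


def _local_search(sub: np.ndarray, order: np.ndarray, sweeps: int = 200) -> np.ndarray:
    # 2-opt segment reversals plus or-opt segment relocations (len 1-3,
    # both orientations) until a local optimum is reached
    k = len(order)
    for _ in range(sweeps):
        improved = False
        base = path_score(sub, order)
        for a in range(k - 1):
            for b in range(a + 1, k):
                new = order.copy()
                new[a : b + 1] = new[a : b + 1][::-1]
                s = path_score(sub, new)
                if s > base + 1e-15:
                    order, base, improved = new, s, True
        for seg_len in (1, 2, 3):
            if seg_len >= k:
                continue
            for a in range(k - seg_len + 1):
                seg = order[a : a + seg_len].copy()
                rest = np.concatenate([order[:a], order[a + seg_len :]])
                for pos in range(len(rest) + 1):
                    for piece in (seg, seg[::-1]):
                        new = np.concatenate([rest[:pos], piece, rest[pos:]])
                        s = path_score(sub, new)
                        if s > base + 1e-15:
                            order, base, improved = new, s, True
                if improved:
                    break
            if improved:
                break
        if not improved:
            break
    return order


def _double_bridge(order: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    k = len(order)
    if k < 4:
        return order[rng.permutation(k)]
    cuts = np.sort(rng.choice(np.arange(1, k), size=3, replace=False))
    a, b, c = cuts
    return np.concatenate([order[:a], order[b:c], order[a:b], order[c:]])


def _greedy_two_opt(
    E_norm: np.ndarray, active: np.ndarray, n_kicks: int = 30
) -> np.ndarray:
    # multi-start greedy chain extension refined by iterated local search
    # (2-opt + or-opt, with deterministic double-bridge perturbations)
    sub = E_norm[np.ix_(active, active)]
    k = len(active)
    rng = np.random.default_rng(0)  # fixed: ordering search is deterministic
    best, best_score = None, -np.inf
    for start in range(k):
        order = _local_search(sub, _greedy_chain(sub, start))
        s = path_score(sub, order)
        for _ in range(n_kicks):
            cand = _local_search(sub, _double_bridge(order, rng))
            s_cand = path_score(sub, cand)
            if s_cand > s + 1e-15:
                order, s = cand, s_cand
        if s > best_score + 1e-15:
            best, best_score = order, s
    return active[best]


def optimal_ordering(E_norm: np.ndarray, exhaustive_limit: int = 9) -> np.ndarray:
    """Cluster ordering maximising the chained normalised connectivity.

    Exhaustive over all K!/2 reversal classes for K <= ``exhaustive_limit``,
    greedy chain extension with 2-opt refinement above.  Clusters with an
    all-zero E~ row and column (empty clusters) are appended at the end.
    The returned ordering is canonically oriented: first index < last.
    """
    k = E_norm.shape[0]
    if k < 2:
        raise ValueError("need at least 2 clusters")
    degenerate = (E_norm.sum(axis=0) == 0) & (E_norm.sum(axis=1) == 0)
    active = np.flatnonzero(~degenerate)
    if len(active) < 2:
        order = np.concatenate([active, np.flatnonzero(degenerate)])
        return order.astype(np.int64)
    if len(active) <= exhaustive_limit:
        core = _exhaustive(E_norm, active)
    else:
        core = _greedy_two_opt(E_norm, active)
    core = _canonical(core)
    return np.concatenate([core, np.flatnonzero(degenerate)]).astype(np.int64)


def cluster_scores_from_ordering(ordering: np.ndarray) -> np.ndarray:
    """Equally spaced scores: cluster at position m gets (m-1)/(K-1)."""
    k = len(ordering)
    scores = np.empty(k)
    scores[np.asarray(ordering)] = np.arange(k) / (k - 1)
    return scores


def nt_scores(C: np.ndarray, ordering: np.ndarray) -> np.ndarray:
    """Niche-level NT scores ``s_j = sum_k c_jk s_k`` in [0, 1]."""
    return C @ cluster_scores_from_ordering(ordering)


def cell_nt_scores(W: sparse.spmatrix, niche_scores: np.ndarray) -> np.ndarray:
    """Cell-level NT scores: association-weighted mean over containing niches.

    ``s~_i = sum_j w_ij s_j / sum_j w_ij``; every cell anchors one niche
    with weight 1, so the denominator is always positive.
    """
    W = sparse.csr_matrix(W)
    num = W @ niche_scores
    denom = np.asarray(W.sum(axis=1)).ravel()
    return num / denom


def build_trajectory(C: np.ndarray, A: sparse.spmatrix | np.ndarray) -> Trajectory:
    """Cluster graph, optimal ordering and cluster scores in one call."""
    cg = cluster_graph(C, A)
    ordering = optimal_ordering(cg.connectivity_norm)
    return Trajectory(
        ordering=ordering,
        cluster_scores=cluster_scores_from_ordering(ordering),
        connectivity=cg.connectivity,
        connectivity_norm=cg.connectivity_norm,
    )
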