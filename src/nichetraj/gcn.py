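"""Graph-convolutional pooling model: forward pass, losses, training.

The encoder is a two-layer graph convolution over the niche network,

    X_t = SeLU((A_tilde + I) X_{t-1} W_t),   X_0 = V,

with A_tilde = D^{-1/2} A D^{-1/2} the symmetrically normalised
adjacency, followed by a softmax cluster-assignment head

    C = softmax(beta * X_2 W_c).

Training minimises

    L_total = lambda_m * L_m + lambda_p * L_p + lambda_r * L_r

where L_m is the negated modularity -Tr(C^T B C)/(2N) with modularity
matrix B = A - d d^T/(2N), L_p is the mean squared error between each
niche's composition and its soft-cluster-mean reconstruction, and L_r
is the collapse regulariser (K/(N(K-1))) * sum c_jk^2.  Note the
modularity denominators use 2N (the niche count) rather than the
conventional 2m (edge count); this follows the method's definition.

The model is small enough (tens of parameters) that the forward and
backward passes are written directly in numpy; gradients of every loss
term are verified against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

# standard published SeLU constants
_SELU_ALPHA = 1.6732632423543772
_SELU_LAMBDA = 1.0507009873554805

_EPS_MASS = 1e-12  # cluster soft-mass floor in the purity loss


def selu(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1.0))


def selu_grad(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def normalize_adjacency(A: sparse.spmatrix | np.ndarray) -> sparse.csr_matrix:
    """Symmetric normalisation D^{-1/2} A D^{-1/2}.

    Degree-0 (isolated) nodes get zero rows/columns; the self-loop added
    later in the propagation operator still carries their own features.
    """
    A = sparse.csr_matrix(A, dtype=np.float64)
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    D = sparse.diags(inv_sqrt)
    return sparse.csr_matrix(D @ A @ D)


@dataclass
class LossReport:
    """Per-epoch record of the three loss terms and their weighted total."""

    epoch: int
    L_m: float
    L_p: float
    L_r: float
    L_total: float


@dataclass
class GraphData:
    """Precomputed per-sample tensors consumed by the model."""

    A: sparse.csr_matrix          # binary adjacency
    P: sparse.csr_matrix          # A_tilde + I propagation operator
    V: np.ndarray                 # (N, M) composition
    degree: np.ndarray            # (N,) node degrees

    @classmethod
    def from_network(cls, network) -> "GraphData":
        A = sparse.csr_matrix(network.adjacency, dtype=np.float64)
        P = normalize_adjacency(A) + sparse.identity(A.shape[0], format="csr")
        deg = np.asarray(A.sum(axis=1)).ravel()
        return cls(A=A, P=sparse.csr_matrix(P), V=np.asarray(network.composition), degree=deg)


def init_params(
    n_types: int, hidden_dim: int, n_clusters: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Glorot-uniform initialisation of W1 (M,H), W2 (H,H), Wc (H,K)."""

    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    return {
        "W1": glorot(n_types, hidden_dim),
        "W2": glorot(hidden_dim, hidden_dim),
        "Wc": glorot(hidden_dim, n_clusters),
    }


def gcn_forward(
    V: np.ndarray,
    P: sparse.spmatrix,
    params: dict[str, np.ndarray],
    beta: float,
    return_cache: bool = False,
):
    """Embedding + soft assignment; optionally the cache for backprop.

    Returns ``(X2, C)`` or ``(X2, C, cache)``.
    """
    if V.shape[1] != params["W1"].shape[0]:
        raise ValueError(
            f"composition width {V.shape[1]} does not match W1 rows "
            f"{params['W1'].shape[0]}"
        )
    PV = P @ V
    Z1 = PV @ params["W1"]
    X1 = selu(Z1)
    PX1 = P @ X1
    Z2 = PX1 @ params["W2"]
    X2 = selu(Z2)
    logits = beta * (X2 @ params["Wc"])
    C = softmax_rows(logits)
    if not return_cache:
        return X2, C
    cache = {"PV": PV, "Z1": Z1, "X1": X1, "PX1": PX1, "Z2": Z2, "X2": X2, "C": C}
    return X2, C, cache


def cluster_assignment(X2: np.ndarray, Wc: np.ndarray, beta: float) -> np.ndarray:
    """Row-stochastic soft cluster assignment ``softmax(beta * X2 Wc)``."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return softmax_rows(beta * (X2 @ Wc))


# ---------------------------------------------------------------------------
# loss terms: each returns (value, dL/dC)
# ---------------------------------------------------------------------------

def modularity_loss(
    C: np.ndarray, A: sparse.spmatrix | np.ndarray, with_grad: bool = False
):
    """Negated modularity -Tr(C^T B C) / (2N), B = A - d d^T / (2N)."""
    A = sparse.csr_matrix(A, dtype=np.float64)
    n = A.shape[0]
    d = np.asarray(A.sum(axis=1)).ravel()
    AC = A @ C
    dC = d @ C  # (K,)
    BC = AC - np.outer(d, dC) / (2.0 * n)
    value = -float(np.sum(C * BC)) / (2.0 * n)
    if not with_grad:
        return value
    grad = -BC / n  # B symmetric: d Tr(C^T B C) / dC = 2 B C
    return value, grad


def purity_loss(C: np.ndarray, V: np.ndarray, with_grad: bool = False):
    """Mean squared reconstruction error of compositions by soft cluster means.

    The cluster centroid is the C-weighted mean composition
    ``v*_k = sum_j c_jk v_j / sum_j c_jk``; clusters with vanishing soft
    mass fall back to the global mean composition (treated as constant).
    """
    n, m = V.shape
    mass = C.sum(axis=0)  # (K,)
    empty = mass < _EPS_MASS
    safe_mass = np.where(empty, 1.0, mass)
    centroids = (C.T @ V) / safe_mass[:, None]  # (K, M)
    if empty.any():
        centroids[empty] = V.mean(axis=0)
    R = V - C @ centroids  # (N, M) residual
    value = float(np.sum(R**2)) / (n * m)
    if not with_grad:
        return value
    # direct path through C @ centroids
    G = -(2.0 / (n * m)) * (R @ centroids.T)
    # path through the centroids themselves (skip empty clusters: constant)
    G_cent = -(2.0 / (n * m)) * (C.T @ R)  # (K, M)
    G_cent[empty] = 0.0
    T = G_cent / safe_mass[:, None]
    G += V @ T.T - np.sum(T * centroids, axis=1)[None, :]
    return value, G


def regularization_loss(C: np.ndarray, with_grad: bool = False):
    """Collapse regulariser (K/(N(K-1))) * sum_jk c_jk^2.

    Bounded in [1/(K-1), K/(K-1)]: minimised by the uniform assignment,
    maximised by any one-hot assignment.
    """
    n, k = C.shape
    coef = k / (n * (k - 1))
    value = coef * float(np.sum(C**2))
    if not with_grad:
        return value
    return value, 2.0 * coef * C


def total_loss_and_grads(
    graph: GraphData, params: dict[str, np.ndarray], config
) -> tuple[LossReport, dict[str, np.ndarray]]:
    """Weighted loss on one graph plus analytic parameter gradients."""
    X2, C, cache = gcn_forward(graph.V, graph.P, params, config.beta, return_cache=True)

    lm, g_m = modularity_loss(C, graph.A, with_grad=True)
    lp, g_p = purity_loss(C, graph.V, with_grad=True)
    lr, g_r = regularization_loss(C, with_grad=True)
    total = config.lambda_m * lm + config.lambda_p * lp + config.lambda_r * lr
    G_C = config.lambda_m * g_m + config.lambda_p * g_p + config.lambda_r * g_r

    # softmax backprop (row-wise Jacobian)
    G_logits = C * (G_C - np.sum(G_C * C, axis=1, keepdims=True))
    G_S = config.beta * G_logits  # logits = beta * X2 Wc

    grads = {}
    grads["Wc"] = cache["X2"].T @ G_S
    G_X2 = G_S @ params["Wc"].T
    G_Z2 = G_X2 * selu_grad(cache["Z2"])
    grads["W2"] = cache["PX1"].T @ G_Z2
    G_X1 = graph.P.T @ G_Z2 @ params["W2"].T
    G_Z1 = G_X1 * selu_grad(cache["Z1"])
    grads["W1"] = cache["PV"].T @ G_Z1

    report = LossReport(epoch=-1, L_m=lm, L_p=lp, L_r=lr, L_total=total)
    return report, grads


class Adam:
    """Adam optimiser over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train(
    networks: list, config, callback=None
) -> tuple[dict[str, np.ndarray], list[LossReport]]:
    """Fit the pooling model on one or more per-sample niche networks.

    A batch is a set of per-sample graphs; per-graph losses are averaged
    within the batch.  Stops at ``max_epochs`` or once the total loss
    has improved by less than ``early_stop_tol`` for
    ``early_stop_patience`` consecutive epochs.

    Returns the trained parameters and the per-epoch loss trace (terms
    averaged over all graphs each epoch).  Fully deterministic given
    ``config.seed``.
    """
    if not networks:
        raise ValueError("need at least one niche network")
    graphs = [GraphData.from_network(nw) for nw in networks]
    m = graphs[0].V.shape[1]
    rng = np.random.default_rng(config.seed)
    params = init_params(m, config.hidden_dim, config.n_clusters, rng)
    opt = Adam(params, lr=config.learning_rate)
    batch_size = config.batch_size or min(len(graphs), 10)

    history: list[LossReport] = []
    best = np.inf
    stall = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(graphs))
        sums = np.zeros(4)
        for start in range(0, len(graphs), batch_size):
            batch = order[start : start + batch_size]
            acc = None
            batch_terms = np.zeros(4)
            for gi in batch:
                rep, grads = total_loss_and_grads(graphs[gi], params, config)
                if not np.isfinite(rep.L_total):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: L_m={rep.L_m}, "
                        f"L_p={rep.L_p}, L_r={rep.L_r}"
                    )
                batch_terms += (rep.L_m, rep.L_p, rep.L_r, rep.L_total)
                if acc is None:
                    acc = grads
                else:
                    for k in acc:
                        acc[k] += grads[k]
            for k in acc:
                acc[k] /= len(batch)
            opt.step(params, acc)
            sums += batch_terms
        lm, lp, lr_, lt = sums / len(graphs)
        report = LossReport(epoch=epoch, L_m=lm, L_p=lp, L_r=lr_, L_total=lt)
        history.append(report)
        if callback is not None:
            callback(report)
        if best - lt < config.early_stop_tol:
            stall += 1
            if stall >= config.early_stop_patience:
                break
        else:
            stall = 0
        best = min(best, lt)
    return params, history
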