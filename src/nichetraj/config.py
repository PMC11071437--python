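"""Run configuration for niche-trajectory analysis.

All defaults follow the published workflow: niches are built from the
k=50 nearest neighbours of each anchoring cell, the Gaussian association
scale sigma_j is the distance to the 20th nearest neighbour, the graph
encoder uses a hidden width of 4, the pooling temperature is beta=0.03,
and the three loss terms are weighted lambda_m=0.3, lambda_p=300,
lambda_r=0.1 under Adam with learning rate 0.03 for at most 1000 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class RunConfig:
    """Hyperparameters of the full niche-trajectory pipeline.

    Parameters
    ----------
    k_neighbors : int
        Number of nearest neighbours forming each niche (the niche is the
        anchoring cell plus its ``k_neighbors`` nearest neighbours).
    sigma_index : int
        The Gaussian association scale ``sigma_j`` of niche *j* is the
        distance from the anchor to its ``sigma_index``-th nearest
        neighbour.
    hidden_dim : int
        Width of the two graph-convolution layers.
    n_clusters : int
        Number of niche clusters K.
    beta : float
        Softmax temperature of the probabilistic cluster assignment.
    lambda_m, lambda_p, lambda_r : float
        Weights of the modularity, purity and collapse-regularisation
        loss terms.
    learning_rate : float
        Adam step size.
    max_epochs : int
        Upper bound on training epochs.
    batch_size : int or None
        Number of per-sample graphs per optimisation step; ``None`` means
        ``min(n_samples, 10)``.
    early_stop_tol, early_stop_patience
        Training stops early once the total loss has improved by less
        than ``early_stop_tol`` for ``early_stop_patience`` consecutive
        epochs.
    seed : int
        Seed for parameter initialisation (and any sampling).
    """

    k_neighbors: int = 50
    sigma_index: int = 20
    hidden_dim: int = 4
    n_clusters: int = 6
    beta: float = 0.03
    lambda_m: float = 0.3
    lambda_p: float = 300.0
    lambda_r: float = 0.1
    learning_rate: float = 0.03
    max_epochs: int = 1000
    batch_size: int | None = None
    early_stop_tol: float = 1e-6
    early_stop_patience: int = 50
    seed: int = 42
    catch_all_type: str = "other"
    column_aliases: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma_index < 1:
            raise ValueError("sigma_index must be >= 1")
        if self.k_neighbors < self.sigma_index:
            raise ValueError(
                f"k_neighbors ({self.k_neighbors}) must be >= sigma_index "
                f"({self.sigma_index})"
            )
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        for name in ("lambda_m", "lambda_p", "lambda_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)
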