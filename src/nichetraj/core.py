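"""Model/Results interface over the niche-trajectory pipeline.

`NicheTrajectory` holds the validated cell table and run configuration
and builds the per-sample niche networks; `fit()` trains the graph
pooling model and returns a `NicheTrajectoryResults` carrying the
trained parameters, soft cluster assignments, the cluster ordering and
all NT scores, plus diagnostics (loss trace, summary table) and
plotting/evaluation helpers.

Example
-------
>>> from nichetraj import NicheTrajectory, simulate_dataset
>>> data = simulate_dataset(seed=0)
>>> model = NicheTrajectory.from_dataframe(data.cells)
>>> res = model.fit()
>>> res.cell_scores  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from . import evaluate as _evaluate
from . import gcn, io, trajectory as _traj
from .config import RunConfig
from .niche import build_niche_network


class NicheTrajectory:
    """Niche-trajectory model for a (possibly multi-sample) cell table.

    Parameters
    ----------
    cells : DataFrame
        Validated cell table (``cell_id, sample, x, y, cell_type``).
    config : RunConfig, optional
        Hyperparameters; defaults follow the published workflow.

    All samples share one trained model: per-sample niche networks are
    built independently (no edges across samples) and their losses are
    averaged during training, while the cluster graph aggregates the
    block-diagonal union of the per-sample adjacencies.
    """

    def __init__(self, cells: pd.DataFrame, config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.cells = io.validate_cell_table(
            cells, catch_all_type=self.config.catch_all_type
        )
        self.cell_types = np.asarray(self.cells["cell_type"].cat.categories)
        self.samples = list(dict.fromkeys(self.cells["sample"]))
        self.networks = [
            build_niche_network(
                self.cells,
                sample,
                self.config.k_neighbors,
                self.config.sigma_index,
                self.cell_types,
            )
            for sample in self.samples
        ]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: RunConfig | None = None,
                       **config_overrides) -> "NicheTrajectory":
        if config is None and config_overrides:
            config = RunConfig(**config_overrides)
        return cls(df, config)

    @classmethod
    def from_csv(cls, path, sep: str = ",", config: RunConfig | None = None,
                 **config_overrides) -> "NicheTrajectory":
        if config is None and config_overrides:
            config = RunConfig(**config_overrides)
        cfg = config or RunConfig()
        cells = io.read_cell_table(
            path, sep=sep, aliases=cfg.column_aliases, catch_all_type=cfg.catch_all_type
        )
        return cls(cells, cfg)

    def fit(self, seed: int | None = None, callback=None) -> "NicheTrajectoryResults":
        """Train the pooling model and construct the trajectory.

        Parameters
        ----------
        seed : int, optional
            Overrides ``config.seed`` for parameter initialisation.
        callback : callable, optional
            Called with each epoch's :class:`~nichetraj.gcn.LossReport`.
        """
        config = self.config
        if seed is not None:
            d = config.to_dict()
            d["seed"] = seed
            config = RunConfig.from_dict(d)
        params, history = gcn.train(self.networks, config, callback=callback)
        return NicheTrajectoryResults(self, config, params, history)


class NicheTrajectoryResults:
    """Fitted niche trajectory: assignments, ordering and NT scores."""

    def __init__(self, model: NicheTrajectory, config: RunConfig,
                 params: dict, history: list):
        self.model = model
        self.config = config
        self.params = params
        self.history = history

        # per-sample soft assignments under the common trained model
        self._C_per_sample = []
        for nw in model.networks:
            graph = gcn.GraphData.from_network(nw)
            _, C = gcn.gcn_forward(graph.V, graph.P, params, config.beta)
            self._C_per_sample.append(C)
        self.assignments = np.vstack(self._C_per_sample)

        # cluster graph over the block-diagonal union of sample adjacencies
        A_union = sparse.block_diag(
            [nw.adjacency for nw in model.networks], format="csr"
        )
        self.trajectory = _traj.build_trajectory(self.assignments, A_union)

        self.niche_scores = _traj.nt_scores(self.assignments, self.trajectory.ordering)
        offs = np.cumsum([0] + [nw.n_niches for nw in model.networks])
        cell_scores = []
        for i, nw in enumerate(model.networks):
            s = self.niche_scores[offs[i] : offs[i + 1]]
            cell_scores.append(_traj.cell_nt_scores(nw.assoc_weights, s))
        self.cell_scores = np.concatenate(cell_scores)

    # -- orientation ---------------------------------------------------
    def reverse(self) -> "NicheTrajectoryResults":
        """Flip the trajectory direction: every score s becomes 1 - s."""
        out = object.__new__(NicheTrajectoryResults)
        out.model, out.config, out.params, out.history = (
            self.model, self.config, self.params, self.history,
        )
        out._C_per_sample = self._C_per_sample
        out.assignments = self.assignments
        out.trajectory = self.trajectory.reverse()
        out.niche_scores = 1.0 - self.niche_scores
        out.cell_scores = 1.0 - self.cell_scores
        return out

    # -- tabular views -------------------------------------------------
    def cell_scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.model.cells["sample"].to_numpy(),
                "cell_id": self.model.cells["cell_id"].to_numpy(),
                "cell_type": self.model.cells["cell_type"].astype(str).to_numpy(),
                "cell_NT_score": self.cell_scores,
            }
        )

    def niche_scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.model.cells["sample"].to_numpy(),
                "cell_id": self.model.cells["cell_id"].to_numpy(),
                "niche_NT_score": self.niche_scores,
            }
        )

    def cluster_probabilities_frame(self) -> pd.DataFrame:
        k = self.config.n_clusters
        frame = pd.DataFrame(
            self.assignments, columns=[f"cluster_{i}" for i in range(k)]
        )
        frame.insert(0, "cell_id", self.model.cells["cell_id"].to_numpy())
        frame.insert(0, "sample", self.model.cells["sample"].to_numpy())
        return frame

    def ordering_frame(self) -> pd.DataFrame:
        ordering = self.trajectory.ordering
        return pd.DataFrame(
            {
                "position": np.arange(1, len(ordering) + 1),
                "cluster": ordering,
                "score": self.trajectory.cluster_scores[ordering],
            }
        )

    def loss_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"epoch": r.epoch, "L_m": r.L_m, "L_p": r.L_p,
                 "L_r": r.L_r, "L_total": r.L_total}
                for r in self.history
            ]
        )

    # -- evaluation ----------------------------------------------------
    def evaluate_against(self, truth) -> _evaluate.EvalReport:
        """Orientation-aligned Spearman correlation against a ground truth."""
        rho, flipped = _evaluate.spearman_aligned(self.cell_scores, truth)
        return _evaluate.EvalReport(spearman_aligned=rho, orientation_flipped=flipped)

    def density_along_trajectory(self, n_bins: int = 100) -> pd.DataFrame:
        return _evaluate.density_along_nt(
            self.cell_scores, self.model.cells["cell_type"], n_bins=n_bins
        )

    def stratify(self, cutoff: float = 0.17) -> pd.Series:
        return _evaluate.stratify_by_nt(self.cell_scores, cutoff)

    def save(self, out_dir) -> dict:
        """Write all result tables (see :func:`nichetraj.io.write_results`)."""
        return io.write_results(out_dir, self)

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fitted trajectory."""
        k = self.config.n_clusters
        ordering = self.trajectory.ordering
        lines = [
            "Niche Trajectory Results",
            "=" * 60,
            f"cells: {len(self.cell_scores)}   samples: {len(self.model.samples)}"
            f"   cell types: {len(self.model.cell_types)}   clusters: {k}",
            f"epochs run: {len(self.history)}   "
            f"final loss: {self.history[-1].L_total:.6f} "
            f"(L_m={self.history[-1].L_m:.4f}, L_p={self.history[-1].L_p:.6f}, "
            f"L_r={self.history[-1].L_r:.4f})",
            f"cluster ordering: {' -> '.join(str(c) for c in ordering)}",
            "",
            f"{'cluster':>8} {'score':>7} {'soft size':>10}",
        ]
        sizes = self.assignments.sum(axis=0)
        for pos, c in enumerate(ordering):
            lines.append(
                f"{c:>8} {self.trajectory.cluster_scores[c]:>7.3f} {sizes[c]:>10.1f}"
            )
        lines.append("")
        s = self.cell_scores
        lines.append(
            f"cell NT scores: min={s.min():.3f}  median={np.median(s):.3f}  "
            f"max={s.max():.3f}"
        )
        return "\n".join(lines)

    def plot_spatial(self, ax=None, sample: str | None = None):
        """Scatter of cells coloured by cell-level NT score."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        cells = self.model.cells
        mask = np.ones(len(cells), dtype=bool)
        if sample is not None:
            mask = (cells["sample"] == sample).to_numpy()
        sc = ax.scatter(
            cells["x"][mask], cells["y"][mask], c=self.cell_scores[mask],
            s=8, cmap="viridis", vmin=0, vmax=1,
        )
        ax.set_aspect("equal")
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        plt.colorbar(sc, ax=ax, label="cell NT score")
        return ax

    def plot_density(self, ax=None, n_bins: int = 100):
        """Per-cell-type density along the trajectory coordinate."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        dens = self.density_along_trajectory(n_bins=n_bins)
        for t, row in dens.iterrows():
            ax.plot(dens.columns, row, label=str(t))
        ax.set_xlabel("NT score")
        ax.set_ylabel("density")
        ax.legend(fontsize=7, ncol=2)
        return ax
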