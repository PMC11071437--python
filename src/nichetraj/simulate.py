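"""Synthetic two-lineage spatial benchmark with known trajectory.

The generator emulates a bifurcating differentiation process embedded in
space: 1,000 cells from 10 cell types (A-J) in two lineages.  Each cell
carries a simulated time t in [0, 1]; lineage-1 cells (types A-G, binned
by time) are placed on circles whose radius is the rescaled time (max
radius 1), so their spatial position encodes their trajectory position
radially.  Lineage-2 cells (types H-J) are scattered area-uniformly in
the unit disk, so their type labels carry no spatial information — the
structure that defeats purely expression-based pseudotime orderings.
The ground-truth cell-level trajectory coordinate is the radius for
every cell.

An optional 135-gene count matrix (35 transcription factors, 50 targets,
50 housekeeping genes) mirrors the shape of the expression data the
benchmark is modelled on; it is a lightweight surrogate and is not
consumed by the core method, which uses only cell types and coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LINEAGE1_TYPES = ("A", "B", "C", "D", "E", "F", "G")
LINEAGE2_TYPES = ("H", "I", "J")

N_TF_GENES = 35
N_TARGET_GENES = 50
N_HOUSEKEEPING_GENES = 50
N_GENES = N_TF_GENES + N_TARGET_GENES + N_HOUSEKEEPING_GENES


@dataclass
class SyntheticDataset:
    """Generated cells plus ground truth.

    ``cells`` is a standard cell table (cell_id, sample, x, y, cell_type)
    with extra columns ``lineage``, ``sim_time`` and ``radius`` (the
    ground-truth trajectory coordinate).  ``expression`` is the optional
    gene count matrix (cells x 135 genes).
    """

    cells: pd.DataFrame
    expression: pd.DataFrame | None
    seed: int

    @property
    def ground_truth(self) -> np.ndarray:
        return self.cells["radius"].to_numpy()


def simulate_lineages(
    n_cells: int = 1000,
    seed: int | np.random.Generator = 0,
    lineage1_fraction: float = 0.7,
) -> pd.DataFrame:
    """Lineage labels, simulated times and cell types.

    Each cell draws a simulated time t ~ Uniform(0, 1) standing in for
    its position along the differentiation trajectory.  Lineage 1 holds
    a ``lineage1_fraction`` share of cells (default 7:3, proportional to
    the 7 vs 3 type counts) and its times are binned into 7 equal
    intervals giving types A-G; lineage 2 uses 3 equal bins for H-J.
    """
    if n_cells < 10:
        raise ValueError("need at least 10 cells to populate all 10 types")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = int(round(n_cells * lineage1_fraction))
    lineage = np.r_[np.ones(n1, dtype=int), np.full(n_cells - n1, 2, dtype=int)]
    t = rng.uniform(0.0, 1.0, size=n_cells)

    types = np.empty(n_cells, dtype=object)
    bins1 = np.minimum((t[:n1] * len(LINEAGE1_TYPES)).astype(int), len(LINEAGE1_TYPES) - 1)
    types[:n1] = np.asarray(LINEAGE1_TYPES, dtype=object)[bins1]
    bins2 = np.minimum((t[n1:] * len(LINEAGE2_TYPES)).astype(int), len(LINEAGE2_TYPES) - 1)
    types[n1:] = np.asarray(LINEAGE2_TYPES, dtype=object)[bins2]

    return pd.DataFrame({"lineage": lineage, "sim_time": t, "cell_type": types})


def assign_spatial(
    lineages: np.ndarray,
    sim_times: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Spatial embedding and ground-truth radius.

    Lineage-1 cell i sits on the circle of radius ``r_i = t_i / max(t)``
    (max over lineage-1 cells, so the largest radius is exactly 1) at a
    uniform random angle.  Lineage-2 cells are placed area-uniformly in
    the unit disk.  The ground-truth trajectory coordinate is
    ``sqrt(x^2 + y^2)`` for every cell.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lineages = np.asarray(lineages)
    t = np.asarray(sim_times, dtype=np.float64)
    if not np.isfinite(t).all():
        raise ValueError("simulated times must be finite")
    n = len(t)
    x = np.empty(n)
    y = np.empty(n)
    r = np.empty(n)

    in1 = lineages == 1
    if in1.any():
        r1 = t[in1] / t[in1].max()
        theta = rng.uniform(0.0, 2.0 * np.pi, size=int(in1.sum()))
        x[in1] = r1 * np.cos(theta)
        y[in1] = r1 * np.sin(theta)
        r[in1] = r1
    in2 = ~in1
    if in2.any():
        n2 = int(in2.sum())
        r2 = np.sqrt(rng.uniform(0.0, 1.0, size=n2))  # area-uniform
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n2)
        x[in2] = r2 * np.cos(theta)
        y[in2] = r2 * np.sin(theta)
        r[in2] = r2
    return pd.DataFrame({"x": x, "y": y, "radius": r})


def gene_names() -> list[str]:
    return (
        [f"TF_{i + 1}" for i in range(N_TF_GENES)]
        + [f"Target_{i + 1}" for i in range(N_TARGET_GENES)]
        + [f"HK_{i + 1}" for i in range(N_HOUSEKEEPING_GENES)]
    )


def expression_means(cells: pd.DataFrame) -> pd.DataFrame:
    """Noise-free per-cell gene expression means.

    TF and target gene means drift linearly (hence monotonically) with
    simulated time within their active lineage — even-indexed dynamic
    genes respond in lineage 1, odd-indexed in lineage 2 — while
    housekeeping means are identical across types, times and lineages.
    """
    n = len(cells)
    t = cells["sim_time"].to_numpy()
    lineage = cells["lineage"].to_numpy()
    means = np.empty((n, N_GENES))
    base = 5.0
    n_dyn = N_TF_GENES + N_TARGET_GENES
    slopes = np.linspace(2.0, 20.0, n_dyn)
    for g in range(n_dyn):
        active = 1 if g % 2 == 0 else 2
        drift = np.where(lineage == active, slopes[g] * t, 0.0)
        means[:, g] = base + drift
    means[:, n_dyn:] = 30.0  # housekeeping
    return pd.DataFrame(means, columns=gene_names(), index=cells["cell_id"].to_numpy())


def simulate_expression(
    cells: pd.DataFrame, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Surrogate 135-gene count matrix (35 TF + 50 target + 50 housekeeping).

    Counts are negative binomial around the :func:`expression_means`
    profiles.  Cosmetic output only — the core method never reads it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = expression_means(cells).to_numpy()
    dispersion = 2.0  # NB size parameter
    p = dispersion / (dispersion + means)
    counts = rng.negative_binomial(dispersion, p)
    return pd.DataFrame(counts, columns=gene_names(), index=cells["cell_id"].to_numpy())


def simulate_dataset(
    n_cells: int = 1000,
    seed: int = 0,
    lineage1_fraction: float = 0.7,
    with_expression: bool = False,
    sample: str = "sim0",
) -> SyntheticDataset:
    """Full benchmark dataset: cells, coordinates, ground truth, expression.

    Deterministic given ``seed``: the same seed reproduces the dataset
    bit for bit.
    """
    rng = np.random.default_rng(seed)
    lin = simulate_lineages(n_cells, rng, lineage1_fraction)
    pos = assign_spatial(lin["lineage"].to_numpy(), lin["sim_time"].to_numpy(), rng)
    cells = pd.concat([lin, pos], axis=1)
    cells.insert(0, "sample", sample)
    cells.insert(0, "cell_id", [f"cell_{i:04d}" for i in range(n_cells)])
    expr = simulate_expression(cells, rng) if with_expression else None
    return SyntheticDataset(cells=cells, expression=expr, seed=seed)
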