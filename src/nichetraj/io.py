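"""Reading, validating and writing cell tables and result tables.

The package's input convention is a delimited text table with one row
per cell and five columns: ``cell_id``, ``sample``, ``x``, ``y`` and
``cell_type``.  Header matching is case-insensitive and common aliases
(``Cell_ID``, ``id``, ``celltype`` ...) are accepted; users can extend
the alias map through :class:`~nichetraj.config.RunConfig`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("nichetraj")

REQUIRED_COLUMNS = ("cell_id", "sample", "x", "y", "cell_type")

#: built-in header aliases, all compared lower-case with ``-``/`` `` → ``_``
DEFAULT_ALIASES: dict[str, str] = {
    "cell_id": "cell_id",
    "cellid": "cell_id",
    "cell": "cell_id",
    "id": "cell_id",
    "cell_name": "cell_id",
    "sample": "sample",
    "sample_id": "sample",
    "slice": "sample",
    "section": "sample",
    "x": "x",
    "x_coord": "x",
    "x_coordinate": "x",
    "y": "y",
    "y_coord": "y",
    "y_coordinate": "y",
    "cell_type": "cell_type",
    "celltype": "cell_type",
    "type": "cell_type",
    "annotation": "cell_type",
}


class CellTableFormatError(ValueError):
    """Raised when the input file does not have the expected columns."""


class CellTableValidationError(ValueError):
    """Raised when the table content violates an invariant."""


def _canonical(name: str) -> str:
    return name.strip().lower().replace("-", "_").replace(" ", "_")


def read_cell_table(
    path: str | Path,
    sep: str = ",",
    aliases: dict[str, str] | None = None,
    catch_all_type: str | None = None,
) -> pd.DataFrame:
    """Read and validate a per-cell table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    sep
        Field delimiter (comma by default).
    aliases
        Extra ``header -> canonical column`` mappings merged over the
        built-in alias map.
    catch_all_type
        If given, rows with an empty/NA cell type are relabelled to this
        catch-all class instead of being rejected (mirroring the use of
        an ``other`` class for unannotated cells in real datasets).

    Returns
    -------
    pandas.DataFrame
        Columns ``cell_id, sample, x, y, cell_type``; ``cell_id`` and
        ``sample`` as strings, coordinates as float64, ``cell_type`` as
        a categorical.

    Raises
    ------
    CellTableFormatError
        A required column is missing.
    CellTableValidationError
        Duplicate cell ids within a sample, non-numeric coordinates, or
        missing values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update({_canonical(k): v for k, v in aliases.items()})

    df = pd.read_csv(path, sep=sep, dtype=str)
    rename = {}
    for col in df.columns:
        canon = alias_map.get(_canonical(col))
        if canon is not None and canon not in rename.values():
            rename[col] = canon
    df = df.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableFormatError(
            f"input file {path} is missing required column(s): "
            f"{', '.join(missing)} (found: {', '.join(df.columns)})"
        )
    df = df[list(REQUIRED_COLUMNS)].copy()
    return validate_cell_table(df, catch_all_type=catch_all_type)


def validate_cell_table(
    df: pd.DataFrame, catch_all_type: str | None = None
) -> pd.DataFrame:
    """Validate an in-memory cell table (same contract as the reader)."""
    df = df.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableFormatError(
            f"cell table is missing required column(s): {', '.join(missing)}"
        )

    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = list(df.index[bad][:5])
            raise CellTableValidationError(
                f"non-numeric {col} coordinate at row(s) {rows}"
            )
        df[col] = coerced.astype(np.float64)

    ct = df["cell_type"].astype("string")
    blank = ct.isna() | (ct.str.strip() == "")
    if blank.any():
        if catch_all_type is None:
            rows = list(df.index[blank][:5])
            raise CellTableValidationError(
                f"missing cell_type at row(s) {rows}; pass a catch-all "
                "type to relabel unannotated cells"
            )
        ct = ct.mask(blank, catch_all_type)
        logger.info(
            "relabelled %d cells with empty cell_type to %r",
            int(blank.sum()), catch_all_type,
        )
    df["cell_type"] = ct

    if df[["x", "y"]].isna().any().any():
        raise CellTableValidationError("missing coordinates after parsing")
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise CellTableValidationError("non-finite coordinates in input")
    if df["cell_id"].isna().any() or df["sample"].isna().any():
        raise CellTableValidationError("missing cell_id or sample values")

    df["cell_id"] = df["cell_id"].astype(str)
    df["sample"] = df["sample"].astype(str)

    dup = df.duplicated(subset=["sample", "cell_id"])
    if dup.any():
        examples = df.loc[dup, ["sample", "cell_id"]].head(3)
        raise CellTableValidationError(
            "duplicate cell_id within a sample: "
            + "; ".join(f"{s}/{c}" for s, c in examples.itertuples(index=False))
        )

    df["cell_type"] = pd.Categorical(df["cell_type"])
    if len(df["cell_type"].cat.categories) < 1:
        raise CellTableValidationError("no cell types present")
    df = df.reset_index(drop=True)
    return df


def write_results(out_dir: str | Path, results, config=None) -> dict[str, Path]:
    """Write all result tables of a fitted niche-trajectory run.

    Produces delimited tables keyed by ``sample``/``cell_id`` so they
    join back onto the input: per-cell NT scores, per-niche NT scores,
    per-niche cluster probabilities, the cluster ordering with its
    equally spaced scores, the cluster connectivity matrix, the training
    loss trace, and a YAML run-metadata file with config and seed.

    Parameters
    ----------
    out_dir
        Output directory, created if absent.
    results
        A :class:`~nichetraj.core.NicheTrajectoryResults`.
    config
        Optional :class:`~nichetraj.config.RunConfig`; defaults to the
        one stored on ``results``.

    Returns
    -------
    dict mapping logical table name to the written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config if config is not None else results.config

    paths = {}

    cell = results.cell_scores_frame()
    paths["cell_nt_score"] = out_dir / "cell_NT_score.csv"
    cell.to_csv(paths["cell_nt_score"], index=False)

    niche = results.niche_scores_frame()
    paths["niche_nt_score"] = out_dir / "niche_NT_score.csv"
    niche.to_csv(paths["niche_nt_score"], index=False)

    probs = results.cluster_probabilities_frame()
    paths["cluster_probabilities"] = out_dir / "niche_cluster_probabilities.csv"
    probs.to_csv(paths["cluster_probabilities"], index=False)

    ordering = results.ordering_frame()
    paths["cluster_ordering"] = out_dir / "cluster_ordering.csv"
    ordering.to_csv(paths["cluster_ordering"], index=False)

    conn = pd.DataFrame(
        results.trajectory.connectivity_norm,
        index=[f"cluster_{k}" for k in range(results.config.n_clusters)],
        columns=[f"cluster_{k}" for k in range(results.config.n_clusters)],
    )
    paths["cluster_connectivity"] = out_dir / "cluster_connectivity.csv"
    conn.to_csv(paths["cluster_connectivity"])

    loss = results.loss_frame()
    paths["loss_trace"] = out_dir / "loss_trace.csv"
    loss.to_csv(paths["loss_trace"], index=False)

    meta = {
        "config": config.to_dict(),
        "n_cells": int(len(cell)),
        "n_samples": int(cell["sample"].nunique()),
        "n_epochs_run": int(len(loss)),
        "final_loss": float(loss["L_total"].iloc[-1]),
    }
    paths["run_metadata"] = out_dir / "run_metadata.yaml"
    with open(paths["run_metadata"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)

    return paths


def save_checkpoint(path: str | Path, params: dict[str, np.ndarray], seed: int) -> None:
    """Dump trained parameters to a JSON text checkpoint (shapes + seed recorded)."""
    payload = {
        "seed": int(seed),
        "params": {
            k: {"shape": list(v.shape), "data": v.ravel().tolist()}
            for k, v in params.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], int]:
    payload = json.loads(Path(path).read_text())
    params = {
        k: np.asarray(v["data"], dtype=np.float64).reshape(v["shape"])
        for k, v in payload["params"].items()
    }
    return params, int(payload["seed"])
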