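"""Reading and writing of the pipeline's file formats.

Everything is plain text: beta matrices as tab-delimited files with a
header row of node ids (one file per participant x condition), node and
behavior tables as TSV, weighted/binary matrices as delimited text with
node-id headers (to prevent node-order bugs), partitions as two-column
TSV, reports as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .community import Partition
from .construction import BetaSeriesSet, BinaryNetwork, WeightedNetwork

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_node_table",
    "write_node_table",
    "write_matrix",
    "read_matrix",
    "write_partition",
    "read_partition",
    "write_json",
    "read_json",
    "write_cohort",
]

log = logging.getLogger("betaconn")


def write_beta_matrix(path, values: np.ndarray, node_ids: list[str]) -> None:
    df = pd.DataFrame(values, columns=node_ids)
    df.to_csv(path, sep="\t", index=False)


def read_beta_matrix(
    path,
    participant: str = "",
    condition: str = "",
    node_ids: list[str] | None = None,
) -> BetaSeriesSet:
    """Read a trials x nodes beta matrix (TSV with node-id header).

    Validates the header against ``node_ids`` when given (same nodes, in
    the same order); blank trailing lines are accepted and logged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", skip_blank_lines=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse beta matrix: {exc}") from exc
    blank = df.isna().all(axis=1)
    if blank.any():
        if not blank.iloc[len(df) - blank.sum():].all():
            raise ValueError(f"{path}: blank line inside the trial block")
        log.info("%s: %d blank trailing line(s) ignored", path, int(blank.sum()))
        df = df[~blank]
    if node_ids is not None:
        file_ids = list(df.columns)
        if file_ids != list(node_ids):
            bad = [c for c in file_ids if c not in node_ids] or [
                c for c in node_ids if c not in file_ids
            ]
            raise ValueError(
                f"{path}: header does not match the node table "
                f"(offending column(s): {bad[:5]})"
            )
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at trial {i + 1}, "
            f"column {df.columns[j]!r}"
        )
    return BetaSeriesSet(
        values=values,
        participant=participant,
        condition=condition,
        node_ids=list(df.columns),
    )


def write_node_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_node_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(path, m: np.ndarray, node_ids: list[str]) -> None:
    pd.DataFrame(m, columns=node_ids).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_partition(path, partition: Partition, node_ids: list[str]) -> None:
    pd.DataFrame(
        {"node_id": node_ids, "community": partition.assignment}
    ).to_csv(path, sep="\t", index=False)


def read_partition(path) -> tuple[Partition, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return (
        Partition(assignment=df["community"].to_numpy(dtype=int)),
        list(df["node_id"]),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, set):
        return sorted(obj)
    return obj


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_cohort(outdir, cohort, node_table: pd.DataFrame) -> list[Path]:
    """Write a synthetic cohort to disk: one beta matrix per participant
    x condition, the node table, behavior table and ground-truth JSON.
    Returns the list of files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    beta_dir = outdir / "beta"
    beta_dir.mkdir(exist_ok=True)
    for (pid, cond), values in cohort.beta.items():
        safe_cond = cond.replace("+", "plus").replace("-", "minus")
        p = beta_dir / f"{pid}_{safe_cond}.tsv"
        write_beta_matrix(p, values, cohort.node_ids)
        written.append(p)
    p = outdir / "nodes.tsv"
    write_node_table(p, node_table)
    written.append(p)
    p = outdir / "behavior.tsv"
    cohort.behavior.to_csv(p, sep="\t", index=False)
    written.append(p)
    truth = cohort.truth
    p = outdir / "ground_truth.json"
    write_json(
        p,
        {
            "partition": truth.partition,
            "target_node": truth.target_node,
            "role_profile": {k: v for k, v in truth.role_profile.items()},
            "rho_in": truth.rho_in,
            "rho_out": truth.rho_out,
            "n_trials": truth.n_trials,
            "n_participants": truth.n_participants,
            "behavior_r": truth.behavior_r,
            "seed": truth.seed,
            "n_strong": truth.n_strong,
            "rho_target": truth.rho_target,
            "attach": truth.attach,
            "n_bridge_per_module": truth.n_bridge_per_module,
            "rho_bridge": truth.rho_bridge,
            "spread_jitter": truth.spread_jitter,
        },
    )
    written.append(p)
    return written
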