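"""Reading and writing of the artifact's on-disk formats.

Everything is plain text: TSV for tables and matrices, JSON for partitions
and group tests, YAML/JSON for configuration.  Floats in matrix files are
written with 10 significant digits so that re-runs with an identical seed
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .types import NODE_TABLE_COLUMNS, FCMatrix, NodeTable, Partition

FLOAT_FMT = "%.10g"


# -- node table ---------------------------------------------------------------

def read_node_table(path: str | Path) -> NodeTable:
    frame = pd.read_csv(path, sep="\t", dtype={"node_id": str, "structure_tag": str})
    frame["is_cortical"] = frame["is_cortical"].astype(bool)
    return NodeTable(frame=frame[NODE_TABLE_COLUMNS])


def write_node_table(table: NodeTable, path: str | Path) -> None:
    frame = table.frame.copy()
    frame["is_cortical"] = frame["is_cortical"].astype(bool)
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# -- FC matrices --------------------------------------------------------------

def read_fc_matrix(path: str | Path, subject_id: str | None = None) -> FCMatrix:
    """Read an FC TSV whose first row/column hold node ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    node_ids = [str(c) for c in frame.columns]
    values = frame.to_numpy(dtype=float)
    if subject_id is None:
        subject_id = Path(path).stem
    return FCMatrix(
        node_ids=node_ids,
        values=values,
        subject_id=subject_id,
        nonnegative=bool(values.min() >= 0.0),
    )


def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(fc.values, index=fc.node_ids, columns=fc.node_ids)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT)


# -- partitions ---------------------------------------------------------------

def read_partition(path: str | Path) -> Partition:
    with open(path) as fh:
        payload = json.load(fh)
    return Partition(
        labels={str(k): int(v) for k, v in payload["labels"].items()},
        level_tag=payload.get("level_tag", "whole_brain"),
    )


def write_partition(p: Partition, path: str | Path) -> None:
    payload = {"level_tag": p.level_tag, "labels": {k: int(v) for k, v in p.labels.items()}}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


# -- generic tables / json ----------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(payload: dict[str, Any], path: str | Path) -> None:
    def _default(obj: Any) -> Any:
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_default)
        fh.write("\n")


def read_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError(f"config at {path} is not a mapping")
    return payload
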