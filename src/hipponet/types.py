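"""Core domain types shared by every analysis stage.

Node identity (``node_id``) is the join key everywhere: matrix row order is
defined by the owning :class:`NodeTable` (or the ``node_ids`` sequence carried
alongside each matrix), never by positional convention alone.  This prevents
silent misalignment between connectivity values, centroids and partitions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NodeTable",
    "FCMatrix",
    "Partition",
    "canonicalize_partition",
    "IncompletePartitionError",
]

#: Columns of the node-table TSV, in file order.
NODE_TABLE_COLUMNS = [
    "node_id",
    "name",
    "hemisphere",
    "x_mm",
    "y_mm",
    "z_mm",
    "is_cortical",
    "structure_tag",
]


class IncompletePartitionError(ValueError):
    """A partition fails to label every node of its owning matrix."""


@dataclass(frozen=True)
class NodeTable:
    """Region-of-interest metadata: identity, hemisphere, MNI centroid.

    Parameters
    ----------
    frame
        DataFrame with columns ``node_id, name, hemisphere, x_mm, y_mm, z_mm,
        is_cortical, structure_tag``.  ``node_id`` values must be unique,
        centroids finite, and hemisphere one of ``{"L", "R"}`` for every node.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in NODE_TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"node table missing columns: {missing}")
        ids = self.frame["node_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate node_ids: {dup}")
        cent = self.frame[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(cent)):
            raise ValueError("non-finite centroid coordinates")
        bad_hemi = set(self.frame["hemisphere"].unique()) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"hemisphere must be L or R, got {sorted(bad_hemi)}")

    @property
    def node_ids(self) -> list[str]:
        return self.frame["node_id"].tolist()

    @property
    def centroids(self) -> np.ndarray:
        """(n, 3) array of MNI centroids in millimetres, in table order."""
        return self.frame[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    def centroid_of(self, node_id: str) -> np.ndarray:
        row = self.frame.loc[self.frame["node_id"] == node_id]
        if row.empty:
            raise KeyError(node_id)
        return row[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)[0]

    @property
    def cortical_ids(self) -> list[str]:
        mask = self.frame["is_cortical"].astype(bool)
        return self.frame.loc[mask, "node_id"].tolist()

    def ids_with_tag(self, tag: str) -> list[str]:
        return self.frame.loc[self.frame["structure_tag"] == tag, "node_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class FCMatrix:
    """Symmetric region-by-region functional connectivity in Fisher-z units.

    ``values[i, j]`` is the Fisher z-transformed Pearson correlation
    ``atanh(r)`` between the time series of ``node_ids[i]`` and
    ``node_ids[j]``.  The diagonal is stored as 0 by convention.  Derived
    accessors expose node strength ``k_i = sum_j w_ij`` and total weight
    ``m = (1/2) sum_ij w_ij``.
    """

    node_ids: list[str]
    values: np.ndarray
    subject_id: str = "unknown"
    nonnegative: bool = False

    _SYM_TOL = 1e-10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} node_ids"
            )
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node_ids in FCMatrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite FC values")
        if not np.allclose(self.values, self.values.T, atol=self._SYM_TOL, rtol=0.0):
            raise ValueError("FC matrix not symmetric within 1e-10")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("FC diagonal must be stored as 0")
        if self.nonnegative and self.values.min() < 0.0:
            raise ValueError("nonnegative flag set but negative entries present")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def strengths(self) -> np.ndarray:
        """Node strength k_i = sum_j w_ij."""
        return self.values.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """m = (1/2) sum_ij w_ij."""
        return float(self.values.sum()) / 2.0

    def index_of(self, node_ids: Iterable[str]) -> np.ndarray:
        pos = {nid: i for i, nid in enumerate(self.node_ids)}
        try:
            return np.asarray([pos[nid] for nid in node_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"node {exc.args[0]!r} not in FCMatrix") from exc

    def submatrix(self, node_ids: Sequence[str]) -> "FCMatrix":
        """Restrict to ``node_ids`` (in the given order)."""
        idx = self.index_of(node_ids)
        return FCMatrix(
            node_ids=list(node_ids),
            values=self.values[np.ix_(idx, idx)].copy(),
            subject_id=self.subject_id,
            nonnegative=self.nonnegative,
        )

    def without_nodes(self, removed: Iterable[str]) -> "FCMatrix":
        removed = set(removed)
        keep = [nid for nid in self.node_ids if nid not in removed]
        return self.submatrix(keep)

    def thresholded_nonnegative(self) -> "FCMatrix":
        """Copy with negative edges set to 0 (edge dropped, node kept)."""
        vals = np.where(self.values < 0.0, 0.0, self.values)
        return FCMatrix(
            node_ids=list(self.node_ids),
            values=vals,
            subject_id=self.subject_id,
            nonnegative=True,
        )


@dataclass
class Partition:
    """A node -> community labelling.

    After :func:`canonicalize_partition`, labels are ``1..K`` ordered by
    descending community size, ties broken by the smallest member ``node_id``.
    """

    labels: dict[str, int]
    level_tag: str = "whole_brain"

    @property
    def node_ids(self) -> list[str]:
        return list(self.labels.keys())

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for nid, lab in self.labels.items():
            out.setdefault(lab, []).append(nid)
        return out

    def members(self, label: int) -> list[str]:
        return [nid for nid, lab in self.labels.items() if lab == label]

    def as_array(self, node_ids: Sequence[str]) -> np.ndarray:
        """Labels as an int array aligned to ``node_ids`` order."""
        try:
            return np.asarray([self.labels[nid] for nid in node_ids], dtype=int)
        except KeyError as exc:
            raise IncompletePartitionError(
                f"incomplete partition: node {exc.args[0]!r} unlabeled"
            ) from exc

    def relabeled(self, mapping: Mapping[int, int]) -> "Partition":
        return Partition(
            labels={nid: mapping[lab] for nid, lab in self.labels.items()},
            level_tag=self.level_tag,
        )


def canonicalize_partition(p: Partition) -> Partition:
    """Relabel communities 1..K by descending size, smallest-member tie-break.

    Pure and idempotent: applying it to any label permutation of the same
    grouping yields the identical output.  The numbering rule is an artifact
    convention — community-detection output is only defined up to label
    permutation.
    """
    if not p.labels:
        raise IncompletePartitionError("incomplete partition: no labels")
    groups = p.communities()
    # sort key: (-size, min node_id) over each community's member list
    order = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    mapping = {old: new for new, (old, _) in enumerate(order, start=1)}
    return p.relabeled(mapping)


def require_same_nodes(p1: Partition, p2: Partition) -> list[str]:
    """Shared node list (sorted) of two partitions; error on mismatch."""
    s1, s2 = set(p1.labels), set(p2.labels)
    if s1 != s2:
        only1 = sorted(s1 - s2)[:5]
        only2 = sorted(s2 - s1)[:5]
        raise ValueError(
            f"partition node sets differ (e.g. only in first: {only1}, "
            f"only in second: {only2})"
        )
    return sorted(s1)
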