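"""Weighted Louvain community detection with resolution selection.

The detection procedure: at each resolution gamma, the Louvain algorithm is
run many times from random node orders; each resulting partition is scored
by ``Q x mean pairwise z-Rand`` (modularity times consistency with the other
runs at that gamma); the best-scoring partition represents the gamma; and
the chosen gamma is the one whose representative both maximizes the
weighted score and separates the primary sensory-motor seed networks.

Modularity uses the Newman–Girvan form with a resolution parameter,

    Q = (1/2m) * sum_ij [ w_ij - gamma * k_i k_j / 2m ] * delta(c_i, c_j),

and the z-Rand score is the pair-counting z-statistic of Traud et al.: the
number of node pairs co-clustered by both partitions, standardized by its
exact mean and variance under the permutation (hypergeometric) model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._utils import child_seeds, substream
from .types import FCMatrix, Partition, canonicalize_partition, require_same_nodes

logger = logging.getLogger("hipponet")

__all__ = [
    "modularity",
    "louvain",
    "zrand",
    "adjusted_rand",
    "label_agreement",
    "SweepRecord",
    "SweepResult",
    "SelectionCriteria",
    "SelectionError",
    "sweep_and_select",
    "SubnetworkSolution",
    "partition_subnetwork",
    "score_peaks",
    "DegenerateGraphError",
]

#: Whole-brain resolution grid used in the reference analysis: 1 to 2.8 by 0.005.
WHOLE_BRAIN_GAMMA_GRID = np.round(np.arange(1.0, 2.8 + 1e-9, 0.005), 3)
#: Subnetwork re-partition grid: 0.75 to 1.1 by 0.05.
SUBNETWORK_GAMMA_GRID = np.round(np.arange(0.75, 1.1 + 1e-9, 0.05), 2)

_MOVE_TOL = 1e-12


class DegenerateGraphError(ValueError):
    """Graph with zero total weight cannot be partitioned meaningfully."""


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def modularity_dense(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Resolution-parameterized modularity on a dense weight matrix."""
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m <= 0.0:
        raise DegenerateGraphError("degenerate graph: total weight is zero")
    q = 0.0
    for lab in np.unique(labels):
        idx = labels == lab
        q += w[np.ix_(idx, idx)].sum() - gamma * k[idx].sum() ** 2 / two_m
    return q / two_m


def modularity(fc: FCMatrix, p: Partition, gamma: float = 1.0) -> float:
    """Modularity Q of partition ``p`` on the (nonnegative) FC graph."""
    if fc.values.min() < 0.0:
        raise ValueError("nonnegative matrix required")
    labels = p.as_array(fc.node_ids)
    return modularity_dense(fc.values, labels, gamma)


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

def _compact_labels(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out


def _move_nodes(
    w: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Local-move phase: greedy single-node reassignments until no Q gain.

    ``w`` may carry self-loops on the diagonal (aggregated graphs); node
    strength includes them, link weights to communities exclude them.
    """
    n = w.shape[0]
    k = w.sum(axis=1)
    two_m = k.sum()
    labels = np.arange(n) if init is None else init.copy()
    comm_tot = np.bincount(labels, weights=k, minlength=n)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = labels[i]
            wi = w[i].copy()
            wi[i] = 0.0
            neigh_w = np.bincount(labels, weights=wi, minlength=n)
            comm_tot[ci] -= k[i]
            gains = neigh_w - gamma * k[i] * comm_tot / two_m
            best = int(np.argmax(gains))
            if gains[best] > gains[ci] + _MOVE_TOL:
                labels[i] = best
                improved = True
            comm_tot[labels[i]] += k[i]
    return _compact_labels(labels)


def _aggregate(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Collapse communities to super-nodes; internal weight becomes self-loops."""
    k = labels.max() + 1
    onehot = np.zeros((w.shape[0], k))
    onehot[np.arange(w.shape[0]), labels] = 1.0
    return onehot.T @ w @ onehot


def louvain_dense(
    w: np.ndarray, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-phase Louvain on a dense nonnegative matrix; returns label array.

    Node visitation order is a seeded shuffle per pass.  A final local-move
    refinement on the original graph guarantees the output is a genuine
    single-node local optimum of Q.
    """
    if w.min() < 0.0:
        raise ValueError("nonnegative matrix required")
    if w.sum() <= 0.0:
        raise DegenerateGraphError("degenerate graph: total weight is zero")
    labels_full = _move_nodes(w, gamma, rng)
    wc = _aggregate(w, labels_full)
    while wc.shape[0] > 1:
        coarse = _move_nodes(wc, gamma, rng)
        if coarse.max() + 1 == wc.shape[0]:
            break
        labels_full = coarse[labels_full]
        wc = _aggregate(wc, coarse)
    # final refinement at the original node level
    labels_full = _move_nodes(w, gamma, rng, init=labels_full)
    return labels_full


def louvain(fc: FCMatrix, gamma: float, seed: int) -> Partition:
    """Seed-deterministic weighted Louvain; canonicalized output labels."""
    rng = np.random.default_rng(int(seed))
    labels = louvain_dense(fc.values, gamma, rng)
    p = Partition(
        labels={nid: int(lab) + 1 for nid, lab in zip(fc.node_ids, labels)},
        level_tag="whole_brain",
    )
    return canonicalize_partition(p)


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------

def _contingency(l1: np.ndarray, l2: np.ndarray) -> np.ndarray:
    u1, i1 = np.unique(l1, return_inverse=True)
    u2, i2 = np.unique(l2, return_inverse=True)
    table = np.zeros((len(u1), len(u2)), dtype=np.int64)
    np.add.at(table, (i1, i2), 1)
    return table


def zrand_from_labels(l1: np.ndarray, l2: np.ndarray) -> float:
    """z-Rand score of two label arrays over the same node order.

    Pair-counting z-statistic: the number w of node pairs placed together by
    both labelings, standardized by its exact mean and variance under random
    permutation of one labeling (Brennan–Light moments).  Symmetric and
    invariant to label renaming.  Degenerate cases with zero permutation
    variance (all-singletons or a single community) return 0.
    """
    n = len(l1)
    if n != len(l2):
        raise ValueError("label arrays differ in length")
    if n < 4:
        raise ValueError("z-Rand needs at least 4 nodes")
    table = _contingency(l1, l2)
    a = table.sum(axis=1).astype(float)
    b = table.sum(axis=0).astype(float)
    nf = float(n)
    m = nf * (nf - 1.0) / 2.0
    m1 = float((a * (a - 1.0) / 2.0).sum())
    m2 = float((b * (b - 1.0) / 2.0).sum())
    tf = table.astype(float)
    w = float((tf * (tf - 1.0) / 2.0).sum())

    c1 = nf * (nf**2 - 3.0 * nf - 2.0) - 8.0 * (nf + 1.0) * m1 + 4.0 * (a**3).sum()
    c2 = nf * (nf**2 - 3.0 * nf - 2.0) - 8.0 * (nf + 1.0) * m2 + 4.0 * (b**3).sum()
    var = (
        m / 16.0
        - ((4.0 * m1 - 2.0 * m) ** 2) * ((4.0 * m2 - 2.0 * m) ** 2) / (256.0 * m**2)
        + c1 * c2 / (16.0 * nf * (nf - 1.0) * (nf - 2.0))
        + (
            ((4.0 * m1 - 2.0 * m) ** 2 - 4.0 * c1 - 4.0 * m)
            * ((4.0 * m2 - 2.0 * m) ** 2 - 4.0 * c2 - 4.0 * m)
        )
        / (64.0 * nf * (nf - 1.0) * (nf - 2.0) * (nf - 3.0))
    )
    if var <= 0.0:
        return 0.0
    return (w - m1 * m2 / m) / np.sqrt(var)


def zrand(p1: Partition, p2: Partition) -> float:
    """z-Rand score of two partitions of the same node set."""
    nodes = require_same_nodes(p1, p2)
    return zrand_from_labels(p1.as_array(nodes), p2.as_array(nodes))


def adjusted_rand(p1: Partition, p2: Partition) -> float:
    """Adjusted Rand index (chance-corrected pair agreement)."""
    nodes = require_same_nodes(p1, p2)
    table = _contingency(p1.as_array(nodes), p2.as_array(nodes)).astype(float)
    n = float(len(nodes))
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    sum_ij = (table * (table - 1.0) / 2.0).sum()
    sum_a = (a * (a - 1.0) / 2.0).sum()
    sum_b = (b * (b - 1.0) / 2.0).sum()
    m = n * (n - 1.0) / 2.0
    expected = sum_a * sum_b / m
    maxi = (sum_a + sum_b) / 2.0
    if maxi == expected:
        return 1.0
    return float((sum_ij - expected) / (maxi - expected))


def label_agreement(p1: Partition, p2: Partition) -> float:
    """Fraction of nodes with matched labels after optimal community matching.

    Communities of ``p2`` are matched one-to-one to communities of ``p1`` by
    maximum-weight bipartite matching on shared-node counts; the returned
    fraction counts nodes inside matched community pairs.
    """
    nodes = require_same_nodes(p1, p2)
    table = _contingency(p1.as_array(nodes), p2.as_array(nodes))
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum()) / len(nodes)


# ---------------------------------------------------------------------------
# resolution sweep and selection
# ---------------------------------------------------------------------------

@dataclass
class SweepRecord:
    """All candidate partitions produced at one resolution."""

    gamma: float
    partitions: list[np.ndarray]  # label arrays aligned to node_ids
    node_ids: list[str]
    q_values: np.ndarray
    mean_zrand: np.ndarray
    passes_criteria: bool = True
    failure_reason: str = ""

    @property
    def weighted_score(self) -> np.ndarray:
        """Q x mean pairwise z-Rand, the selection score of each partition."""
        return self.q_values * self.mean_zrand

    @property
    def representative_index(self) -> int:
        return int(np.argmax(self.weighted_score))

    @property
    def representative_score(self) -> float:
        return float(self.weighted_score[self.representative_index])

    def representative_partition(self, level_tag: str = "whole_brain") -> Partition:
        labels = self.partitions[self.representative_index]
        p = Partition(
            labels={nid: int(lab) + 1 for nid, lab in zip(self.node_ids, labels)},
            level_tag=level_tag,
        )
        return canonicalize_partition(p)


@dataclass
class SelectionCriteria:
    """Programmatic form of the sensory-separation requirement.

    ``sensory_seed_sets`` maps network names (visual, auditory, somatomotor)
    to small seed-node lists.  A partition passes when the modal community of
    each seed set is distinct from every other seed set's modal community.
    """

    sensory_seed_sets: dict[str, list[str]] = field(default_factory=dict)
    require_separation: bool = True

    def __post_init__(self) -> None:
        if self.require_separation:
            seen: set[str] = set()
            for name, ids in self.sensory_seed_sets.items():
                if not ids:
                    raise ValueError(f"empty seed set for {name!r}")
                overlap = seen & set(ids)
                if overlap:
                    raise ValueError(f"seed sets overlap on {sorted(overlap)}")
                seen |= set(ids)

    def check(self, p: Partition) -> tuple[bool, str]:
        if not self.require_separation or not self.sensory_seed_sets:
            return True, ""
        modal: dict[str, int] = {}
        for name, ids in self.sensory_seed_sets.items():
            labs = [p.labels[i] for i in ids]
            modal[name] = max(set(labs), key=labs.count)
        names = list(modal)
        for i, na in enumerate(names):
            for nb in names[i + 1 :]:
                if modal[na] == modal[nb]:
                    return False, f"{na} and {nb} share modal community {modal[na]}"
        return True, ""


class SelectionError(RuntimeError):
    """No resolution satisfied the selection criteria."""


def _pairwise_mean_zrand(partitions: list[np.ndarray]) -> np.ndarray:
    """Mean z-Rand of each partition vs. all others (unordered pairs).

    Identical partitions are grouped first so that z-Rand is evaluated once
    per unique pair of groupings — a large saving at stable resolutions.
    """
    n = len(partitions)
    if n < 2:
        raise ValueError("need at least 2 partitions per resolution")
    keys = [tuple(lab) for lab in partitions]
    uniq: dict[tuple, int] = {}
    group_of = np.empty(n, dtype=int)
    for i, key in enumerate(keys):
        group_of[i] = uniq.setdefault(key, len(uniq))
    g = len(uniq)
    reps = [None] * g
    for i, gi in enumerate(group_of):
        if reps[gi] is None:
            reps[gi] = partitions[i]
    counts = np.bincount(group_of, minlength=g).astype(float)
    z = np.zeros((g, g))
    for a in range(g):
        for b in range(a, g):
            z[a, b] = z[b, a] = zrand_from_labels(reps[a], reps[b])
    # mean over the other n-1 partitions, counting duplicates
    totals = z @ counts - np.diag(z)  # exclude self once
    return totals[group_of] / (n - 1)


def sweep_gamma(
    fc: FCMatrix,
    gamma: float,
    n_iter: int,
    seed: int,
) -> SweepRecord:
    """Run Louvain ``n_iter`` times at one resolution and score each run."""
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    w = fc.values
    seeds = child_seeds(seed, f"louvain@{gamma:.6f}", n_iter)
    partitions = [
        louvain_dense(w, gamma, np.random.default_rng(int(s))) for s in seeds
    ]
    q_values = np.array([modularity_dense(w, lab, gamma) for lab in partitions])
    mean_z = _pairwise_mean_zrand(partitions)
    return SweepRecord(
        gamma=float(gamma),
        partitions=partitions,
        node_ids=list(fc.node_ids),
        q_values=q_values,
        mean_zrand=mean_z,
    )


@dataclass
class SweepResult:
    records: list[SweepRecord]
    chosen_gamma: float
    chosen_partition: Partition

    def report_frame(self):
        """Long table: gamma, iteration, Q, mean_zrand, weighted_score."""
        import pandas as pd

        rows = []
        for rec in self.records:
            ws = rec.weighted_score
            for it in range(len(rec.partitions)):
                rows.append(
                    (rec.gamma, it, rec.q_values[it], rec.mean_zrand[it], ws[it])
                )
        return pd.DataFrame(
            rows, columns=["gamma", "iteration", "Q", "mean_zrand", "weighted_score"]
        )


def sweep_and_select(
    fc: FCMatrix,
    gammas: Sequence[float],
    n_iter: int,
    crit: SelectionCriteria,
    seed: int,
) -> SweepResult:
    """Resolution sweep with modularity-weighted z-Rand selection.

    At each gamma the representative partition is the run maximizing
    ``Q x mean_zrand``; the chosen gamma maximizes the representative score
    among resolutions whose representative passes the sensory-separation
    criteria.  Raises :class:`SelectionError` (listing per-gamma failures)
    when no resolution qualifies.
    """
    if fc.values.min() < 0.0:
        raise ValueError("nonnegative matrix required")
    records: list[SweepRecord] = []
    for gamma in gammas:
        rec = sweep_gamma(fc, float(gamma), n_iter, seed)
        ok, reason = crit.check(rec.representative_partition())
        rec.passes_criteria = ok
        rec.failure_reason = reason
        records.append(rec)
    passing = [rec for rec in records if rec.passes_criteria]
    if not passing:
        failures = "; ".join(
            f"gamma={rec.gamma:g}: {rec.failure_reason}" for rec in records
        )
        raise SelectionError(f"no resolution satisfied criteria ({failures})")
    best = max(passing, key=lambda rec: rec.representative_score)
    logger.info(
        "sweep: chose gamma=%g (weighted score %.4f) among %d/%d passing",
        best.gamma,
        best.representative_score,
        len(passing),
        len(records),
    )
    return SweepResult(
        records=records,
        chosen_gamma=best.gamma,
        chosen_partition=best.representative_partition(),
    )


# ---------------------------------------------------------------------------
# subnetwork re-partitioning
# ---------------------------------------------------------------------------

def score_peaks(scores: np.ndarray) -> list[int]:
    """Indices of local maxima of a score profile over the gamma grid.

    A local peak strictly exceeds both grid neighbors; endpoints qualify by
    the one-sided comparison (so a monotone profile yields a single endpoint
    peak).  A perfectly flat profile falls back to the global argmax.
    """
    scores = np.asarray(scores, dtype=float)
    peaks: list[int] = []
    for i in range(len(scores)):
        left_ok = i == 0 or scores[i] > scores[i - 1]
        right_ok = i == len(scores) - 1 or scores[i] > scores[i + 1]
        if left_ok and right_ok:
            peaks.append(i)
    if not peaks:
        peaks = [int(np.argmax(scores))]
    return peaks


@dataclass
class SubnetworkSolution:
    gamma: float
    partition: Partition
    weighted_score: float
    selected: bool = False


def partition_subnetwork(
    fc: FCMatrix,
    p: Partition,
    community: int,
    gammas: Sequence[float],
    n_iter: int,
    seed: int,
) -> list[SubnetworkSolution]:
    """Re-partition one community over a resolution grid; return score peaks.

    Community detection is repeated on the submatrix restricted to the
    community's nodes; the returned solutions are the partitions at local
    maxima of the representative weighted score over gamma (a local peak
    strictly exceeds both grid neighbors; endpoints qualify one-sided).  The
    global peak is marked ``selected``.
    """
    members = p.members(community)
    if len(members) < 3:
        raise ValueError(
            f"community {community} has {len(members)} nodes; need at least 3"
        )
    members = [nid for nid in fc.node_ids if nid in set(members)]
    sub = fc.submatrix(members)
    dead = [nid for nid, s in zip(sub.node_ids, sub.strengths) if s <= 0.0]
    if dead:
        raise ValueError(f"submatrix has all-zero rows for nodes: {dead}")
    records = [sweep_gamma(sub, float(g), n_iter, seed) for g in gammas]
    scores = np.array([rec.representative_score for rec in records])
    peaks = score_peaks(scores)
    best = peaks[int(np.argmax(scores[peaks]))]
    return [
        SubnetworkSolution(
            gamma=records[i].gamma,
            partition=records[i].representative_partition(level_tag="subnetwork"),
            weighted_score=float(scores[i]),
            selected=(i == best),
        )
        for i in peaks
    ]
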