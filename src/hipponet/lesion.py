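"""Virtual-lesion path-length analysis and participation coefficients.

Connectivity weights are inverted to lengths (``d_ij = 1/w_ij``; absent or
zero-weight edges are infinitely long), geodesics come from Dijkstra, and a
"lesion" deletes a node set before re-measuring the mean shortest-path
length between a source and a target set.  Removal effects are benchmarked
against removal of every other community (paired t-tests), random node
removals (per-subject z-scores, group one-sample t), and a spatially
distance-matched control set.  Connection diversity is quantified by the
participation coefficient ``PC_i = 1 - sum_s (k_is/k_i)^2`` across a range
of proportional edge densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from ._utils import substream
from .types import FCMatrix, NodeTable, Partition

logger = logging.getLogger("hipponet")

__all__ = [
    "GeodesicMatrix",
    "shortest_path_matrix",
    "SetPathLength",
    "setwise_path_length",
    "LesionOutcome",
    "lesion_compare",
    "NullResult",
    "random_removal_null",
    "MatchingError",
    "distance_matched_controls",
    "ParticipationTable",
    "participation_coefficient",
    "DEFAULT_DENSITIES",
]

#: Proportional edge densities 5% to 20% at 1% intervals.
DEFAULT_DENSITIES = np.round(np.arange(0.05, 0.20 + 1e-9, 0.01), 2)


@dataclass
class GeodesicMatrix:
    """All-pairs weighted shortest-path lengths after an optional lesion."""

    node_ids: list[str]
    values: np.ndarray  # n x n, +inf for unreachable pairs, 0 diagonal

    def index_of(self, node_ids: Iterable[str]) -> np.ndarray:
        pos = {nid: i for i, nid in enumerate(self.node_ids)}
        missing = [nid for nid in node_ids if nid not in pos]
        if missing:
            raise ValueError(f"nodes absent from geodesic matrix: {missing}")
        return np.asarray([pos[nid] for nid in node_ids], dtype=int)


def _length_graph(values: np.ndarray) -> csr_matrix:
    """Invert positive weights to lengths; zero weights become absent edges."""
    with np.errstate(divide="ignore"):
        lengths = np.where(values > 0.0, 1.0 / values, 0.0)
    np.fill_diagonal(lengths, 0.0)
    return csr_matrix(lengths)


def shortest_path_matrix(fc: FCMatrix, removed: Iterable[str] = ()) -> GeodesicMatrix:
    """Delete ``removed`` nodes, invert weights to 1/w, run Dijkstra.

    Requires a nonnegative matrix (negative connectivity is excluded
    upstream).  Unreachable pairs are +inf.
    """
    if fc.values.min() < 0.0:
        raise ValueError("nonnegative matrix required for path analysis")
    sub = fc.without_nodes(removed) if removed else fc
    geo = dijkstra(_length_graph(sub.values), directed=False)
    return GeodesicMatrix(node_ids=list(sub.node_ids), values=geo)


@dataclass
class SetPathLength:
    """Mean geodesic between two node sets, with disconnection made visible."""

    mean_length: float
    disconnected_fraction: float
    n_pairs: int


def setwise_path_length(
    geo: GeodesicMatrix, set_a: Sequence[str], set_b: Sequence[str]
) -> SetPathLength:
    """Mean geodesic over all (u in A, v in B) pairs.

    Infinite (disconnected) pairs are excluded from the mean and reported as
    a disconnection fraction that callers must surface.
    """
    if not set_a or not set_b:
        raise ValueError("both node sets must be nonempty")
    if set(set_a) & set(set_b):
        raise ValueError("node sets must be disjoint")
    ia = geo.index_of(set_a)
    ib = geo.index_of(set_b)
    block = geo.values[np.ix_(ia, ib)].ravel()
    finite = np.isfinite(block)
    frac_disc = float((~finite).mean())
    mean = float(block[finite].mean()) if finite.any() else float("inf")
    return SetPathLength(mean, frac_disc, block.size)


def _subject_path_length(
    fc: FCMatrix,
    removed_idx: np.ndarray,
    src_idx: np.ndarray,
    tgt_idx: np.ndarray,
) -> tuple[float, float]:
    """Fast path: setwise length source<->target after removing index set."""
    keep = np.ones(fc.n_nodes, dtype=bool)
    keep[removed_idx] = False
    kept_pos = np.cumsum(keep) - 1
    sub = fc.values[np.ix_(keep, keep)]
    geo = dijkstra(_length_graph(sub), directed=False, indices=kept_pos[src_idx])
    block = geo[:, kept_pos[tgt_idx]].ravel()
    finite = np.isfinite(block)
    mean = float(block[finite].mean()) if finite.any() else float("inf")
    return mean, float((~finite).mean())


@dataclass
class LesionOutcome:
    """Per-subject path lengths for each removal, plus paired comparisons."""

    path_lengths: pd.DataFrame  # columns: subject, removed_set, path_length, disconnected_fraction
    comparisons: pd.DataFrame  # columns: removed_set, t, df, p (focal vs. alternative)
    focal: str = ""


def lesion_compare(
    subject_fcs: Sequence[FCMatrix],
    partition: Partition,
    source_nodes: Sequence[str],
    target_nodes: Sequence[str],
    removal_candidates: Mapping[str, Sequence[str]],
    focal: str,
) -> LesionOutcome:
    """Compare path-length impact of removing the focal set vs. alternatives.

    For each subject and candidate node set, the candidate is deleted and
    the mean source-target geodesic recomputed; the focal removal is then
    compared with every alternative by paired t-test (df = n_subjects - 1).
    Zero-variance differences are flagged with NaN statistics, not a crash.
    """
    if len(subject_fcs) < 2:
        raise ValueError("need at least 2 subjects for paired comparisons")
    if focal not in removal_candidates:
        raise ValueError(f"focal set {focal!r} not among removal candidates")
    src, tgt = set(source_nodes), set(target_nodes)
    for name, nodes in removal_candidates.items():
        bad = (set(nodes) & src) | (set(nodes) & tgt)
        if bad:
            raise ValueError(
                f"removal candidate {name!r} overlaps source/target: {sorted(bad)[:5]}"
            )
    ref_ids = subject_fcs[0].node_ids
    src_idx = subject_fcs[0].index_of(source_nodes)
    tgt_idx = subject_fcs[0].index_of(target_nodes)
    rows = []
    per_set: dict[str, list[float]] = {name: [] for name in removal_candidates}
    for fc in subject_fcs:
        if fc.node_ids != ref_ids:
            raise ValueError(f"subject {fc.subject_id!r} node set differs")
        for name, nodes in removal_candidates.items():
            rm_idx = fc.index_of(nodes)
            mean, frac = _subject_path_length(fc, rm_idx, src_idx, tgt_idx)
            per_set[name].append(mean)
            rows.append((fc.subject_id, name, mean, frac))
    path_lengths = pd.DataFrame(
        rows, columns=["subject", "removed_set", "path_length", "disconnected_fraction"]
    )
    focal_vals = np.asarray(per_set[focal])
    comp_rows = []
    for name, vals in per_set.items():
        if name == focal:
            continue
        diff = focal_vals - np.asarray(vals)
        if np.allclose(diff.std(ddof=1), 0.0):
            logger.warning("paired t undefined (zero variance) for %s vs %s", focal, name)
            t, p = float("nan"), float("nan")
        else:
            t, p = stats.ttest_rel(focal_vals, np.asarray(vals))
        comp_rows.append((name, float(t), len(focal_vals) - 1, float(p)))
    comparisons = pd.DataFrame(comp_rows, columns=["removed_set", "t", "df", "p"])
    return LesionOutcome(path_lengths=path_lengths, comparisons=comparisons, focal=focal)


@dataclass
class NullResult:
    """Random-removal null distribution of path lengths, per subject."""

    k_removed: int
    n_iter: int
    focal_per_subject: np.ndarray
    null_mean_per_subject: np.ndarray
    null_sd_per_subject: np.ndarray
    z_per_subject: np.ndarray  # NaN where the null SD was zero (flagged)
    group_t: float
    group_p: float
    flagged_subjects: list[str] = field(default_factory=list)


def random_removal_null(
    subject_fcs: Sequence[FCMatrix],
    source_nodes: Sequence[str],
    target_nodes: Sequence[str],
    focal_set: Sequence[str],
    k: int,
    n_iter: int,
    seed: int,
    extra_protected: Sequence[str] = (),
    exclude_focal: bool = False,
) -> NullResult:
    """z-score the focal removal against random k-node removals.

    Per subject: ``n_iter`` random draws of ``k`` nodes outside the source,
    target and protected sets are removed, giving a null distribution of
    source-target path lengths; the subject's z is
    ``(focal - null mean) / null SD``, and a one-sample t-test asks whether
    the group of z-scores differs from 0.  Focal nodes stay *in* the null
    pool by default (random draws may overlap the focal set — this is what
    gives the null its variance when the focal set dominates the route);
    set ``exclude_focal`` to carve them out too.
    """
    ref = subject_fcs[0]
    protected = set(source_nodes) | set(target_nodes) | set(extra_protected)
    if exclude_focal:
        protected |= set(focal_set)
    pool = [nid for nid in ref.node_ids if nid not in protected]
    if len(pool) < k:
        raise ValueError(f"only {len(pool)} unprotected nodes available, need k={k}")
    pool_idx = ref.index_of(pool)
    src_idx = ref.index_of(source_nodes)
    tgt_idx = ref.index_of(target_nodes)
    focal_idx = ref.index_of(focal_set)

    n_subj = len(subject_fcs)
    focal_len = np.empty(n_subj)
    null_mean = np.empty(n_subj)
    null_sd = np.empty(n_subj)
    z = np.full(n_subj, np.nan)
    flagged = []
    for s, fc in enumerate(subject_fcs):
        if fc.node_ids != ref.node_ids:
            raise ValueError(f"subject {fc.subject_id!r} node set differs")
        rng = substream(seed, "random_removal_null", s)
        focal_len[s], _ = _subject_path_length(fc, focal_idx, src_idx, tgt_idx)
        draws = np.empty(n_iter)
        for it in range(n_iter):
            rm = rng.choice(pool_idx, size=k, replace=False)
            draws[it], _ = _subject_path_length(fc, rm, src_idx, tgt_idx)
        null_mean[s] = draws.mean()
        null_sd[s] = draws.std(ddof=1)
        if null_sd[s] == 0.0:
            flagged.append(fc.subject_id)
        else:
            z[s] = (focal_len[s] - null_mean[s]) / null_sd[s]
    valid = np.isfinite(z)
    if valid.sum() >= 2:
        group_t, group_p = stats.ttest_1samp(z[valid], 0.0)
    else:
        group_t, group_p = float("nan"), float("nan")
    if flagged:
        logger.warning("null SD zero for subjects: %s", flagged)
    return NullResult(
        k_removed=k,
        n_iter=n_iter,
        focal_per_subject=focal_len,
        null_mean_per_subject=null_mean,
        null_sd_per_subject=null_sd,
        z_per_subject=z,
        group_t=float(group_t),
        group_p=float(group_p),
        flagged_subjects=flagged,
    )


class MatchingError(RuntimeError):
    """No distance-matched control set could be found."""


def _set_distances(
    centroids: np.ndarray, members: np.ndarray, ref_idx: np.ndarray
) -> np.ndarray:
    """Per-member mean Euclidean distance to a reference node set."""
    diffs = centroids[members][:, None, :] - centroids[ref_idx][None, :, :]
    return np.linalg.norm(diffs, axis=2).mean(axis=1)


def distance_matched_controls(
    nodes: NodeTable,
    focal_net: Sequence[str],
    ref_sets: Mapping[str, Sequence[str]],
    size: int,
    seed: int,
    candidates: Sequence[str] | None = None,
    max_sweeps: int = 200,
    n_restarts: int = 20,
) -> list[str]:
    """Find ``size`` non-focal nodes distance-matched to each reference set.

    The target band for each reference set is mean +/- 1 SD of the focal
    network's per-node mean distances to that set; a returned control set's
    *mean* distance to every reference set must lie inside its band.  The
    search is a seeded randomized greedy swap with a bounded budget; raises
    :class:`MatchingError` with the best-achieved deviations on failure.
    """
    ids = nodes.node_ids
    pos = {nid: i for i, nid in enumerate(ids)}
    cent = nodes.centroids
    focal_idx = np.asarray([pos[n] for n in focal_net])
    bands = {}
    ref_idx = {}
    for name, ref in ref_sets.items():
        ref_idx[name] = np.asarray([pos[n] for n in ref])
        d = _set_distances(cent, focal_idx, ref_idx[name])
        bands[name] = (d.mean() - d.std(ddof=1), d.mean() + d.std(ddof=1))
    excluded = set(focal_net)
    for ref in ref_sets.values():
        excluded |= set(ref)
    if candidates is None:
        candidates = [nid for nid in ids if nid not in excluded]
    else:
        candidates = [nid for nid in candidates if nid not in excluded]
    if len(candidates) < size:
        raise ValueError(
            f"candidate pool has {len(candidates)} nodes, need size={size}"
        )
    cand_idx = np.asarray([pos[n] for n in candidates])
    # per-candidate mean distance to each reference set
    dist = {name: _set_distances(cent, cand_idx, ref_idx[name]) for name in ref_sets}
    for name, (lo, hi) in bands.items():
        if dist[name].min() > hi or dist[name].max() < lo:
            raise MatchingError(
                f"infeasible: no candidate within band for reference {name!r}"
            )

    def violation(mask: np.ndarray) -> float:
        tot = 0.0
        for name, (lo, hi) in bands.items():
            mu = dist[name][mask].mean()
            tot += max(0.0, lo - mu) + max(0.0, mu - hi)
        return tot

    rng = substream(seed, "distance_matched_controls")
    n_cand = len(candidates)
    best_overall = None
    best_viol = np.inf
    for _ in range(n_restarts):
        chosen = rng.choice(n_cand, size=size, replace=False)
        mask = np.zeros(n_cand, dtype=bool)
        mask[chosen] = True
        v = violation(mask)
        for _ in range(max_sweeps):
            if v == 0.0:
                break
            inside = np.flatnonzero(mask)
            outside = np.flatnonzero(~mask)
            i = rng.choice(inside)
            j = rng.choice(outside)
            mask[i], mask[j] = False, True
            v_new = violation(mask)
            if v_new < v:
                v = v_new
            else:
                mask[i], mask[j] = True, False
        if v < best_viol:
            best_viol = v
            best_overall = mask.copy()
        if v == 0.0:
            break
    if best_viol > 0.0:
        devs = {
            name: float(dist[name][best_overall].mean()) for name in ref_sets
        }
        raise MatchingError(
            f"no matched control set found; best mean distances {devs}, "
            f"bands {bands}"
        )
    return [candidates[i] for i in np.flatnonzero(best_overall)]


# ---------------------------------------------------------------------------
# participation coefficient
# ---------------------------------------------------------------------------

@dataclass
class ParticipationTable:
    """Per-node participation coefficients across a density sweep."""

    pc_by_density: pd.DataFrame  # index node_id, one column per density
    pc_mean: pd.Series  # NaN for excluded nodes
    excluded_low_strength: pd.Series  # bool per node


def proportional_threshold(values: np.ndarray, density: float) -> np.ndarray:
    """Keep the strongest ``density`` fraction of off-diagonal edges.

    Edges keep their weights.  The retained count is
    ``round(density * n_pairs)`` over upper-triangle pairs; ties at the cut
    are broken by stable (row, col) order.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    n_keep = int(round(density * len(w)))
    order = np.argsort(-w, kind="stable")
    keep = order[:n_keep]
    out = np.zeros_like(values)
    out[iu[keep], ju[keep]] = w[keep]
    out[ju[keep], iu[keep]] = w[keep]
    return out


def participation_from_dense(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """PC_i = 1 - sum_s (k_is / k_i)^2 on a weighted graph; NaN if k_i = 0."""
    k = w.sum(axis=1)
    pc = np.full(w.shape[0], np.nan)
    uniq = np.unique(labels)
    k_is = np.stack([w[:, labels == lab].sum(axis=1) for lab in uniq], axis=1)
    ok = k > 0
    pc[ok] = 1.0 - ((k_is[ok] / k[ok, None]) ** 2).sum(axis=1)
    # PC is bounded in [0, 1]; clamp float round-off at the boundaries
    pc[ok] = np.clip(pc[ok], 0.0, 1.0)
    return pc


def participation_coefficient(
    fc: FCMatrix,
    partition: Partition,
    densities: Sequence[float] = DEFAULT_DENSITIES,
    strength_percentile_cut: float = 0.25,
) -> ParticipationTable:
    """Participation coefficients across proportional densities.

    At each density the strongest fraction of edges is retained (weighted),
    PC computed from community-wise strengths, and ``pc_mean`` averages over
    densities.  Nodes whose full-matrix strength falls in the bottom
    ``strength_percentile_cut`` quantile are flagged excluded and reported
    without a mean (low-strength nodes make PC unstable).  Nodes isolated at
    a density get NaN there and that density is dropped from their mean.
    """
    if fc.values.min() < 0.0:
        raise ValueError("nonnegative matrix required")
    labels = partition.as_array(fc.node_ids)
    strengths = fc.strengths
    cut = np.quantile(strengths, strength_percentile_cut)
    excluded = pd.Series(strengths < cut, index=fc.node_ids)
    cols = {}
    for d in densities:
        wt = proportional_threshold(fc.values, float(d))
        pc = participation_from_dense(wt, labels)
        if np.isnan(pc).any():
            iso = [fc.node_ids[i] for i in np.flatnonzero(np.isnan(pc))]
            logger.info("density %.2f: isolated nodes (PC undefined): %s", d, iso)
        cols[float(d)] = pc
    table = pd.DataFrame(cols, index=fc.node_ids)
    pc_mean = table.mean(axis=1, skipna=True)
    pc_mean[excluded] = np.nan
    return ParticipationTable(
        pc_by_density=table, pc_mean=pc_mean, excluded_low_strength=excluded
    )
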