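"""End-to-end pipeline driver.

Runs the full analysis — FC construction, resolution-swept community
detection, subnetwork re-partitioning, virtual lesions with random and
distance-matched nulls, participation coefficients, hippocampal profiles
and contrasts, representational-profile similarity with confound
residualization, and term decoding — from a single config, writing plain
TSV/JSON outputs.  Deterministic given ``config.seed``: all randomness is
derived from that one seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import communities, io, lesion
from ._utils import array_hash, stage_log
from .connectivity import fc_from_timeseries, group_average_fc, subject_qc
from .decoding import decode_terms
from .hippocampus import hippocampal_contrasts, network_fc_profile
from .rsa import (
    activation_similarity,
    profile_similarity,
    residualize_similarity,
    trial_rdm,
    within_between_contrast,
)
from .synthetic import (
    Coupling,
    GroundTruth,
    SyntheticSpec,
    TrialBlock,
    make_parcellation,
    simulate_subject_timeseries,
    simulate_term_maps,
    simulate_trial_patterns,
)
from .types import FCMatrix, NodeTable, Partition

logger = logging.getLogger("hipponet")

ALL_STAGES = (
    "fc",
    "partition",
    "subnetwork",
    "lesion",
    "participation",
    "hippocampus",
    "rsa",
    "decode",
)


class StageDependencyError(RuntimeError):
    """A stage's required input is unavailable."""


@dataclass
class PipelineConfig:
    """Everything the driver needs; build from YAML/JSON via :meth:`from_dict`."""

    seed: int = 0
    synthetic: SyntheticSpec | None = None
    data_dir: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    gamma_grid: tuple[float, float, float] = (0.5, 3.0, 0.1)
    n_iter: int = 100
    sub_gamma_grid: tuple[float, float, float] = (0.75, 1.1, 0.05)
    n_iter_sub: int = 100
    densities: tuple[float, ...] = tuple(lesion.DEFAULT_DENSITIES)
    fd_max_mm: float = 0.15
    null_k: int = 30
    null_iter: int = 1000
    control_size: int = 20
    n_subjects_rsa: int | None = 22
    top_k_terms: int = 10
    write_subject_fc: bool = False

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "PipelineConfig":
        payload = dict(payload)
        syn = payload.pop("synthetic", None)
        if syn is not None:
            syn = dict(syn)
            if "coupling" in syn:
                syn["coupling"] = Coupling(**syn["coupling"])
            if "trial_block" in syn:
                syn["trial_block"] = TrialBlock(**syn["trial_block"])
            for key in ("networks", "subnetwork_sizes", "bridged"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            syn = SyntheticSpec(**syn)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages",):
            if key in payload:
                payload[key] = tuple(payload[key])
        for key in ("gamma_grid", "sub_gamma_grid", "densities"):
            if key in payload:
                payload[key] = tuple(float(v) for v in payload[key])
        return cls(synthetic=syn, **payload)


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    return np.round(np.arange(lo, hi + step / 2.0, step), 6)


@dataclass
class ResultBundle:
    """In-memory handles to everything the pipeline produced."""

    out_dir: Path
    node_table: NodeTable | None = None
    truth: GroundTruth | None = None
    subject_fcs: list[FCMatrix] = field(default_factory=list)
    group_fc: FCMatrix | None = None
    partition: Partition | None = None
    chosen_gamma: float | None = None
    subnetwork: list[communities.SubnetworkSolution] = field(default_factory=list)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    stats: dict[str, Any] = field(default_factory=dict)


def _modal_community(partition: Partition, nodes: Sequence[str]) -> int:
    labs = [partition.labels[n] for n in nodes]
    return max(set(labs), key=labs.count)


def run_full_pipeline(
    config: PipelineConfig, out_dir: str | Path, seed: int | None = None
) -> ResultBundle:
    """Execute the configured stages; write result tables under ``out_dir``.

    Only the synthetic input mode generates data internally; with a
    ``data_dir`` the driver reads node tables and subject FC matrices, and
    stages whose inputs are absent raise :class:`StageDependencyError`
    naming the stage.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(out_dir=out)
    stages = config.stages

    # ------------------------------------------------------------------ inputs
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        table, truth = make_parcellation(spec)
        bundle.node_table, bundle.truth = table, truth
        io.write_node_table(table, out / "node_table.tsv")
        io.write_partition(truth.network_partition, out / "ground_truth_partition.json")
        with stage_log("simulate", n_subjects=spec.n_subjects, T=spec.T):
            subjects = [
                simulate_subject_timeseries(spec, i, table, truth)
                for i in range(spec.n_subjects)
            ]
    elif config.data_dir is not None:
        data = Path(config.data_dir)
        table = io.read_node_table(data / "node_table.tsv")
        bundle.node_table = table
        spec = None
        truth = None
        subjects = None
    else:
        raise ValueError("config must name either a synthetic spec or a data_dir")

    # ---------------------------------------------------------------------- fc
    if "fc" in stages:
        if subjects is not None:
            qc = subject_qc(subjects, config.fd_max_mm)
            kept = [ts for ts in subjects if ts.subject_id in set(qc.kept)]
            io.write_json(
                {"kept": qc.kept, "excluded": qc.excluded, "unassessable": qc.unassessable},
                out / "qc.json",
            )
            with stage_log("fc", input_hash=array_hash(kept[0].data) if kept else "none", n_kept=len(kept)):
                bundle.subject_fcs = [fc_from_timeseries(ts) for ts in kept]
        else:
            fc_dir = Path(config.data_dir) / "fc"
            if not fc_dir.is_dir():
                raise StageDependencyError(
                    "stage dependency unmet: fc requires time series or an fc/ directory"
                )
            bundle.subject_fcs = [
                io.read_fc_matrix(p) for p in sorted(fc_dir.glob("*.tsv"))
            ]
        if not bundle.subject_fcs:
            raise StageDependencyError("stage dependency unmet: fc produced no subjects")
        bundle.group_fc = group_average_fc(bundle.subject_fcs, exclude_negatives=True)
        io.write_fc_matrix(bundle.group_fc, out / "group_fc.tsv")
        if config.write_subject_fc:
            for fc in bundle.subject_fcs:
                io.write_fc_matrix(fc, out / f"fc_{fc.subject_id}.tsv")

    def _require(stage: str, what: str, obj: Any) -> Any:
        if obj is None or (isinstance(obj, (list, dict)) and not obj):
            raise StageDependencyError(f"stage dependency unmet: {stage} requires {what}")
        return obj

    # ------------------------------------------------------------ partitioning
    cortical = table.cortical_ids
    if "partition" in stages:
        group = _require("partition", "the fc stage", bundle.group_fc)
        cort_fc = group.submatrix(cortical)
        if truth is not None:
            seed_sets = {
                net: truth.network_nodes[net][:3] for net in ("VIS", "AUD", "SMN")
                if net in truth.network_nodes
            }
        else:
            seed_sets = {}
        crit = communities.SelectionCriteria(
            sensory_seed_sets=seed_sets, require_separation=bool(seed_sets)
        )
        gammas = _grid(*config.gamma_grid)
        with stage_log(
            "partition",
            input_hash=array_hash(cort_fc.values),
            n_gamma=len(gammas),
            n_iter=config.n_iter,
        ):
            sweep = communities.sweep_and_select(
                cort_fc, gammas, config.n_iter, crit, seed=config.seed
            )
        bundle.partition = sweep.chosen_partition
        bundle.chosen_gamma = sweep.chosen_gamma
        report = sweep.report_frame()
        io.write_table(report, out / "sweep_report.tsv")
        io.write_partition(sweep.chosen_partition, out / "chosen_partition.json")
        io.write_json({"chosen_gamma": sweep.chosen_gamma}, out / "chosen_gamma.json")
        bundle.tables["sweep_report"] = report

    partition = bundle.partition

    # -------------------------------------------------------------- subnetwork
    if "subnetwork" in stages:
        partition = _require("subnetwork", "the partition stage", partition)
        group = bundle.group_fc.submatrix(cortical)
        if truth is not None:
            target_label = _modal_community(
                partition, truth.network_nodes[spec.subdivided_network]
            )
        else:
            # largest community by default
            sizes = {
                lab: len(m) for lab, m in partition.communities().items()
            }
            target_label = max(sizes, key=sizes.get)
        with stage_log("subnetwork", community=target_label):
            bundle.subnetwork = communities.partition_subnetwork(
                group,
                partition,
                target_label,
                _grid(*config.sub_gamma_grid),
                config.n_iter_sub,
                seed=config.seed,
            )
        for sol in bundle.subnetwork:
            if sol.selected:
                io.write_partition(sol.partition, out / "subnetwork_partition.json")
        io.write_json(
            {
                "peaks": [
                    {"gamma": s.gamma, "weighted_score": s.weighted_score, "selected": s.selected}
                    for s in bundle.subnetwork
                ],
                "community": int(target_label),
            },
            out / "subnetwork_peaks.json",
        )

    # ------------------------------------------------------------------ lesion
    if "lesion" in stages:
        partition = _require("lesion", "the partition stage", partition)
        fcs = [fc.submatrix(cortical).thresholded_nonnegative() for fc in bundle.subject_fcs]
        if truth is None:
            raise StageDependencyError(
                "stage dependency unmet: lesion requires planted network identities "
                "(synthetic mode) or explicit node sets"
            )
        net_label = {
            net: _modal_community(partition, nodes)
            for net, nodes in truth.network_nodes.items()
        }
        comm = partition.communities()
        src_net, tgt_net = truth.bridged
        source = [n for n in comm[net_label[src_net]]]
        target = [n for n in comm[net_label[tgt_net]] if n not in set(source)]
        excluded_labels = {net_label[src_net], net_label[tgt_net]}
        candidates = {
            f"community_{lab}": [n for n in members]
            for lab, members in comm.items()
            if lab not in excluded_labels
        }
        focal = f"community_{net_label[truth.bridge_network]}"
        with stage_log(
            "lesion",
            input_hash=array_hash(fcs[0].values),
            n_candidates=len(candidates),
        ):
            outcome = lesion.lesion_compare(
                fcs, partition, source, target, candidates, focal
            )
        io.write_table(outcome.path_lengths, out / "lesion_path_lengths.tsv")
        io.write_table(outcome.comparisons, out / "lesion_comparisons.tsv")
        bundle.tables["lesion_comparisons"] = outcome.comparisons
        bundle.tables["lesion_path_lengths"] = outcome.path_lengths
        with stage_log("lesion_null", k=config.null_k, n_iter=config.null_iter):
            null = lesion.random_removal_null(
                fcs,
                source,
                target,
                candidates[focal],
                k=min(config.null_k, len(candidates[focal])),
                n_iter=config.null_iter,
                seed=config.seed,
            )
        io.write_table(
            pd.DataFrame(
                {
                    "subject": [fc.subject_id for fc in fcs],
                    "z": null.z_per_subject,
                }
            ),
            out / "lesion_null_z.tsv",
        )
        bundle.stats["lesion_null"] = {
            "mean_z": float(np.nanmean(null.z_per_subject)),
            "group_t": null.group_t,
            "group_p": null.group_p,
        }
        # distance-matched control removal
        try:
            controls = lesion.distance_matched_controls(
                table,
                focal_net=candidates[focal],
                ref_sets={"source": source, "target": target},
                size=min(config.control_size, len(candidates[focal])),
                seed=config.seed,
                candidates=[n for n in cortical],
            )
            ctrl_outcome = lesion.lesion_compare(
                fcs,
                partition,
                source,
                target,
                {focal: candidates[focal], "matched_controls": controls},
                focal,
            )
            io.write_table(ctrl_outcome.comparisons, out / "lesion_matched_control.tsv")
            bundle.tables["lesion_matched_control"] = ctrl_outcome.comparisons
            bundle.stats["matched_controls"] = controls
        except lesion.MatchingError as exc:
            logger.warning("matched-control search failed: %s", exc)
            bundle.stats["matched_controls"] = None
        bundle.stats["lesion_focal"] = focal

    # --------------------------------------------------------- participation
    if "participation" in stages:
        partition = _require("participation", "the partition stage", partition)
        rows = []
        with stage_log("participation", densities=len(config.densities)):
            for fc in bundle.subject_fcs:
                sub = fc.submatrix(cortical).thresholded_nonnegative()
                res = lesion.participation_coefficient(
                    sub, partition, config.densities
                )
                for nid in sub.node_ids:
                    rows.append(
                        (
                            fc.subject_id,
                            nid,
                            float(res.pc_mean[nid]),
                            bool(res.excluded_low_strength[nid]),
                        )
                    )
        pc_frame = pd.DataFrame(rows, columns=["subject", "node_id", "pc_mean", "excluded"])
        io.write_table(pc_frame, out / "participation.tsv")
        bundle.tables["participation"] = pc_frame

    # ----------------------------------------------------------- hippocampus
    if "hippocampus" in stages:
        partition = _require("hippocampus", "the partition stage", partition)
        if truth is None:
            raise StageDependencyError(
                "stage dependency unmet: hippocampus requires tagged hippocampal ROIs"
            )
        profs = []
        with stage_log("hippocampus", n_subjects=len(bundle.subject_fcs)):
            for fc in bundle.subject_fcs:
                profs.append(network_fc_profile(fc, partition, truth.hippo_rois))
        profiles = pd.concat(profs, ignore_index=True)
        contrasts = hippocampal_contrasts(profiles)
        io.write_table(profiles, out / "hippo_profiles.tsv")
        io.write_table(contrasts.membership, out / "hippo_membership.tsv")
        io.write_table(contrasts.axis, out / "hippo_axis_contrast.tsv")
        io.write_table(contrasts.laterality, out / "hippo_laterality_contrast.tsv")
        bundle.tables["hippo_profiles"] = profiles
        bundle.stats["hippo_contrasts"] = contrasts

    # --------------------------------------------------------------------- rsa
    if "rsa" in stages:
        partition = _require("rsa", "the partition stage", partition)
        if config.synthetic is None:
            raise StageDependencyError(
                "stage dependency unmet: rsa requires trial-pattern data"
            )
        n_rsa = config.n_subjects_rsa or spec.n_subjects
        pms = []
        with stage_log("rsa", n_subjects=n_rsa):
            dist = None
            for i in range(n_rsa):
                tps = simulate_trial_patterns(spec, i, table, truth)
                rdms = [trial_rdm(tps, roi) for roi in tps.roi_ids]
                pm = profile_similarity(rdms, subject_id=tps.subject_id)
                act = activation_similarity(tps)
                if dist is None:
                    idx = table.frame.set_index("node_id")
                    cents = idx.loc[pm.roi_ids, ["x_mm", "y_mm", "z_mm"]].to_numpy()
                    diff = cents[:, None, :] - cents[None, :, :]
                    dist = np.linalg.norm(diff, axis=2)
                pm_res = residualize_similarity(pm, act.to_numpy(), "activation")
                pm_res = residualize_similarity(pm_res, dist, "distance")
                pms.append((pm, pm_res))
        raw = within_between_contrast([p for p, _ in pms], partition)
        resid = within_between_contrast([p for _, p in pms], partition)
        io.write_table(raw.per_subject, out / "rsa_within_between.tsv")
        io.write_json(
            {
                "raw": {"t": raw.t, "df": raw.df, "p": raw.p},
                "residualized": {"t": resid.t, "df": resid.df, "p": resid.p},
            },
            out / "rsa_group_test.json",
        )
        bundle.stats["rsa"] = {"raw": raw, "residualized": resid}

    # ------------------------------------------------------------------ decode
    if "decode" in stages:
        partition = _require("decode", "the partition stage", partition)
        if truth is None:
            raise StageDependencyError(
                "stage dependency unmet: decode requires a term-map stack"
            )
        stack = simulate_term_maps(spec, truth)
        # masks are built from the detected partition labels: every grid
        # element of a node assigned to the community is marked
        node_pos = {nid: i for i, nid in enumerate(truth.cortical_node_ids)}
        net_of_label = {
            _modal_community(partition, nodes): net
            for net, nodes in truth.network_nodes.items()
        }
        frames = []
        with stage_log("decode", n_terms=len(stack.terms)):
            for lab, members in sorted(partition.communities().items()):
                member_idx = [node_pos[n] for n in members if n in node_pos]
                mask = np.isin(truth.node_of_element, member_idx).astype(float)
                ranked = decode_terms(mask, stack, top_k=config.top_k_terms)
                ranked.insert(0, "network", net_of_label.get(lab, f"community_{lab}"))
                ranked.insert(0, "community", lab)
                frames.append(ranked)
        decode_frame = pd.concat(frames, ignore_index=True)
        io.write_table(decode_frame, out / "decoding.tsv")
        bundle.tables["decoding"] = decode_frame

    return bundle
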