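"""Synthetic multi-subject data with planted ground truth.

Everything the pipeline consumes can be generated here: ROI tables with
spatially coherent network clusters, subject time series whose correlation
structure plants a hierarchical community layout, trial-level multivoxel
patterns with network-shared tuning, and term-map stacks concentrated on
given networks.

The time-series generator is a latent-factor model: one latent signal per
network, one per subnetwork of the subdivided network, one per bridge
channel, and one global background latent.  Node series are weighted sums
of their latents plus Gaussian noise, so time series, FC, lesion topology
and the hippocampal gradient all emerge from a single mechanism whose
parameters are loadings rather than target correlations.

Planted motifs:

* six networks (visual, auditory, somatomotor, frontoparietal, a
  default-mode analogue ``DMN`` and a medial-temporal analogue ``MTN``);
* ``DMN`` subdivided into three subnetworks;
* a bridge: ``VIS`` and ``DMN`` share *no* latent; each shares one bridge
  channel with ``MTN``, so their direct FC is ~0 while both couple to the
  bridge — removing ``MTN`` severs the only strong ``VIS``-``DMN`` route;
* a shared sensorimotor background latent coupling ``AUD`` and ``SMN``
  more strongly than any other network pair, so that low resolutions merge
  the two primary sensory-motor networks and the resolution sweep must move
  upward before the sensory-separation criterion is met — the behaviour
  that motivates tuning the resolution in the first place;
* ``FPN`` placed at the spatial mirror image of ``MTN`` relative to the
  ``VIS``/``DMN`` clusters, so a distance-matched control set exists by
  construction;
* four hippocampal nodes (anterior/posterior x L/R) with a long-axis
  connectivity gradient: anterior loads more on ``MTN``, posterior more on
  ``DMN``;
* per-network trial tuning plus univariate-amplitude and spatial-proximity
  confounds in the trial patterns;
* one planted term map per network plus pure-noise filler terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._utils import substream
from .connectivity import ROITimeSeries
from .decoding import TermMapStack
from .rsa import TrialPatternSet
from .types import NodeTable, Partition

__all__ = [
    "Coupling",
    "TrialBlock",
    "SyntheticSpec",
    "GroundTruth",
    "make_parcellation",
    "simulate_subject_timeseries",
    "simulate_trial_patterns",
    "simulate_term_maps",
    "network_mask",
]

#: Fixed cluster centres (mm, MNI-like) for the default six networks.
#: FPN mirrors MTN across the x=0 plane so its nodes sit at the same
#: distances to VIS and DMN — the feasible distance-matched control pool.
_NETWORK_CENTERS = {
    "VIS": (0.0, -80.0, -5.0),
    "AUD": (-55.0, -25.0, 8.0),
    "SMN": (0.0, -25.0, 62.0),
    "FPN": (32.0, -20.0, -12.0),
    "DMN": (0.0, 45.0, 30.0),
    "MTN": (-32.0, -20.0, -12.0),
}

_HIPPO_CENTERS = {
    "ant_L": (-28.0, -18.0, -20.0),
    "ant_R": (28.0, -18.0, -20.0),
    "post_L": (-25.0, -36.0, -2.0),
    "post_R": (25.0, -36.0, -2.0),
}


@dataclass(frozen=True)
class Coupling:
    """Latent loadings (unitless): within-network, within-subnetwork,
    between-network background, and bridge-channel weights."""

    within: float = 1.0
    subnetwork: float = 0.8
    between: float = 0.3
    bridge: float = 0.6
    sensory: float = 0.65

    def __post_init__(self) -> None:
        if not self.within > self.between:
            raise ValueError("within-network coupling must exceed between-network")


@dataclass(frozen=True)
class TrialBlock:
    """Trial-pattern generator settings."""

    n_trials: int = 48
    n_runs: int = 4
    n_features: int = 40
    tuning_strength: float = 1.0
    activation_confound_sd: float = 0.5
    distance_confound_weight: float = 0.4
    incorrect_fraction: float = 0.15
    pattern_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("need at least 2 runs (cross-run exclusions untestable)")
        if self.n_trials < 2 * self.n_runs:
            raise ValueError("need at least 2 trials per run")


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of the planted dataset."""

    networks: tuple[str, ...] = ("VIS", "AUD", "SMN", "FPN", "DMN", "MTN")
    nodes_per_network: int = 20
    subdivided_network: str = "DMN"
    subnetwork_sizes: tuple[int, ...] = (7, 7, 6)
    bridge_network: str = "MTN"
    bridged: tuple[str, str] = ("VIS", "DMN")
    coupling: Coupling = field(default_factory=Coupling)
    hippo_gradient: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"MTN": (0.7, 0.35), "DMN": (0.3, 0.6)}
    )
    noise_sd: float = 1.0
    n_subjects: int = 40
    T: int = 400
    tr_s: float = 1.22
    n_runs_rest: int = 4
    mean_fd_mm: float = 0.08
    fd_sd_mm: float = 0.03
    centroid_scatter_mm: float = 8.0
    trial_block: TrialBlock = field(default_factory=TrialBlock)
    grid_elements_per_node: int = 84
    n_filler_terms: int = 20
    term_signal: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nodes_per_network < 2:
            raise ValueError("networks need at least 2 nodes")
        if self.noise_sd <= 0.0:
            raise ValueError("noise_sd must be positive")
        if self.T < 8:
            raise ValueError("need at least 8 timepoints")
        if self.subdivided_network not in self.networks:
            raise ValueError("subdivided_network not among networks")
        if self.bridge_network not in self.networks:
            raise ValueError("bridge_network not among networks")
        if any(s < 2 for s in self.subnetwork_sizes):
            raise ValueError("subnetwork sizes must be at least 2")
        if sum(self.subnetwork_sizes) != self.nodes_per_network:
            raise ValueError("subnetwork sizes must sum to nodes_per_network")
        bad = set(self.bridged) - set(self.networks)
        if bad or self.bridge_network in self.bridged:
            raise ValueError("bridged pair must be two non-bridge networks")
        unknown = set(self.hippo_gradient) - set(self.networks)
        if unknown:
            raise ValueError(f"hippo_gradient names unknown networks: {sorted(unknown)}")

    @property
    def n_cortical(self) -> int:
        return len(self.networks) * self.nodes_per_network

    @property
    def n_nodes(self) -> int:
        return self.n_cortical + 4


@dataclass
class GroundTruth:
    """Planted structure to validate every recovery analysis against."""

    network_partition: Partition  # cortical nodes -> network index (1-based)
    subnetwork_partition: Partition  # subdivided-network nodes -> subnetwork
    network_nodes: dict[str, list[str]]
    bridge_network: str
    bridged: tuple[str, str]
    hippo_rois: dict[str, str]  # role -> node_id
    hippo_gradient: dict[str, tuple[float, float]]
    planted_terms: dict[str, str]  # network -> term token
    cortical_node_ids: list[str]
    node_of_element: np.ndarray  # grid element -> cortical node index


def make_parcellation(spec: SyntheticSpec, seed: int | None = None) -> tuple[NodeTable, GroundTruth]:
    """Assign nodes to networks and draw spatially coherent centroids.

    Centroids come from distinct per-network 3-D Gaussian clusters at fixed
    centres, so networks are spatially coherent and distance-based analyses
    (matched controls, spatial confounds) are meaningful.
    """
    if seed is None:
        seed = spec.seed
    rng = substream(seed, "parcellation")
    rows = []
    network_nodes: dict[str, list[str]] = {}
    labels: dict[str, int] = {}
    for ni, net in enumerate(spec.networks, start=1):
        center = np.asarray(_NETWORK_CENTERS.get(net, (0.0, 0.0, 0.0)))
        if net not in _NETWORK_CENTERS:
            center = rng.normal(0.0, 35.0, size=3)
        for j in range(spec.nodes_per_network):
            nid = f"{net}_{j:02d}"
            xyz = center + rng.normal(0.0, spec.centroid_scatter_mm, size=3)
            hemi = "L" if xyz[0] < 0 else "R"
            rows.append((nid, f"{net} region {j}", hemi, *xyz, True, f"net_{net}"))
            network_nodes.setdefault(net, []).append(nid)
            labels[nid] = ni
    hippo_rois = {}
    for role, center in _HIPPO_CENTERS.items():
        nid = f"HC_{role}"
        xyz = np.asarray(center) + rng.normal(0.0, 2.0, size=3)
        hemi = "L" if role.endswith("L") else "R"
        rows.append((nid, f"hippocampus {role}", hemi, *xyz, False, f"{role.split('_')[0]}_hippocampus"))
        hippo_rois[role] = nid
    frame = pd.DataFrame(
        rows,
        columns=["node_id", "name", "hemisphere", "x_mm", "y_mm", "z_mm", "is_cortical", "structure_tag"],
    )
    table = NodeTable(frame=frame)

    sub_labels: dict[str, int] = {}
    start = 0
    for si, size in enumerate(spec.subnetwork_sizes, start=1):
        for nid in network_nodes[spec.subdivided_network][start : start + size]:
            sub_labels[nid] = si
        start += size

    cortical_ids = [nid for net in spec.networks for nid in network_nodes[net]]
    node_of_element = np.repeat(np.arange(len(cortical_ids)), spec.grid_elements_per_node)
    truth = GroundTruth(
        network_partition=Partition(labels=labels, level_tag="whole_brain"),
        subnetwork_partition=Partition(labels=sub_labels, level_tag="subnetwork"),
        network_nodes=network_nodes,
        bridge_network=spec.bridge_network,
        bridged=spec.bridged,
        hippo_rois=hippo_rois,
        hippo_gradient=dict(spec.hippo_gradient),
        planted_terms={net: f"planted_{net.lower()}" for net in spec.networks},
        cortical_node_ids=cortical_ids,
        node_of_element=node_of_element,
    )
    return table, truth


def _loading_matrix(spec: SyntheticSpec, table: NodeTable, truth: GroundTruth) -> np.ndarray:
    """Node x latent loadings implementing the planted structure.

    Latent order: one per network, one per subnetwork, two bridge channels
    (bridge<->first bridged network, bridge<->second), one global
    background.  The two bridged networks load on no shared latent except
    through the bridge network's channels.
    """
    nets = list(spec.networks)
    # latents: networks, subnetworks, two bridge channels, sensorimotor
    # background (AUD+SMN), global background
    n_latent = len(nets) + len(spec.subnetwork_sizes) + 2 + 1 + 1
    node_ids = table.node_ids
    lam = np.zeros((len(node_ids), n_latent))
    idx_of = {nid: i for i, nid in enumerate(node_ids)}
    c = spec.coupling
    sub_base = len(nets)
    ch_a, ch_b = sub_base + len(spec.subnetwork_sizes), sub_base + len(spec.subnetwork_sizes) + 1
    sensory_col = n_latent - 2
    global_col = n_latent - 1

    for ni, net in enumerate(nets):
        for nid in truth.network_nodes[net]:
            lam[idx_of[nid], ni] = c.within
            # the global background couples every network except the bridged
            # pair's isolated member(s): both bridged networks stay off it so
            # their only shared route is the bridge network's channels
            if net not in spec.bridged:
                lam[idx_of[nid], global_col] = c.between
    for nid, si in truth.subnetwork_partition.labels.items():
        lam[idx_of[nid], sub_base + si - 1] = c.subnetwork
    # bridge channels
    net_a, net_b = spec.bridged
    for nid in truth.network_nodes[net_a]:
        lam[idx_of[nid], ch_a] = c.bridge
    for nid in truth.network_nodes[net_b]:
        lam[idx_of[nid], ch_b] = c.bridge
    for nid in truth.network_nodes[spec.bridge_network]:
        lam[idx_of[nid], ch_a] = c.bridge
        lam[idx_of[nid], ch_b] = c.bridge
    # sensorimotor background: auditory and somatomotor couple more strongly
    # than any other pair, so low resolutions merge them
    for net in ("AUD", "SMN"):
        if net in truth.network_nodes and net not in spec.bridged:
            for nid in truth.network_nodes[net]:
                lam[idx_of[nid], sensory_col] = c.sensory
    # hippocampal long-axis gradient
    for role, nid in truth.hippo_rois.items():
        anterior = role.startswith("ant")
        for net, (ant_w, post_w) in spec.hippo_gradient.items():
            lam[idx_of[nid], nets.index(net)] = ant_w if anterior else post_w
    return lam


def simulate_subject_timeseries(
    spec: SyntheticSpec,
    subject_index: int,
    table: NodeTable | None = None,
    truth: GroundTruth | None = None,
) -> ROITimeSeries:
    """Latent-factor BOLD-like series for one subject.

    ``x = Z @ Lambda.T + noise_sd * E`` with T x n_latent standard-normal
    latents Z.  Subjects share the loading structure but draw independent
    latents and noise.  A mean frame displacement is drawn so motion QC is
    exercisable.
    """
    if table is None or truth is None:
        table, truth = make_parcellation(spec)
    lam = _loading_matrix(spec, table, truth)
    rng = substream(spec.seed, "timeseries", subject_index)
    z = rng.standard_normal((spec.T, lam.shape[1]))
    noise = rng.standard_normal((spec.T, lam.shape[0]))
    data = z @ lam.T + spec.noise_sd * noise
    run_len = spec.T // spec.n_runs_rest
    breaks = tuple(run_len * r for r in range(1, spec.n_runs_rest))
    fd = abs(rng.normal(spec.mean_fd_mm, spec.fd_sd_mm))
    return ROITimeSeries(
        subject_id=f"sub-{subject_index:03d}",
        tr_s=spec.tr_s,
        data=data,
        node_ids=table.node_ids,
        run_breaks=breaks,
        mean_fd_mm=float(fd),
    )


def _spatial_confound_loadings(
    spec: SyntheticSpec, table: NodeTable, truth: GroundTruth
) -> tuple[np.ndarray, dict[str, int]]:
    """Factorize sqrt(1 - d/d_max) over cortical centroids into loadings.

    Returns (A, row-index map) with ``A @ A.T`` equal to the kernel up to
    PSD truncation of (numerically) negative eigenvalues.
    """
    idx = table.frame.set_index("node_id")
    cents = idx.loc[truth.cortical_node_ids, ["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=2)
    kernel = np.sqrt(np.clip(1.0 - d / (1.05 * d.max()), 0.0, None))
    evals, evecs = np.linalg.eigh(kernel)
    keep = evals > 1e-12
    loadings = evecs[:, keep] * np.sqrt(evals[keep])
    return loadings, {nid: i for i, nid in enumerate(truth.cortical_node_ids)}


def simulate_trial_patterns(
    spec: SyntheticSpec,
    subject_index: int,
    table: NodeTable | None = None,
    truth: GroundTruth | None = None,
    trial_block: TrialBlock | None = None,
) -> TrialPatternSet:
    """Trial x feature patterns for every cortical ROI of one subject.

    Each network owns a latent trial-by-feature tuning map; an ROI's pattern
    is its network's map scaled by ``tuning_strength``, plus ROI-private
    noise, plus two confounds: a shared per-trial amplitude that multiplies
    an ROI-specific static map (univariate activation), and spatial-anchor
    latents whose loadings decay with centroid distance (spatial
    proximity).  Trials carry run labels and a configurable fraction of
    incorrect trials.
    """
    if table is None or truth is None:
        table, truth = make_parcellation(spec)
    tb = trial_block if trial_block is not None else spec.trial_block
    rng = substream(spec.seed, "trials", subject_index)
    nt, nf = tb.n_trials, tb.n_features
    # tuning maps are demeaned per trial row so they drive pattern
    # *structure* without leaking into trial-mean (univariate) activity;
    # pattern-similarity Pearson is row-mean-invariant, so this does not
    # change the planted RDM structure
    tuning = {}
    for net in spec.networks:
        t_map = rng.standard_normal((nt, nf))
        tuning[net] = t_map - t_map.mean(axis=1, keepdims=True)
    amp = rng.standard_normal(nt)
    # Spatial-proximity confound: ROI loadings over shared latent maps are
    # rows of a factorized kernel A A^T = sqrt(1 - d/d_max).  The RDM-level
    # similarity two ROIs inherit from shared latents scales with the
    # *square* of their loading overlap, so the induced profile-similarity
    # confound is linear in centroid distance — the same (linear) form the
    # distance residualization removes.
    spatial_loadings, cort_row = _spatial_confound_loadings(spec, table, truth)
    spatial_latents = rng.standard_normal((spatial_loadings.shape[1], nt, nf))

    patterns: dict[str, np.ndarray] = {}
    for net in spec.networks:
        for nid in truth.network_nodes[net]:
            static_map = rng.normal(0.5, 1.0, size=nf)
            pat = (
                tb.tuning_strength * tuning[net]
                + tb.activation_confound_sd * amp[:, None] * static_map[None, :]
                + tb.distance_confound_weight
                * np.tensordot(spatial_loadings[cort_row[nid]], spatial_latents, axes=1)
                + tb.pattern_noise_sd * rng.standard_normal((nt, nf))
            )
            patterns[nid] = pat
    per_run = nt // tb.n_runs
    runs = np.minimum(np.arange(nt) // per_run, tb.n_runs - 1)
    correct = rng.random(nt) >= tb.incorrect_fraction
    meta = pd.DataFrame({"trial": np.arange(nt), "run": runs, "correct": correct})
    return TrialPatternSet(
        subject_id=f"sub-{subject_index:03d}", patterns=patterns, trial_meta=meta
    )


def simulate_term_maps(
    spec: SyntheticSpec, truth: GroundTruth, seed: int | None = None
) -> TermMapStack:
    """One planted term per network plus pure-noise fillers.

    The grid expands every cortical node into ``grid_elements_per_node``
    elements; a planted term is unit-variance noise plus ``term_signal`` on
    its own network's elements.
    """
    if seed is None:
        seed = spec.seed
    rng = substream(seed, "terms")
    g = len(truth.node_of_element)
    node_net = np.empty(len(truth.cortical_node_ids), dtype=object)
    for net, nodes in truth.network_nodes.items():
        for nid in nodes:
            node_net[truth.cortical_node_ids.index(nid)] = net
    elem_net = node_net[truth.node_of_element]
    terms, maps = [], []
    for net in spec.networks:
        tmap = rng.standard_normal(g)
        tmap[elem_net == net] += spec.term_signal
        terms.append(truth.planted_terms[net])
        maps.append(tmap)
    for i in range(spec.n_filler_terms):
        terms.append(f"filler_{i:02d}")
        maps.append(rng.standard_normal(g))
    return TermMapStack(terms=terms, maps=np.stack(maps), grid_id="synthetic-node-patch")


def network_mask(truth: GroundTruth, network: str) -> np.ndarray:
    """Binary grid mask of one network (elements of its nodes set to 1)."""
    member_idx = {
        truth.cortical_node_ids.index(nid) for nid in truth.network_nodes[network]
    }
    return np.isin(truth.node_of_element, list(member_idx)).astype(float)
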