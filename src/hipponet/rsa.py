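"""Representational-profile similarity across ROIs.

First order: for each ROI, a trial-by-trial pattern-similarity matrix
(Pearson r between multivoxel patterns), with pairs invalidated when the
two trials share a scanning run or either trial was answered incorrectly —
the classic leakage controls for event-wise pattern similarity.

Second order: each ROI's valid upper-triangle entries are vectorized over
the *intersection* of all ROIs' validity masks (so every ROI pair is
compared on identical trial pairs) and correlated between ROIs, giving an
ROI-by-ROI representational-profile similarity matrix.  Within-network
vs. between-network profile similarity is contrasted by a paired t-test
across subjects, optionally after regressing out univariate-activation
similarity or centroid-distance confounds from the profile matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import Partition

logger = logging.getLogger("hipponet")

__all__ = [
    "TrialPatternSet",
    "TrialRDM",
    "ProfileMatrix",
    "trial_rdm",
    "activation_similarity",
    "profile_similarity",
    "within_between_means",
    "WithinBetweenResult",
    "within_between_contrast",
    "residualize_similarity",
]


@dataclass
class TrialPatternSet:
    """Multivoxel patterns per ROI with shared trial metadata.

    ``patterns`` maps roi_id to a trials x features array; ``trial_meta``
    has columns ``trial, run, correct`` and applies to every ROI.
    """

    subject_id: str
    patterns: dict[str, np.ndarray]
    trial_meta: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"trial", "run", "correct"}
        if not need <= set(self.trial_meta.columns):
            raise ValueError(f"trial_meta needs columns {sorted(need)}")
        n_trials = len(self.trial_meta)
        for roi, mat in self.patterns.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != n_trials:
                raise ValueError(f"ROI {roi!r} patterns must be {n_trials} x features")
            if mat.shape[1] < 2:
                raise ValueError(f"ROI {roi!r} has fewer than 2 features")
            self.patterns[roi] = mat
        if self.trial_meta["run"].nunique() < 2:
            raise ValueError("need at least 2 runs for cross-run similarity")

    @property
    def roi_ids(self) -> list[str]:
        return list(self.patterns.keys())

    @property
    def n_trials(self) -> int:
        return len(self.trial_meta)


@dataclass
class TrialRDM:
    """Trial-by-trial pattern similarity for one ROI, with validity mask."""

    roi_id: str
    sim: np.ndarray
    valid_mask: np.ndarray


def _base_valid_mask(meta: pd.DataFrame) -> np.ndarray:
    """Valid trial pairs: different runs, both correct, off-diagonal."""
    runs = meta["run"].to_numpy()
    correct = meta["correct"].to_numpy(dtype=bool)
    cross_run = runs[:, None] != runs[None, :]
    both_correct = correct[:, None] & correct[None, :]
    mask = cross_run & both_correct
    np.fill_diagonal(mask, False)
    return mask


def trial_rdm(patterns: TrialPatternSet, roi_id: str) -> TrialRDM:
    """Pearson pattern similarity between all trial pairs of one ROI.

    The mask invalidates the diagonal, same-run pairs, pairs touching an
    incorrect trial, and pairs touching a constant (zero-variance) pattern.
    """
    mat = patterns.patterns[roi_id]
    mask = _base_valid_mask(patterns.trial_meta)
    sd = mat.std(axis=1)
    flat = sd == 0.0
    if flat.any():
        logger.warning(
            "ROI %s: %d constant trial patterns invalidated", roi_id, int(flat.sum())
        )
        mask[flat, :] = False
        mask[:, flat] = False
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.corrcoef(mat)
    sim = np.where(np.isfinite(sim), sim, 0.0)
    np.fill_diagonal(sim, 1.0)
    return TrialRDM(roi_id=roi_id, sim=sim, valid_mask=mask)


def activation_similarity(patterns: TrialPatternSet) -> pd.DataFrame:
    """ROI-by-ROI correlation of trial-wise mean activity (correct trials).

    The univariate-confound matrix: per ROI, mean activity over features for
    each valid (correct) trial; ROI pairs are correlated over those trials.
    Zero-variance activity vectors yield NaN entries (flagged).
    """
    correct = patterns.trial_meta["correct"].to_numpy(dtype=bool)
    rois = patterns.roi_ids
    acts = np.stack([patterns.patterns[r][correct].mean(axis=1) for r in rois])
    sds = acts.std(axis=1)
    if (sds == 0.0).any():
        flat = [rois[i] for i in np.flatnonzero(sds == 0.0)]
        logger.warning("zero-variance activity vectors for ROIs: %s", flat)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.corrcoef(acts)
    return pd.DataFrame(sim, index=rois, columns=rois)


@dataclass
class ProfileMatrix:
    """ROI-by-ROI similarity of vectorized representational profiles."""

    roi_ids: list[str]
    sim: np.ndarray
    confounds_removed: list[str] = field(default_factory=list)
    subject_id: str = "unknown"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sim, index=self.roi_ids, columns=self.roi_ids)


def profile_similarity(
    rdms: Sequence[TrialRDM],
    min_valid_pairs: int = 10,
    method: str = "pearson",
    subject_id: str = "unknown",
) -> ProfileMatrix:
    """Second-order similarity: correlate ROIs' vectorized RDM profiles.

    Profiles are built on the intersection of all ROIs' validity masks
    (upper triangle only) so that every ROI pair is compared on identical
    trial pairs.  ``method`` may be ``"pearson"`` (default) or
    ``"spearman"``.
    """
    if not rdms:
        raise ValueError("no RDMs given")
    inter = rdms[0].valid_mask.copy()
    for rdm in rdms[1:]:
        inter &= rdm.valid_mask
    iu = np.triu_indices(inter.shape[0], k=1)
    sel = inter[iu]
    n_valid = int(sel.sum())
    if n_valid < min_valid_pairs:
        raise ValueError(
            f"only {n_valid} valid trial pairs in the mask intersection "
            f"(need {min_valid_pairs})"
        )
    vectors = np.stack([rdm.sim[iu][sel] for rdm in rdms])
    if method == "spearman":
        vectors = np.apply_along_axis(stats.rankdata, 1, vectors)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sim = np.corrcoef(vectors)
    sim = (sim + sim.T) / 2.0
    return ProfileMatrix(
        roi_ids=[rdm.roi_id for rdm in rdms], sim=sim, subject_id=subject_id
    )


def within_between_means(pm: ProfileMatrix, partition: Partition) -> tuple[float, float]:
    """Mean within-network vs. between-network profile similarity.

    Self-pairs (the diagonal) are excluded so within-network similarity is
    not inflated; networks with a single ROI contribute no within pairs.
    """
    labels = partition.as_array(pm.roi_ids)
    iu = np.triu_indices(len(pm.roi_ids), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = pm.sim[iu]
    if not same.any() or same.all():
        raise ValueError("need both within- and between-network ROI pairs")
    singletons = [
        lab for lab, mem in partition.communities().items() if len(mem) == 1
    ]
    if singletons:
        logger.info("networks with a single ROI (no within pairs): %s", singletons)
    return float(vals[same].mean()), float(vals[~same].mean())


@dataclass
class WithinBetweenResult:
    per_subject: pd.DataFrame  # subject, within, between
    t: float
    df: int
    p: float


def within_between_contrast(
    pms: Sequence[ProfileMatrix], partition: Partition
) -> WithinBetweenResult:
    """Group paired t-test of within- vs. between-network profile similarity."""
    rows = []
    for pm in pms:
        w, b = within_between_means(pm, partition)
        rows.append((pm.subject_id, w, b))
    frame = pd.DataFrame(rows, columns=["subject", "within", "between"])
    diff = frame["within"].to_numpy() - frame["between"].to_numpy()
    if len(diff) < 2 or np.allclose(diff.std(ddof=1), 0.0):
        # degenerate: identical within/between everywhere is a true zero
        # effect; a constant nonzero difference has no defined t
        t = 0.0 if np.allclose(diff, 0.0) else float("nan")
        p = 1.0 if t == 0.0 else float("nan")
    else:
        t, p = stats.ttest_rel(frame["within"], frame["between"])
    return WithinBetweenResult(per_subject=frame, t=float(t), df=len(diff) - 1, p=float(p))


def residualize_similarity(
    pm: ProfileMatrix, confound: pd.DataFrame | np.ndarray, tag: str
) -> ProfileMatrix:
    """Regress a confound matrix out of the profile matrix (per subject).

    Vectorized off-diagonal upper-triangle entries of ``pm`` are regressed
    by OLS on the matching confound entries plus an intercept; residuals are
    re-packed symmetrically (diagonal untouched) and ``tag`` is appended to
    ``confounds_removed``.
    """
    if isinstance(confound, pd.DataFrame):
        conf = confound.loc[pm.roi_ids, pm.roi_ids].to_numpy(dtype=float)
    else:
        conf = np.asarray(confound, dtype=float)
        if conf.shape != pm.sim.shape:
            raise ValueError("confound shape does not match profile matrix")
    if not np.allclose(conf, conf.T, atol=1e-8):
        raise ValueError("confound matrix must be symmetric")
    iu = np.triu_indices(len(pm.roi_ids), k=1)
    x = conf[iu]
    if np.allclose(x.std(), 0.0):
        raise ValueError("confound has no variance")
    y = pm.sim[iu]
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    out = pm.sim.copy()
    out[iu] = resid
    out[(iu[1], iu[0])] = resid
    return replace(
        pm, sim=out, confounds_removed=[*pm.confounds_removed, tag]
    )
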