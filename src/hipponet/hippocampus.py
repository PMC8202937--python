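"""Hippocampal-cortical connectivity profiles and long-axis contrasts.

For each hippocampal ROI (anterior/posterior x left/right) a connectivity
profile averages the raw Fisher-z FC to the cortical nodes of each network.
Network membership is screened with one-sample t-tests (Bonferroni over
networks x ROIs), and the long-axis (anterior vs. posterior) and laterality
(left vs. right) contrasts are within-subject paired t-tests per network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import FCMatrix, Partition

__all__ = [
    "HIPPO_ROLES",
    "network_fc_profile",
    "HippocampalContrasts",
    "hippocampal_contrasts",
]

#: The four hippocampal ROI roles expected by the contrasts.
HIPPO_ROLES = ("ant_L", "ant_R", "post_L", "post_R")


def network_fc_profile(
    subject_fc: FCMatrix,
    partition: Partition,
    hippo_rois: Mapping[str, str],
) -> pd.DataFrame:
    """Mean FC of each hippocampal ROI to each cortical network.

    ``hippo_rois`` maps role (``ant_L`` etc.) to node_id.  Negative weights
    are retained — profiles are raw FC, not the thresholded graph.  The
    partition must cover cortical nodes only (hippocampal nodes are excluded
    from community detection), and every network needs at least one cortical
    member.
    """
    overlap = set(hippo_rois.values()) & set(partition.labels)
    if overlap:
        raise ValueError(
            f"hippocampal nodes must not appear in the cortical partition: {sorted(overlap)}"
        )
    rows = []
    communities = partition.communities()
    for label, members in sorted(communities.items()):
        if not members:
            raise ValueError(f"network {label} has no cortical members")
    for role, roi in hippo_rois.items():
        roi_row = subject_fc.values[subject_fc.index_of([roi])[0]]
        for label, members in sorted(communities.items()):
            idx = subject_fc.index_of(members)
            rows.append(
                (subject_fc.subject_id, role, roi, int(label), float(roi_row[idx].mean()))
            )
    return pd.DataFrame(rows, columns=["subject", "roi", "node_id", "network", "fc"])


@dataclass
class HippocampalContrasts:
    """Membership screening plus long-axis and laterality paired contrasts."""

    membership: pd.DataFrame  # network, roi, mean_fc, t, df, p, p_corrected, significant
    membership_pooled: pd.DataFrame  # network, mean_fc, t, df, p
    axis: pd.DataFrame  # network, t, df, p (anterior - posterior)
    laterality: pd.DataFrame  # network, t, df, p (left - right)


def _one_sample(values: np.ndarray) -> tuple[float, int, float]:
    if np.allclose(values.std(ddof=1), 0.0):
        return float("nan"), len(values) - 1, float("nan")
    t, p = stats.ttest_1samp(values, 0.0)
    return float(t), len(values) - 1, float(p)


def hippocampal_contrasts(profiles: pd.DataFrame) -> HippocampalContrasts:
    """Contrast hippocampal network profiles across subjects.

    ``profiles`` is the long table from :func:`network_fc_profile`, stacked
    over subjects, with all four ROI roles present per subject.  Membership
    tests are Bonferroni-corrected over (networks x ROIs).  The long-axis
    contrast averages hemispheres within subject before the paired test; the
    laterality contrast averages axis positions.  Zero across-subject
    variance yields NaN statistics with the row retained (flagged).
    """
    roles = set(profiles["roi"].unique())
    missing = set(HIPPO_ROLES) - roles
    if missing:
        raise ValueError(f"profiles missing hippocampal ROI roles: {sorted(missing)}")
    n_subj = profiles["subject"].nunique()
    if n_subj < 3:
        raise ValueError(f"need at least 3 subjects, got {n_subj}")

    wide = profiles.pivot_table(
        index=["subject", "network"], columns="roi", values="fc"
    ).reset_index()
    networks = sorted(profiles["network"].unique())
    n_tests = len(networks) * len(HIPPO_ROLES)

    mem_rows = []
    for net in networks:
        sub = wide[wide["network"] == net]
        for role in HIPPO_ROLES:
            vals = sub[role].to_numpy(dtype=float)
            t, df, p = _one_sample(vals)
            p_corr = min(1.0, p * n_tests) if np.isfinite(p) else float("nan")
            mem_rows.append(
                (net, role, float(vals.mean()), t, df, p, p_corr, bool(p_corr < 0.05))
            )
    membership = pd.DataFrame(
        mem_rows,
        columns=["network", "roi", "mean_fc", "t", "df", "p", "p_corrected", "significant"],
    )

    pooled_rows, axis_rows, lat_rows = [], [], []
    for net in networks:
        sub = wide[wide["network"] == net]
        pooled = sub[list(HIPPO_ROLES)].mean(axis=1).to_numpy(dtype=float)
        t, df, p = _one_sample(pooled)
        pooled_rows.append((net, float(pooled.mean()), t, df, p))

        ant = sub[["ant_L", "ant_R"]].mean(axis=1).to_numpy(dtype=float)
        post = sub[["post_L", "post_R"]].mean(axis=1).to_numpy(dtype=float)
        t, df, p = _one_sample(ant - post)
        axis_rows.append((net, t, df, p))

        left = sub[["ant_L", "post_L"]].mean(axis=1).to_numpy(dtype=float)
        right = sub[["ant_R", "post_R"]].mean(axis=1).to_numpy(dtype=float)
        t, df, p = _one_sample(left - right)
        lat_rows.append((net, t, df, p))

    return HippocampalContrasts(
        membership=membership,
        membership_pooled=pd.DataFrame(
            pooled_rows, columns=["network", "mean_fc", "t", "df", "p"]
        ),
        axis=pd.DataFrame(axis_rows, columns=["network", "t", "df", "p"]),
        laterality=pd.DataFrame(lat_rows, columns=["network", "t", "df", "p"]),
    )
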