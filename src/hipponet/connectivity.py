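"""From ROI time series to functional-connectivity matrices.

The denoising arithmetic applied here mirrors a standard resting-state
pipeline: per run, the series is demeaned and de-trended (linear and
quadratic), bandpass filtered to 0.008–0.09 Hz, and residualized on an
equally filtered confound set by least squares.  Runs are cleaned
independently and concatenated before correlation, connectivity is the
Fisher z-transform ``atanh(r)`` of the Pearson correlation, and subjects
with mean frame displacement above 0.15 mm are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import linalg

from .types import FCMatrix

logger = logging.getLogger("hipponet")

DEFAULT_BAND_HZ = (0.008, 0.09)
DEFAULT_FD_MAX_MM = 0.15

__all__ = [
    "ROITimeSeries",
    "ConfoundSet",
    "QCResult",
    "compute_tsnr",
    "clean_timeseries",
    "fc_from_timeseries",
    "subject_qc",
    "group_average_fc",
    "DEFAULT_BAND_HZ",
    "DEFAULT_FD_MAX_MM",
]


@dataclass
class ROITimeSeries:
    """ROI-level BOLD time series for one subject.

    ``data`` is timepoints x regions; ``run_breaks`` are the starting indices
    of runs 2..R (so an empty tuple means a single run).  ``mean_fd_mm`` is
    the subject's mean frame displacement, used only for QC.
    """

    subject_id: str
    tr_s: float
    data: np.ndarray
    node_ids: list[str]
    run_breaks: tuple[int, ...] = ()
    mean_fd_mm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be T x n")
        t, n = self.data.shape
        if t < 8:
            raise ValueError(f"need at least 8 timepoints, got {t}")
        if n != len(self.node_ids):
            raise ValueError("node_ids length does not match data columns")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in time series")
        breaks = tuple(int(b) for b in self.run_breaks)
        if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])) or any(
            not 0 < b < t for b in breaks
        ):
            raise ValueError("run_breaks must be strictly increasing and in (0, T)")
        self.run_breaks = breaks

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    def run_slices(self) -> list[slice]:
        edges = [0, *self.run_breaks, self.data.shape[0]]
        return [slice(a, b) for a, b in zip(edges, edges[1:])]


@dataclass
class ConfoundSet:
    """Nuisance regressors aligned with a time series (e.g. the 9p set)."""

    data: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.names):
            raise ValueError("confound data must be T x len(names)")


def compute_tsnr(ts: ROITimeSeries) -> np.ndarray:
    """Temporal SNR per node: temporal mean / temporal SD over all runs.

    Runs are concatenated before computation.  Nodes with zero temporal
    variance get NaN (undefined) rather than a silent 0, with a warning.
    """
    mean = ts.data.mean(axis=0)
    sd = ts.data.std(axis=0, ddof=1)
    tsnr = np.full(ts.data.shape[1], np.nan)
    ok = sd > 0
    tsnr[ok] = mean[ok] / sd[ok]
    if not ok.all():
        bad = [ts.node_ids[i] for i in np.flatnonzero(~ok)]
        logger.warning("tSNR undefined (zero variance) for nodes: %s", bad)
    return tsnr


def _trend_basis(t: int) -> np.ndarray:
    u = np.linspace(-1.0, 1.0, t)
    return np.column_stack([np.ones(t), u, u**2])


def _residualize(x: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def _bandpass_fft(x: np.ndarray, tr_s: float, band_hz: tuple[float, float]) -> np.ndarray:
    """Zero-phase frequency-domain bandpass along axis 0."""
    low, high = band_hz
    t = x.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr_s)
    keep = (freqs >= low) & (freqs <= high)
    xf = np.fft.rfft(x, axis=0)
    xf[~keep] = 0.0
    return np.fft.irfft(xf, n=t, axis=0)


def _independent_columns(a: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    if a.shape[1] == 0:
        return np.array([], dtype=int)
    _, r, piv = linalg.qr(a, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * max(diag[0], 1.0)).sum()) if diag.size else 0
    return np.sort(piv[:rank])


def clean_timeseries(
    ts: ROITimeSeries,
    conf: ConfoundSet | None = None,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> ROITimeSeries:
    """Demean/detrend, bandpass, and residualize on filtered confounds.

    Each run is processed independently: (1) mean, linear and quadratic
    trends removed; (2) data *and* confounds bandpass filtered to
    ``band_hz`` with a zero-phase frequency-domain filter (zero phase
    preserves correlation structure); (3) data residualized on the filtered
    confounds by least squares.  Rank-deficient confound matrices have
    dependent columns dropped with a warning.
    """
    low, high = band_hz
    nyquist = 1.0 / (2.0 * ts.tr_s)
    if not 0.0 < low < high < nyquist:
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for Nyquist {nyquist:.4f} Hz"
        )
    if conf is not None and conf.data.shape[0] != ts.n_timepoints:
        raise ValueError("confound rows do not match time-series length")

    def _detrend_bandpass(x: np.ndarray) -> np.ndarray:
        # bandpass, then residualize on the *bandpassed* trend basis: the
        # result is in-band and orthogonal to mean/linear/quadratic trends,
        # and the combined operator is an exact projection (idempotent)
        t = x.shape[0]
        x = _bandpass_fft(x - x.mean(axis=0), ts.tr_s, band_hz)
        basis = _bandpass_fft(_trend_basis(t), ts.tr_s, band_hz)
        return _residualize(x, basis)

    out = np.empty_like(ts.data)
    for sl in ts.run_slices():
        seg = _detrend_bandpass(ts.data[sl])
        if conf is not None:
            c = _detrend_bandpass(conf.data[sl])
            keep = _independent_columns(c)
            if len(keep) < c.shape[1]:
                dropped = [conf.names[i] for i in range(c.shape[1]) if i not in set(keep)]
                logger.warning("dropping dependent confound columns: %s", dropped)
            c = c[:, keep]
            if c.shape[1]:
                beta, *_ = np.linalg.lstsq(c, seg, rcond=None)
                seg = seg - c @ beta
        out[sl] = seg
    return replace(ts, data=out)


def fc_from_timeseries(ts: ROITimeSeries) -> FCMatrix:
    """Fisher-z FC: ``atanh`` of all pairwise Pearson correlations.

    Off-diagonal correlations with |r| = 1 are clipped to ±(1 − 1e-7)
    before the transform (with a warning); the diagonal is stored as 0.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    r = np.corrcoef(ts.data, rowvar=False)
    if not np.all(np.isfinite(r)):
        raise ValueError("correlation undefined: constant node series present")
    off = ~np.eye(r.shape[0], dtype=bool)
    clip = 1.0 - 1e-7
    if np.any(np.abs(r[off]) >= 1.0):
        logger.warning(
            "subject %s: |r|=1 off-diagonal, clipping before atanh", ts.subject_id
        )
    z = np.arctanh(np.clip(r, -clip, clip))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # exact symmetry against float round-off
    return FCMatrix(node_ids=list(ts.node_ids), values=z, subject_id=ts.subject_id)


@dataclass
class QCResult:
    """Motion-based subject triage."""

    kept: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
    unassessable: list[str] = field(default_factory=list)


def subject_qc(
    subjects: Sequence[ROITimeSeries], fd_max_mm: float = DEFAULT_FD_MAX_MM
) -> QCResult:
    """Exclude subjects with mean frame displacement strictly above threshold.

    Subjects without an FD value are flagged unassessable rather than
    silently kept.
    """
    res = QCResult()
    for ts in subjects:
        if ts.mean_fd_mm is None:
            res.unassessable.append(ts.subject_id)
        elif ts.mean_fd_mm > fd_max_mm:
            res.excluded.append(ts.subject_id)
        else:
            res.kept.append(ts.subject_id)
    if res.excluded or res.unassessable:
        logger.info(
            "subject QC: excluded=%s unassessable=%s (fd_max=%g mm)",
            res.excluded,
            res.unassessable,
            fd_max_mm,
        )
    return res


def group_average_fc(
    subject_fcs: Sequence[FCMatrix], exclude_negatives: bool = True
) -> FCMatrix:
    """Element-wise mean FC across subjects.

    With ``exclude_negatives`` each subject's negative entries are set to 0
    *before* averaging (edges dropped, nodes kept, shapes stable).
    """
    if not subject_fcs:
        raise ValueError("no subject matrices given")
    ref = subject_fcs[0].node_ids
    for fc in subject_fcs[1:]:
        if fc.node_ids != ref:
            raise ValueError(
                f"node set of subject {fc.subject_id!r} does not match "
                f"subject {subject_fcs[0].subject_id!r}"
            )
    stack = np.stack(
        [
            np.where(fc.values < 0.0, 0.0, fc.values) if exclude_negatives else fc.values
            for fc in subject_fcs
        ]
    )
    return FCMatrix(
        node_ids=list(ref),
        values=stack.mean(axis=0),
        subject_id="group",
        nonnegative=exclude_negatives,
    )
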