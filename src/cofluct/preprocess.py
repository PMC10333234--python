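"""Nuisance-confound design, signal cleaning, run trimming, and motion diagnostics.

The cleaning recipe mirrors common resting-state fMRI practice: a 12-column
nuisance design built from white-matter, CSF and global-signal means (each with
its square, backward-difference derivative, and squared derivative), optional
binary spike regressors for high-motion frames, linear detrending, and a
zero-phase Butterworth bandpass (default 0.008-0.08 Hz).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.008, 0.08)
DEFAULT_FD_SPIKE_THRESHOLD = 0.25  # mm


@dataclass
class ParcellatedRun:
    """One subject-run BOLD matrix (time x parcels) with acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (n_timepoints, n_parcels)
        Parcel-aggregated BOLD signal. Parcel columns share a fixed order
        across all runs of a cohort.
    tr : float
        Repetition time in seconds.
    subject_id : str
    day : int
        Scan day, 1 or 2.
    encoding : str
        Phase-encoding direction label, "A" or "B".
    """

    data: np.ndarray
    tr: float
    subject_id: str = "sub-0"
    day: int = 1
    encoding: str = "A"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("run data must be a 2-D (time x parcel) matrix")
        if self.data.shape[0] < 3:
            raise ValueError("run must have at least 3 timepoints")
        if np.isnan(self.data).any():
            raise ValueError("run data contains missing values (NaN)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.day not in (1, 2):
            raise ValueError("day must be 1 or 2")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    def replace_data(self, data: np.ndarray) -> "ParcellatedRun":
        return ParcellatedRun(
            data=data, tr=self.tr, subject_id=self.subject_id, day=self.day,
            encoding=self.encoding,
        )


@dataclass
class ConfoundSet:
    """Per-run nuisance series: WM/CSF/GS means and framewise displacement (mm)."""

    wm: np.ndarray
    csf: np.ndarray
    gs: np.ndarray
    fd: np.ndarray
    fd_spike_threshold: float = DEFAULT_FD_SPIKE_THRESHOLD

    def __post_init__(self) -> None:
        self.wm = np.asarray(self.wm, dtype=float).ravel()
        self.csf = np.asarray(self.csf, dtype=float).ravel()
        self.gs = np.asarray(self.gs, dtype=float).ravel()
        self.fd = np.asarray(self.fd, dtype=float).ravel()
        n = len(self.wm)
        for name in ("csf", "gs", "fd"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"confound series '{name}' has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        if (self.fd < 0).any():
            raise ValueError("framewise displacement must be nonnegative")

    @property
    def n_timepoints(self) -> int:
        return len(self.wm)


def _derivative(x: np.ndarray) -> np.ndarray:
    """Backward difference with a leading zero (length-preserving)."""
    d = np.empty_like(x)
    d[0] = 0.0
    d[1:] = np.diff(x)
    return d


def build_confound_design(confounds: ConfoundSet) -> tuple[np.ndarray, list[str]]:
    """Expand a ConfoundSet into a labelled nuisance design matrix.

    For each of WM/CSF/GS: the series, its square, its backward-difference
    temporal derivative, and the squared derivative -- 12 columns in total.
    One binary spike column per frame with fd above threshold is appended
    after the 12 (spikes are extras, not part of the 12-parameter count).

    Returns
    -------
    design : ndarray, shape (n_timepoints, 12 + n_spikes)
    labels : list of str, one per column
    """
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for name, series in (("wm", confounds.wm), ("csf", confounds.csf),
                         ("gs", confounds.gs)):
        d = _derivative(series)
        cols.extend([series, series ** 2, d, d ** 2])
        labels.extend([name, f"{name}_sq", f"{name}_deriv", f"{name}_deriv_sq"])
    spike_frames = np.flatnonzero(confounds.fd > confounds.fd_spike_threshold)
    n = confounds.n_timepoints
    for t in spike_frames:
        col = np.zeros(n)
        col[t] = 1.0
        cols.append(col)
        labels.append(f"spike_t{t}")
    return np.column_stack(cols), labels


def _drop_collinear(design: np.ndarray, labels: list[str],
                    tol: float = 1e-10) -> tuple[np.ndarray, list[str]]:
    """Greedily drop columns that are linearly dependent on earlier ones."""
    keep: list[int] = []
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) \
                == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping collinear design column %r", labels[j])
    if len(keep) < design.shape[1]:
        warnings.warn(
            f"dropped {design.shape[1] - len(keep)} collinear design column(s)",
            RuntimeWarning, stacklevel=3,
        )
    return design[:, keep], [labels[j] for j in keep]


def _bandpass(x: np.ndarray, tr: float, band: tuple[float, float],
              order: int = 5) -> np.ndarray:
    nyq = 0.5 / tr
    low, high = band
    sos = sp_signal.butter(order, [low / nyq, high / nyq], btype="band",
                           output="sos")
    return sp_signal.sosfiltfilt(sos, x, axis=0)


def clean_run(
    run: ParcellatedRun,
    design: np.ndarray | None = None,
    band: tuple[float, float] | None = DEFAULT_BAND,
    detrend: bool = True,
    design_labels: list[str] | None = None,
    filter_order: int = 5,
) -> ParcellatedRun:
    """Detrend, bandpass, and regress nuisance columns out of a run.

    Both the data and the design are detrended and filtered before the
    regression, so the cleaned output is exactly orthogonal to every retained
    (processed) design column. Pass ``band=None`` to skip filtering.
    """
    x = run.data.copy()
    if band is not None:
        low, high = band
        nyq = 0.5 / run.tr
        if not (0 < low < high < nyq):
            raise ValueError(
                f"band {band} infeasible for tr={run.tr}s (Nyquist {nyq:.4f} Hz)"
            )
    if detrend:
        x = sp_signal.detrend(x, axis=0, type="linear")
    if band is not None:
        x = _bandpass(x, run.tr, band, order=filter_order)
    if design is not None and design.shape[1] > 0:
        d = np.asarray(design, dtype=float)
        if d.shape[0] != run.n_timepoints:
            raise ValueError(
                f"design has {d.shape[0]} rows, run has {run.n_timepoints}"
            )
        if detrend:
            d = sp_signal.detrend(d, axis=0, type="linear")
        if band is not None:
            d = _bandpass(d, run.tr, band, order=filter_order)
        labels = design_labels or [f"c{j}" for j in range(d.shape[1])]
        # keep only nonzero columns (a constant column detrends to ~0)
        nz = np.ptp(d, axis=0) > 1e-12 * max(1.0, np.abs(d).max())
        d, labels = d[:, nz], [l for l, k in zip(labels, nz) if k]
        if d.shape[1]:
            d, labels = _drop_collinear(d, labels)
            # intercept alongside the nuisance columns: residuals are exactly
            # orthogonal to each retained column and mean-free
            d_aug = np.column_stack([np.ones(d.shape[0]), d])
            beta, *_ = np.linalg.lstsq(d_aug, x, rcond=None)
            x = x - d_aug @ beta
    return run.replace_data(x)


def trim_run(run: ParcellatedRun, head: int, tail: int) -> ParcellatedRun:
    """Drop ``head`` leading and ``tail`` trailing frames (e.g. 20/18 -> 440)."""
    if head < 0 or tail < 0:
        raise ValueError("head and tail must be nonnegative")
    if head + tail >= run.n_timepoints:
        raise ValueError(
            f"cannot trim {head}+{tail} frames from a run of length "
            f"{run.n_timepoints}"
        )
    stop = run.n_timepoints - tail
    return run.replace_data(run.data[head:stop])


def rss_motion_correlation(rss: np.ndarray, fd: np.ndarray) -> float:
    """Pearson correlation between an RSS co-fluctuation trace and FD.

    A near-zero value is the expected diagnostic outcome when co-fluctuation
    amplitude is not motion-driven.
    """
    rss = np.asarray(rss, dtype=float).ravel()
    fd = np.asarray(fd, dtype=float).ravel()
    if len(rss) != len(fd):
        raise ValueError("rss and fd must have equal lengths")
    if len(rss) < 3:
        raise ValueError("need at least 3 frames")
    if np.std(rss) == 0 or np.std(fd) == 0:
        raise ValueError("zero-variance input")
    return float(stats.pearsonr(rss, fd).statistic)
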