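"""Edge time series, co-fluctuation amplitude, time-point sampling, and FC.

The edge time series (ETS) of a parcellated BOLD run is the per-timepoint
element-wise product of the z-scored signals of every parcel pair: for edge
(i, j) at time t, ets(t) = z_i(t) * z_j(t). Its time-mean recovers the
full-run Pearson functional connectivity (FC) edge for edge, which is why
z-scoring here uses the population standard deviation (ddof = 0). The root
sum of squares (RSS) over edges at each timepoint measures brain-wide
co-fluctuation amplitude; ranking timepoints by RSS defines high- (HACF) and
low-amplitude (LACF) co-fluctuation moments, which the three sampling
strategies (sequential thresholds, individual bins, combined bin pairs) turn
into FC estimates from selected timepoints only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

from .preprocess import ParcellatedRun

Strategy = Literal["sequential_hacf", "sequential_lacf", "individual_bin",
                   "combined_bins", "full"]

DEFAULT_SEQUENTIAL_THRESHOLDS = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


def edge_index(n_parcels: int) -> list[tuple[int, int]]:
    """Upper-triangle (i, j) pairs with i < j, row-major — the canonical edge order."""
    iu = np.triu_indices(n_parcels, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


@dataclass
class EdgeTimeSeries:
    """Time x edge co-fluctuation products in canonical edge order."""

    values: np.ndarray
    edge_index: list[tuple[int, int]]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]


@dataclass
class RSSTrace:
    """Per-timepoint root-sum-of-squares co-fluctuation amplitude."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if (self.values < 0).any():
            raise ValueError("RSS values must be nonnegative")


@dataclass
class SamplingSpec:
    """Which timepoints of the RSS ranking to keep for FC estimation.

    strategy:
      - "sequential_hacf"/"sequential_lacf": top/bottom ``threshold_pct`` %
        of the ranking;
      - "individual_bin": bin ``bin`` of ``n_bins`` equal bins, bin 1 =
        highest co-fluctuation;
      - "combined_bins": union of the two bins in ``bin_pair`` (b1 < b2);
      - "full": every timepoint.
    """

    strategy: Strategy
    threshold_pct: float | None = None
    bin: int | None = None
    bin_pair: tuple[int, int] | None = None
    n_bins: int | None = None

    def __post_init__(self) -> None:
        s = self.strategy
        if s in ("sequential_hacf", "sequential_lacf"):
            if self.threshold_pct is None:
                raise ValueError(f"{s} requires threshold_pct")
            if not 0 < self.threshold_pct <= 100:
                raise ValueError("threshold_pct must be in (0, 100]")
            if self.bin is not None or self.bin_pair is not None:
                raise ValueError("bin fields not valid for sequential sampling")
        elif s == "individual_bin":
            if self.bin is None or self.n_bins is None:
                raise ValueError("individual_bin requires bin and n_bins")
            if not 1 <= self.bin <= self.n_bins:
                raise ValueError(f"bin {self.bin} out of range 1..{self.n_bins}")
        elif s == "combined_bins":
            if self.bin_pair is None or self.n_bins is None:
                raise ValueError("combined_bins requires bin_pair and n_bins")
            b1, b2 = self.bin_pair
            if not (1 <= b1 < b2 <= self.n_bins):
                raise ValueError(f"bin_pair {self.bin_pair} invalid for "
                                 f"n_bins={self.n_bins}")
        elif s == "full":
            pass
        else:
            raise ValueError(f"unknown strategy {s!r}")

    def label(self) -> str:
        if self.strategy == "full":
            return "full"
        if self.strategy in ("sequential_hacf", "sequential_lacf"):
            side = "hacf" if self.strategy.endswith("hacf") else "lacf"
            return f"seq_{side}_{self.threshold_pct:g}pct"
        if self.strategy == "individual_bin":
            return f"bin_{self.bin}_of_{self.n_bins}"
        b1, b2 = self.bin_pair
        return f"bins_{b1}+{b2}_of_{self.n_bins}"


@dataclass
class FCMatrix:
    """Symmetric Pearson FC with a canonical upper-triangle vectorisation."""

    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]

    @property
    def vec(self) -> np.ndarray:
        iu = np.triu_indices(self.n_parcels, k=1)
        return self.matrix[iu]

    @classmethod
    def from_vec(cls, vec: np.ndarray, n_parcels: int,
                 provenance: dict | None = None) -> "FCMatrix":
        m = np.eye(n_parcels)
        iu = np.triu_indices(n_parcels, k=1)
        m[iu] = vec
        m.T[iu] = vec
        return cls(m, provenance or {})


def compute_ets(run: ParcellatedRun) -> EdgeTimeSeries:
    """Edge time series of a run: products of population-z-scored parcel pairs."""
    x = run.data
    sd = x.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance parcel(s): {bad.tolist()}")
    z = (x - x.mean(axis=0)) / sd
    iu = np.triu_indices(run.n_parcels, k=1)
    values = z[:, iu[0]] * z[:, iu[1]]
    return EdgeTimeSeries(values=values, edge_index=edge_index(run.n_parcels))


def compute_rss(ets: EdgeTimeSeries) -> RSSTrace:
    """RSS(t) = sqrt(sum over edges of ets(t, e)^2)."""
    return RSSTrace(values=np.sqrt(np.sum(ets.values ** 2, axis=1)))


def rank_time_points(rss: RSSTrace) -> np.ndarray:
    """Time indices sorted by descending RSS; ties broken by ascending time."""
    return np.argsort(-rss.values, kind="stable")


def select_time_points(ranking: np.ndarray, spec: SamplingSpec) -> np.ndarray:
    """Apply a sampling spec to an RSS ranking; returns ascending time indices."""
    ranking = np.asarray(ranking)
    t = len(ranking)
    if spec.strategy == "full":
        sel = ranking
    elif spec.strategy in ("sequential_hacf", "sequential_lacf"):
        k = int(np.floor(spec.threshold_pct / 100.0 * t))
        if k < 2:
            raise ValueError(
                f"threshold {spec.threshold_pct}% of {t} timepoints yields "
                f"{k} < 2 points"
            )
        sel = ranking[:k] if spec.strategy == "sequential_hacf" else ranking[-k:]
    else:
        if t % spec.n_bins != 0:
            raise ValueError(
                f"{t} timepoints not divisible into {spec.n_bins} bins"
            )
        w = t // spec.n_bins
        if spec.strategy == "individual_bin":
            sel = ranking[(spec.bin - 1) * w: spec.bin * w]
        else:
            b1, b2 = spec.bin_pair
            sel = np.concatenate([ranking[(b1 - 1) * w: b1 * w],
                                  ranking[(b2 - 1) * w: b2 * w]])
    return np.sort(sel)


def estimate_fc(run: ParcellatedRun, indices: np.ndarray,
                provenance: dict | None = None) -> FCMatrix:
    """Pearson FC on the sub-series restricted to the selected timepoints.

    Means and standard deviations are recomputed on the subset (plain Pearson
    on the extracted rows). A parcel constant over the subset gets zero
    correlations with a warning.
    """
    indices = np.asarray(indices)
    if indices.size < 3:
        raise ValueError("need at least 3 selected timepoints")
    if indices.min() < 0 or indices.max() >= run.n_timepoints:
        raise ValueError("selected indices out of range")
    sub = run.data[indices]
    sd = sub.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"parcel(s) {np.flatnonzero(const).tolist()} constant over the "
            "selected timepoints; correlations set to 0",
            RuntimeWarning, stacklevel=2,
        )
        sub = sub.copy()
        sub[:, const] = 0.0
        sd = sub.std(axis=0, ddof=0)
        sd[const] = 1.0
    z = (sub - sub.mean(axis=0)) / sd
    m = (z.T @ z) / len(indices)
    m[const, :] = 0.0
    m[:, const] = 0.0
    np.fill_diagonal(m, 1.0)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    prov = dict(provenance or {})
    prov.setdefault("subject", run.subject_id)
    prov.setdefault("day", run.day)
    prov.setdefault("encoding", run.encoding)
    return FCMatrix(matrix=m, provenance=prov)


def aggregate_fc(
    fcs: Mapping[tuple, FCMatrix],
    level: Literal["per_day", "per_subject"],
) -> dict[tuple, FCMatrix]:
    """Average FC matrices over acquisition keys.

    ``fcs`` is keyed by (subject, day, encoding). "per_day" averages across
    encodings, leaving two matrices per subject (the identification input);
    "per_subject" further averages across days, leaving one (the prediction
    input). Averaging is element-wise on raw correlations.
    """
    by_day: dict[tuple, list[FCMatrix]] = {}
    for (subject, day, _enc), fc in fcs.items():
        by_day.setdefault((subject, day), []).append(fc)
    day_means = {
        key: FCMatrix(
            matrix=np.mean([fc.matrix for fc in group], axis=0),
            provenance={"subject": key[0], "day": key[1], "level": "per_day"},
        )
        for key, group in sorted(by_day.items())
    }
    if level == "per_day":
        return day_means
    if level != "per_subject":
        raise ValueError(f"unknown aggregation level {level!r}")
    by_subject: dict[tuple, list[FCMatrix]] = {}
    for (subject, _day), fc in day_means.items():
        by_subject.setdefault((subject,), []).append(fc)
    return {
        key: FCMatrix(
            matrix=np.mean([fc.matrix for fc in group], axis=0),
            provenance={"subject": key[0], "level": "per_subject"},
        )
        for key, group in sorted(by_subject.items())
    }
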