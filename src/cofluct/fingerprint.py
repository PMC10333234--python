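"""Connectome fingerprinting: identification accuracy and differential identifiability.

Identification asks whether a subject's FC profile from one scan day is more
similar (Pearson r between upper-triangle FC vectors) to their own profile
from the other day than to any other subject's. Identification accuracy
(i_acc) is the fraction of subjects for whom this holds, averaged over the
day1->day2 and day2->day1 directions. Differential identifiability is
i_diff = (i_self - i_other) * 100, the gap between mean within-subject and
mean between-subject cross-day correlations. Uncertainty comes from a
bootstrap over subjects (resample with replacement, keep unique subjects),
and conditions are compared with two-tailed Wilcoxon signed-rank tests under
Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class IdentResult:
    i_acc: float
    i_self: float
    i_other: float

    @property
    def i_diff(self) -> float:
        return (self.i_self - self.i_other) * 100.0


@dataclass
class BootstrapResult:
    results: list[IdentResult]
    n_boot: int
    seed: int
    unique_counts: list[int] = field(default_factory=list)

    @property
    def i_acc(self) -> np.ndarray:
        return np.array([r.i_acc for r in self.results])

    @property
    def i_diff(self) -> np.ndarray:
        return np.array([r.i_diff for r in self.results])

    def summary(self) -> dict:
        def stats_of(x: np.ndarray) -> dict:
            lo, hi = np.percentile(x, [2.5, 97.5])
            return {"mean": float(x.mean()), "ci_low": float(lo),
                    "ci_high": float(hi)}
        return {"i_acc": stats_of(self.i_acc), "i_diff": stats_of(self.i_diff),
                "n_boot": self.n_boot, "seed": self.seed}


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs Pearson r between rows of a and rows of b."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az ** 2).sum(axis=1))
    bsd = np.sqrt((bz ** 2).sum(axis=1))
    if (asd == 0).any() or (bsd == 0).any():
        raise ValueError("zero-variance FC vector")
    return (az @ bz.T) / np.outer(asd, bsd)


def similarity_matrix(day1: np.ndarray, day2: np.ndarray) -> np.ndarray:
    """Cross-day similarity: entry (a, b) = Pearson r(day1[a], day2[b]).

    Rows of ``day1``/``day2`` are subjects' upper-triangle FC vectors, in the
    same subject order on both days.
    """
    day1 = np.atleast_2d(np.asarray(day1, dtype=float))
    day2 = np.atleast_2d(np.asarray(day2, dtype=float))
    if day1.shape != day2.shape:
        raise ValueError("day1 and day2 must have the same shape")
    return _rowwise_corr(day1, day2)


def identification_accuracy(sim: np.ndarray) -> float:
    """Mean of the day1->day2 and day2->day1 identification rates.

    A subject counts as identified only if their diagonal similarity is the
    strict maximum of its row (resp. column); a tied maximum is a failure.
    """
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if sim.ndim != 2 or sim.shape[1] != n:
        raise ValueError("similarity matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    diag = np.diag(sim)
    off = sim.copy()
    np.fill_diagonal(off, -np.inf)
    rows = np.mean(diag > off.max(axis=1))
    cols = np.mean(diag > off.max(axis=0))
    return float((rows + cols) / 2.0)


def differential_identifiability(sim: np.ndarray) -> IdentResult:
    """i_self, i_other, and i_diff = (i_self - i_other) * 100 from one cross-day matrix."""
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    i_self = float(np.diag(sim).mean())
    mask = ~np.eye(n, dtype=bool)
    i_other = float(sim[mask].mean())
    return IdentResult(i_acc=identification_accuracy(sim), i_self=i_self,
                       i_other=i_other)


def identify(day1: np.ndarray, day2: np.ndarray) -> IdentResult:
    """Convenience: similarity matrix + both fingerprinting metrics."""
    return differential_identifiability(similarity_matrix(day1, day2))


def bootstrap_identification(day1: np.ndarray, day2: np.ndarray,
                             n_boot: int = 1000, seed: int = 0) -> BootstrapResult:
    """Bootstrap the fingerprinting metrics over subjects.

    Each resample draws n subjects with replacement, keeps the unique
    subjects, and recomputes both metrics on that subset. Resamples with
    fewer than 2 unique subjects are redrawn.
    """
    day1 = np.atleast_2d(np.asarray(day1, dtype=float))
    day2 = np.atleast_2d(np.asarray(day2, dtype=float))
    n = day1.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    results: list[IdentResult] = []
    unique_counts: list[int] = []
    while len(results) < n_boot:
        idx = np.unique(rng.integers(0, n, size=n))
        if idx.size < 2:
            logger.warning("resample with < 2 unique subjects redrawn")
            continue
        sim = similarity_matrix(day1[idx], day2[idx])
        results.append(differential_identifiability(sim))
        unique_counts.append(int(idx.size))
    return BootstrapResult(results=results, n_boot=n_boot, seed=seed,
                           unique_counts=unique_counts)


def compare_conditions(a: np.ndarray, b: np.ndarray,
                       n_comparisons: int = 1) -> dict:
    """Two-tailed Wilcoxon signed-rank test on paired metric series, Bonferroni-corrected.

    All-zero differences leave the test undefined; p = 1 is reported with a
    ``degenerate`` flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    d = a - b
    if np.all(d == 0):
        return {"statistic": float("nan"), "p_raw": 1.0, "p_bonferroni": 1.0,
                "significant": False, "degenerate": True}
    res = stats.wilcoxon(a, b, alternative="two-sided")
    p_bonf = min(1.0, float(res.pvalue) * n_comparisons)
    return {"statistic": float(res.statistic), "p_raw": float(res.pvalue),
            "p_bonferroni": p_bonf, "significant": p_bonf < 0.05,
            "degenerate": False}
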