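"""Structure-function coupling: SC-FC correlation and SC-residualised FC features.

Structural connectivity (SC) is a parcel x parcel streamline-count matrix
from diffusion tractography, consumed here as given. Coupling is the Pearson
correlation between a subject's SC and FC upper-triangle edge vectors, per
co-fluctuation bin. To ask what FC predicts beyond structure, SC can be
regressed out of each subject's FC edge vector (per-subject OLS across
edges) and the residuals used as prediction features.
"""

from __future__ import annotations

import numpy as np

from .ets import FCMatrix


class SCMatrix:
    """Nonnegative symmetric streamline-count matrix with zero diagonal."""

    def __init__(self, matrix: np.ndarray, log_transform: bool = False):
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("SC matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("SC matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("SC counts must be nonnegative")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("SC diagonal must be zero")
        self.matrix = np.log1p(m) if log_transform else m

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]

    @property
    def vec(self) -> np.ndarray:
        iu = np.triu_indices(self.n_parcels, k=1)
        return self.matrix[iu]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt((a ** 2).sum()), np.sqrt((b ** 2).sum())
    if na == 0 or nb == 0:
        raise ValueError("zero-variance vector")
    return float((a @ b) / (na * nb))


def sc_fc_correlation(fc: FCMatrix | np.ndarray, sc: SCMatrix) -> float:
    """Pearson correlation between a subject's FC and SC edge vectors."""
    fc_vec = fc.vec if isinstance(fc, FCMatrix) else np.asarray(fc, float).ravel()
    sc_vec = sc.vec
    if len(fc_vec) != len(sc_vec):
        raise ValueError("FC and SC must share the parcel order / edge count")
    if len(fc_vec) < 3:
        raise ValueError("need at least 3 edges")
    return _pearson(fc_vec, sc_vec)


def regress_sc_from_fc(fc: FCMatrix | np.ndarray, sc: SCMatrix) -> np.ndarray:
    """Per-subject OLS of the FC edge vector on [1, SC edge vector]; returns residuals."""
    fc_vec = fc.vec if isinstance(fc, FCMatrix) else np.asarray(fc, float).ravel()
    sc_vec = sc.vec
    if len(fc_vec) != len(sc_vec):
        raise ValueError("FC and SC must share the parcel order / edge count")
    if np.ptp(sc_vec) == 0:
        raise ValueError("constant SC vector is collinear with the intercept")
    x = np.column_stack([np.ones(len(sc_vec)), sc_vec])
    beta, *_ = np.linalg.lstsq(x, fc_vec, rcond=None)
    return fc_vec - x @ beta
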