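"""Bayesian region-of-practical-equivalence (ROPE) comparison of CV scores.

Two models' per-fold cross-validation scores are compared through the
posterior of their mean score difference. Under the Bayesian correlated
t-test for cross-validated results, the posterior is Student-t with
location mean(d), scale sqrt((1/k + n_test/n_train) * var(d)), and k - 1
degrees of freedom, where d are the k paired fold differences and the
n_test/n_train term is the Nadeau-Bengio correction for the overlap between
training sets of different folds. The posterior mass left of the ROPE, inside
it, and right of it gives P(x < y), P(x = y), and P(x > y). The default
half-width of 0.05 treats differences of up to five accuracy points (or 0.05
in correlation units) as practically equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_ROPE_HALFWIDTH = 0.05


@dataclass
class ROPEResult:
    """Posterior probabilities of a paired model comparison x vs y."""

    p_left: float       # P(x < y): model y better
    p_rope: float       # P(x = y): practically equivalent
    p_right: float      # P(x > y): model x better
    rope_halfwidth: float

    @property
    def decision(self) -> str:
        probs = {"<": self.p_left, "=": self.p_rope, ">": self.p_right}
        best = max(probs.values())
        # ties broken toward equivalence
        if self.p_rope == best:
            return "="
        return max(probs, key=probs.get)

    def as_dict(self) -> dict:
        return {"p_left": self.p_left, "p_rope": self.p_rope,
                "p_right": self.p_right, "rope_halfwidth": self.rope_halfwidth,
                "decision": self.decision}


def rope_compare(
    scores_x: np.ndarray,
    scores_y: np.ndarray,
    rope_halfwidth: float = DEFAULT_ROPE_HALFWIDTH,
    n_train: int | None = None,
    n_test: int | None = None,
    correlated: bool = True,
) -> ROPEResult:
    """Compare two models' paired per-fold scores with a ROPE on the mean difference.

    Parameters
    ----------
    scores_x, scores_y : array-like, shape (k,)
        Paired fold scores of models x and y (same folds).
    rope_halfwidth : float
        Half-width of the practical-equivalence region, in score units.
    n_train, n_test : int, optional
        Per-fold training/test sizes for the correlated variance correction;
        required when ``correlated`` is true.
    correlated : bool
        Apply the Nadeau-Bengio correction (default). With ``False`` — or in
        the limit n_test/n_train -> 0 — the posterior reduces to the plain
        paired t posterior with scale sqrt(var(d)/k).
    """
    x = np.asarray(scores_x, dtype=float).ravel()
    y = np.asarray(scores_y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("score series must be paired (equal length)")
    k = len(x)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if rope_halfwidth < 0:
        raise ValueError("rope_halfwidth must be nonnegative")
    d = x - y
    loc = float(d.mean())
    var = float(d.var(ddof=1))
    if correlated:
        if n_train is None or n_test is None:
            raise ValueError("correlated comparison requires n_train and n_test")
        factor = 1.0 / k + n_test / n_train
    else:
        factor = 1.0 / k
    lo, hi = -rope_halfwidth, rope_halfwidth
    if var == 0.0:
        # degenerate: all posterior mass at the observed mean difference
        p_left = 1.0 if loc < lo else 0.0
        p_right = 1.0 if loc > hi else 0.0
        p_rope = 1.0 - p_left - p_right
    else:
        scale = np.sqrt(factor * var)
        post = stats.t(df=k - 1, loc=loc, scale=scale)
        p_left = float(post.cdf(lo))
        p_right = float(post.sf(hi))
        p_rope = max(0.0, 1.0 - p_left - p_right)
    return ROPEResult(p_left=p_left, p_rope=p_rope, p_right=p_right,
                      rope_halfwidth=rope_halfwidth)
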