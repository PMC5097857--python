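"""Support-recovery and estimation-accuracy metrics.

Edges are unordered off-diagonal pairs (i, j), i < j; the diagonal is always
"present" and carries no support information, so all confusion counts are over
the ``p (p - 1) / 2`` candidate edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .objective import SampleCovariance

__all__ = ["ConfusionCounts", "confusion", "mcc", "estimation_error", "rescaled_n"]


@dataclass
class ConfusionCounts:
    """Edge-recovery confusion counts over the off-diagonal upper triangle."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_support(support, p: int, name: str) -> set:
    out = set()
    for pair in support:
        i, j = pair
        if not (0 <= i < p and 0 <= j < p) or i == j:
            raise ValueError(f"{name} contains out-of-range or diagonal pair {pair}")
        out.add((min(i, j), max(i, j)))
    return out


def confusion(true_support, est_support, p_obs: int) -> ConfusionCounts:
    """Compare estimated vs true edge sets over all candidate edges."""
    t = _check_support(true_support, p_obs, "true_support")
    e = _check_support(est_support, p_obs, "est_support")
    tp = len(t & e)
    fp = len(e - t)
    fn = len(t - e)
    tn = p_obs * (p_obs - 1) // 2 - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    ``(tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))``; 0 by convention
    when any factor of the denominator vanishes.
    """
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den == 0:
        return 0.0
    return float(c.tp * c.tn - c.fp * c.fn) / math.sqrt(den)


def estimation_error(S, est) -> float:
    """Spectral-norm identity gap ``|| S (Omega - L) - I ||_2``.

    ``est`` may be a :class:`~halfgraph.admm.PrecisionEstimate` or a bare
    precision matrix.  Zero exactly when the fitted marginal precision inverts
    the reference covariance.
    """
    Smat = S.S if isinstance(S, SampleCovariance) else np.asarray(S, dtype=float)
    R = est if isinstance(est, np.ndarray) else est.precision
    R = np.asarray(R, dtype=float)
    if Smat.shape != R.shape:
        raise ValueError(f"shape mismatch: {Smat.shape} vs {R.shape}")
    return float(np.linalg.norm(Smat @ R - np.eye(Smat.shape[0]), ord=2))


def rescaled_n(n: int, s: int, r: int, p: int) -> float:
    """Rescaled sample size ``n / ((s + r) log p)`` (natural log).

    The theoretical sample complexity of sparse-plus-low-rank recovery scales
    with the sparsity level s plus the latent rank r, times log p; plotting
    accuracy against this quantity aligns problems of different sizes.
    """
    if s + r <= 0:
        raise ValueError("s + r must be positive")
    if p < 2:
        raise ValueError("p must be >= 2")
    return float(n) / ((s + r) * math.log(p))
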