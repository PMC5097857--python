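"""Penalized Gaussian log-likelihood objectives for latent graphical models.

The data object is a sample covariance ``S`` (p x p, with its sample count n).
The model decomposes the precision of the observed variables as a sparse part
``Omega`` minus a low-rank part ``L`` capturing marginalized latent variables:

.. math::

    \\min_{\\Omega - L \\succ 0,\\; L \\succeq 0}
    \\operatorname{Tr} S(\\Omega - L) - \\log\\det(\\Omega - L)
    + \\lambda_1 P_1(\\Omega) + \\lambda_2 P_2(L)

with either the concave pair :math:`P_1 = \\sum |\\omega_{ij}|^{1/2}`,
:math:`P_2 = \\sum \\sqrt{\\sigma_i(L)}` ("half" family) or the convex pair
:math:`P_1 = \\|\\Omega\\|_1`, :math:`P_2 = \\|L\\|_*` ("convex" family, the
classical latent-variable graphical lasso).  Setting ``lam2 = 0`` and
``L = 0`` recovers the plain graphical lasso objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "SampleCovariance",
    "PenaltyConfig",
    "penalty_value",
    "neg_loglik",
    "objective",
]

SYM_TOL = 1e-8
PSD_TOL = 1e-8


@dataclass
class SampleCovariance:
    """A symmetric p x p covariance matrix together with its sample count.

    Attributes
    ----------
    S : ndarray
        Symmetric covariance (asymmetry beyond 1e-8 is an error; smaller
        asymmetry is symmetrized away).
    n : int
        Number of samples behind ``S`` (used by the BIC).
    ids : list of str, optional
        Variable labels; defaults to ``v0..v{p-1}``.
    """

    S: np.ndarray
    n: int
    ids: list | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError(f"covariance must be square, got shape {self.S.shape}")
        asym = float(np.max(np.abs(self.S - self.S.T))) if self.S.size else 0.0
        if asym > SYM_TOL:
            raise ValueError(f"covariance asymmetry {asym:.2e} exceeds {SYM_TOL:.0e}")
        self.S = 0.5 * (self.S + self.S.T)
        if np.any(np.diag(self.S) < 0):
            raise ValueError("covariance has a negative diagonal entry")
        if self.n < 1:
            raise ValueError(f"sample count must be >= 1, got {self.n}")
        if self.ids is None:
            self.ids = [f"v{i}" for i in range(self.p)]
        elif len(self.ids) != self.p:
            raise ValueError("number of ids does not match matrix dimension")

    @property
    def p(self) -> int:
        return self.S.shape[0]

    @classmethod
    def from_data(cls, X, ids=None, scale: str = "mle", center: bool = True):
        """Sample covariance from an (n_samples, p) data matrix.

        ``scale='mle'`` uses the 1/n maximum-likelihood normalization matching
        the likelihood term of the objective; ``scale='unbiased'`` uses 1/(n-1).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("data must be 2-D (n_samples, p)")
        n = X.shape[0]
        Xc = X - X.mean(axis=0) if center else X
        if scale == "mle":
            S = Xc.T @ Xc / n
        elif scale == "unbiased":
            if n < 2:
                raise ValueError("unbiased scaling needs n >= 2")
            S = Xc.T @ Xc / (n - 1)
        else:
            raise ValueError(f"unknown scale {scale!r}")
        return cls(S=S, n=n, ids=ids)


@dataclass
class PenaltyConfig:
    """Penalty family and weights.

    family : {"half", "convex"}
        "half" uses the concave bridge penalties (entrywise l1/2 on Omega,
        sum of square-rooted singular values on L); "convex" the classical
        l1 + nuclear pair.
    lam1, lam2, lam3 : float
        Sparsity, low-rank, and (joint model only) fusion weights; all >= 0.
    penalize_diagonal : bool
        Whether the diagonal of Omega is penalized (default True, the literal
        objective); support metrics ignore the diagonal either way.
    """

    family: str = "half"
    lam1: float = 0.1
    lam2: float = 0.5
    lam3: float = 0.0
    penalize_diagonal: bool = True

    def __post_init__(self):
        if self.family not in ("half", "convex"):
            raise ValueError(f"unknown penalty family {self.family!r}")
        for name in ("lam1", "lam2", "lam3"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
            setattr(self, name, v)

    @property
    def sparse_kind(self) -> str:
        return "half" if self.family == "half" else "l1"

    @property
    def lowrank_kind(self) -> str:
        return "quasinuclear" if self.family == "half" else "nuclear"

    def mask(self, p: int):
        """Boolean penalization mask for a p x p Omega (None = all entries)."""
        if self.penalize_diagonal:
            return None
        return ~np.eye(p, dtype=bool)


def penalty_value(M, kind: str, mask=None) -> float:
    """Value of a sparsity / low-rank penalty on ``M``.

    kind:
      - ``"l1"``: sum of |entries| over the mask;
      - ``"half"``: sum of sqrt(|entries|) over the mask (the l1/2 bridge
        penalty raised to the 1/2 power, i.e. the quantity actually added to
        the objective);
      - ``"nuclear"``: sum of singular values (symmetric M);
      - ``"quasinuclear"``: sum of sqrt(singular values) (symmetric M) — the
        square root of the 1/2 quasinuclear norm ``(sum sqrt(sigma_i))**2``.
    """
    M = np.asarray(M, dtype=float)
    if kind in ("l1", "half"):
        v = M if mask is None else M[np.asarray(mask, dtype=bool)]
        a = np.abs(v)
        return float(np.sum(a) if kind == "l1" else np.sum(np.sqrt(a)))
    if kind in ("nuclear", "quasinuclear"):
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("nuclear penalties need a square (symmetric) matrix")
        sig = np.abs(np.linalg.eigvalsh(0.5 * (M + M.T)))
        return float(np.sum(sig) if kind == "nuclear" else np.sum(np.sqrt(sig)))
    raise ValueError(f"unknown penalty kind {kind!r}")


def neg_loglik(S, R) -> float:
    """Gaussian negative log-likelihood term ``Tr(S R) - log det R``.

    ``S`` may be a :class:`SampleCovariance` or a bare matrix; ``R`` is the
    candidate (marginal) precision ``Omega - L`` and must be positive
    definite — the Cholesky factorization fails loudly otherwise, reporting
    the smallest eigenvalue.
    """
    Smat = S.S if isinstance(S, SampleCovariance) else np.asarray(S, dtype=float)
    R = np.asarray(R, dtype=float)
    R = 0.5 * (R + R.T)
    try:
        C = scipy.linalg.cholesky(R, lower=True)
    except scipy.linalg.LinAlgError:
        wmin = float(np.linalg.eigvalsh(R)[0])
        raise ValueError(
            f"precision candidate is not positive definite (smallest eigenvalue {wmin:.3e})"
        ) from None
    logdet = 2.0 * float(np.sum(np.log(np.diag(C))))
    return float(np.sum(Smat * R)) - logdet


def objective(S, Omega, L, cfg: PenaltyConfig) -> float:
    """Full penalized objective at ``(Omega, L)`` under ``cfg``.

    ``neg_loglik(S, Omega - L) + lam1 * P1(Omega) + lam2 * P2(L)`` with the
    penalty pair picked by ``cfg.family``.  ``L`` must be PSD to 1e-8
    (negative eigenvalues within tolerance are clipped for the penalty
    evaluation).
    """
    Omega = np.asarray(Omega, dtype=float)
    L = np.asarray(L, dtype=float)
    if L.size:
        wmin = float(np.linalg.eigvalsh(0.5 * (L + L.T))[0])
        if wmin < -PSD_TOL:
            raise ValueError(f"L has eigenvalue {wmin:.3e} below -{PSD_TOL:.0e}; not PSD")
    val = neg_loglik(S, Omega - L)
    p = Omega.shape[0]
    val += cfg.lam1 * penalty_value(Omega, cfg.sparse_kind, cfg.mask(p))
    val += cfg.lam2 * penalty_value(L, cfg.lowrank_kind)
    return val
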