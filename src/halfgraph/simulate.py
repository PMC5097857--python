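"""Synthetic latent-variable graphical model problems.

The generator emulates the standard sparse-plus-latent benchmark: plant a
small fraction of Gaussian-weighted entries in a p x p template, symmetrize,
boost the diagonal until positive definite, then marginalize out a random
subset of "latent" variables.  By the Schur complement, the inverse of the
observed block's marginal covariance decomposes as

.. math::

    \\Sigma_O^{-1} = \\Omega_{OO} - \\Omega_{OH} \\Omega_{HH}^{-1} \\Omega_{HO},

a sparse part (the ground-truth support) minus a PSD part whose rank is at
most the number of latent variables — exactly the structure the estimator is
asked to recover.

Defaults follow the benchmark protocol: p = 50 variables, 5% planted
entries (exactly round(0.05 p^2) template positions), entry variance
sigma2 = 3, 10% latent variables (45 observed), and sample sizes swept as
multiples of the observed dimension (n = p/2 and n = p being the two
low-complexity regimes of interest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .objective import SampleCovariance

__all__ = [
    "SyntheticProblem",
    "generate_precision",
    "split_latent",
    "sample_gaussian",
    "perturb_support",
]

#: diagonal boost added iteratively until the precision template is PD
DIAG_BOOST = 1.1


@dataclass
class SyntheticProblem:
    """Ground truth for one synthetic problem instance.

    ``true_sparse - true_lowrank`` equals ``inverse(Sigma_obs)`` exactly (the
    Schur-complement identity, validated to 1e-8 at construction).
    """

    Omega_full: np.ndarray
    observed_idx: np.ndarray
    Sigma_obs: np.ndarray
    true_sparse: np.ndarray
    true_lowrank: np.ndarray
    r: int  #: latent count (upper bound on rank of true_lowrank)
    s: int  #: number of nonzero off-diagonal entries of true_sparse (i < j pairs)

    @property
    def p_obs(self) -> int:
        return self.Sigma_obs.shape[0]

    @property
    def true_support(self) -> set:
        iu, ju = np.triu_indices(self.p_obs, k=1)
        keep = self.true_sparse[iu, ju] != 0
        return set(zip(iu[keep].tolist(), ju[keep].tolist()))


def generate_precision(
    p: int, density: float = 0.05, sigma2: float = 3.0, seed=None,
    return_template: bool = False,
):
    """Sparse symmetric positive-definite precision matrix.

    Exactly ``round(density * p**2)`` template positions are drawn uniformly
    without replacement in the p x p template and filled with N(0, sigma2)
    draws; the template is symmetrized (``Omega = T + T'``) and ``1.1 * I`` is
    added repeatedly until the smallest eigenvalue is positive.  Exact-count
    placement keeps the planted fraction testable.  Returns ``(Omega,
    support)`` with the off-diagonal support as {(i, j), i < j}; with
    ``return_template`` also the pre-symmetrization template.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0 < density < 1:
        raise ValueError("density must lie in (0, 1)")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    m = int(round(density * p * p))
    if m < 1:
        raise ValueError("density * p**2 must be at least 1")
    rng = np.random.default_rng(seed)
    flat = rng.choice(p * p, size=m, replace=False)
    T = np.zeros((p, p))
    T.flat[flat] = rng.normal(0.0, np.sqrt(sigma2), size=m)
    Omega = T + T.T
    while np.linalg.eigvalsh(Omega)[0] <= 0:
        Omega = Omega + DIAG_BOOST * np.eye(p)
    iu, ju = np.triu_indices(p, k=1)
    keep = Omega[iu, ju] != 0
    support = set(zip(iu[keep].tolist(), ju[keep].tolist()))
    if return_template:
        return Omega, support, T
    return Omega, support


def split_latent(
    Omega, latent_frac: float = 0.1, seed=None, mode: str = "marginal"
) -> SyntheticProblem:
    """Marginalize a random subset of variables out of a full precision matrix.

    ``round((1 - latent_frac) * p)`` indices are kept as observed.  In the
    default ``mode="marginal"`` the observed covariance is the true marginal
    ``(Omega^{-1})_OO``, whose inverse is the Schur complement
    ``Omega_OO - Omega_OH Omega_HH^{-1} Omega_HO`` — sparse minus low-rank.
    ``mode="subblock"`` instead inverts the precision subblock directly
    (``Sigma_obs = Omega_OO^{-1}``), which produces no low-rank component;
    it is kept for protocol audits only.
    """
    Omega = np.asarray(Omega, dtype=float)
    p = Omega.shape[0]
    if not 0 <= latent_frac < 1:
        raise ValueError("latent_frac must lie in [0, 1)")
    wmin = float(np.linalg.eigvalsh(Omega)[0])
    if wmin <= 0:
        raise ValueError(f"Omega must be PD (smallest eigenvalue {wmin:.3e})")
    n_obs = int(round((1.0 - latent_frac) * p))
    rng = np.random.default_rng(seed)
    observed = np.sort(rng.choice(p, size=n_obs, replace=False))
    hidden = np.setdiff1d(np.arange(p), observed)

    Ooo = Omega[np.ix_(observed, observed)]
    if mode == "marginal":
        if hidden.size:
            Ooh = Omega[np.ix_(observed, hidden)]
            Ohh = Omega[np.ix_(hidden, hidden)]
            lowrank = Ooh @ np.linalg.solve(Ohh, Ooh.T)
        else:
            lowrank = np.zeros_like(Ooo)
        Sigma_obs = np.linalg.inv(Ooo - lowrank)
    elif mode == "subblock":
        lowrank = np.zeros_like(Ooo)
        Sigma_obs = np.linalg.inv(Ooo)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    Sigma_obs = 0.5 * (Sigma_obs + Sigma_obs.T)
    lowrank = 0.5 * (lowrank + lowrank.T)

    iu, ju = np.triu_indices(n_obs, k=1)
    s = int(np.sum(Ooo[iu, ju] != 0))
    return SyntheticProblem(
        Omega_full=Omega,
        observed_idx=observed,
        Sigma_obs=Sigma_obs,
        true_sparse=Ooo,
        true_lowrank=lowrank,
        r=int(hidden.size),
        s=s,
    )


def sample_gaussian(Sigma, n: int, seed=None, center: bool = False):
    """Draw ``n`` i.i.d. zero-mean Gaussian vectors with covariance ``Sigma``.

    Returns ``(data, SampleCovariance)`` where the covariance uses the 1/n
    (maximum likelihood) normalization of the raw second moments — the mean is
    known to be zero, so no centering by default.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2")
    try:
        C = scipy.linalg.cholesky(0.5 * (Sigma + Sigma.T), lower=True)
    except scipy.linalg.LinAlgError:
        wmin = float(np.linalg.eigvalsh(Sigma)[0])
        raise ValueError(f"Sigma is not PD (smallest eigenvalue {wmin:.3e})") from None
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, Sigma.shape[0]))
    X = Z @ C.T
    Xc = X - X.mean(axis=0) if center else X
    S = Xc.T @ Xc / n
    return X, SampleCovariance(S=0.5 * (S + S.T), n=n)


def perturb_support(Omega, n_rewire: int, seed=None):
    """Rewire ``n_rewire`` off-diagonal edges of a precision matrix.

    Simple plumbing for two-condition experiments: moves the weight of
    ``n_rewire`` randomly chosen present edges onto randomly chosen absent
    positions, re-symmetrizes, and re-boosts the diagonal until PD.  Returns
    the perturbed matrix.
    """
    Omega = np.asarray(Omega, dtype=float).copy()
    p = Omega.shape[0]
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(p, k=1)
    present = np.flatnonzero(Omega[iu, ju] != 0)
    absent = np.flatnonzero(Omega[iu, ju] == 0)
    k = min(n_rewire, present.size, absent.size)
    drop = rng.choice(present, size=k, replace=False)
    add = rng.choice(absent, size=k, replace=False)
    for d, a in zip(drop, add):
        w = Omega[iu[d], ju[d]]
        Omega[iu[d], ju[d]] = Omega[ju[d], iu[d]] = 0.0
        Omega[iu[a], ju[a]] = Omega[ju[a], iu[a]] = w
    while np.linalg.eigvalsh(Omega)[0] <= 0:
        Omega = Omega + DIAG_BOOST * np.eye(p)
    return Omega
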