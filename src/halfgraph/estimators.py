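"""scikit-learn style estimators over the functional core.

:class:`LatentGGM` mirrors :class:`sklearn.covariance.GraphicalLasso` in shape
— ``fit(X)`` on an (n_samples, n_features) matrix, fitted attributes with a
trailing underscore, ``score`` as average Gaussian log-likelihood — but
decomposes the precision into a sparse part minus a PSD low-rank part for
marginalized latent variables, with either concave ("half") or convex
penalties.  :class:`LatentGGMBIC` adds BIC-based grid selection of the two
weights; :class:`JointLatentGGM` fits several conditions coupled by a fused
concave penalty.  All compose with sklearn's ``clone``/``get_params`` model
selection machinery.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .admm import ADMMConfig, fit_lvggm
from .joint import JointProblem, fit_joint
from .objective import PenaltyConfig, SampleCovariance, neg_loglik
from .selection import BICConfig, DEFAULT_LAM1_GRID, DEFAULT_LAM2_GRID, grid_search

__all__ = ["LatentGGM", "LatentGGMBIC", "JointLatentGGM"]


def _to_cov(X, covariance: str | None, scale: str, center: bool) -> SampleCovariance:
    if isinstance(X, SampleCovariance):
        return X
    X = check_array(X, ensure_min_features=2, ensure_min_samples=2)
    if covariance == "precomputed":
        return SampleCovariance(S=X, n=max(X.shape[0], 1))
    return SampleCovariance.from_data(X, scale=scale, center=center)


class LatentGGM(BaseEstimator):
    """Sparse-plus-low-rank Gaussian graphical model with concave penalties.

    Parameters
    ----------
    lam1 : float
        Sparsity weight on the entrywise penalty of the sparse part.
    lam2 : float
        Low-rank weight on the singular-value penalty of the latent part.
    penalty : {"half", "convex"}
        Concave bridge-l1/2 pair (default) or the classical l1 + nuclear pair.
    penalize_diagonal : bool
        Penalize the diagonal of the sparse part (default True).
    covariance : {None, "precomputed"}
        With "precomputed", ``fit`` expects a covariance matrix instead of a
        data matrix (its row count then stands in for the sample count; pass a
        :class:`SampleCovariance` to keep the true n).
    rho, max_iter, tol, tol_change, momentum
        ADMM controls; see :class:`halfgraph.admm.ADMMConfig`.

    Attributes
    ----------
    sparse_ : ndarray of shape (p, p)
        Fitted sparse part Omega (conditional dependencies among observed
        variables).
    lowrank_ : ndarray of shape (p, p)
        Fitted PSD low-rank part L (effect of marginalized latent variables).
    precision_ : ndarray of shape (p, p)
        Marginal precision ``Omega - L``.
    support_ : set of (i, j), i < j
        Estimated off-diagonal edge set of the sparse part.
    rank_ : int
        Rank of the low-rank part (eigenvalues above 1e-8).
    n_iter_ : int
        ADMM sweeps performed.
    converged_ : bool
    """

    def __init__(
        self,
        lam1: float = 0.01,
        lam2: float = 0.1,
        penalty: str = "half",
        penalize_diagonal: bool = True,
        covariance: str | None = None,
        scale: str = "mle",
        center: bool = True,
        rho: float = 1.0,
        max_iter: int = 500,
        tol: float = 1e-5,
        tol_change: float = 1e-6,
        momentum: str = "accelerated",
    ):
        self.lam1 = lam1
        self.lam2 = lam2
        self.penalty = penalty
        self.penalize_diagonal = penalize_diagonal
        self.covariance = covariance
        self.scale = scale
        self.center = center
        self.rho = rho
        self.max_iter = max_iter
        self.tol = tol
        self.tol_change = tol_change
        self.momentum = momentum

    def _admm_config(self) -> ADMMConfig:
        return ADMMConfig(
            rho=self.rho, max_iter=self.max_iter, tol_primal=self.tol,
            tol_change=self.tol_change, momentum=self.momentum,
        )

    def _penalty_config(self) -> PenaltyConfig:
        return PenaltyConfig(
            family=self.penalty, lam1=self.lam1, lam2=self.lam2,
            penalize_diagonal=self.penalize_diagonal,
        )

    def fit(self, X, y=None):
        S = _to_cov(X, self.covariance, self.scale, self.center)
        est = fit_lvggm(S, self._penalty_config(), self._admm_config())
        self.covariance_ = S.S
        self.n_features_in_ = S.p
        self.sparse_ = est.Omega
        self.lowrank_ = est.L
        self.precision_ = est.precision
        self.support_ = est.support
        self.rank_ = est.rank
        self.n_iter_ = est.n_iter
        self.converged_ = est.converged
        self.estimate_ = est
        return self

    def score(self, X_test, y=None) -> float:
        """Average Gaussian log-likelihood of held-out data (up to constants)."""
        check_is_fitted(self, "precision_")
        S_test = _to_cov(X_test, self.covariance, self.scale, self.center)
        return -neg_loglik(S_test, self.precision_)


class LatentGGMBIC(LatentGGM):
    """:class:`LatentGGM` with (lam1, lam2) chosen by BIC over a grid.

    The grid is traversed row-major with warm starts (the concave problem is
    nonconvex, so the path is fixed and documented); the fitted attributes
    are those of the BIC-optimal grid point.

    Additional attributes: ``lam1_``, ``lam2_`` (chosen weights),
    ``bic_surface_`` and ``grid_result_``.
    """

    def __init__(
        self,
        lam1_grid=DEFAULT_LAM1_GRID,
        lam2_grid=DEFAULT_LAM2_GRID,
        gamma: float = 1.0,
        penalty: str = "half",
        penalize_diagonal: bool = True,
        covariance: str | None = None,
        scale: str = "mle",
        center: bool = True,
        rho: float = 1.0,
        max_iter: int = 500,
        tol: float = 1e-5,
        tol_change: float = 1e-6,
        momentum: str = "accelerated",
    ):
        super().__init__(
            penalty=penalty, penalize_diagonal=penalize_diagonal,
            covariance=covariance, scale=scale, center=center, rho=rho,
            max_iter=max_iter, tol=tol, tol_change=tol_change, momentum=momentum,
        )
        self.lam1_grid = lam1_grid
        self.lam2_grid = lam2_grid
        self.gamma = gamma

    def get_params(self, deep=True):
        params = super().get_params(deep=deep)
        params.pop("lam1", None)
        params.pop("lam2", None)
        return params

    def fit(self, X, y=None):
        S = _to_cov(X, self.covariance, self.scale, self.center)
        gr = grid_search(
            S, self.lam1_grid, self.lam2_grid,
            cfg=PenaltyConfig(family=self.penalty, penalize_diagonal=self.penalize_diagonal),
            acfg=self._admm_config(),
            bcfg=BICConfig(gamma=self.gamma),
        )
        est = gr.best_estimate
        self.covariance_ = S.S
        self.n_features_in_ = S.p
        self.lam1_, self.lam2_ = gr.best
        self.bic_surface_ = gr.bic_surface
        self.grid_result_ = gr
        self.sparse_ = est.Omega
        self.lowrank_ = est.L
        self.precision_ = est.precision
        self.support_ = est.support
        self.rank_ = est.rank
        self.n_iter_ = est.n_iter
        self.converged_ = est.converged
        self.estimate_ = est
        return self


class JointLatentGGM(BaseEstimator):
    """Fused joint model over k >= 2 conditions.

    ``fit`` accepts a list of per-condition data matrices (each n_i x p over
    the same p variables) or :class:`SampleCovariance` objects.  ``lam3``
    couples consecutive conditions; ``tie_08`` applies the two-stage preset
    ``lam1[1] = 0.8 * lam1[0]`` before fitting.

    Attributes: ``sparse_``, ``lowrank_``, ``precision_``, ``support_``,
    ``rank_`` (lists, one entry per condition), ``differential_support_``.
    """

    def __init__(
        self,
        lam1: float = 0.01,
        lam2: float = 0.1,
        lam3: float = 0.01,
        penalty: str = "half",
        penalize_diagonal: bool = True,
        tie_08: bool = False,
        covariance: str | None = None,
        scale: str = "mle",
        center: bool = True,
        rho: float = 1.0,
        max_iter: int = 500,
        tol: float = 1e-5,
        tol_change: float = 1e-6,
        momentum: str = "accelerated",
    ):
        self.lam1 = lam1
        self.lam2 = lam2
        self.lam3 = lam3
        self.penalty = penalty
        self.penalize_diagonal = penalize_diagonal
        self.tie_08 = tie_08
        self.covariance = covariance
        self.scale = scale
        self.center = center
        self.rho = rho
        self.max_iter = max_iter
        self.tol = tol
        self.tol_change = tol_change
        self.momentum = momentum

    def fit(self, Xs, y=None):
        covs = [_to_cov(X, self.covariance, self.scale, self.center) for X in Xs]
        lam1 = self.lam1
        if self.tie_08:
            base = lam1 if np.isscalar(lam1) else lam1[0]
            lam1 = [base] * len(covs)
            lam1[1] = 0.8 * base
        problem = JointProblem(
            covs=covs, lam1=lam1, lam2=self.lam2, lam3=self.lam3,
            family=self.penalty, penalize_diagonal=self.penalize_diagonal,
        )
        acfg = ADMMConfig(
            rho=self.rho, max_iter=self.max_iter, tol_primal=self.tol,
            tol_change=self.tol_change, momentum=self.momentum,
        )
        fit = fit_joint(problem, acfg)
        self.n_features_in_ = problem.p
        self.sparse_ = [e.Omega for e in fit.estimates]
        self.lowrank_ = [e.L for e in fit.estimates]
        self.precision_ = [e.precision for e in fit.estimates]
        self.support_ = [e.support for e in fit.estimates]
        self.rank_ = [e.rank for e in fit.estimates]
        self.differential_support_ = fit.differential_support
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.fit_result_ = fit
        return self
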