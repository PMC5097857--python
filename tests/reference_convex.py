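"""Independent reference solver for the convex latent-variable graphical lasso.

Plain ADMM, written from scratch for cross-checking: no momentum, L updated
before Omega, scipy-based linear algebra.  The convex problem

    min  Tr(S(Omega - L)) - log det(Omega - L)
         + lam1 ||Omega||_1 + lam2 ||L||_*
    s.t. Omega - L > 0,  L >= 0

has a unique optimum, so any correct solver must reach the same objective
value; this one deliberately shares no code with the package solver beyond
numpy/scipy primitives.
"""

import numpy as np
import scipy.linalg


def _logdet_resolvent(C, rho):
    """argmin_X Tr of quadratic coupling: solves rho X - X^{-1} = C."""
    d, Q = scipy.linalg.eigh(0.5 * (C + C.T))
    x = (d + np.sqrt(d**2 + 4.0 * rho)) / (2.0 * rho)
    return (Q * x) @ Q.T


def _soft(M, t):
    return np.sign(M) * np.maximum(np.abs(M) - t, 0.0)


def _svt_psd(M, t):
    d, Q = scipy.linalg.eigh(0.5 * (M + M.T))
    d = np.maximum(d, 0.0)
    d = np.maximum(d - t, 0.0)
    return (Q * d) @ Q.T


def solve_convex_lvggm(S, lam1, lam2, rho=1.0, max_iter=4000, tol=1e-9):
    """Reference fit; returns (Omega, L) at convergence."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    X = np.eye(p)
    Omega = np.eye(p)
    L = np.zeros((p, p))
    Y = np.zeros((p, p))
    for _ in range(max_iter):
        X = _logdet_resolvent(rho * (Omega - L) - Y - S, rho)
        L = _svt_psd(Omega - X - Y / rho, lam2 / rho)
        Omega = _soft(X + L + Y / rho, lam1 / rho)
        Y = Y - rho * (Omega - L - X)
        r = np.linalg.norm(Omega - L - X)
        if r < tol:
            break
    return Omega, L
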