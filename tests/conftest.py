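import numpy as np
import pytest

from halfgraph.objective import SampleCovariance
from halfgraph.simulate import generate_precision, sample_gaussian, split_latent


def scalar_prox_oracle(y: float, lam: float, lo=None, hi=None) -> float:
    """Brute-force minimizer of 0.5*(x-y)**2 + lam*sqrt(|x|).

    Dense grid (step 1e-4) followed by local golden-section refinement;
    independent of the closed-form implementation.
    """
    if lo is None:
        lo = -abs(y) - 1.0
    if hi is None:
        hi = abs(y) + 1.0
    xs = np.arange(lo, hi, 1e-4)
    f = 0.5 * (xs - y) ** 2 + lam * np.sqrt(np.abs(xs))
    i = int(np.argmin(f))
    a, b = xs[max(i - 2, 0)], xs[min(i + 2, len(xs) - 1)]
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(80):
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc = 0.5 * (c - y) ** 2 + lam * np.sqrt(abs(c))
        fd = 0.5 * (d - y) ** 2 + lam * np.sqrt(abs(d))
        if fc < fd:
            b = d
        else:
            a = c
    x = 0.5 * (a + b)
    # x = 0 is always a candidate (the objective is nonconvex with a kink there)
    if 0.5 * y * y <= 0.5 * (x - y) ** 2 + lam * np.sqrt(abs(x)):
        return 0.0
    return float(x)


def fused_prox_oracle(a1: float, a2: float, lam: float):
    """2-D brute-force minimizer of the fused-l1/2 objective on a dense grid."""
    lo = min(a1, a2) - 1.0
    hi = max(a1, a2) + 1.0
    xs = np.arange(lo, hi, 2e-3)
    X1, X2 = np.meshgrid(xs, xs, indexing="ij")
    F = 0.5 * (X1 - a1) ** 2 + 0.5 * (X2 - a2) ** 2 + lam * np.sqrt(np.abs(X2 - X1))
    i, j = np.unravel_index(np.argmin(F), F.shape)
    # refine: for fixed difference structure the exact minimizer preserves the
    # mean, so polish by a fine 1-D search over the difference
    m = 0.5 * (a1 + a2)
    ds = np.arange(-(hi - lo), hi - lo, 1e-4)
    g = 0.25 * (ds - (a2 - a1)) ** 2 + lam * np.sqrt(np.abs(ds))
    d = ds[int(np.argmin(g))]
    cand = [(float(xs[i]), float(xs[j])), (m - d / 2.0, m + d / 2.0), (m, m)]
    best = min(
        cand,
        key=lambda t: 0.5 * (t[0] - a1) ** 2 + 0.5 * (t[1] - a2) ** 2
        + lam * np.sqrt(abs(t[1] - t[0])),
    )
    return best


@pytest.fixture(scope="session")
def bench_problem():
    """A benchmark-scale synthetic problem: p=50, 5% density, 10% latent."""
    Omega, _ = generate_precision(50, density=0.05, sigma2=3.0, seed=0)
    return split_latent(Omega, latent_frac=0.1, seed=100)


@pytest.fixture(scope="session")
def bench_cov(bench_problem):
    """Sample covariance at n = p_obs from the benchmark problem."""
    _, S = sample_gaussian(bench_problem.Sigma_obs, n=45, seed=200)
    return S


@pytest.fixture(scope="session")
def small_cov():
    """A well-conditioned 10x10 covariance with a known sparse precision."""
    rng = np.random.default_rng(7)
    A = rng.normal(size=(10, 10)) * (rng.random((10, 10)) < 0.2)
    Omega = A @ A.T + np.eye(10)
    Sigma = np.linalg.inv(Omega)
    return SampleCovariance(S=0.5 * (Sigma + Sigma.T), n=100)
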