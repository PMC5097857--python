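"""Proximity operators against brute-force minimization oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from halfgraph.prox import (
    half_threshold,
    half_threshold_limit,
    half_zero_threshold,
    prox_fused_half,
    prox_half_matrix,
    prox_quasinuclear_half,
    soft_threshold,
    svt,
)

from conftest import fused_prox_oracle, scalar_prox_oracle


class TestHalfThreshold:
    @pytest.mark.parametrize(
        "y, lam, expected",
        [
            (1.4, 1.0, 0.0),  # below threshold (3/2)*1**(2/3) = 1.5
            (2.0, 0.0, 2.0),  # identity at lam=0
            (2.0, 1.0, 1.6054),
            (3.0, 1.0, 2.69545),
            (-3.0, 1.0, -2.69545),  # odd symmetry
            (1.5, 1.0, 0.0),  # exact tie resolves to the sparse minimizer
        ],
    )
    def test_known_values(self, y, lam, expected):
        assert half_threshold(y, lam) == pytest.approx(expected, abs=1e-4)

    def test_matches_brute_force_oracle_on_grid(self):
        ys = np.linspace(-5, 5, 81)
        lams = [0.1, 0.5, 1.0, 2.0]
        checked = 0
        for lam in lams:
            for y in ys:
                assert half_threshold(y, lam) == pytest.approx(
                    scalar_prox_oracle(y, lam), abs=1e-4
                ), (y, lam)
                checked += 1
        assert checked >= 200

    def test_matches_cubic_root_route(self):
        # nonzero branch equals the squared largest root of u^3 - |y| u + lam/2
        rng = np.random.default_rng(0)
        for _ in range(50):
            lam = rng.uniform(0.1, 2.0)
            y = rng.uniform(half_zero_threshold(lam) + 1e-3, 6.0)
            roots = np.roots([1.0, 0.0, -y, lam / 2.0])
            u = max(r.real for r in roots if abs(r.imag) < 1e-12)
            assert half_threshold(y, lam) == pytest.approx(u * u, abs=1e-10)

    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 2.0])
    def test_threshold_law(self, lam):
        t = half_zero_threshold(lam)
        assert half_threshold(t - 1e-3, lam) == 0.0
        assert half_threshold(t, lam) == 0.0
        assert half_threshold(t + 1e-3, lam) != 0.0

    def test_jump_at_threshold(self):
        # the nonzero branch tends to (2/3) T(lam) as |y| decreases to T(lam)
        lam = 1.0
        t = half_zero_threshold(lam)
        assert half_threshold(t + 1e-9, lam) == pytest.approx(
            half_threshold_limit(lam), abs=1e-4
        )
        assert half_threshold_limit(1.0) == pytest.approx(1.0)

    def test_branch_objectives_tie_at_threshold(self):
        # at lam=1, y=1.5 both the zero and the limiting nonzero branch give 1.125
        y, lam = 1.5, 1.0
        x = half_threshold_limit(lam)
        f_zero = 0.5 * y * y
        f_nonzero = 0.5 * (x - y) ** 2 + lam * np.sqrt(x)
        assert f_zero == pytest.approx(1.125)
        assert f_nonzero == pytest.approx(1.125)

    @given(
        y=st.floats(-10, 10, allow_nan=False),
        lam=st.floats(0.01, 5, allow_nan=False),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_oddness_and_shrinkage(self, y, lam):
        x = half_threshold(y, lam)
        assert half_threshold(-y, lam) == pytest.approx(-x, abs=1e-12)
        if y > 0:
            assert 0.0 <= x <= y  # shrinks toward zero, never overshoots

    @given(y=st.floats(0.1, 10, allow_nan=False))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_zero_region_grows_with_lam(self, y):
        lams = np.linspace(0.01, 5, 30)
        zero = [half_threshold(y, lam) == 0.0 for lam in lams]
        # once zero, stays zero as lam grows
        assert zero == sorted(zero)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            half_threshold(1.0, -0.1)
        with pytest.raises(ValueError):
            half_threshold(np.nan, 1.0)
        with pytest.raises(ValueError):
            half_threshold(np.inf, 1.0)


class TestMatrixProx:
    def test_elementwise_application(self):
        M = np.array([[2.0, 1.4], [1.4, 2.0]])
        out = prox_half_matrix(M, 1.0)
        expected = np.array([[1.6054, 0.0], [0.0, 1.6054]])
        np.testing.assert_allclose(out, expected, atol=1e-4)

    def test_lam_zero_is_identity(self):
        M = np.arange(9, dtype=float).reshape(3, 3)
        np.testing.assert_array_equal(prox_half_matrix(M, 0.0), M)

    def test_mask_passthrough(self):
        M = np.array([[2.0, 1.4], [1.4, 2.0]])
        mask = ~np.eye(2, dtype=bool)
        out = prox_half_matrix(M, 1.0, mask)
        np.testing.assert_allclose(out, np.array([[2.0, 0.0], [0.0, 2.0]]), atol=1e-12)

    def test_mask_shape_mismatch(self):
        with pytest.raises(ValueError):
            prox_half_matrix(np.eye(3), 1.0, np.ones((2, 2), dtype=bool))

    def test_preserves_symmetry(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(6, 6))
        M = A + A.T
        out = prox_half_matrix(M, 0.3)
        np.testing.assert_allclose(out, out.T)


class TestQuasinuclearProx:
    def test_diagonal_case(self):
        out = prox_quasinuclear_half(np.diag([3.0, 1.2]), 1.0)
        np.testing.assert_allclose(out, np.diag([2.69545, 0.0]), atol=1e-4)

    def test_lam_zero_is_identity(self):
        M = np.diag([3.0, 1.2])
        np.testing.assert_allclose(prox_quasinuclear_half(M, 0.0), M, atol=1e-12)

    def test_orthogonal_conjugation_equivariance(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            d = rng.uniform(-4, 4, size=4)
            Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
            M = (Q * d) @ Q.T
            lam = rng.uniform(0.2, 1.5)
            out = prox_quasinuclear_half(M, lam)
            # oracle: scalar brute force on each eigenvalue, conjugated back
            t = np.array([scalar_prox_oracle(v, lam) for v in d])
            np.testing.assert_allclose(out, (Q * t) @ Q.T, atol=1e-4)

    def test_rank_never_increases_and_thresholds(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = rng.uniform(-3, 3, size=5)
            Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
            M = (Q * d) @ Q.T
            lam = 1.0
            out = prox_quasinuclear_half(M, lam)
            rank_in = np.sum(np.abs(d) > 1e-12)
            rank_out = np.sum(np.abs(np.linalg.eigvalsh(out)) > 1e-12)
            assert rank_out <= rank_in
            if np.any(np.abs(d) <= half_zero_threshold(lam)):
                assert rank_out < rank_in

    def test_psd_projection(self):
        M = np.diag([3.0, -5.0])
        out = prox_quasinuclear_half(M, 1.0, project_psd=True)
        np.testing.assert_allclose(out, np.diag([2.69545, 0.0]), atol=1e-4)
        assert np.linalg.eigvalsh(out)[0] >= 0

    def test_asymmetry_warns(self):
        M = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.warns(UserWarning, match="asymmetr"):
            prox_quasinuclear_half(M, 0.1)

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            prox_quasinuclear_half(np.ones((2, 3)), 0.1)


class TestFusedProx:
    def test_equal_inputs_fixed(self):
        for a in [-2.0, 0.0, 3.5]:
            assert prox_fused_half(a, a, 1.0) == (a, a)

    def test_fuse_to_mean_below_threshold(self):
        x1, x2 = prox_fused_half(0.0, 1.0, 0.5)
        assert (x1, x2) == pytest.approx((0.5, 0.5), abs=1e-6)

    def test_split_above_threshold(self):
        x1, x2 = prox_fused_half(0.0, 3.0, 0.5)
        assert x1 == pytest.approx(0.15227, abs=1e-4)
        assert x2 == pytest.approx(2.84773, abs=1e-4)

    def test_matches_2d_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a1, a2 = rng.uniform(-3, 3, size=2)
            lam = rng.uniform(0.05, 1.0)
            x1, x2 = prox_fused_half(a1, a2, lam)
            o1, o2 = fused_prox_oracle(a1, a2, lam)
            assert x1 == pytest.approx(o1, abs=1e-4)
            assert x2 == pytest.approx(o2, abs=1e-4)

    @given(
        a1=st.floats(-5, 5, allow_nan=False),
        a2=st.floats(-5, 5, allow_nan=False),
        lam=st.floats(0.01, 2, allow_nan=False),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_mean_preserved_exactly(self, a1, a2, lam):
        x1, x2 = prox_fused_half(a1, a2, lam)
        assert x1 + x2 == pytest.approx(a1 + a2, abs=1e-9)

    def test_vectorized_over_matrices(self):
        A1 = np.array([[0.0, 0.0], [1.0, 3.0]])
        A2 = np.array([[0.0, 1.0], [1.0, 0.0]])
        X1, X2 = prox_fused_half(A1, A2, 0.5)
        assert X1.shape == (2, 2)
        assert X1[1, 0] == X2[1, 0] == 1.0  # equal pair unchanged
        assert X1[0, 1] == pytest.approx(0.5, abs=1e-6)  # fused to mean


class TestConvexCounterparts:
    @pytest.mark.parametrize(
        "y, lam, expected", [(2.0, 0.5, 1.5), (0.3, 0.5, 0.0), (-2.0, 0.5, -1.5)]
    )
    def test_soft_threshold(self, y, lam, expected):
        assert soft_threshold(y, lam) == expected

    def test_svt_diagonal(self):
        out = svt(np.diag([3.0, 0.4]), 0.5)
        np.testing.assert_allclose(out, np.diag([2.5, 0.0]))

    def test_svt_psd_projection(self):
        out = svt(np.diag([3.0, -2.0]), 0.5, project_psd=True)
        np.testing.assert_allclose(out, np.diag([2.5, 0.0]))

    def test_negative_lam_raises(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -1.0)
        with pytest.raises(ValueError):
            svt(np.eye(2), -1.0)
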