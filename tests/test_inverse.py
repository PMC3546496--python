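"""Regularized difference-imaging solvers vs dense brute-force oracles."""

import numpy as np
import pytest
import scipy.linalg as la
from hypothesis import given, settings, strategies as st

from bladdereit import inverse as inv


def _dense_oracle(j, dv, d):
    """Brute-force normal-equations solve (J'J + diag(d))^-1 J' dv."""
    return np.linalg.solve(j.T @ j + np.diag(d), j.T @ dv)


class TestClosedFormExamples:
    def test_identity_tikhonov(self):
        dx = inv.solve_tikhonov(np.eye(3), np.array([2.0, 4.0, 6.0]), 1.0).delta_x
        assert np.allclose(dx, [1.0, 2.0, 3.0])

    def test_diagonal_noser(self):
        j = np.diag([1.0, 2.0])
        dv = np.array([3.0, 5.0])
        dx = inv.solve_noser(j, dv, 0.5).delta_x
        expect = np.diag(j) * dv / (np.diag(j) ** 2 * 1.5)
        assert np.allclose(dx, expect)

    @pytest.mark.parametrize("method", ["tikhonov", "noser", "combined"])
    def test_zero_difference_gives_zero(self, method):
        j = np.random.default_rng(0).normal(size=(12, 6))
        cfg = inv.RegularizationConfig(method=method, lam=0.2, epsilon=0.3)
        assert np.all(inv.solve(j, np.zeros(12), cfg).delta_x == 0)


@settings(max_examples=25, deadline=None)
@given(
    m=st.integers(8, 40),
    n=st.integers(3, 100),
    seed=st.integers(0, 2**31 - 1),
    lam=st.floats(1e-3, 10.0),
    eps=st.floats(0.01, 0.99),
)
def test_solvers_match_dense_oracle(m, n, seed, lam, eps):
    """All three solvers agree with the dense oracle to 1e-8 relative,
    in both the primal (n <= m) and dual (n > m) branches."""
    rng = np.random.default_rng(seed)
    j = rng.normal(size=(m, n))
    dv = rng.normal(size=m)
    d = np.einsum("me,me->e", j, j)
    cases = [
        (inv.solve_tikhonov(j, dv, lam).delta_x, np.full(n, lam)),
        (inv.solve_noser(j, dv, eps).delta_x, eps * d),
        (inv.solve_combined(j, dv, lam, eps).delta_x, lam + eps * d),
    ]
    for got, pen in cases:
        expect = _dense_oracle(j, dv, pen)
        denom = max(np.linalg.norm(expect), 1e-12)
        assert np.linalg.norm(got - expect) / denom < 1e-8


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), alpha=st.floats(-5.0, 5.0))
def test_solution_linear_in_dv(seed, alpha):
    rng = np.random.default_rng(seed)
    j = rng.normal(size=(20, 12))
    dv = rng.normal(size=20)
    base = inv.solve_combined(j, dv, 0.3, 0.1).delta_x
    scaled = inv.solve_combined(j, alpha * dv, 0.3, 0.1).delta_x
    assert np.allclose(scaled, alpha * base, rtol=1e-10, atol=1e-12)


class TestLimitingCases:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.j = rng.normal(size=(30, 18))
        self.dv = rng.normal(size=30)

    def test_small_epsilon_approaches_tikhonov(self):
        a = inv.solve_combined(self.j, self.dv, 0.5, 1e-10).delta_x
        b = inv.solve_tikhonov(self.j, self.dv, 0.5).delta_x
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 1e-6

    def test_small_lambda_approaches_noser(self):
        a = inv.solve_combined(self.j, self.dv, 1e-12, 0.2).delta_x
        b = inv.solve_noser(self.j, self.dv, 0.2).delta_x
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 1e-6


class TestValidation:
    def test_bad_parameters(self):
        j = np.eye(4)
        dv = np.ones(4)
        with pytest.raises(ValueError):
            inv.solve_tikhonov(j, dv, -1.0)
        with pytest.raises(ValueError):
            inv.solve_noser(j, dv, 1.5)
        with pytest.raises(ValueError):
            inv.solve_combined(j, dv, 0.1, 0.0)
        with pytest.raises(ValueError):
            inv.RegularizationConfig(method="magic").validate()

    def test_insensitive_element_identified(self):
        j = np.ones((5, 3))
        j[:, 1] = 0.0  # element 1 has no sensitivity
        with pytest.raises(ValueError, match="element 1"):
            inv.solve_noser(j, np.ones(5), 0.2)

    def test_nonfinite_rejected(self):
        j = np.eye(3)
        with pytest.raises(ValueError):
            inv.solve_tikhonov(j, np.array([1.0, np.nan, 0.0]), 0.1)


def test_ridge_reconstructor_matches_single_shot():
    rng = np.random.default_rng(9)
    j = rng.normal(size=(40, 90))
    solver = inv.RidgeReconstructor(j, lam=0.2, epsilon=0.1)
    for s in range(3):
        dv = rng.normal(size=40)
        a = solver.solve(dv).delta_x
        b = inv.solve_combined(j, dv, 0.2, 0.1).delta_x
        assert np.allclose(a, b, rtol=1e-10, atol=1e-14)


def test_first_difference_operator_and_general_l(unit_lattice):
    mesh = unit_lattice
    l_mat = inv.first_difference_operator(mesh)
    assert l_mat.shape[1] == mesh.n_tets
    # each row is (+1, -1) over a face-adjacent pair
    assert np.all(np.asarray(np.abs(l_mat).sum(axis=1)).ravel() == 2)
    assert np.all(np.asarray(l_mat.sum(axis=1)).ravel() == 0)
    rng = np.random.default_rng(3)
    j = rng.normal(size=(30, mesh.n_tets))[:, :50]
    lm = l_mat[:, :50].tocsr()
    keep = np.flatnonzero(np.asarray(np.abs(lm).sum(axis=1)).ravel() == 2)
    lm = lm[keep]
    dv = rng.normal(size=30)
    got = inv.solve_tikhonov(j, dv, 0.4, l_mat=lm).delta_x
    expect = np.linalg.solve(j.T @ j + 0.4 * (lm.T @ lm).toarray(), j.T @ dv)
    assert np.linalg.norm(got - expect) / np.linalg.norm(expect) < 1e-8


class TestConditionNumber:
    def test_trivial_matrices(self):
        cfg = inv.RegularizationConfig
        assert inv.condition_number(np.eye(3), cfg(method="jacobian")) == 1.0
        assert inv.condition_number(np.diag([2.0, 1.0]), cfg(method="jacobian")) == 2.0

    def test_regularization_strictly_improves_conditioning(self):
        rng = np.random.default_rng(11)
        j = rng.normal(size=(60, 40))
        cfg = inv.RegularizationConfig
        raw = inv.condition_number(j, cfg(method="jacobian")) ** 2  # cond(J'J)
        for method in ["tikhonov", "noser", "combined"]:
            reg = inv.condition_number(
                j, cfg(method=method, lam=0.5, epsilon=0.2)
            )
            assert 1.0 <= reg < raw

    def test_combined_below_noser(self):
        """Adding the lambda*I term to the NOSER matrix lowers the
        condition number for any lambda > 0."""
        rng = np.random.default_rng(13)
        j = rng.normal(size=(50, 30))
        cfg = inv.RegularizationConfig
        noser = inv.condition_number(j, cfg(method="noser", epsilon=0.1))
        comb = inv.condition_number(
            j, cfg(method="combined", lam=1.0, epsilon=0.1)
        )
        assert comb < noser

    def test_lanczos_path_matches_dense(self):
        """Above the dense cutoff the Woodbury shift-invert Lanczos path
        reproduces the dense eigendecomposition."""
        rng = np.random.default_rng(17)
        j = rng.normal(size=(60, 4500))
        cfg = inv.RegularizationConfig(method="combined", lam=0.3, epsilon=0.2)
        got = inv.condition_number(j, cfg)
        c = j.T @ j + 0.3 * np.eye(4500) + 0.2 * np.diag(np.einsum("me,me->e", j, j))
        ev = la.eigvalsh(c)
        assert abs(got - ev[-1] / ev[0]) / (ev[-1] / ev[0]) < 1e-8
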