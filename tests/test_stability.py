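"""Equilibrium finding and stability classification oracles."""

import numpy as np
import pytest

from dualosc.odes import assemble_odes
from dualosc.params import InducerCondition
from dualosc.stability import (
    classify_stability,
    find_equilibria,
    jacobian_at,
    routh_hurwitz_stable,
)

from conftest import make_circuit


class _Scalar:
    """Birth-death toy system: dx/dt = b - lam * x."""

    def __init__(self, b=6.0, lam=0.03):
        self.b, self.lam = b, lam

    def rhs(self, t, y):
        return np.array([self.b - self.lam * y[0]])


class _Linear:
    def __init__(self, A):
        self.A = np.asarray(A, dtype=float)

    def rhs(self, t, y):
        return self.A @ y


class TestJacobian:
    def test_linear_system_recovers_matrix(self, rng):
        A = rng.normal(size=(4, 4))
        J = jacobian_at(_Linear(A), rng.normal(size=4), method="fd")
        assert np.allclose(J, A, rtol=1e-6, atol=1e-6)

    def test_conservation_columns_sum_to_zero(self, params, rng):
        """Differentiating the per-class conservation identity: within each
        promoter class, every Jacobian column sums to zero across the
        class's occupancy rows."""
        system = assemble_odes(make_circuit("lac_ara"), params,
                               InducerCondition(0.3, 0.1))
        y = np.abs(rng.normal(5.0, 2.0, system.n))
        J = system.jacobian(0.0, y)
        for sl, _ in system.conserved_blocks:
            assert np.allclose(J[sl].sum(axis=0), 0.0, atol=1e-12)


class TestRouthHurwitz:
    @pytest.mark.parametrize(
        "coeffs,stable",
        [
            ([1.0, 1.0], True),            # s + 1
            ([1.0, 0.1, 1.0], True),       # s^2 + 0.1 s + 1 (Re = -0.05)
            ([1.0, -0.1, 1.0], False),
            ([1.0, 2.0, 3.0, 1.0], True),
            ([1.0, 1.0, 2.0, 8.0], False),  # classic Routh counterexample
        ],
    )
    def test_small_polynomials(self, coeffs, stable):
        assert routh_hurwitz_stable(coeffs) is stable

    def test_agrees_with_eigenvalues_on_random_matrices(self, rng):
        """Brute-force cross-validation: on 1000 random matrices of size
        <= 6, the Routh test on the characteristic polynomial matches the
        eigenvalue sign decision."""
        n_checked = 0
        for _ in range(1000):
            n = int(rng.integers(1, 7))
            A = rng.normal(scale=1.0, size=(n, n))
            eig_stable = bool(np.max(np.linalg.eigvals(A).real) < 0)
            # skip near-marginal draws where both methods sit on the fence
            if abs(np.max(np.linalg.eigvals(A).real)) < 1e-6:
                continue
            assert routh_hurwitz_stable(np.poly(A)) is eig_stable
            n_checked += 1
        assert n_checked > 900


class TestClassify:
    def test_one_by_one(self):
        label, eig, _ = classify_stability(np.array([[-1.0]]))
        assert label == "stable" and eig[0] == pytest.approx(-1.0)

    def test_companion_of_weakly_damped_quadratic(self):
        # s^2 + 0.1 s + 1: roots -0.05 +- i
        A = np.array([[0.0, 1.0], [-1.0, -0.1]])
        label, eig, flags = classify_stability(A)
        assert label == "stable"
        assert np.allclose(sorted(eig.real), [-0.05, -0.05])
        assert flags.get("routh_stable") is True

    def test_marginal_flag(self):
        label, _, _ = classify_stability(np.array([[1e-12]]))
        assert label == "marginal"

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            classify_stability(np.ones((2, 3)))
        with pytest.raises(ValueError):
            classify_stability(np.array([[np.nan]]))

    def test_constraint_projection_discards_structural_zero(self):
        """A conserved pair (x1 + x2 constant) contributes a zero eigenvalue
        that must not veto stability on the invariant manifold."""
        A = np.array([[-1.0, 1.0], [1.0, -1.0]])
        label_full, _, _ = classify_stability(A)
        assert label_full == "marginal"
        label, eig, _ = classify_stability(A, constraints=np.array([[1.0, 1.0]]))
        assert label == "stable" and eig.real.max() == pytest.approx(-2.0)


class TestFindEquilibria:
    def test_scalar_birth_death_closed_form(self):
        system = _Scalar(b=6.0, lam=0.03)
        reports = find_equilibria(system, [np.array([10.0])])
        assert len(reports) == 1
        r = reports[0]
        assert r.converged and r.stable
        assert r.point[0] == pytest.approx(6.0 / 0.03)
        assert r.residual_norm <= 1e-8

    def test_duplicate_roots_deduplicated(self):
        system = _Scalar()
        reports = find_equilibria(
            system, [np.array([1.0]), np.array([500.0]), np.array([123.0])]
        )
        assert len([r for r in reports if r.converged]) == 1

    def test_contract_residual_bound(self, params):
        """Every converged equilibrium satisfies ||RHS|| <= tol."""
        system = assemble_odes(make_circuit("lac"), params,
                               InducerCondition(0.01, 0.001))
        guesses = [system.initial_state(), system.initial_state(100.0, 100.0)]
        reports = find_equilibria(system, guesses, tol=1e-7)
        converged = [r for r in reports if r.converged]
        assert converged
        for r in converged:
            assert r.residual_norm <= 1e-7
            assert np.linalg.norm(system.rhs(0.0, r.point)) <= 1e-7

    def test_requires_guesses_and_positive_tol(self):
        with pytest.raises(ValueError):
            find_equilibria(_Scalar(), [])
        with pytest.raises(ValueError):
            find_equilibria(_Scalar(), [np.array([1.0])], tol=0.0)


class TestStableCellOracle:
    def test_newton_equilibrium_agrees_with_long_integration(self, params):
        """On a stable cell, integrate-to-steady-state lands on the Newton
        root (the integrate-to-steady-state oracle for the classifier)."""
        from dualosc.timecourse import integrate

        system = assemble_odes(make_circuit("lac_ara"), params,
                               InducerCondition(0.01, 0.001))
        traj = integrate(system, system.initial_state(), 800.0)
        end = traj.values[-1]
        reports = find_equilibria(system, [end], tol=1e-9)
        r = next(rep for rep in reports if rep.converged)
        assert r.stable
        # a perturbed restart converges back to the same equilibrium
        perturbed = r.point.copy()
        perturbed[system.i_a] += 5.0
        perturbed[system.i_l] += 5.0
        traj2 = integrate(system, perturbed, 1200.0)
        assert np.allclose(traj2.values[-1], r.point, rtol=1e-3, atol=1e-3)
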