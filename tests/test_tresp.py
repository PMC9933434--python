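"""Transition charges, couplings, induced dipoles and screening."""

import numpy as np
import pytest

from exciham import (
    EnvironmentModel,
    K_E,
    TransitionChargeSet,
    coulomb_coupling,
    fit_tresp_model,
    polarization_site_contribution,
    scale_charges,
    screening_term,
    solve_induced_dipoles,
    total_coupling,
)
from exciham.tresp import PolarizationError, neutralize, transition_dipole

from test_descriptors import make_geom


def pol_env(positions, alphas, charges=None):
    positions = np.atleast_2d(positions)
    n = positions.shape[0]
    return EnvironmentModel(
        positions=positions,
        charges=np.zeros(n) if charges is None else np.atleast_1d(charges),
        residue_ids=np.arange(n),
        polarizabilities=np.atleast_1d(alphas),
    )


class TestTrespRegression:
    def test_constant_targets_under_strong_shrinkage(self, small_ensemble):
        q0 = np.linspace(-0.1, 0.1, 17)
        q0 -= q0.mean()
        targets = [q0] * 30
        res = fit_tresp_model(small_ensemble[:30], targets, ridge_lambda=1e8)
        pred = res.predict(small_ensemble[30:35])
        for p in pred:
            np.testing.assert_allclose(p.charges, q0, atol=1e-4)

    def test_exact_recovery_of_linear_map(self, small_ensemble, rng):
        from exciham import coulomb_matrix

        X = np.stack([coulomb_matrix(g).values for g in small_ensemble])
        W = rng.normal(0, 0.01, (X.shape[1], 17))
        targets = X @ W  # exactly linear in the descriptor
        res = fit_tresp_model(small_ensemble, targets, ridge_lambda=1e-10,
                              neutralize_predictions=False)
        pred = res.predict(small_ensemble[:5])
        for p, t in zip(pred, targets[:5]):
            np.testing.assert_allclose(p.charges, t, atol=1e-8)

    def test_neutralization(self, small_ensemble, rng):
        targets = [rng.normal(0, 0.05, 17) for _ in range(20)]
        res = fit_tresp_model(small_ensemble[:20], targets)
        for p in res.predict(small_ensemble[20:25]):
            assert abs(p.charges.sum()) < 1e-12

    def test_inconsistent_atom_counts_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            fit_tresp_model(small_ensemble[:3], [np.zeros(17), np.zeros(17), np.zeros(5)])


class TestScaling:
    def test_identity_and_doubling(self):
        q = TransitionChargeSet(charges=[0.1, -0.1])
        assert np.array_equal(scale_charges(q, 1.0).charges, q.charges)
        np.testing.assert_array_equal(scale_charges(q, 2.0).charges, 2 * q.charges)

    def test_coupling_scales_as_gamma_product(self, rng):
        qI = TransitionChargeSet(charges=neutralize(rng.normal(0, 0.1, 4)))
        qJ = TransitionChargeSet(charges=neutralize(rng.normal(0, 0.1, 4)))
        posI = rng.normal(0, 1, (4, 3))
        posJ = rng.normal(0, 1, (4, 3)) + [12, 0, 0]
        v = coulomb_coupling(qI, posI, qJ, posJ)
        v_scaled = coulomb_coupling(
            scale_charges(qI, 1.3), posI, scale_charges(qJ, 0.7), posJ
        )
        assert v_scaled == pytest.approx(1.3 * 0.7 * v, rel=1e-12)


class TestCoulombCoupling:
    def test_unit_charges_at_one_angstrom(self):
        v = coulomb_coupling([1.0], [[0, 0, 0]], [1.0], [[0, 0, 1.5]])
        assert v == pytest.approx(K_E / 1.5, rel=1e-12)

    def test_sign_flip(self, rng):
        qI, qJ = rng.normal(0, 0.1, 3), rng.normal(0, 0.1, 3)
        pI = rng.normal(0, 1, (3, 3))
        pJ = rng.normal(0, 1, (3, 3)) + [10, 0, 0]
        assert coulomb_coupling(qI, pI, -qJ, pJ) == pytest.approx(
            -coulomb_coupling(qI, pI, qJ, pJ), rel=1e-12
        )

    def test_two_point_dipoles_against_bruteforce(self):
        qI = [0.1, -0.1]
        posI = [[0, 0, 0.5], [0, 0, -0.5]]
        qJ = [0.1, -0.1]
        posJ = [[10, 0, 0.5], [10, 0, -0.5]]
        expected = sum(
            K_E * qi * qj / np.linalg.norm(np.array(ri) - np.array(rj))
            for qi, ri in zip(qI, posI)
            for qj, rj in zip(qJ, posJ)
        )
        assert coulomb_coupling(qI, posI, qJ, posJ) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        qI, qJ = rng.normal(0, 0.1, 5), rng.normal(0, 0.1, 5)
        pI = rng.normal(0, 1, (5, 3))
        pJ = rng.normal(0, 1, (5, 3)) + [9, 0, 0]
        assert coulomb_coupling(qI, pI, qJ, pJ) == pytest.approx(
            coulomb_coupling(qJ, pJ, qI, pI), rel=1e-12
        )

    def test_overlap_rejected(self):
        with pytest.raises(PolarizationError):
            coulomb_coupling([0.1], [[0, 0, 0]], [0.1], [[0.5, 0, 0]])

    def test_dipole_dipole_distance_scaling(self):
        """Neutral two-point dipole pairs couple as 1/R^3 at long range."""
        qI = [0.1, -0.1]
        posI = np.array([[0, 0, 0.5], [0, 0, -0.5]])
        Rs = np.linspace(20, 100, 9)
        vals = [
            abs(coulomb_coupling(qI, posI, qI, posI + [R, 0, 0])) for R in Rs
        ]
        slope = np.polyfit(np.log(Rs), np.log(vals), 1)[0]
        assert slope == pytest.approx(-3.0, abs=0.05)


class TestInducedDipoles:
    def test_single_site_isolated_response(self):
        env = pol_env([[10.0, 0, 0]], [1.0])
        mu = solve_induced_dipoles(env, [1.0], [[0.0, 0.0, 0.0]])
        np.testing.assert_allclose(mu.dipoles, [[0.01, 0.0, 0.0]], atol=1e-15)

    def test_zero_polarizability_zero_dipoles(self, rng):
        env = pol_env(rng.normal(0, 1, (4, 3)) + [10, 0, 0], np.zeros(4))
        mu = solve_induced_dipoles(env, [1.0], [[0, 0, 0]])
        assert np.all(mu.dipoles == 0.0)

    def test_two_sites_match_dense_oracle(self):
        pos = np.array([[8.0, 0, 0], [8.0, 3.0, 0]])
        alpha = np.array([1.2, 0.8])
        env = pol_env(pos, alpha)
        q, qpos = [0.5], [[0.0, 0.0, 0.0]]
        mu = solve_induced_dipoles(env, q, qpos)
        # independent 6x6 construction
        E = np.zeros(6)
        for s in range(2):
            dr = pos[s] - np.array(qpos[0])
            E[3 * s:3 * s + 3] = 0.5 * dr / np.linalg.norm(dr) ** 3
        T = np.zeros((6, 6))
        dr = pos[1] - pos[0]
        r = np.linalg.norm(dr)
        block = (3 * np.outer(dr, dr) / r**2 - np.eye(3)) / r**3
        T[0:3, 3:6] = block
        T[3:6, 0:3] = block
        A = np.eye(6) - np.repeat(alpha, 3)[:, None] * T
        expected = np.linalg.solve(A, np.repeat(alpha, 3) * E).reshape(2, 3)
        np.testing.assert_allclose(mu.dipoles, expected, rtol=0, atol=1e-12)

    def test_linear_system_residual(self, rng):
        pos = rng.normal(0, 3, (6, 3)) + [12, 0, 0]
        alpha = rng.uniform(0.3, 1.5, 6)
        env = pol_env(pos, alpha)
        q = rng.normal(0, 0.2, 3)
        qpos = rng.normal(0, 1, (3, 3))
        mu = solve_induced_dipoles(env, q, qpos).dipoles
        from exciham.tresp import _dipole_interaction_matrix, charge_field

        E = charge_field(q, qpos, pos)
        T = _dipole_interaction_matrix(pos)
        rhs = (E.ravel() + T @ mu.ravel()) * np.repeat(alpha, 3)
        assert np.abs(mu.ravel() - rhs).max() <= 1e-10

    def test_close_sites_rejected(self):
        env = pol_env([[10, 0, 0], [10.5, 0, 0]], [1.0, 1.0])
        with pytest.raises(PolarizationError):
            solve_induced_dipoles(env, [1.0], [[0, 0, 0]])


class TestPolarizationContribution:
    def test_zero_transition_charges(self, ref_geom):
        env = pol_env([[12.0, 0, 0]], [1.0])
        q = TransitionChargeSet(charges=np.zeros(ref_geom.n_atoms), gamma=1.0)
        assert polarization_site_contribution(q, ref_geom, env) == 0.0

    def test_single_site_closed_form(self):
        geom = make_geom(["C"], [[0.0, 0.0, 0.0]])
        r, alpha, q = 8.0, 1.3, 0.4
        env = pol_env([[r, 0, 0]], [alpha])
        val = polarization_site_contribution(
            TransitionChargeSet(charges=[q]), geom, env
        )
        assert val == pytest.approx(-0.5 * K_E * alpha * q**2 / r**4, rel=1e-12)
        assert val < 0

    def test_against_independent_bruteforce(self, rng):
        geom = make_geom(["C"] * 5, rng.normal(0, 1.5, (5, 3)) * 0.8 + np.eye(5, 3) * 4)
        q = rng.normal(0, 0.2, 5)
        pos = rng.normal(0, 2, (3, 3)) + [10, 0, 0]
        alpha = rng.uniform(0.5, 1.5, 3)
        env = pol_env(pos, alpha)
        val = polarization_site_contribution(TransitionChargeSet(charges=q), geom, env)
        # independent: assemble field, solve, contract -- all with loops
        E = np.zeros((3, 3))
        for m in range(3):
            for i in range(5):
                dr = pos[m] - geom.coordinates[i]
                E[m] += q[i] * dr / np.linalg.norm(dr) ** 3
        A = np.eye(9)
        for m in range(3):
            for mp in range(3):
                if m == mp:
                    continue
                dr = pos[m] - pos[mp]
                r = np.linalg.norm(dr)
                A[3 * m:3 * m + 3, 3 * mp:3 * mp + 3] -= alpha[m] * (
                    (3 * np.outer(dr, dr) / r**2 - np.eye(3)) / r**3
                )
        mu = np.linalg.solve(A, np.repeat(alpha, 3) * E.ravel()).reshape(3, 3)
        expected = -0.5 * K_E * np.sum(mu * E)
        assert val == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_and_monotone_in_alpha(self, ref_geom, rng):
        q = TransitionChargeSet(charges=rng.normal(0, 0.1, ref_geom.n_atoms))
        # well-separated sites: keeps the response far from the
        # polarization instability, where monotonicity in alpha holds
        pos = np.array([[11.0, 0, 0], [11.0, 6.0, 0], [11.0, 0, 6.0], [17.0, 0, 0]])
        vals = []
        for scale in (0.5, 1.0, 2.0):
            env = pol_env(pos, scale * np.ones(4))
            vals.append(polarization_site_contribution(q, ref_geom, env))
        assert all(v <= 0 for v in vals)
        assert abs(vals[0]) <= abs(vals[1]) <= abs(vals[2])


class TestScreening:
    def _fixture(self, rng, n_sites=4):
        qI = TransitionChargeSet(charges=neutralize(rng.normal(0, 0.1, 3)))
        qJ = TransitionChargeSet(charges=neutralize(rng.normal(0, 0.1, 3)))
        posI = rng.normal(0, 1, (3, 3))
        posJ = rng.normal(0, 1, (3, 3)) + [14, 0, 0]
        pos = rng.normal(0, 1.5, (n_sites, 3)) + [7, 3, 0]
        env = pol_env(pos, rng.uniform(0.5, 1.5, n_sites))
        return qI, posI, qJ, posJ, env

    def test_no_polarizable_sites_is_zero(self, rng):
        qI, posI, qJ, posJ, env = self._fixture(rng)
        bare = EnvironmentModel(
            positions=env.positions, charges=env.charges,
            residue_ids=env.residue_ids,
            polarizabilities=np.zeros(env.n_atoms),
        )
        assert screening_term(qI, posI, qJ, posJ, bare) == 0.0
        assert screening_term(qI, posI, qJ, posJ, EnvironmentModel.empty()) == 0.0

    def test_symmetric_under_exchange(self, rng):
        for _ in range(5):
            qI, posI, qJ, posJ, env = self._fixture(rng)
            a = screening_term(qI, posI, qJ, posJ, env)
            b = screening_term(qJ, posJ, qI, posI, env)
            assert a == pytest.approx(b, abs=1e-10)

    def test_midway_site_screens_like_oriented_dipoles(self):
        """A polarizable site between two parallel dipoles reduces |V|."""
        qI = [0.2, -0.2]
        posI = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        posJ = posI + [12.0, 0, 0]
        env = pol_env([[6.0, 0, 0]], [1.5])
        v_coul = coulomb_coupling(qI, posI, qI, posJ)
        v_tot = total_coupling(qI, posI, qI, posJ, env)
        assert abs(v_tot) < abs(v_coul)

    def test_total_coupling_without_env_is_coulomb(self, rng):
        qI, posI, qJ, posJ, _ = self._fixture(rng)
        assert total_coupling(qI, posI, qJ, posJ) == coulomb_coupling(
            qI, posI, qJ, posJ
        )


def test_transition_dipole():
    q = [0.1, -0.1]
    pos = [[0, 0, 1.0], [0, 0, -1.0]]
    np.testing.assert_allclose(transition_dipole(q, pos), [0, 0, 0.2], atol=1e-15)
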