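"""Equilibria, spectra, normal-form signatures, limit cycles, categories."""

import numpy as np
import pytest

from kinecrit import (
    IntegrationOptions,
    StabilityThresholds,
    characterize_dynamics,
    classify_stability,
    equilibrium_report,
    estimate_cycle_radius,
    find_equilibrium,
    integrate,
    jacobian_at,
    make_linear_chain,
    make_normal_form_oscillator,
    orbit_structure,
    perturb_initial,
    probe_limit_cycle,
)
from kinecrit.stability import NormalFormSignature


class TestFindEquilibrium:
    def test_chain_equilibrium_location_and_residual(self, chain2):
        rep = find_equilibrium(chain2, np.array([1.0, 1.0]))
        assert rep.found
        np.testing.assert_allclose(rep.x_eq, [0.5, 0.25], rtol=1e-8)
        assert rep.residual_norm < 1e-10

    def test_knocked_chain_has_no_root(self, chain2):
        rep = find_equilibrium(chain2.knockout("e2"), chain2.x0)
        assert not rep.found  # dX2/dt = v0 > 0 everywhere upstream-balanced

    def test_residual_below_tolerance_whenever_found(self, ccm, branched):
        th = StabilityThresholds()
        for model in (ccm, branched):
            rep = find_equilibrium(model, model.x0 * 1.3, th)
            assert rep.found
            assert rep.residual_norm <= th.residual_tol

    def test_nonfinite_guess_rejected(self, chain2):
        with pytest.raises(ValueError):
            find_equilibrium(chain2, np.array([np.nan, 1.0]))


class TestJacobian:
    def test_chain_bidiagonal_structure(self, chain2):
        J = jacobian_at(chain2, chain2.x0)
        np.testing.assert_allclose(J, [[-2.0, 0.0], [2.0, -4.0]], atol=1e-6)

    def test_oscillator_at_origin_matches_analytic_blocks(self, oscillator):
        x = np.zeros(oscillator.n_dynamic)
        J = jacobian_at(oscillator, x)
        expected = np.zeros((5, 5))
        expected[:2, :2] = [[-1.0, -1.0], [1.0, -1.0]]  # beta = -1 planar block
        expected[2, 2] = expected[3, 3] = -1.0
        expected[4, 4] = +1.0
        np.testing.assert_allclose(J, expected, atol=1e-5)

    def test_finite_difference_vs_analytic_on_random_chains(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(2, 5))
            k = rng.uniform(0.5, 5.0, size=n)
            model = make_linear_chain(n, k=k)
            x = rng.uniform(0.1, 2.0, size=n)
            analytic = np.diag(-k)
            for i in range(1, n):
                analytic[i, i - 1] = k[i - 1]
            assert np.max(np.abs(jacobian_at(model, x) - analytic)) < 1e-5


class TestClassifyStability:
    def test_all_negative_is_stable(self):
        label, sig = classify_stability(np.array([-1.0, -2.0]))
        assert label == "asymptotically_stable"
        assert (sig.N_s, sig.N_u, sig.center_pairs) == (2, 0, 0)

    def test_any_positive_is_unstable(self):
        label, sig = classify_stability(np.array([+0.5, -1.0]))
        assert label == "unstable"
        assert (sig.N_s, sig.N_u, sig.center_pairs) == (1, 1, 0)

    def test_pure_imaginary_pair_is_center_candidate(self):
        ev = np.array([-1.0, -2.0, 2j, -2j, 3.0])
        label, sig = classify_stability(ev)
        assert label == "center_candidate"
        assert (sig.N_s, sig.N_u, sig.center_pairs) == (2, 1, 1)
        assert sig.dimension == 5

    def test_relative_tolerance_for_imaginary_axis(self):
        ev = np.array([1e-9 + 1.0j, 1e-9 - 1.0j])
        label, _ = classify_stability(ev, imag_tol=1e-6)
        assert label == "center_candidate"

    def test_random_triangular_matrices_follow_diagonal_signs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(2, 8))
            L = np.tril(rng.normal(size=(n, n)))
            diag = rng.choice([-1.0, 1.0], size=n) * rng.uniform(0.5, 3.0, size=n)
            np.fill_diagonal(L, diag)
            label, sig = classify_stability(np.linalg.eigvals(L))
            if np.all(diag < 0):
                assert label == "asymptotically_stable"
            else:
                assert label == "unstable"
            assert sig.N_s == int(np.sum(diag < 0))
            assert sig.N_u == int(np.sum(diag > 0))


class TestOrbitStructure:
    def test_mixed_signature_with_center_pair(self):
        sig = NormalFormSignature(N_s=15, N_u=1, center_pairs=1, sigma=+1, beta=-1.0)
        orb = orbit_structure(sig)
        assert orb.expanding_dims == 1 and orb.contracting_dims == 15
        assert orb.limit_cycle == "unstable"
        assert orb.cycle_radius == pytest.approx(1.0)

    def test_all_contracting_is_asymptotic_stability(self):
        orb = orbit_structure(NormalFormSignature(N_s=4, N_u=0, center_pairs=0))
        assert orb.limit_cycle == "none"
        assert "contract" in orb.description

    def test_unknown_beta_leaves_cycle_undetermined(self):
        orb = orbit_structure(NormalFormSignature(N_s=1, N_u=0, center_pairs=1))
        assert orb.limit_cycle == "undetermined"


class TestLimitCycleProbe:
    def test_inside_converges_outside_diverges(self):
        m = make_normal_form_oscillator(-1.0, +1)
        eq = np.zeros(2)
        out = probe_limit_cycle(m, eq, (0, 1), [0.5, 1.5], t_end=20.0)
        assert out[0.5] == "converged"
        assert out[1.5] == "diverged"

    def test_stable_node_converges_at_every_radius(self, chain2):
        out = probe_limit_cycle(chain2, np.array([0.5, 0.25]), (0, 1),
                                [0.05, 0.1], t_end=10.0)
        assert set(out.values()) == {"converged"}

    def test_on_cycle_radius_keeps_cycling_over_short_horizon(self):
        m = make_normal_form_oscillator(-1.0, +1)
        out = probe_limit_cycle(m, np.zeros(2), (0, 1), [1.0], t_end=5.0)
        assert out[1.0] == "cycling"

    @pytest.mark.parametrize("beta", [-0.5, -1.0, -2.0])
    def test_bisection_recovers_cycle_radius(self, beta):
        m = make_normal_form_oscillator(beta, +1)
        r = estimate_cycle_radius(m, np.zeros(2), (0, 1),
                                  r_lo=0.2 * np.sqrt(-beta), r_hi=1.4 * np.sqrt(-beta))
        assert r == pytest.approx(np.sqrt(-beta), rel=0.05)

    def test_bad_bracket_rejected(self):
        m = make_normal_form_oscillator(-1.0, +1)
        with pytest.raises(ValueError, match="bracket"):
            estimate_cycle_radius(m, np.zeros(2), (0, 1), r_lo=0.1, r_hi=0.5)


class TestCharacterizeDynamics:
    def test_chain_interior_knockout_no_equilibrium(self, chain2):
        rep = characterize_dynamics(chain2, "e2", chain2.x0,
                                    options=IntegrationOptions(t_end=50.0, n_grid=50))
        assert rep.category == "no_equilibrium"

    def test_dead_knockout_is_near_stable(self, branched):
        # bLow carries little flux; its deletion relocates the equilibrium
        # only slightly
        eq = find_equilibrium(branched, branched.x0)
        rep = characterize_dynamics(branched, "bLow", eq.x_eq,
                                    options=IntegrationOptions(t_end=300.0, n_grid=100))
        assert rep.category == "near_stable"
        assert all(r.residual_norm <= StabilityThresholds().residual_tol
                   for r in rep.equilibria)

    def test_strong_branch_knockout_relocates_far(self, branched):
        eq = find_equilibrium(branched, branched.x0)
        rep = characterize_dynamics(branched, "bHigh", eq.x_eq,
                                    options=IntegrationOptions(t_end=300.0, n_grid=100))
        # S moves 0.4 -> 8: far beyond half the reference norm
        assert rep.category in ("extreme_deviation", "relocated_stable")


class TestStableFixtureConvergence:
    def test_perturbed_trajectories_converge_to_found_equilibrium(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 4))
            k = rng.uniform(0.5, 5.0, size=n)
            model = make_linear_chain(n, k=k)
            rep = find_equilibrium(model, np.ones(n))
            assert rep.found
            t_end = 25.0 / k.min()
            for direction in ("+", "-"):
                x0 = perturb_initial(rep.x_eq, 0.1, direction)
                traj = integrate(model, x0, IntegrationOptions(t_end=t_end, n_grid=20))
                assert np.linalg.norm(traj.endpoint - rep.x_eq) < 1e-4
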