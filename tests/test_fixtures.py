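"""Fixture generators: closed-form anchors and reproducibility."""

import numpy as np
import pytest
import yaml
from scipy.optimize import brentq

from kinecrit import (
    FixtureSpec,
    IntegrationOptions,
    find_equilibrium,
    integrate,
    jacobian_at,
    make_branched_compensation,
    make_fixture,
    make_linear_chain,
    make_normal_form_oscillator,
)
from kinecrit.fixtures import CENTRAL_CARBON_FLUXES, CENTRAL_CARBON_STEADY_STATE
from kinecrit.model import ModelValidationError


class TestLinearChain:
    def test_analytic_steady_state(self, chain2):
        assert np.allclose(chain2.x0, [0.5, 0.25])
        assert np.max(np.abs(chain2.rhs(chain2.x0))) < 1e-12

    def test_analytic_jacobian_eigenvalues(self, chain2):
        J = jacobian_at(chain2, chain2.x0)
        assert sorted(np.linalg.eigvals(J).real) == pytest.approx([-4.0, -2.0])
        # lower-bidiagonal structure
        assert J[0, 1] == pytest.approx(0.0, abs=1e-8)
        assert J[1, 0] == pytest.approx(2.0, rel=1e-6)

    def test_knocked_step_accumulates(self, chain2):
        km = chain2.knockout("e2")
        # dX2/dt -> k1*X1* = v0 at the upstream steady state
        assert km.rhs(km.x0)[1] == pytest.approx(1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ModelValidationError):
            make_linear_chain(2, k=[1.0, -1.0])
        with pytest.raises(ModelValidationError):
            make_linear_chain(0)

    def test_random_chains_hit_closed_form_steady_state(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(1, 5))
            k = rng.uniform(0.5, 5.0, size=n)
            v0 = float(rng.uniform(0.5, 2.0))
            model = make_linear_chain(n, v0=v0, k=k)
            t_end = 25.0 / k.min()
            traj = integrate(model, np.ones(n),
                             IntegrationOptions(t_end=t_end, n_grid=50))
            assert traj.status == "completed"
            np.testing.assert_allclose(traj.endpoint, v0 / k, rtol=1e-6)


class TestBranchedCompensation:
    @staticmethod
    def _source_balance(model, dead=()):
        p = model.parameters
        vh = 0.0 if "bHigh" in dead else p["Vh"]
        vl = 0.0 if "bLow" in dead else p["Vl"]
        return lambda s: vh * s / (p["Kh"] + s) + vl * s / (p["Kl"] + s) - p["v0"]

    def test_baseline_fluxes_sum_to_inflow(self, branched):
        eq = find_equilibrium(branched, branched.x0)
        assert eq.found
        rates = branched.evaluate_rates(eq.x_eq)
        idx = branched.reaction_ids.index
        assert rates[idx("bHigh")] + rates[idx("bLow")] == pytest.approx(1.0, rel=1e-8)

    def test_deleting_high_branch_raises_low_branch_flux(self, branched):
        # independent oracle: 1-D root of the source balance of the residual system
        s_star = brentq(self._source_balance(branched, dead=("bHigh",)), 1e-6, 1e3)
        p = branched.parameters
        oracle_flux = p["Vl"] * s_star / (p["Kl"] + s_star)

        eq0 = find_equilibrium(branched, branched.x0)
        low0 = branched.evaluate_rates(eq0.x_eq)[branched.reaction_ids.index("bLow")]
        km = branched.knockout("bHigh")
        traj = integrate(km, branched.x0, IntegrationOptions(t_end=200.0))
        eq = find_equilibrium(km, traj.endpoint)
        assert eq.found
        low = km.evaluate_rates(eq.x_eq)[km.reaction_ids.index("bLow")]
        assert low > low0
        assert low == pytest.approx(oracle_flux, rel=1e-6)

    def test_deleting_both_branches_leaves_no_equilibrium(self, branched):
        km = branched.knockout("bHigh").knockout("bLow")
        eq = find_equilibrium(km, branched.x0)
        assert not eq.found  # source accumulates under constant inflow


class TestNormalFormOscillator:
    def test_inside_radius_converges(self):
        m = make_normal_form_oscillator(-1.0, +1)
        x0 = m.x0.copy()
        x0[0] = 0.5
        traj = integrate(m, x0, IntegrationOptions(t_end=30.0, n_grid=100))
        assert traj.status == "completed"
        assert np.hypot(*traj.endpoint[:2]) < 1e-3

    def test_outside_radius_diverges(self):
        # the cubic radial growth has a finite-time singularity: the run
        # ends early either via the ceiling event or via step-size collapse
        m = make_normal_form_oscillator(-1.0, +1)
        x0 = m.x0.copy()
        x0[0] = 1.5
        traj = integrate(m, x0, IntegrationOptions(t_end=30.0, n_grid=100))
        assert traj.status in ("blew_up", "solver_failed")

    def test_stable_coordinates_decay_exponentially(self, oscillator):
        x0 = oscillator.x0.copy()
        x0[:2] = 0.0  # stay at the planar origin
        traj = integrate(oscillator, x0, IntegrationOptions(t_end=3.0, n_grid=30))
        s1 = traj.column("s1")
        np.testing.assert_allclose(s1, np.exp(-traj.times), rtol=1e-6)

    def test_unstable_coordinate_grows(self, oscillator):
        x0 = oscillator.x0.copy()
        x0[:2] = 0.0
        x0[oscillator.state_index("u1")] = 1e-3
        traj = integrate(oscillator, x0, IntegrationOptions(t_end=3.0, n_grid=30))
        np.testing.assert_allclose(traj.column("u1"), 1e-3 * np.exp(traj.times), rtol=1e-6)


class TestReproducibility:
    @pytest.mark.parametrize(
        "spec",
        [
            FixtureSpec(kind="linear_chain", size=4, seed=3),
            FixtureSpec(kind="branched_compensation", seed=0),
            FixtureSpec(kind="normal_form_oscillator", size=2),
        ],
    )
    def test_identical_spec_identical_serialization(self, spec):
        a = yaml.safe_dump(make_fixture(spec).to_dict(), sort_keys=True)
        b = yaml.safe_dump(make_fixture(spec).to_dict(), sort_keys=True)
        assert a == b

    def test_different_seed_different_chain(self):
        a = make_fixture(FixtureSpec(kind="linear_chain", size=4, seed=1))
        b = make_fixture(FixtureSpec(kind="linear_chain", size=4, seed=2))
        assert a != b


class TestCentralCarbonDesign:
    def test_reference_state_is_exact_equilibrium(self, ccm):
        assert np.max(np.abs(ccm.rhs(ccm.x0))) < 1e-7

    def test_designed_fluxes_realized(self, ccm):
        rates = ccm.evaluate_rates(ccm.x0)
        for rid, rate in zip(ccm.reaction_ids, rates):
            assert rate == pytest.approx(CENTRAL_CARBON_FLUXES[rid], abs=1e-7), rid

    def test_flux_balance_of_design_table(self, ccm):
        # the declared flux table itself satisfies A.v = 0
        v = np.array([CENTRAL_CARBON_FLUXES[rid] for rid in ccm.reaction_ids])
        assert np.max(np.abs(ccm.A @ v)) < 1e-12

    def test_state_table_matches_model_x0(self, ccm):
        for mid, value in CENTRAL_CARBON_STEADY_STATE.items():
            assert ccm.initial_state[mid] == value
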