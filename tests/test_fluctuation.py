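"""Amplitudes, the (d, f) profile and the impact measure M."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinecrit import (
    IntegrationOptions,
    Trajectory,
    amplitude,
    fluctuation_profile,
    impact_measure,
    integrate,
    make_linear_chain,
)
from kinecrit.network import DistanceMap


def traj_from_columns(columns: dict) -> Trajectory:
    names = list(columns)
    states = np.column_stack([np.asarray(columns[c], dtype=float) for c in names])
    return Trajectory(
        times=np.arange(states.shape[0], dtype=float),
        states=states,
        status="completed",
        columns=names,
    )


class TestAmplitude:
    def test_identical_trajectories_give_zero(self):
        t0 = traj_from_columns({"X": [1.0, 2.0, 3.0]})
        assert amplitude(t0, t0, "X") == 0.0

    def test_constant_columns_one_vs_two(self):
        t0 = traj_from_columns({"X": [1.0, 1.0]})
        te = traj_from_columns({"X": [2.0, 2.0]})
        assert amplitude(t0, te, "X") == pytest.approx(1.0)

    def test_mixed_column_example(self):
        t0 = traj_from_columns({"X": [1.0, 1.0]})
        te = traj_from_columns({"X": [1.0, 3.0]})
        assert amplitude(t0, te, "X") == pytest.approx(np.sqrt(2.0))

    def test_mismatched_grids_rejected(self):
        t0 = traj_from_columns({"X": [1.0, 1.0]})
        te = traj_from_columns({"X": [1.0, 1.0]})
        te.times = te.times + 0.5
        with pytest.raises(ValueError, match="time grid"):
            amplitude(t0, te, "X")


class TestImpactMeasure:
    def setup_method(self):
        self.d = DistanceMap(origin="e", entity_kind="metabolite",
                             d={"a": 1, "b": 2, "c": None})

    def test_discount_examples(self):
        f = np.array([1.0, 0.5, 7.0])  # unreachable c contributes nothing
        assert impact_measure(self.d, f, ["a", "b", "c"], n=1) == pytest.approx(1.25)
        assert impact_measure(self.d, f, ["a", "b", "c"], n=2) == pytest.approx(1.125)

    def test_weight_mode(self):
        f = np.array([1.0, 0.5, 0.0])
        assert impact_measure(self.d, f, ["a", "b", "c"], n=1, mode="weight") == pytest.approx(2.0)

    def test_zero_amplitudes_give_zero(self):
        for n in (1, 2, 3):
            assert impact_measure(self.d, np.zeros(3), ["a", "b", "c"], n=n) == 0.0

    def test_indexing_mismatch_rejected(self):
        with pytest.raises(ValueError):
            impact_measure(self.d, np.zeros(2), ["a", "b", "c"], n=1)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            impact_measure(self.d, np.zeros(3), ["a", "b", "c"], n=0)

    @given(
        f=st.lists(st.floats(0, 1e3), min_size=1, max_size=12),
        dvals=st.lists(st.integers(1, 9), min_size=12, max_size=12),
        n=st.integers(1, 5),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_monotone_nonincreasing_in_n(self, f, dvals, n):
        ents = [f"x{i}" for i in range(len(f))]
        dmap = DistanceMap("e", "metabolite", dict(zip(ents, dvals)))
        f = np.asarray(f)
        assert impact_measure(dmap, f, ents, n=n + 1) <= impact_measure(dmap, f, ents, n=n) + 1e-12


class TestProfile:
    def test_dead_enzyme_knockout_has_zero_profile(self, branched):
        dead = branched.knockout("bLow")
        prof = fluctuation_profile(dead, "bLow",
                                   options=IntegrationOptions(t_end=50.0, n_grid=50))
        assert np.all(prof.f == 0.0)
        assert all(v == 0.0 for v in prof.M.values())

    def test_chain_knockout_closed_form_amplitude(self, chain2):
        # starting at the steady state, e2 deletion leaves X1 untouched and
        # ramps X2 as X2* + v0*t; both columns have closed forms
        opts = IntegrationOptions(t_end=10.0, n_grid=100)
        prof = fluctuation_profile(chain2, "e2", options=opts)
        t = np.linspace(0, opts.t_end, opts.n_grid + 1)
        expected_x2 = np.sqrt(
            np.trapezoid((1.0 * t) ** 2, t) / np.trapezoid(np.full(t.shape, 0.25**2), t)
        )
        i_x2 = prof.entities.index("X2")
        assert prof.f[i_x2] == pytest.approx(expected_x2, rel=1e-6)
        assert prof.f[prof.entities.index("X1")] == pytest.approx(0.0, abs=1e-6)

    def test_flux_view_excludes_own_reaction(self, chain2):
        prof = fluctuation_profile(chain2, "e2", view="flux",
                                   options=IntegrationOptions(t_end=10.0, n_grid=50))
        assert "e2" not in prof.entities

    def test_zero_norm_column_flagged_not_crashed(self):
        # X2 starts at 0 and stays 0 in the wild type (k1 = 0 silences the chain)
        model = make_linear_chain(2, v0=1.0, k=[1.0, 1.0])
        model.parameters["k1"] = 0.0
        x0 = np.array([0.0, 0.0])
        prof = fluctuation_profile(model, "e2",
                                   options=IntegrationOptions(t_end=10.0, n_grid=20),
                                   x0=x0)
        assert prof.f[prof.entities.index("X2")] == 0.0  # difference is also zero
        assert "X2" in prof.zero_norm_entities

    def test_truncated_flag_on_divergent_knockout(self):
        model = make_linear_chain(2, v0=1.0, k=[1.0, 1.0])
        prof = fluctuation_profile(
            model, "e2",
            options=IntegrationOptions(t_end=3e6, n_grid=300),
        )
        assert prof.truncated  # X2 ramp crosses the 1e6 mM ceiling before t_end

    def test_amplitude_behavior_after_convergence(self, branched):
        # once both systems sit at their steady states, an entity with a
        # persistent deviation (S relocates 0.4 -> 8) keeps a stable
        # amplitude, while one that returns to baseline (T ends at its
        # original value) sees its amplitude diluted by the converged tail
        prof_short = fluctuation_profile(
            branched, "bHigh", options=IntegrationOptions(t_end=300.0, n_grid=300)
        )
        prof_long = fluctuation_profile(
            branched, "bHigh", options=IntegrationOptions(t_end=600.0, n_grid=600)
        )
        i_s = prof_short.entities.index("S")
        i_t = prof_short.entities.index("T")
        assert prof_long.f[i_s] == pytest.approx(prof_short.f[i_s], rel=5e-2)
        assert prof_long.f[i_t] < prof_short.f[i_t]
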