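"""Michaelis-Menten kinetics, inactivation law and the transport solver."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import telisim as ts
from telisim.errors import DataError, SolverError
from telisim.reaction_transport import (
    TURNOVERS_PER_INF,
    KineticParams,
    PowerTrace,
    ReactionTrace,
    active_enzyme,
    heat_source_series,
    mm_rate,
    simulate_reaction_diffusion,
)
from telisim.units import FMOL

from conftest import tiny_geometry, tiny_resolution


class TestMMRate:
    def test_hand_evaluated_example(self):
        # 10 fmol catalase at kcat 260000 1/s, S = 1 mM, Km = 93 mM
        v = mm_rate(1.0, 10 * FMOL, 260_000.0, 93.0)
        assert v == pytest.approx(2.6e-9 / 94.0, rel=1e-12)
        assert v == pytest.approx(2.766e-11, rel=1e-3)

    def test_zero_substrate_and_half_saturation(self):
        assert mm_rate(0.0, 10 * FMOL, 2.6e5, 93.0) == 0.0
        assert mm_rate(93.0, 10 * FMOL, 2.6e5, 93.0) == pytest.approx(
            0.5 * 2.6e5 * 10 * FMOL)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mm_rate(-1.0, 1e-15, 1e5, 93.0)
        with pytest.raises(ValueError):
            mm_rate(1.0, -1e-15, 1e5, 93.0)

    @given(st.floats(0, 1e3), st.floats(0, 1e3))
    def test_bounded_and_monotone_in_s(self, s1, s2):
        E, kcat, Km = 2.5 * FMOL, 1e5, 93.0
        lo, hi = sorted((s1, s2))
        assert mm_rate(lo, E, kcat, Km) <= mm_rate(hi, E, kcat, Km)
        assert mm_rate(hi, E, kcat, Km) <= kcat * E


class TestActiveEnzyme:
    def test_linear_depletion_examples(self):
        Ea = 2.5 * FMOL
        assert active_enzyme(Ea, 0.0, 4.0) == Ea
        # exhaustion at C = Ea * InF * 1e7 = 1e-7 mol
        assert active_enzyme(Ea, 1.0e-7, 4.0) == pytest.approx(0.0, abs=1e-25)
        assert active_enzyme(Ea, 5.0e-8, 4.0) == pytest.approx(1.25 * FMOL)

    def test_infinite_inf_disables_inactivation(self):
        assert active_enzyme(1 * FMOL, 1e3, math.inf) == 1 * FMOL

    @given(st.floats(0, 1e-6), st.floats(0, 1e-6))
    def test_monotone_nonincreasing_in_consumption(self, c1, c2):
        lo, hi = sorted((c1, c2))
        assert active_enzyme(1 * FMOL, hi, 2.0) <= active_enzyme(1 * FMOL, lo, 2.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            active_enzyme(1 * FMOL, -1.0, 4.0)
        with pytest.raises(ValueError):
            active_enzyme(1 * FMOL, 0.0, 0.0)


class TestKineticParams:
    @pytest.mark.parametrize("bad", [
        dict(Ea=-1e-15, kcat=1e5),
        dict(Ea=1e-15, kcat=0.0),
        dict(Ea=1e-15, kcat=1e5, Km=0.0),
        dict(Ea=1e-15, kcat=1e5, InF=0.0),
        dict(Ea=1e-15, kcat=1e5, dH=-1.0),
    ])
    def test_invariants(self, bad):
        with pytest.raises(ValueError):
            KineticParams(**bad)

    def test_turnover_capacity(self):
        kin = KineticParams(Ea=2.5 * FMOL, kcat=1e5, InF=4.0)
        assert kin.turnover_capacity == pytest.approx(1e-7)
        assert math.isinf(KineticParams(Ea=1e-15, kcat=1e5).turnover_capacity)


class TestWellMixedOracle:
    """Closed well-mixed reactor vs an independent high-accuracy ODE solve."""

    def test_matches_ode_integration_within_1pct(self, tiny_grid):
        kin = KineticParams(Ea=10 * FMOL, kcat=260_000.0, Km=93.0,
                            t_start=0.0)
        S0 = 1.0
        trace, _ = simulate_reaction_diffusion(
            tiny_grid, kin, S0, t_end=5.0, dt=0.02,
            diffusion=False, sink="all_liquid")
        V = tiny_grid.region_volume("channel_liquid", "reaction_zone")

        def rhs(t, y):
            return [-kin.kcat * kin.Ea * y[0] / ((kin.Km + y[0]) * V)]

        sol = solve_ivp(rhs, (0.0, 5.0), [S0], t_eval=trace.times,
                        rtol=1e-10, atol=1e-14)
        consumed_ode = (S0 - sol.y[0]) * V
        mask = consumed_ode > 1e-18
        assert np.allclose(trace.consumed[mask], consumed_ode[mask], rtol=0.01)

    def test_no_enzyme_conserves_substrate(self, tiny_grid):
        kin = KineticParams(Ea=0.0, kcat=1e5)
        trace, _ = simulate_reaction_diffusion(tiny_grid, kin, 1.0,
                                               t_end=1.0, dt=0.02)
        assert np.all(trace.consumed <= 1e-6 * trace.initial_substrate)
        assert np.all(np.abs(trace.rate) <= 1e-6 * trace.initial_substrate)
        assert np.all(trace.active == 0.0)


class TestTransportSolver:
    @pytest.mark.parametrize("S0,kcat,InF", [
        (1.0, 2.6e5, math.inf),
        (10.0, 1e5, 4.0),
        (5.0, 5e4, 1.0),
    ])
    def test_mass_conservation(self, tiny_grid, S0, kcat, InF):
        kin = KineticParams(Ea=5 * FMOL, kcat=kcat, InF=InF)
        trace, snaps = simulate_reaction_diffusion(
            tiny_grid, kin, S0, t_end=3.0, dt=0.02,
            field_times=[1.0, 3.0])
        bx, by, bz = tiny_grid.channel_box
        vols = tiny_grid.volumes()[bx, by, bz]
        for t, field in snaps:
            remaining = float((vols * field).sum())
            i = int(round(t / 0.02))
            total = remaining + trace.consumed[i]
            assert total == pytest.approx(trace.initial_substrate, rel=1e-3)
            assert np.all(field >= 0)

    def test_inactivation_plateau_at_capacity(self, tiny_grid):
        # enzyme so weakly protected it dies mid-run: consumption
        # plateaus at Ea * InF * 1e7
        kin = KineticParams(Ea=0.05 * FMOL, kcat=1e6, Km=93.0, InF=0.02,
                            t_start=0.0)
        trace, _ = simulate_reaction_diffusion(tiny_grid, kin, 50.0,
                                               t_end=8.0, dt=0.02)
        cap = kin.turnover_capacity
        assert trace.consumed[-1] == pytest.approx(cap, rel=1e-6)
        assert trace.active[-1] <= 1e-5 * kin.Ea
        # plateau: last second adds (nearly) nothing
        i = int(round(7.0 / 0.02))
        assert trace.consumed[-1] - trace.consumed[i] < 1e-3 * cap

    def test_consumption_monotone_in_enzyme_amount(self, tiny_grid):
        traces = []
        for ea in (1 * FMOL, 2 * FMOL, 5 * FMOL):
            kin = KineticParams(Ea=ea, kcat=1e5)
            tr, _ = simulate_reaction_diffusion(tiny_grid, kin, 5.0,
                                                t_end=2.0, dt=0.02)
            traces.append(tr.consumed)
        assert np.all(traces[1] >= traces[0] - 1e-20)
        assert np.all(traces[2] >= traces[1] - 1e-20)

    def test_dt_halving_drift_below_2pct(self, tiny_grid):
        kin = KineticParams(Ea=5 * FMOL, kcat=2.6e5)
        a, _ = simulate_reaction_diffusion(tiny_grid, kin, 1.0, t_end=2.0,
                                           dt=0.02)
        b, _ = simulate_reaction_diffusion(tiny_grid, kin, 1.0, t_end=2.0,
                                           dt=0.01)
        assert b.consumed[-1] == pytest.approx(a.consumed[-1], rel=0.02)

    def test_invalid_inputs(self, tiny_grid):
        kin = KineticParams(Ea=1 * FMOL, kcat=1e5)
        with pytest.raises(ValueError):
            simulate_reaction_diffusion(tiny_grid, kin, -1.0)
        with pytest.raises(ValueError):
            simulate_reaction_diffusion(tiny_grid, kin, 1.0, t_end=0.01)


class TestHeatSource:
    def test_constant_turnover_gives_constant_power(self):
        times = np.arange(11) * 0.1
        consumed = 1e-9 * times  # 1 nmol/s
        rt = ReactionTrace(times=times, consumed=consumed,
                           active=np.full(11, 1e-15), rate=np.full(11, 1e-9),
                           initial_substrate=1.0)
        pt = heat_source_series(rt, 9.8e4)
        assert np.allclose(pt.power[1:], 98e-6)  # 98 uW
        assert pt.power[0] == 0.0

    def test_energy_closes_with_enthalpy(self, tiny_grid):
        kin = KineticParams(Ea=5 * FMOL, kcat=2.6e5)
        rt, _ = simulate_reaction_diffusion(tiny_grid, kin, 5.0, t_end=2.0,
                                            dt=0.02)
        pt = heat_source_series(rt, kin.dH)
        assert pt.energy() == pytest.approx(kin.dH * rt.consumed[-1],
                                            rel=0.005)

    def test_zero_consumption_zero_power(self):
        times = np.arange(5) * 0.1
        rt = ReactionTrace(times=times, consumed=np.zeros(5),
                           active=np.ones(5) * 1e-15, rate=np.zeros(5),
                           initial_substrate=1.0)
        assert np.all(heat_source_series(rt, 9.8e4).power == 0)

    def test_non_monotone_consumption_rejected(self):
        times = np.arange(4) * 0.1
        with pytest.raises(DataError):
            ReactionTrace(times=times,
                          consumed=np.array([0.0, 1e-12, 5e-13, 2e-12]),
                          active=np.full(4, 1e-15), rate=np.zeros(4),
                          initial_substrate=1.0)
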