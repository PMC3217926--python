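"""ODE compilation and protocol simulation: conservation, equilibria,
ground-state behavior."""


import numpy as np
import pytest

from integrinsim import bngl, fixtures
from integrinsim import simulate as sim
from integrinsim.engine import generate_network


def _compile_fixture(fid):
    fx = fixtures.generate_toy_fixture(fid)
    parsed = bngl.parse_model(fx.model_text)
    net = generate_network(parsed.molecules, parsed.rules, [s.species for s in parsed.seeds])
    volumes = dict(parsed.compartments)
    volumes.setdefault("EC", 1.0)
    volumes.setdefault("PM", 0.01)
    volumes.setdefault("CP", 1.0)
    system = sim.compile_odes(net, volumes)
    return fx, parsed, net, system


def _seed_state(parsed, net, system):
    y0 = np.zeros(system.n_species)
    for seed in parsed.seeds:
        y0[net.index[seed.species.label]] = parsed.parameters[seed.amount_expr]
    return y0


class TestDimerEquilibrium:
    def test_matches_closed_form(self):
        """A+B<->AB relaxes to the root of the quadratic KD relation."""
        fx, parsed, net, system = _compile_fixture("dimer")
        k = system.rates(parsed.parameters)
        y = system.steady_state(_seed_state(parsed, net, system), k)
        ab = y[net.index["@CP:A(b!1).B(a!1)"]]
        p = parsed.parameters
        expected = fx.oracle["equilibrium_AB"](p["kon"], p["koff"], p["A_tot"], p["B_tot"])
        assert ab == pytest.approx(expected, rel=1e-6)

    def test_symmetric_dimer_closed_form(self):
        """The kon/2 convention gives the documented A+A equilibrium."""
        fx, parsed, net, system = _compile_fixture("symmetric-dimer")
        k = system.rates(parsed.parameters)
        y = system.steady_state(_seed_state(parsed, net, system), k)
        aa = y[net.index["@CP:A(b!1).A(b!1)"]]
        p = parsed.parameters
        expected = fx.oracle["equilibrium_AA"](p["kon"], p["koff"], p["A_tot"])
        assert aa == pytest.approx(expected, rel=1e-6)

    def test_shuttle_equilibrium_closed_form(self):
        """Shuttling plus membrane binding: amounts match the exact algebra
        with the 1/V_PM collision correction."""
        fx, parsed, net, system = _compile_fixture("shuttling-pair")
        p = parsed.parameters
        k = system.rates(p)
        y = system.steady_state(_seed_state(parsed, net, system), k)
        expected = fx.oracle["equilibrium"](
            p["kin"], p["kout"], p["KD"], p["M_tot"], p["N_tot"], 0.01
        )
        assert y[net.index["@PM:M(x)"]] == pytest.approx(expected["M_pm_free"], rel=1e-5)
        assert y[net.index["@CP:M(x)"]] == pytest.approx(expected["M_cp_free"], rel=1e-5)
        assert y[net.index["@PM:M(x!1).N(x!1)"]] == pytest.approx(expected["MN"], rel=1e-5)


class TestConservation:
    def test_mass_conserved_along_trajectory(self, default_model, default_system):
        params = default_model.parameters()
        gs = sim.find_ground_state(default_model, default_system, params)
        traj = sim.run_protocol(
            default_model, default_system, params, sim.Protocol.oi(), gs
        )
        for mol, w in default_system.conservation.items():
            tot = traj.states @ w
            ref = max(tot.max(), 1e-12)
            assert np.ptp(tot) / ref < 1e-6, mol

    def test_nonnegative_states(self, default_model, default_system):
        params = default_model.parameters()
        gs = sim.find_ground_state(default_model, default_system, params)
        traj = sim.run_protocol(
            default_model, default_system, params, sim.Protocol.io(), gs
        )
        assert traj.states.min() >= 0.0


class TestGroundState:
    def test_restarting_stays_put(self, default_model, default_system):
        params = default_model.parameters()
        gs = sim.find_ground_state(default_model, default_system, params)
        p = dict(params)
        p["k7b"] = 0.0
        p["L_tot"] = 0.0
        k = default_system.rates(p)
        y = default_system._odeint(gs, np.array([0.0, 36000.0]), k)[-1]
        assert np.abs(y - gs).max() < 1e-6 * max(gs.max(), 1.0)

    def test_membrane_talin_and_pipki_nonzero_at_rest(
        self, default_model, default_system, observable_matrix
    ):
        """Talin and PIPKI accumulate at the membrane even without ligand."""
        params = default_model.parameters()
        gs = sim.find_ground_state(default_model, default_system, params)
        obs = observable_matrix @ gs
        names = default_model.observable_names
        assert obs[names.index("TAL_PM")] > 0.05
        assert obs[names.index("PIPKI_PM")] > 0.01

    def test_gs_trajectory_constant(self, default_model, default_system):
        params = default_model.parameters()
        gs = sim.find_ground_state(default_model, default_system, params)
        traj = sim.run_protocol(
            default_model, default_system, params, sim.Protocol.gs(), gs
        )
        drift = np.abs(traj.states - gs).max()
        assert drift < 1e-6 * max(gs.max(), 1.0)


class TestNumerics:
    def test_tolerance_independence(self, default_model, default_system, observable_matrix):
        """Halving solver tolerances moves final observables by < 0.1%."""
        params = default_model.parameters()
        gs = sim.find_ground_state(default_model, default_system, params)
        p = dict(params)
        p["k7b"], lig = 0.0, None
        for seed in default_model.seeds:
            if seed.amount_expr == "L_tot":
                lig = seed.species.label
        k = default_system.rates(p)
        y0 = gs.copy()
        y0[default_system.network.index[lig]] = p["L_tot"]
        t = np.array([0.0, 36000.0])
        a = default_system._odeint(y0, t, k)[-1]
        b = default_system._odeint(y0, t, k, rtol=sim.RTOL / 2, atol=sim.ATOL / 2)[-1]
        oa, ob = observable_matrix @ a, observable_matrix @ b
        scale = np.maximum(np.abs(oa), 1e-6)
        assert np.max(np.abs(oa - ob) / scale) < 1e-3


class TestProtocols:
    def test_protocol_invariants(self):
        with pytest.raises(ValueError):
            sim.Protocol(mode="GS", rule_7b_enabled=True)
        with pytest.raises(ValueError):
            sim.Protocol(mode="IO", ligand_total=10.0)
        assert sim.Protocol.io().rule_7b_enabled

    def test_io_with_talin_knockout_stays_at_ground_state(
        self, default_model, default_system, observable_matrix
    ):
        """Inside-out signaling is talin-dependent: the knockout shows no
        activation above its own ground state."""
        from integrinsim.model import knockout

        ko = knockout(default_model, "TAL")
        params = dict(default_model.parameters())
        params["TAL_tot"] = 0.0
        gs = sim.find_ground_state(ko, default_system, params)
        traj = sim.run_protocol(ko, default_system, params, sim.Protocol.io(), gs, observable_matrix)
        oi = default_model.observable_names.index("openINT")
        gs_open = (observable_matrix @ gs)[oi]
        assert traj.steady("openINT") < gs_open * 1.5 + 1e-3

    def test_activation_precedes_talin_engagement(
        self, default_model, default_system, observable_matrix
    ):
        """Outside-in: open integrin reaches half its final rise before the
        talin:integrin complex does (fast activation, slow recruitment)."""
        from integrinsim.scans import half_time

        params = default_model.parameters()
        params["TAL_tot"] = 5.0  # talin-replete conditions
        gs = sim.find_ground_state(default_model, default_system, params)
        traj = sim.run_protocol(
            default_model, default_system, params, sim.Protocol.oi(), gs, observable_matrix
        )
        t_open = half_time(traj.times, traj.observable("openINT"), traj.observable("openINT")[0])
        t_tal = half_time(traj.times, traj.observable("INT_TAL"), traj.observable("INT_TAL")[0])
        assert t_open < t_tal
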