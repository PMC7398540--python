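"""Weekly energy-balance dynamics: scalar algebra, vectorized step, fixed points."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from obesinet.dynamics import (
    AgentState,
    ModelParams,
    apply_threshold,
    env_modulate,
    initialize_states,
    run_simulation,
    social_influence,
    adjacency_matrix,
    step_week,
    weight_update,
)
from obesinet.network import SocialNetwork, HomophilyParams, generate_network
from obesinet.population import compute_ree, partition_energy
from conftest import make_person


def make_network(persons, edges):
    g = nx.Graph()
    g.add_nodes_from(p.id for p in persons)
    g.add_edges_from(edges)
    return SocialNetwork(graph=g, density_param=0.0, homophily_params=HomophilyParams(), seed=0)


class TestSocialInfluence:
    def setup_method(self):
        self.persons = [make_person(id=i, ei=2000 + 100 * i) for i in range(4)]
        self.net = make_network(self.persons, [(0, 1), (0, 2), (0, 3)])
        self.params = ModelParams()

    def test_mean_neighbour_difference(self):
        rng = np.random.default_rng(0)
        states = initialize_states(self.persons, self.params, rng)
        states.ei = np.array([2000.0, 2100.0, 1900.0, 2300.0])
        assert social_influence(states, self.net, 0, "EI") == pytest.approx(100.0)

    def test_homogeneous_neighbours_zero(self):
        rng = np.random.default_rng(0)
        states = initialize_states(self.persons, self.params, rng)
        states.ei = np.full(4, 2000.0)
        assert social_influence(states, self.net, 0, "EI") == 0.0

    def test_isolated_agent_zero(self):
        net = make_network(self.persons, [(1, 2)])
        rng = np.random.default_rng(0)
        states = initialize_states(self.persons, self.params, rng)
        assert social_influence(states, net, 0, "EI") == 0.0
        assert social_influence(states, net, 0, "PA") == 0.0


class TestEnvModulate:
    def test_env_one_is_identity(self):
        for channel in ("EI", "PA"):
            for raw in (-80.0, 0.0, 120.0):
                assert env_modulate(raw, 1.0, channel) == pytest.approx(raw)

    def test_harmful_env_amplifies_positive_intake_influence(self):
        assert env_modulate(50.0, 0.82, "EI") == pytest.approx(50.0 / 0.82)

    def test_harmful_env_dampens_positive_activity_influence(self):
        assert env_modulate(50.0, 0.82, "PA") == pytest.approx(41.0)

    def test_negative_influences_mirrored(self):
        assert env_modulate(-50.0, 0.82, "EI") == pytest.approx(-41.0)
        assert env_modulate(-50.0, 0.82, "PA") == pytest.approx(-50.0 / 0.82)

    def test_nonpositive_env_rejected(self):
        with pytest.raises(ValueError):
            env_modulate(10.0, 0.0, "EI")

    @given(raw=st.floats(0.01, 500), env_a=st.floats(0.5, 1.9), env_b=st.floats(0.5, 1.9))
    @settings(max_examples=40, deadline=None)
    def test_monotonicity_in_env(self, raw, env_a, env_b):
        """Positive influence: intake channel non-increasing in Env, activity
        channel non-decreasing; signs always preserved."""
        lo, hi = sorted((env_a, env_b))
        assert env_modulate(raw, lo, "EI") >= env_modulate(raw, hi, "EI")
        assert env_modulate(raw, lo, "PA") <= env_modulate(raw, hi, "PA")
        assert env_modulate(raw, lo, "EI") > 0 and env_modulate(-raw, lo, "PA") < 0


class TestApplyThreshold:
    def test_deadband(self):
        assert apply_threshold(2000.0, 100.0, 0.07, 0.05) == 2000.0

    def test_upward_adjustment(self):
        assert apply_threshold(2000.0, 150.0, 0.07, 0.05) == pytest.approx(2100.0)

    def test_downward_adjustment(self):
        assert apply_threshold(2000.0, -150.0, 0.07, 0.05) == pytest.approx(1900.0)

    def test_no_change_at_exact_boundary(self):
        # strict inequalities: equality leaves the level untouched
        assert apply_threshold(2000.0, 140.0, 0.07, 0.05) == 2000.0
        assert apply_threshold(2000.0, -140.0, 0.07, 0.05) == 2000.0

    @given(prev=st.floats(100, 5000), combined=st.floats(-2000, 2000))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_for_impact_below_one(self, prev, combined):
        assert apply_threshold(prev, combined, 0.07, 0.99) >= 0.0


class TestWeightUpdate:
    def make_state(self, ei, pa, bw=70.0):
        return AgentState(ei=ei, pa=pa, bw=bw, bw_initial=bw, env=1.0)

    def test_equilibrium_no_change(self):
        s = self.make_state(ei=2400.0, pa=500.0)
        assert weight_update(s, ModelParams(), ee=2400.0) == pytest.approx(70.0)

    def test_surplus_direct_value(self):
        # 100 kcal/day surplus, lambda 1/4, rho 7700 -> +175/7700 kg per week
        s = self.make_state(ei=2500.0, pa=500.0)
        new = weight_update(s, ModelParams(), ee=2400.0)
        assert new - 70.0 == pytest.approx(175.0 / 7700.0)

    def test_deficit_antisymmetric(self):
        s = self.make_state(ei=2300.0, pa=500.0)
        new = weight_update(s, ModelParams(), ee=2400.0)
        assert new - 70.0 == pytest.approx(-175.0 / 7700.0)

    def test_floor(self):
        s = self.make_state(ei=0.0, pa=0.0, bw=30.001)
        assert weight_update(s, ModelParams(), ee=8000.0) == 30.0

    def test_energy_density_hook(self):
        params = ModelParams(energy_density=lambda bw0: 7700.0 + 10.0 * bw0)
        s = self.make_state(ei=2500.0, pa=500.0)
        new = weight_update(s, params, ee=2400.0)
        assert new - 70.0 == pytest.approx(175.0 / 8400.0)


def scalar_week_trace(persons, edges, ei, pa, bw, env, params, weeks):
    """Independent per-agent trace of the weekly cycle, plain Python loops."""
    n = len(persons)
    nbrs = {i: [] for i in range(n)}
    for u, v in edges:
        nbrs[u].append(v)
        nbrs[v].append(u)
    ei, pa, bw = list(ei), list(pa), list(bw)
    bw0 = list(bw)
    for _ in range(weeks):
        new_ei, new_pa, new_bw = [], [], []
        for i in range(n):
            if nbrs[i]:
                inf_ei = sum(ei[j] - ei[i] for j in nbrs[i]) / len(nbrs[i])
                inf_pa = sum(pa[j] - pa[i] for j in nbrs[i]) / len(nbrs[i])
            else:
                inf_ei = inf_pa = 0.0
            c_ei = inf_ei / env[i] if inf_ei >= 0 else inf_ei * env[i]
            c_pa = inf_pa * env[i] if inf_pa >= 0 else inf_pa / env[i]
            e = ei[i]
            if c_ei > params.t_ei * e:
                e = e * (1 + params.i_ei)
            elif c_ei < -params.t_ei * e:
                e = e * (1 - params.i_ei)
            a = pa[i]
            if c_pa > params.t_pa * a:
                a = a * (1 + params.i_pa)
            elif c_pa < -params.t_pa * a:
                a = a * (1 - params.i_pa)
            p = persons[i]
            ree = compute_ree(p.sex, bw[i], p.height_m * 100, p.age)
            ee = ree + 0.10 * e + a
            delta = params.lambda_discount * params.cycle_days * (e - ee) / 7700.0
            new_ei.append(e)
            new_pa.append(a)
            new_bw.append(max(bw[i] + delta, params.bw_floor))
        ei, pa, bw = new_ei, new_pa, new_bw
    return ei, pa, bw


class TestStepWeek:
    def test_homogeneous_population_fixed_point(self):
        persons = [make_person(id=i, ei=2400.0) for i in range(5)]
        net = make_network(persons, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])
        params = ModelParams()
        states = initialize_states(persons, params, np.random.default_rng(0))
        adj = adjacency_matrix(net, states.ids)
        new = step_week(states, adj, params)
        assert np.allclose(new.ei, states.ei)
        assert np.allclose(new.pa, states.pa)
        assert np.allclose(new.bw, states.bw)  # equilibrium: EI = EE exactly

    def test_two_agent_hand_trace(self):
        """Two connected agents at 2000/3000 kcal: influence +-500 exceeds
        both deadbands, so each adjusts toward the other by its impact."""
        persons = [make_person(id=0, ei=2000.0), make_person(id=1, ei=3000.0)]
        net = make_network(persons, [(0, 1)])
        params = ModelParams()
        states = initialize_states(persons, params, np.random.default_rng(3))
        states.env = np.ones(2)
        adj = adjacency_matrix(net, states.ids)
        new = step_week(states, adj, params)
        assert new.ei[0] == pytest.approx(2000.0 * 1.05)
        assert new.ei[1] == pytest.approx(3000.0 * 0.95)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_five_agent_scalar_oracle(self, seed):
        """Vectorized weekly step equals an independently coded scalar trace."""
        rng = np.random.default_rng(seed)
        persons = [
            make_person(id=i, age=int(rng.integers(24, 80)),
                        sex="male" if rng.random() < 0.5 else "female",
                        height_m=float(rng.uniform(1.5, 1.8)),
                        bw0=float(rng.uniform(45, 95)),
                        ei=float(rng.uniform(1600, 3200)))
            for i in range(5)
        ]
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4), (1, 3)]
        net = make_network(persons, edges)
        params = ModelParams()
        states = initialize_states(persons, params, rng)
        adj = adjacency_matrix(net, states.ids)
        cur = states
        for _ in range(8):
            cur = step_week(cur, adj, params)
        ei0 = [partition_energy(p).tee for p in persons]
        pa0 = [partition_energy(p).pa for p in persons]
        ref_ei, ref_pa, ref_bw = scalar_week_trace(
            persons, edges, ei0, pa0, [p.bw0 for p in persons], list(states.env), params, 8
        )
        assert np.allclose(cur.ei, ref_ei)
        assert np.allclose(cur.pa, ref_pa)
        assert np.allclose(cur.bw, ref_bw)


class TestRunSimulation:
    def test_zero_weeks_is_initial_state(self, small_population):
        net = generate_network(small_population, 0.267, seed=2)
        traj = run_simulation(small_population, net, weeks=0, seed=2)
        assert len(traj.week) == 1
        assert np.allclose(traj.final.bw, traj.initial.bw)

    def test_determinism(self, small_population):
        net = generate_network(small_population, 0.267, seed=4)
        a = run_simulation(small_population, net, weeks=20, seed=4)
        b = run_simulation(small_population, net, weeks=20, seed=4)
        assert np.array_equal(a.final.bw, b.final.bw)
        assert np.array_equal(a.mean_bw, b.mean_bw)

    def test_mass_conserved_in_homogeneous_population(self):
        persons = [make_person(id=i, ei=2400.0) for i in range(30)]
        net = generate_network(persons, 0.267, seed=0)
        traj = run_simulation(persons, net, weeks=30, seed=0)
        assert traj.final.bw.sum() == pytest.approx(traj.initial.bw.sum())

    def test_ei_pa_stay_nonnegative(self, small_population):
        net = generate_network(small_population, 0.267, seed=6)
        traj = run_simulation(small_population, net, weeks=52, seed=6)
        assert np.all(traj.final.ei >= 0)
        assert np.all(traj.final.pa >= 0)

    def test_no_exogenous_drift_bound(self, small_population):
        """Without intervention only network influence moves weight."""
        net = generate_network(small_population, 0.267, seed=8)
        traj = run_simulation(small_population, net, weeks=104, seed=8)
        change = traj.final.bw - traj.initial.bw
        assert np.abs(change.mean()) < 2.0


class TestModelParams:
    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(t_ei=0.0)
        with pytest.raises(ValueError):
            ModelParams(lambda_discount=1.5)
        with pytest.raises(ValueError):
            ModelParams(env_low=1.2, env_high=0.9)
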