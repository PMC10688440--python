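"""Simulation dynamics: selection, combination, diffusion, rewiring, runs.

The deepest check here compares the full engine on an isolated dyad
against an exact absorbing Markov chain built by enumerating every
weighted without-replacement draw — an independent oracle for the joint
effect of partner choice, the 1/2 contribution split, score-proportional
sampling and recipe lookup.
"""

import itertools
import math
import random
from dataclasses import replace

import networkx as nx
import numpy as np
import pytest

import potionsim as ps
from potionsim.domain import Trajectory
from potionsim.engine import Simulation, _weighted_sample


def _seeded_cfg(seed=0, **kw):
    kw.setdefault("network", ps.NetworkSpec("er", n=20, p=0.2))
    return ps.SimConfig(seed=seed, **kw)


class TestSelectionWeights:
    def test_worked_initial_probabilities(self, table):
        w = ps.selection_weights(ps.initial_inventory(table))
        assert round(w["a1"], 3) == 0.125
        assert round(w["a2"], 3) == 0.167
        assert round(w["a3"], 3) == 0.208
        assert round(w["b1"], 3) == 0.125
        assert sum(w.values()) == pytest.approx(1.0)

    def test_single_item(self, table):
        item = table.items["a1"]
        assert ps.selection_weights([item]) == {"a1": 1.0}

    def test_direct_normalization(self):
        items = [
            ps.Item(n, Trajectory.A, 1, s, 48.0) for n, s in (("u", 1), ("v", 1), ("w", 2))
        ]
        w = ps.selection_weights(items)
        assert w == {"u": 0.25, "v": 0.25, "w": 0.5}


class TestSplitContribution:
    def test_counts_sum_to_three_and_are_fair(self, rng):
        draws = [ps.split_contribution(rng) for _ in range(10_000)]
        assert all(sum(d) == 3 and d in ((1, 2), (2, 1)) for d in draws)
        frac = sum(1 for d in draws if d == (1, 2)) / len(draws)
        assert abs(frac - 0.5) < 4 * math.sqrt(0.25 / len(draws))

    def test_reproducible_under_seed(self):
        a = [ps.split_contribution(random.Random(5)) for _ in range(10)]
        b = [ps.split_contribution(random.Random(5)) for _ in range(10)]
        assert a == b


def _p_exact_draw(subset, weights):
    """Probability that a weighted without-replacement draw of len(subset)
    equals ``subset`` (sum over orderings)."""
    total = sum(weights.values())
    p = 0.0
    for perm in itertools.permutations(subset):
        q, rem = 1.0, total
        for name in perm:
            q *= weights[name] / rem
            rem -= weights[name]
        p += q
    return p


class TestSampleItems:
    def test_exhaustive_pair_from_two(self, table):
        items = [table.items["a1"], table.items["a2"]]
        got = ps.sample_items(items, 2, random.Random(0))
        assert {it.name for it in got} == {"a1", "a2"}

    def test_too_many_requested(self, table):
        with pytest.raises(ValueError):
            ps.sample_items([table.items["a1"]], 2, random.Random(0))

    def test_pair_distribution_matches_enumeration(self):
        items = [
            ps.Item(n, Trajectory.A, 1, s, 48.0) for n, s in (("x", 1), ("y", 1), ("z", 2))
        ]
        weights = {"x": 1, "y": 1, "z": 2}
        rng = random.Random(11)
        n_draws = 20_000
        counts: dict[frozenset, int] = {}
        for _ in range(n_draws):
            got = frozenset(it.name for it in ps.sample_items(items, 2, rng))
            counts[got] = counts.get(got, 0) + 1
        for pair in (frozenset("xy"), frozenset("xz"), frozenset("yz")):
            expected = _p_exact_draw(set(pair), weights)
            got = counts.get(pair, 0) / n_draws
            se = math.sqrt(expected * (1 - expected) / n_draws)
            assert abs(got - expected) < 4 * se

    def test_singleton_probability_is_weight_share(self, table):
        rng = random.Random(2)
        inv = ps.initial_inventory(table)
        n_draws = 20_000
        hits = sum(
            1 for _ in range(n_draws) if ps.sample_items(inv, 1, rng)[0].name == "a3"
        )
        se = math.sqrt(0.208 * (1 - 0.208) / n_draws)
        assert abs(hits / n_draws - 10 / 48) < 4 * se


class TestSelectPartner:
    def test_single_neighbour_certain(self):
        g = nx.path_graph(3)
        sim = Simulation(_seeded_cfg(network=g))
        assert all(sim.select_partner(0) == 1 for _ in range(50))

    def test_uniform_over_neighbours(self):
        sim = Simulation(_seeded_cfg(network=nx.star_graph(3), seed=8))
        n_draws = 12_000
        counts = {1: 0, 2: 0, 3: 0}
        for _ in range(n_draws):
            counts[sim.select_partner(0)] += 1
        se = math.sqrt((1 / 3) * (2 / 3) / n_draws)
        for v in counts.values():
            assert abs(v / n_draws - 1 / 3) < 4 * se

    def test_weighted_proportional_to_edge_weight(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_edge(0, 2, weight=3.0)
        g.graph["weighted"] = True
        sim = Simulation(_seeded_cfg(network=g, seed=9))
        n_draws = 20_000
        hits = sum(1 for _ in range(n_draws) if sim.select_partner(0) == 1)
        se = math.sqrt(0.25 * 0.75 / n_draws)
        assert abs(hits / n_draws - 0.25) < 4 * se

    def test_isolated_focal_skips(self):
        g = nx.Graph([(0, 1)])
        g.add_node(2)
        sim = Simulation(_seeded_cfg(network=g))
        assert sim.select_partner(2) is None
        sim.step()  # the isolated agent simply takes no turn
        assert sim.agents[2].score == 0.0


class TestWeightedSampleHelper:
    def test_degenerate_and_errors(self):
        assert _weighted_sample([1.0], 1, random.Random(0)) == [0]
        with pytest.raises(ValueError):
            _weighted_sample([1.0, 2.0], 3, random.Random(0))

    def test_draws_are_distinct(self, rng):
        for _ in range(200):
            got = _weighted_sample([1, 2, 3, 4], 3, rng)
            assert len(set(got)) == 3


class TestAttemptAndDiffuse:
    def test_only_valid_products_and_both_updated(self, table):
        sim = Simulation(_seeded_cfg(network=ps.NetworkSpec("complete", n=2), seed=4))
        products = []
        for _ in range(4000):
            item = sim.attempt_combination(0, 1)
            if item is not None:
                products.append(item.name)
                assert sim.ct.id_of[item.name] in sim.agents[0].items
                assert sim.ct.id_of[item.name] in sim.agents[1].items
        assert products  # discoveries do happen
        assert set(products) <= set(table.items)

    def test_no_diffusion_at_zero(self):
        sim = Simulation(
            _seeded_cfg(network=ps.NetworkSpec("complete", n=10), diffusion=0.0)
        )
        item = sim.ct.table.items["1a"]
        sim.agents[0].add(sim.ct.id_of["1a"], sim.ct)
        sim.agents[1].add(sim.ct.id_of["1a"], sim.ct)
        assert sim.diffuse(item, 0, 1) == set()

    def test_full_diffusion_reaches_everyone(self):
        sim = Simulation(
            _seeded_cfg(network=ps.NetworkSpec("complete", n=12), diffusion=1.0)
        )
        item = sim.ct.table.items["1a"]
        sim.agents[0].add(sim.ct.id_of["1a"], sim.ct)
        sim.agents[1].add(sim.ct.id_of["1a"], sim.ct)
        assert sim.diffuse(item, 0, 1) == set(range(2, 12))

    def test_half_diffusion_reaches_about_half(self):
        # complete network: each of the other n-2 agents gets one
        # Bernoulli(1/2) chance, so recipients ~ Binomial(n-2, 1/2)
        n, reps = 42, 300
        got = []
        for seed in range(reps):
            sim = Simulation(
                _seeded_cfg(network=ps.NetworkSpec("complete", n=n), diffusion=0.5, seed=seed)
            )
            item = sim.ct.table.items["1a"]
            sim.agents[0].add(sim.ct.id_of["1a"], sim.ct)
            sim.agents[1].add(sim.ct.id_of["1a"], sim.ct)
            got.append(len(sim.diffuse(item, 0, 1)))
        mean = sum(got) / reps
        expected = (n - 2) / 2
        se = math.sqrt((n - 2) * 0.25 / reps)
        assert abs(mean - expected) < 3 * se


class TestRewire:
    def test_zero_probability_no_change(self, rng):
        g = ps.make_ring(6)
        before = set(g.edges)
        assert ps.rewire(g, 0, 0.0, rng) is None
        assert set(g.edges) == before

    def test_complete_graph_no_op(self, rng):
        g = ps.make_complete(5)
        assert ps.rewire(g, 0, 1.0, rng) is None
        assert g.number_of_edges() == 10

    def test_path_graph_single_legal_move(self, rng):
        g = nx.path_graph(3)  # 0-1-2
        change = ps.rewire(g, 0, 1.0, rng)
        assert change == (1, 2)
        assert set(map(frozenset, g.edges)) == {frozenset({0, 2}), frozenset({1, 2})}
        assert g.degree(0) == 1

    def test_degree_and_edge_count_conserved(self):
        rng = random.Random(0)
        g = ps.make_random_network(20, 0.2, seed=3)
        m = g.number_of_edges()
        for _ in range(200):
            agent = rng.randrange(20)
            deg = g.degree(agent)
            if ps.rewire(g, agent, 1.0, rng) is not None:
                assert g.degree(agent) == deg
            assert g.number_of_edges() == m

    def test_weight_travels_with_link(self, rng):
        g = nx.Graph()
        g.add_edge(0, 1, weight=2.5)
        g.add_node(2)
        change = ps.rewire(g, 0, 1.0, rng)
        assert change == (1, 2)
        assert g[0][2]["weight"] == 2.5


class TestStepAndRun:
    def test_dyad_always_pairs(self):
        sim = Simulation(_seeded_cfg(network=ps.NetworkSpec("complete", n=2)))
        assert sim.select_partner(0) == 1
        assert sim.select_partner(1) == 0

    def test_inventories_monotone(self):
        sim = Simulation(_seeded_cfg(network=ps.NetworkSpec("er", n=15, p=0.3), seed=2))
        prev = [set(ag.items) for ag in sim.agents]
        for _ in range(30):
            sim.step()
            cur = [set(ag.items) for ag in sim.agents]
            assert all(p <= c for p, c in zip(prev, cur))
            prev = cur

    def test_bit_identical_under_equal_seed(self):
        cfg = _seeded_cfg(network=ps.NetworkSpec("er", n=25, p=0.2), rewire=0.2, seed=42)
        r1 = ps.run(cfg)
        r2 = ps.run(cfg)
        assert r1.to_dict() == r2.to_dict()
        assert set(r1.network.edges) == set(r2.network.edges)

    def test_combination_accounting(self):
        res = ps.run(_seeded_cfg(network=ps.NetworkSpec("er", n=18, p=0.25), seed=3))
        assert res.combinations == res.steps * res.n_agents

    def test_step_cap_binds(self):
        cfg = _seeded_cfg(
            network=ps.NetworkSpec("er", n=40, p=0.2), diffusion=0.0, max_steps=1
        )
        res = ps.run(cfg)
        assert res.steps == 1
        assert not res.crossover_achieved

    def test_score_ladder_and_termination(self):
        res = _first_crossover_run()
        assert set(res.final_scores) <= {0.0, 48.0, 109.0, 188.0, 358.0}
        assert max(res.final_scores) == 358.0
        assert res.steps_to_crossover == res.steps
        assert all(a <= b for a, b in zip(res.max_score_series, res.max_score_series[1:]))

    def test_crossover_requires_both_terminals_first(self):
        res = _first_crossover_run()
        fc = res.first_creation
        assert fc["x"][0] >= fc["3a"][0]
        assert fc["x"][0] >= fc["3b"][0]

    def test_closure_safety(self, table):
        res = ps.run(_seeded_cfg(network=ps.NetworkSpec("er", n=15, p=0.3), seed=6))
        closure = table.closure()
        for inv in res.final_inventories:
            assert set(inv) <= closure

    def test_post_crossover_steps_appended(self):
        cfg = _seeded_cfg(
            network=ps.NetworkSpec("er", n=30, p=0.15), post_crossover_steps=25, seed=1
        )
        res = ps.run(cfg)
        assert res.crossover_achieved
        assert res.steps == res.steps_to_crossover + 25
        assert len(res.gini_series) == res.steps

    def test_invalid_config_fails_before_running(self):
        with pytest.raises(ValueError):
            ps.run(_seeded_cfg(diffusion=1.5))
        with pytest.raises(ValueError):
            ps.run(_seeded_cfg(max_steps=0))

    def test_first_discoverers_are_dyads_not_recipients(self):
        res = _first_crossover_run()
        for step, dyad in res.first_discoverers.values():
            assert len(dyad) == 2
            assert 1 <= step <= res.steps


def _first_crossover_run(seed=0):
    while True:
        res = ps.run(
            ps.SimConfig(network=ps.NetworkSpec("er", n=30, p=0.15), seed=seed)
        )
        if res.crossover_achieved:
            return res
        seed += 1


# -- exact dyad Markov chain oracle -----------------------------------------

def _dyad_chain(table):
    """Exact per-step transition matrix of an isolated dyad's shared state.

    States are (a_tier, b_tier) pairs plus the absorbing crossover; a step
    is two sequential combination attempts (each agent focal once), each
    attempt's discovery probabilities computed by enumerating the split
    and all weighted without-replacement draws from both inventories.
    """
    by_level = {
        (it.trajectory, it.tier): it.name
        for it in table.items.values()
        if it.trajectory in (Trajectory.A, Trajectory.B)
    }
    cross_triad = next(t for t, p in table.recipes.items() if p == "x")
    basics = {it.name: it.innovation_score for it in table.basics()}

    def inventory(a, b):
        w = dict(basics)
        for lvl in range(1, a + 1):
            name = by_level[(Trajectory.A, lvl)]
            w[name] = table.items[name].innovation_score
        for lvl in range(1, b + 1):
            name = by_level[(Trajectory.B, lvl)]
            w[name] = table.items[name].innovation_score
        return w

    def p_discover(triad, w):
        p = 0.0
        for kf in (1, 2):
            for part in itertools.combinations(triad, kf):
                p += 0.5 * _p_exact_draw(set(part), w) * _p_exact_draw(
                    set(triad) - set(part), w
                )
        return p

    states = [(a, b) for a in range(4) for b in range(4)]
    idx = {s: i for i, s in enumerate(states)}
    m = len(states)
    A = np.zeros((m + 1, m + 1))
    A[m, m] = 1.0
    for a, b in states:
        w = inventory(a, b)
        i = idx[(a, b)]
        moves = {}
        if a < 3:
            name = by_level[(Trajectory.A, a + 1)]
            triad = next(t for t, p in table.recipes.items() if p == name)
            moves[(a + 1, b)] = p_discover(triad, w)
        if b < 3:
            name = by_level[(Trajectory.B, b + 1)]
            triad = next(t for t, p in table.recipes.items() if p == name)
            moves[(a, b + 1)] = p_discover(triad, w)
        if a == 3 and b == 3:
            moves["X"] = p_discover(cross_triad, w)
        A[i, i] += 1.0 - sum(moves.values())
        for s, p in moves.items():
            j = m if s == "X" else idx[s]
            A[i, j] += p
    return A @ A, states  # one step = two attempts


class TestDyadMarkovOracle:
    def test_state_distribution_matches_exact_chain(self, table):
        steps, reps = 40, 400
        step_matrix, states = _dyad_chain(table)
        v = np.zeros(len(states) + 1)
        v[0] = 1.0
        exact = v @ np.linalg.matrix_power(step_matrix, steps)

        a_names = {it.name for it in table.items.values() if it.trajectory is Trajectory.A}
        b_names = {it.name for it in table.items.values() if it.trajectory is Trajectory.B}
        counts = np.zeros(len(states) + 1)
        base = ps.SimConfig(network=ps.NetworkSpec("complete", n=2), max_steps=steps)
        for rep in range(reps):
            res = ps.run(replace(base, seed=rep))
            inv = set(res.final_inventories[0])
            assert inv == set(res.final_inventories[1])  # dyad shares everything
            if res.crossover_achieved:
                counts[-1] += 1
            else:
                state = (len(inv & a_names), len(inv & b_names))
                counts[states.index(state)] += 1
        freqs = counts / reps

        rare_exact = rare_obs = 0.0
        for p, f in zip(exact, freqs):
            if p < 0.01:
                rare_exact += p
                rare_obs += f
                continue
            se = math.sqrt(p * (1 - p) / reps)
            assert abs(f - p) < 4 * se, (p, f)
        se = math.sqrt(max(rare_exact * (1 - rare_exact), 1e-6) / reps)
        assert abs(rare_obs - rare_exact) < 5 * se + 0.01
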