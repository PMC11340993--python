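import numpy as np
import pytest
from scipy.stats import ks_2samp

from wavewire import RewiringConfig, SpatialDigraph, init_random_digraph
from wavewire.diffusion_kernels import advection_kernel, consensus_kernel
from wavewire.rewiring_engine import (
    EvolutionError,
    adaptive_rewire,
    boosted_matrix,
    eligible_nodes,
    evolve,
    proximity_rewire,
    select_rewiring_target,
    wave_rewire,
)

from oracles import adaptive_choice_oracle, make_graph, proximity_choice_oracle


def graph_from_edges(n, edges, positions=None, weights=None):
    A = np.zeros((n, n))
    for idx, (s, t) in enumerate(edges):
        A[t, s] = 1.0 if weights is None else weights[idx]
    pos = positions if positions is not None else np.random.default_rng(0).random((n, 2))
    return SpatialDigraph(A, np.asarray(pos, dtype=float))


class TestTargetSelection:
    def test_zero_in_degree_node_never_selected(self, rng):
        # node 2 has in-degree 0
        G = graph_from_edges(3, [(0, 1), (2, 1), (1, 0)])
        assert 2 not in eligible_nodes(G, "in")
        for _ in range(50):
            assert select_rewiring_target(G, "in", rng) != 2

    def test_complete_digraph_has_no_eligible_node(self, rng):
        edges = [(i, j) for i in range(4) for j in range(4) if i != j]
        G = graph_from_edges(4, edges)
        with pytest.raises(EvolutionError):
            select_rewiring_target(G, "in", rng)

    def test_selection_uniform_over_eligible_nodes(self, rng):
        # nodes 0, 1, 2 have in-degree 1; nodes 3, 4 have in-degree 0
        G = graph_from_edges(5, [(3, 0), (4, 1), (0, 2)])
        assert list(eligible_nodes(G, "in")) == [0, 1, 2]
        draws = 20000
        counts = np.zeros(5)
        for _ in range(draws):
            counts[select_rewiring_target(G, "in", rng)] += 1
        sigma = np.sqrt(draws * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts[:3] - draws / 3) <= 3 * sigma)


class TestAdaptiveRewire:
    def test_three_node_chain_in_link_matches_enumeration(self):
        G = graph_from_edges(3, [(0, 1), (1, 2)])
        c = consensus_kernel(G.weights, 1.0)
        expected = adaptive_choice_oracle(G, 2, "in", c)
        removed, added = adaptive_rewire(G, 2, "in", c)
        assert (removed, added) == expected

    @pytest.mark.parametrize("direction", ["in", "out"])
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle_on_random_graphs(self, direction, seed, rng):
        G = make_graph(10, 35, seed=seed)
        kernel = (
            consensus_kernel(G.weights, 1.0)
            if direction == "in"
            else advection_kernel(G.weights, 1.0)
        )
        pool = eligible_nodes(G, direction)
        v = int(pool[rng.integers(pool.size)])
        expected = adaptive_choice_oracle(G, v, direction, kernel)
        deg_before = (G.in_degrees() if direction == "in" else G.out_degrees())[v]
        m_before = G.m
        removed, added = adaptive_rewire(G, v, direction, kernel)
        assert (removed, added) == expected
        deg_after = (G.in_degrees() if direction == "in" else G.out_degrees())[v]
        assert deg_after == deg_before and G.m == m_before


class TestWaveRewire:
    def test_weight_multiset_reset_after_wave(self):
        G = make_graph(10, 30, seed=7)
        before = G.weight_multiset()
        wave_rewire(G, 3, "in", initiators=(0,), B=1.0, t=1.0)
        assert np.array_equal(G.weight_multiset(), before)

    def test_boosted_matrix_has_unit_grand_sum(self):
        G = make_graph(10, 30, seed=7)
        W = boosted_matrix(G, (0, 4), B=1.0)
        assert abs(W.sum() - 1.0) < 1e-12
        # boost changes magnitudes only on existing edges, never the support
        assert np.all((W > 0) == (G.weights > 0))
        # un-normalising recovers plain weights off the initiators' columns
        total = G.weights.sum() + 1.0 * (G.weights[:, [0, 4]] > 0).sum()
        off = np.ones(10, dtype=bool)
        off[[0, 4]] = False
        assert np.allclose(W[:, off] * total, G.weights[:, off], atol=1e-12)

    def test_boost_can_change_the_added_edge(self):
        # frozen 4-node instance where the boosted kernel redirects the new
        # in-link of node 2 toward the wave initiator (node 0)
        G = make_graph(4, 6, seed=0, hub_threshold=1)
        c_plain = consensus_kernel(G.weights, 1.0)
        c_boost = consensus_kernel(boosted_matrix(G, (0,), 1.0), 1.0)
        plain_choice = adaptive_choice_oracle(G, 2, "in", c_plain)
        boost_choice = adaptive_choice_oracle(G, 2, "in", c_boost)
        assert plain_choice[1] != boost_choice[1]
        removed, added = wave_rewire(G.copy(), 2, "in", (0,), B=1.0, t=1.0)
        assert (removed, added) == boost_choice
        assert added == (0, 2)

    def test_initiator_without_out_links_warns_but_proceeds(self, caplog):
        # node 4 has no out-links
        G = graph_from_edges(5, [(0, 4), (1, 4), (0, 1), (2, 3)])
        with caplog.at_level("WARNING"):
            wave_rewire(G, 4, "in", initiators=(4,), B=1.0, t=1.0)
        assert any("no out-links" in r.message for r in caplog.records)

    def test_empty_initiator_set_rejected(self):
        G = make_graph(6, 12, seed=1)
        with pytest.raises(EvolutionError):
            wave_rewire(G, 2, "in", initiators=(), B=1.0, t=1.0)


class TestProximityRewire:
    def test_removes_farthest_adds_nearest(self):
        # v=0 at origin; in-neighbours at distance 3 (node 1) and 1 (node 2);
        # non-neighbour at distance 0.5 (node 3)
        pos = [[0, 0], [3, 0], [1, 0], [0.5, 0]]
        G = graph_from_edges(4, [(1, 0), (2, 0), (3, 2)], positions=pos)
        removed, added = proximity_rewire(G, 0, "in")
        assert removed == (1, 0) and added == (3, 0)

    @pytest.mark.parametrize("direction", ["in", "out"])
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_sorted_distance_oracle(self, direction, seed, rng):
        G = make_graph(10, 30, seed=seed)
        pool = eligible_nodes(G, direction)
        v = int(pool[rng.integers(pool.size)])
        expected = proximity_choice_oracle(G, v, direction)
        pos_before = G.positions.copy()
        d = G.distances()
        length = lambda e: d[e[0], e[1]]
        nbrs = G.in_neighbors(v) if direction == "in" else G.out_neighbors(v)
        axis_d = d[:, v] if direction == "in" else d[v, :]
        already_minimal = max(axis_d[nbrs]) <= min(
            axis_d[u]
            for u in range(G.n)
            if u != v and u not in set(int(x) for x in nbrs)
        )
        removed, added = proximity_rewire(G, v, direction)
        assert (removed, added) == expected
        # v's total link length decreases unless its links were already the
        # spatially shortest available (then the forced swap may lengthen it)
        if not already_minimal:
            assert length(added) < length(removed)
        assert np.array_equal(G.positions, pos_before)


class TestEvolve:
    def test_zero_iterations_returns_graph_unchanged(self):
        cfg = RewiringConfig(n=15, m=60, M=0, seed=3)
        G = init_random_digraph(cfg)
        A0 = G.weights.copy()
        G, events = evolve(G, cfg)
        assert events == [] and np.array_equal(G.weights, A0)

    @pytest.mark.parametrize(
        "mix",
        [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0), (0.4, 0.3, 0.3)],
        ids=["adaptive", "wave", "proximity", "mixed"],
    )
    def test_conservation_for_every_rule_mix(self, mix):
        pa, pw, pp = mix
        cfg = RewiringConfig(
            n=25, m=120, M=150, p_adaptive=pa, p_wave=pw, p_proximity=pp, seed=11
        )
        G = init_random_digraph(cfg)
        before = G.weight_multiset()
        G, events = evolve(G, cfg)
        assert len(events) == 150
        assert G.n == 25 and G.m == 120
        assert np.allclose(np.sort(before), G.weight_multiset(), atol=0)
        G.validate()

    def test_same_seed_gives_identical_trajectory(self):
        cfg = RewiringConfig(
            n=20, m=80, M=100, p_adaptive=0.5, p_wave=0.3, p_proximity=0.2, seed=5
        )
        G1, ev1 = evolve(init_random_digraph(cfg), cfg)
        G2, ev2 = evolve(init_random_digraph(cfg), cfg)
        assert ev1 == ev2
        assert np.array_equal(G1.weights, G2.weights)

    def test_rule_frequencies_match_probabilities(self):
        probs = {"adaptive": 0.5, "wave": 0.2, "proximity": 0.3}
        cfg = RewiringConfig(
            n=20, m=80, M=10000,
            p_adaptive=probs["adaptive"], p_wave=probs["wave"],
            p_proximity=probs["proximity"], seed=8,
        )
        _, events = evolve(init_random_digraph(cfg), cfg)
        counts = {r: sum(e.rule == r for e in events) for r in probs}
        for rule, p in probs.items():
            sigma = np.sqrt(cfg.M * p * (1 - p))
            assert abs(counts[rule] - cfg.M * p) <= 3 * sigma, rule
        directions = sum(e.direction == "in" for e in events)
        assert abs(directions - cfg.M * 0.5) <= 3 * np.sqrt(cfg.M * 0.25)

    def test_pure_proximity_shrinks_total_length(self):
        # each move swaps a longest link for the shortest available one; a
        # move can lengthen the graph only when the rewired node's links were
        # already the spatially shortest possible, so the total wiring length
        # contracts strongly over a run
        cfg = RewiringConfig(
            n=20, m=80, M=200, p_adaptive=0.0, p_wave=0.0, p_proximity=1.0, seed=2
        )
        G = init_random_digraph(cfg)
        d = G.distances()
        initial = G.total_edge_length()
        topo = (G.weights > 0).copy()
        _, events = evolve(G, cfg)
        for e in events:
            gain = d[e.added[0], e.added[1]] - d[e.removed[0], e.removed[1]]
            if gain > 1e-12:
                # only legal when every alternative partner was farther than
                # the removed (farthest) neighbour
                v = e.node
                if e.direction == "in":
                    nbrs = np.flatnonzero(topo[v])
                    axis_d = d[:, v]
                else:
                    nbrs = np.flatnonzero(topo[:, v])
                    axis_d = d[v, :]
                cands = [u for u in range(G.n) if u != v and u not in set(nbrs)]
                assert max(axis_d[nbrs]) <= min(axis_d[cands]) + 1e-12
            topo[e.removed[1], e.removed[0]] = False
            topo[e.added[1], e.added[0]] = True
        assert G.total_edge_length() < 0.75 * initial

    def test_event_log_is_consistent_replay(self):
        cfg = RewiringConfig(
            n=15, m=50, M=80, p_adaptive=0.6, p_wave=0.2, p_proximity=0.2, seed=13
        )
        G0 = init_random_digraph(cfg)
        topo = (G0.weights > 0).copy()
        G, events = evolve(G0.copy(), cfg)
        for e in events:
            rs, rt = e.removed
            as_, at = e.added
            assert topo[rt, rs] and not topo[at, as_]
            topo[rt, rs] = False
            topo[at, as_] = True
        assert np.array_equal(topo, G.weights > 0)

    def test_no_initiator_effect_without_waves(self):
        # with p_wave = 0 the designated initiator is exchangeable with any
        # other node: its final out-degree distribution matches the rest
        init_degs, other_degs = [], []
        for rep in range(50):
            cfg = RewiringConfig(
                n=30, m=150, M=200,
                p_adaptive=0.5, p_wave=0.0, p_proximity=0.5,
                initiators=(0,), seed=1000 + rep,
            )
            G, _ = evolve(init_random_digraph(cfg), cfg)
            out = G.out_degrees()
            init_degs.append(out[0])
            other_degs.extend(out[1:])
        assert ks_2samp(init_degs, other_degs).pvalue > 0.005
        ratio = np.mean(init_degs) / np.mean(other_degs)
        assert 0.8 < ratio < 1.25
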