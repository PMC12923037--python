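"""Forward model: construction, propagation, marginals, gradients."""

import numpy as np
import pytest

from degradograph import (
    DegradationGraph,
    ProteinRecord,
    build_graph,
    conditional_distribution,
    forward_pass,
    marginal_gradient,
    marginal_recursive,
    reach_probabilities,
    reach_probability,
)

from conftest import (
    brute_force_marginal,
    feasible_observation,
    make_graph,
    random_graph,
    random_weights,
)


class TestBuildGraph:
    def test_nested_peptides_get_containment_edges(self, toy_protein):
        g = build_graph({(1, 6): 0.4, (1, 4): 0.6}, toy_protein)
        ivs = {(n.start, n.end): n.id for n in g.nodes}
        edges = {(g.nodes[u].interval, g.nodes[v].interval) for u, v in g.edges}
        assert edges == {
            ((0, 10), (1, 6)),
            ((0, 10), (1, 4)),
            ((1, 6), (1, 4)),
        }
        assert g.nodes[ivs[(1, 6)]].observed_abundance == 0.4

    def test_single_peptide_hangs_off_root(self, toy_protein):
        g = build_graph({(2, 7): 1.0}, toy_protein)
        assert g.edges == [(0, 1)]

    def test_disjoint_peptides_share_no_edge(self, toy_protein):
        g = build_graph({(0, 4): 0.5, (5, 9): 0.5}, toy_protein)
        assert all(u == 0 for u, _ in g.edges)
        assert len(g.edges) == 2

    def test_transitive_reduction_removes_shortcut(self, toy_protein):
        full = build_graph({(1, 6): 0.4, (1, 4): 0.6}, toy_protein)
        red = build_graph({(1, 6): 0.4, (1, 4): 0.6}, toy_protein, policy="reduction")
        assert red.n_edges == full.n_edges - 1  # root->(1,4) shortcut dropped

    def test_out_of_span_peptide_rejected(self, toy_protein):
        with pytest.raises(ValueError):
            build_graph({(5, 12): 1.0}, toy_protein)

    def test_every_node_reachable_from_root(self, toy_protein):
        g = build_graph({(0, 3): 0.3, (4, 9): 0.4, (5, 8): 0.3}, toy_protein)
        reached = {0}
        for u, v in g.edges:
            if u in reached:
                reached.add(v)
        assert reached == set(range(g.n_nodes))


class TestForwardPass:
    def test_full_transition_absorbs_at_leaf(self, toy_protein):
        g = make_graph([(0, 10), (1, 6)], [(0, 1)], [1.0])
        P = forward_pass(g)
        assert P[1] == pytest.approx(1.0)
        assert P[0] == pytest.approx(0.0)

    def test_chain_hand_propagation(self, chain_graph):
        P = forward_pass(chain_graph)
        assert P.values_array == pytest.approx([0.5, 0.25, 0.25])

    def test_diamond_matches_path_enumeration(self, diamond_graph):
        P = forward_pass(diamond_graph)
        assert P.values_array == pytest.approx(brute_force_marginal(diamond_graph))

    def test_invalid_weights_rejected(self, chain_graph):
        with pytest.raises(ValueError):
            chain_graph.set_weights(np.array([0.7, 0.5]), absorption=np.array([0.3, -0.2, 1.0]))
            forward_pass(chain_graph)

    def test_mass_conserved_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            g = random_graph(rng, n_nodes=int(rng.integers(3, 13)))
            assert forward_pass(g).total() == pytest.approx(1.0, abs=1e-9)


class TestConditional:
    def test_leaf_is_one_hot(self, chain_graph):
        c = conditional_distribution(chain_graph, 2)
        assert c.values_array == pytest.approx([0.0, 0.0, 1.0])

    def test_root_conditional_equals_forward_pass(self, diamond_graph):
        c = conditional_distribution(diamond_graph, 0)
        assert c.values_array == pytest.approx(forward_pass(diamond_graph).values_array)

    def test_chain_interior_node(self, chain_graph):
        c = conditional_distribution(chain_graph, 1)
        assert c.values_array == pytest.approx([0.0, 0.5, 0.5])

    def test_unknown_node_rejected(self, chain_graph):
        with pytest.raises(KeyError):
            conditional_distribution(chain_graph, 99)

    def test_downstream_recursion_holds(self):
        # P(.|k) = sum_i w[k->i] P(.|i) + 1_k w[k->k]
        rng = np.random.default_rng(5)
        g = random_graph(rng, n_nodes=9)
        for k in range(g.n_nodes):
            lhs = conditional_distribution(g, k).values_array
            rhs = np.zeros(g.n_nodes)
            rhs[k] = g.absorption[k]
            for e in g.out_edges[k]:
                rhs += g.weights[e] * conditional_distribution(
                    g, int(g.edge_dst[e])
                ).values_array
            assert lhs == pytest.approx(rhs, abs=1e-12)


class TestMarginalRecursive:
    def test_chain_matches_forward(self, chain_graph):
        P = marginal_recursive(chain_graph)
        assert P.values_array == pytest.approx([0.5, 0.25, 0.25])

    def test_single_edge_closed_form(self, toy_protein):
        g = make_graph([(0, 10), (1, 6)], [(0, 1)], [0.3])
        P = marginal_recursive(g)
        assert P[0] == pytest.approx(0.7)  # root absorption
        assert P[1] == pytest.approx(0.3)

    def test_equivalence_on_random_graphs(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            g = random_graph(rng, n_nodes=20, protein_len=80)
            a = forward_pass(g).values_array
            b = marginal_recursive(g).values_array
            assert np.max(np.abs(a - b)) < 1e-9

    def test_zero_absorption_fallback(self, toy_protein):
        # interior node absorbs nothing: ratio form undefined, fallback used
        g = make_graph(
            [(0, 10), (1, 6), (1, 4)], [(0, 1), (1, 2)], [0.5, 1.0]
        )
        assert g.absorption[1] == pytest.approx(0.0)
        a = forward_pass(g).values_array
        b = marginal_recursive(g).values_array
        assert b == pytest.approx(a, abs=1e-12)


class TestReachProbability:
    def test_root_reaches_itself(self, chain_graph):
        assert reach_probability(chain_graph, 0) == 1.0

    def test_chain_path_product(self, chain_graph):
        assert reach_probability(chain_graph, 2) == pytest.approx(0.25)

    def test_diamond_sums_both_paths(self, diamond_graph):
        # 0.5*0.5 via A plus 0.5*0.5 via B
        assert reach_probability(diamond_graph, 3) == pytest.approx(0.5)

    def test_equals_marginal_over_absorption(self):
        rng = np.random.default_rng(3)
        g = random_graph(rng, n_nodes=8)
        P = forward_pass(g).values_array
        reach = reach_probabilities(g)
        for v in range(g.n_nodes):
            if g.absorption[v] > 1e-9:
                assert reach[v] == pytest.approx(P[v] / g.absorption[v])


class TestMarginalGradient:
    def test_single_edge_formula(self, toy_protein):
        g = make_graph([(0, 10), (1, 6)], [(0, 1)], [0.3])
        grad = marginal_gradient(g, (0, 1))
        assert grad[1] == pytest.approx(1.0)  # reach(root)=1 times P(A|A)=1

    def test_self_loop_gradient_at_leaf(self, chain_graph):
        grad = marginal_gradient(chain_graph, (2, 2))
        expected = np.zeros(3)
        expected[2] = reach_probability(chain_graph, 2)
        assert grad.values_array == pytest.approx(expected)

    def test_missing_edge_rejected(self, chain_graph):
        with pytest.raises(KeyError):
            marginal_gradient(chain_graph, (0, 2))

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(17)
        h = 1e-6
        for _ in range(10):
            g = random_graph(rng, n_nodes=10)
            w0, a0 = g.weights.copy(), g.absorption.copy()
            for e in range(g.n_edges):
                i, j = int(g.edge_src[e]), int(g.edge_dst[e])
                grad = marginal_gradient(g, (i, j)).values_array
                for sign, store in ((+1, "hi"), (-1, "lo")):
                    w = w0.copy()
                    w[e] += sign * h
                    g.set_weights(w, absorption=a0, validate=False)
                    if sign > 0:
                        hi = forward_pass(g, validate=False).values_array
                    else:
                        lo = forward_pass(g, validate=False).values_array
                fd = (hi - lo) / (2 * h)
                g.set_weights(w0, absorption=a0)
                assert np.max(np.abs(grad - fd)) < 1e-6

    def test_absorption_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(19)
        g = random_graph(rng, n_nodes=8)
        h = 1e-6
        w0, a0 = g.weights.copy(), g.absorption.copy()
        for i in range(g.n_nodes):
            grad = marginal_gradient(g, (i, i)).values_array
            a = a0.copy()
            a[i] += h
            g.set_weights(w0, absorption=a, validate=False)
            hi = forward_pass(g, validate=False).values_array
            a[i] -= 2 * h
            g.set_weights(w0, absorption=a, validate=False)
            lo = forward_pass(g, validate=False).values_array
            g.set_weights(w0, absorption=a0)
            assert np.max(np.abs(grad - (hi - lo) / (2 * h))) < 1e-6


class TestMonotonicity:
    def test_more_root_flow_does_not_shrink_subtree_mass(self, diamond_graph):
        # raise w[root->A], taking the mass from root absorption
        g = diamond_graph
        g.set_weights(np.array([0.4, 0.4, 0.5, 0.5]))  # root absorbs 0.2
        base = forward_pass(g).values_array
        w = g.weights.copy()
        w[0] += 0.2  # root absorption drops to 0
        g.set_weights(w)
        bumped = forward_pass(g).values_array
        # subtree of A = {A, C}
        assert bumped[1] + bumped[3] >= base[1] + base[3] - 1e-12


class TestStructureInvariants:
    def test_edge_must_be_strict_containment(self, toy_protein):
        from degradograph import PeptideNode

        nodes = [
            PeptideNode(0, 0, 10, toy_protein.sequence),
            PeptideNode(1, 0, 4, toy_protein.sequence[0:4]),
            PeptideNode(2, 5, 9, toy_protein.sequence[5:9]),
        ]
        with pytest.raises(ValueError):
            DegradationGraph(nodes, [(0, 1), (1, 2)])

    def test_absorption_complements_outgoing(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng, n_nodes=12)
        out = np.zeros(g.n_nodes)
        np.add.at(out, g.edge_src, g.weights)
        assert g.absorption + out == pytest.approx(np.ones(g.n_nodes), abs=1e-9)
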