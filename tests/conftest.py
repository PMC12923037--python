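"""Shared fixtures: hand-built toy graphs and random-graph generators."""

from __future__ import annotations

import numpy as np
import pytest

from degradograph import DegradationGraph, PeptideDistribution, PeptideNode, ProteinRecord

TOY_SEQ = "MDDDIAALVV"


@pytest.fixture
def toy_protein() -> ProteinRecord:
    return ProteinRecord("toy", TOY_SEQ)


def make_graph(intervals, edges, weights, seq=TOY_SEQ, abundances=None):
    """Build a graph from explicit intervals/edges (root interval first)."""
    abundances = abundances or {}
    nodes = [
        PeptideNode(
            id=i,
            start=s,
            end=e,
            sequence=seq[s:e],
            observed_abundance=abundances.get((s, e), 0.0),
        )
        for i, (s, e) in enumerate(intervals)
    ]
    return DegradationGraph(nodes, edges, np.asarray(weights, dtype=float))


@pytest.fixture
def chain_graph():
    """Root -> A (w=0.5) -> B (w=0.5): P = {root: 0.5, A: 0.25, B: 0.25}."""
    return make_graph(
        intervals=[(0, 10), (1, 6), (1, 4)],
        edges=[(0, 1), (1, 2)],
        weights=[0.5, 0.5],
    )


@pytest.fixture
def diamond_graph():
    """Root -> {A, B} -> C with all split weights 0.5."""
    return make_graph(
        intervals=[(0, 10), (0, 6), (2, 10), (3, 5)],
        edges=[(0, 1), (0, 2), (1, 3), (2, 3)],
        weights=[0.5, 0.5, 0.5, 0.5],
    )


def random_graph(
    rng: np.random.Generator,
    n_nodes: int = 10,
    protein_len: int = 60,
    edge_keep: float = 0.7,
) -> DegradationGraph:
    """Random containment DAG with random softmax weights.

    Every containment edge is kept with probability ``edge_keep``; nodes left
    without a parent are connected to the root so all are reachable.
    """
    ivals = set()
    while len(ivals) < n_nodes - 1:
        s = int(rng.integers(0, protein_len - 1))
        e = int(rng.integers(s + 1, protein_len + 1))
        if (s, e) != (0, protein_len):
            ivals.add((s, e))
    order = sorted([(0, protein_len), *ivals], key=lambda iv: (iv[0], iv[0] - iv[1], iv[1]))
    index = {iv: i for i, iv in enumerate(order)}
    edges = []
    for a in order:
        for b in order:
            if a == b:
                continue
            if a[0] <= b[0] and b[1] <= a[1] and (b[1] - b[0]) < (a[1] - a[0]):
                if a == (0, protein_len) or rng.random() < edge_keep:
                    edges.append((index[a], index[b]))
    has_parent = {v for _, v in edges}
    for iv, i in index.items():
        if i != 0 and i not in has_parent:
            edges.append((0, i))
    edges = sorted(set(edges))
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=protein_len))
    nodes = [
        PeptideNode(id=i, start=s, end=e, sequence=seq[s:e])
        for i, (s, e) in enumerate(order)
    ]
    graph = DegradationGraph(nodes, edges)
    graph.set_weights(random_weights(rng, graph))
    return graph


def random_weights(
    rng: np.random.Generator, graph: DegradationGraph, root_absorbs: bool = True
) -> np.ndarray:
    """Random stochastic edge weights (softmax of normal logits per node)."""
    w = np.zeros(graph.n_edges)
    for u in range(graph.n_nodes):
        eids = graph.out_edges[u]
        if not eids:
            continue
        logits = rng.normal(size=len(eids) + 1)
        ex = np.exp(logits - logits.max())
        s = ex / ex.sum()
        if u == 0 and not root_absorbs:
            s = s[:-1] / s[:-1].sum()  # root keeps nothing
        for j, eid in enumerate(eids):
            w[eid] = s[j]
    return w


def brute_force_marginal(graph: DegradationGraph) -> np.ndarray:
    """Exhaustive path enumeration: sum over all root->v paths of the
    product of edge weights times v's absorption.  Exponential; only for
    small graphs."""
    P = np.zeros(graph.n_nodes)

    def walk(u: int, prob: float) -> None:
        P[u] += prob * graph.absorption[u]
        for e in graph.out_edges[u]:
            walk(int(graph.edge_dst[e]), prob * graph.weights[e])

    walk(0, 1.0)
    return P


def feasible_observation(
    rng: np.random.Generator, graph: DegradationGraph
) -> PeptideDistribution:
    """A normalized observation with zero root mass (always LP-feasible,
    since every node is reachable from the root)."""
    y = rng.random(graph.n_nodes)
    y[0] = 0.0
    return PeptideDistribution(graph, y / y.sum())
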