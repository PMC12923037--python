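"""Core degradation-graph model.

A degradation graph represents sequential proteolysis of one parent protein
as a directed acyclic graph.  Nodes are peptides, identified by their
half-open interval ``[start, end)`` on the parent sequence, plus a root node
Ω spanning the full protein.  A directed edge ``u -> v`` states that peptide
``u`` can be cleaved into the strictly contained peptide ``v``; the edge
carries a transition probability ``w[u->v]``.  Whatever probability does not
leave a node is absorbed there (the peptide persists), so for every node

    absorption(v) + sum_{u in children(v)} w[v->u] = 1.

Injecting unit mass at Ω and propagating it through the DAG yields the
marginal peptide distribution **P**: the steady-state probability that each
peptide is the endpoint of a degradation pathway.  Because strict interval
containment forces acyclicity, all mass is eventually absorbed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "PeptideNode",
    "PeptideDistribution",
    "DegradationGraph",
    "build_graph",
    "forward_pass",
    "reach_probability",
    "reach_probabilities",
    "conditional_distribution",
    "marginal_recursive",
    "marginal_gradient",
]

#: tolerance for probability-sum invariants
PROB_TOL = 1e-9


@dataclass(frozen=True)
class PeptideNode:
    """An observed peptide positioned on the parent protein.

    ``start``/``end`` are 0-based half-open coordinates; ``observed_abundance``
    is the Y(v) entry of the normalized observed distribution (0 for Ω and
    for latent nodes).
    """

    id: int
    start: int
    end: int
    sequence: str
    observed_abundance: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"node interval [{self.start}, {self.end}) is empty")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval length "
                f"{self.end - self.start}"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


class PeptideDistribution(Mapping[int, float]):
    """A vector of non-negative mass over the nodes of a graph.

    Used both for the observed distribution Y and the modeled marginal P.
    Behaves as a read-only mapping node-id -> value; the underlying numpy
    array is available as ``.values_array`` (aligned with ``graph.nodes``).
    """

    def __init__(self, graph: "DegradationGraph", values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (graph.n_nodes,):
            raise ValueError("distribution length does not match node count")
        self.graph = graph
        self.values_array = values

    def __getitem__(self, node_id: int) -> float:
        return float(self.values_array[node_id])

    def __iter__(self) -> Iterator[int]:
        return iter(range(self.graph.n_nodes))

    def __len__(self) -> int:
        return self.graph.n_nodes

    def total(self) -> float:
        return float(self.values_array.sum())

    def by_interval(self) -> dict[tuple[int, int], float]:
        return {n.interval: self[n.id] for n in self.graph.nodes}

    def __repr__(self) -> str:  # pragma: no cover
        return f"PeptideDistribution({self.by_interval()!r})"


class DegradationGraph:
    """DAG of peptide nodes with transition and absorption probabilities.

    Nodes are stored in topological order with the root Ω at index 0.
    Self-loops (absorption) are stored as a per-node scalar, not as edges,
    so the edge list is a proper DAG.
    """

    def __init__(
        self,
        nodes: list[PeptideNode],
        edges: list[tuple[int, int]],
        weights: np.ndarray | None = None,
        protein_id: str = "",
    ):
        self.nodes = nodes
        self.protein_id = protein_id
        self.edge_src = np.array([u for u, _ in edges], dtype=np.int64)
        self.edge_dst = np.array([v for _, v in edges], dtype=np.int64)
        self._check_structure()
        # adjacency as lists of edge indices
        self.out_edges: list[list[int]] = [[] for _ in nodes]
        self.in_edges: list[list[int]] = [[] for _ in nodes]
        for e, (u, v) in enumerate(edges):
            self.out_edges[u].append(e)
            self.in_edges[v].append(e)
        if weights is None:
            weights = self.uniform_weights()
        self.set_weights(weights)

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    @property
    def root(self) -> PeptideNode:
        return self.nodes[0]

    @property
    def edges(self) -> list[tuple[int, int]]:
        return list(zip(self.edge_src.tolist(), self.edge_dst.tolist()))

    def children(self, u: int) -> list[int]:
        return [int(self.edge_dst[e]) for e in self.out_edges[u]]

    def parents(self, v: int) -> list[int]:
        return [int(self.edge_src[e]) for e in self.in_edges[v]]

    def edge_index(self, u: int, v: int) -> int:
        for e in self.out_edges[u]:
            if self.edge_dst[e] == v:
                return e
        raise KeyError(f"edge ({u} -> {v}) not in graph")

    def _check_structure(self) -> None:
        ivals = [n.interval for n in self.nodes]
        root = self.nodes[0]
        for n in self.nodes[1:]:
            if not (root.start <= n.start and n.end <= root.end):
                raise ValueError(
                    f"node {n.interval} outside root span {root.interval}"
                )
        if len(set(ivals)) != len(ivals):
            raise ValueError("duplicate node intervals")
        for u, v in zip(self.edge_src, self.edge_dst):
            a, b = self.nodes[u], self.nodes[v]
            contained = a.start <= b.start and b.end <= a.end and len(b) < len(a)
            if not contained:
                raise ValueError(
                    f"edge {a.interval} -> {b.interval} violates strict containment"
                )
            if u >= v:
                raise ValueError("edges must point forward in topological order")

    # -- weights -----------------------------------------------------------

    def uniform_weights(self) -> np.ndarray:
        """Weights from θ = 0: each node splits mass uniformly over its
        children plus its own absorption."""
        w = np.empty(self.n_edges)
        for u in range(self.n_nodes):
            k = len(self.out_edges[u])
            for e in self.out_edges[u]:
                w[e] = 1.0 / (k + 1)
        return w

    def set_weights(
        self,
        weights: np.ndarray,
        absorption: np.ndarray | None = None,
        validate: bool = True,
    ) -> None:
        """Assign edge weights; absorption defaults to ``1 - outgoing sum``.

        An explicit ``absorption`` vector decouples the self-loop weight from
        the edge weights (needed e.g. when probing P as a function of one raw
        weight with the others held fixed); validation then only checks
        non-negativity.
        """
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (self.n_edges,):
            raise ValueError("weight vector length does not match edge count")
        out_sum = np.zeros(self.n_nodes)
        np.add.at(out_sum, self.edge_src, weights)
        if validate and np.any(weights < -PROB_TOL):
            raise ValueError("negative edge weight")
        if absorption is None:
            if validate and np.any(out_sum > 1.0 + 1e-6):
                raise ValueError("outgoing weights exceed 1 at some node")
            absorption = 1.0 - out_sum
        else:
            absorption = np.asarray(absorption, dtype=float)
            if absorption.shape != (self.n_nodes,):
                raise ValueError("absorption vector length does not match node count")
        self.weights = weights
        self.absorption = absorption

    def validate_weights(self, tol: float = PROB_TOL) -> None:
        """Assert the stochastic invariant absorption + outgoing = 1 per node."""
        out_sum = np.zeros(self.n_nodes)
        np.add.at(out_sum, self.edge_src, self.weights)
        if np.any(self.weights < -tol) or np.any(self.absorption < -tol):
            raise ValueError("negative probability in weight assignment")
        resid = np.abs(self.absorption + out_sum - 1.0)
        if resid.max(initial=0.0) > 1e-6:
            raise ValueError(
                f"absorption + outgoing deviates from 1 by {resid.max():.3g}"
            )

    def weight(self, u: int, v: int) -> float:
        if u == v:
            return float(self.absorption[u])
        return float(self.weights[self.edge_index(u, v)])

    def observed(self) -> PeptideDistribution:
        """The observed distribution Y carried on the nodes."""
        return PeptideDistribution(
            self, np.array([n.observed_abundance for n in self.nodes])
        )

    def copy(self) -> "DegradationGraph":
        return DegradationGraph(
            list(self.nodes), self.edges, self.weights.copy(), self.protein_id
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DegradationGraph(protein={self.protein_id!r}, "
            f"nodes={self.n_nodes}, edges={self.n_edges})"
        )


# ---------------------------------------------------------------------------
# construction


def _topological_sort_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    # (start, -length, end) orders every strict container before its content
    return sorted(intervals, key=lambda iv: (iv[0], iv[0] - iv[1], iv[1]))


def build_graph(
    distribution: Mapping[tuple[int, int], float],
    protein,
    policy: str = "full",
    protein_id: str | None = None,
) -> DegradationGraph:
    """Build a degradation graph over the observed peptides of one protein.

    Parameters
    ----------
    distribution
        Map ``(start, end) -> normalized abundance`` of observed peptides
        (0-based half-open coordinates on the protein).
    protein
        Object with ``identifier`` and ``sequence`` attributes, or a plain
        sequence string.
    policy
        ``"full"`` inserts an edge for every strict interval containment
        among nodes (including Ω -> v for every v); ``"reduction"`` keeps
        only containment edges with no intermediate observed node
        (transitive reduction), which lowers the parameter count.

    Every node unreachable through another peptide keeps a direct Ω edge,
    so mass can always reach every observed peptide.  Initial weights are
    uniform (θ = 0).
    """
    seq = protein if isinstance(protein, str) else protein.sequence
    pid = protein_id or ("" if isinstance(protein, str) else protein.identifier)
    if not distribution:
        raise ValueError("need at least one observed peptide")
    L = len(seq)
    for (s, e) in distribution:
        if not (0 <= s < e <= L):
            raise ValueError(f"peptide [{s}, {e}) outside protein span [0, {L})")
    if (0, L) in distribution:
        raise ValueError("observed peptide coincides with the full-length protein")

    order = _topological_sort_intervals([(0, L), *distribution.keys()])
    index = {iv: i for i, iv in enumerate(order)}
    nodes = [
        PeptideNode(
            id=i,
            start=s,
            end=e,
            sequence=seq[s:e],
            observed_abundance=float(distribution.get((s, e), 0.0)),
        )
        for i, (s, e) in enumerate(order)
    ]

    def contains(a: tuple[int, int], b: tuple[int, int]) -> bool:
        return a[0] <= b[0] and b[1] <= a[1] and (b[1] - b[0]) < (a[1] - a[0])

    edges = [
        (index[a], index[b])
        for a, b in itertools.permutations(order, 2)
        if contains(a, b)
    ]
    if policy == "reduction":
        import networkx as nx

        g = nx.DiGraph(edges)
        g.add_nodes_from(range(len(order)))
        edges = list(nx.transitive_reduction(g).edges())
    elif policy != "full":
        raise ValueError(f"unknown edge policy {policy!r}")
    edges.sort()
    return DegradationGraph(nodes, edges, protein_id=pid)


# ---------------------------------------------------------------------------
# forward model


def _propagate(graph: DegradationGraph, source: int) -> np.ndarray:
    """Reach probabilities p(v) for unit mass injected at ``source``."""
    p = np.zeros(graph.n_nodes)
    p[source] = 1.0
    for u in range(source, graph.n_nodes):
        if p[u] == 0.0:
            continue
        for e in graph.out_edges[u]:
            p[graph.edge_dst[e]] += p[u] * graph.weights[e]
    return p


def forward_pass(
    graph: DegradationGraph, validate: bool = True
) -> PeptideDistribution:
    """Propagate unit mass from Ω and return the absorbed-mass distribution P.

    Mass moves through nodes in topological order; at each node the fraction
    ``absorption(v)`` of the arriving mass stays, the rest follows the
    outgoing weights.  For a valid weight assignment ``sum(P) == 1``.
    """
    if validate:
        graph.validate_weights()
    p = _propagate(graph, 0)
    P = p * graph.absorption
    if validate and abs(P.sum() - 1.0) > 1e-6:
        raise ValueError(f"absorbed mass sums to {P.sum():.12f}, expected 1")
    return PeptideDistribution(graph, P)


def reach_probabilities(graph: DegradationGraph) -> np.ndarray:
    """Cumulative probability P(Ω -> u) of reaching each node from the root,
    integrated over all degradation paths.  P(Ω -> Ω) = 1."""
    return _propagate(graph, 0)


def reach_probability(graph: DegradationGraph, u: int) -> float:
    return float(reach_probabilities(graph)[u])


def conditional_distribution(graph: DegradationGraph, k: int) -> PeptideDistribution:
    """Absorption distribution P(.|k) for unit mass injected at node ``k``.

    Satisfies the downstream recursion
    ``P(.|k) = sum_i w[k->i] P(.|i) + 1_k w[k->k]``; for k = Ω it equals the
    forward-pass marginal.
    """
    if not (0 <= k < graph.n_nodes):
        raise KeyError(f"unknown node {k}")
    p = _propagate(graph, k)
    return PeptideDistribution(graph, p * graph.absorption)


def marginal_recursive(graph: DegradationGraph) -> PeptideDistribution:
    """Marginal P computed by the parent-sum recursion.

    ``P(Ω) = w[Ω->Ω]`` and, in topological order,

        P(v) = sum_{u in parents(v)} P(u) / w[u->u] * w[u->v] * w[v->v].

    The ratio ``P(u)/w[u->u]`` is the reach probability of ``u``; where a
    node with children absorbs exactly 0 the ratio is undefined, and the
    recursion falls back to explicitly tracked reach probabilities (the two
    forms are identical whenever the ratio exists).
    """
    n = graph.n_nodes
    reach = np.zeros(n)
    reach[0] = 1.0
    P = np.zeros(n)
    P[0] = graph.absorption[0]
    for v in range(1, n):
        acc = 0.0
        for e in graph.in_edges[v]:
            u = int(graph.edge_src[e])
            w_uu = graph.absorption[u]
            r = P[u] / w_uu if w_uu > 0.0 else reach[u]
            acc += r * graph.weights[e]
        reach[v] = acc
        P[v] = acc * graph.absorption[v]
    return PeptideDistribution(graph, P)


def marginal_gradient(
    graph: DegradationGraph, edge: tuple[int, int]
) -> PeptideDistribution:
    """Closed-form gradient of the marginal P w.r.t. one raw weight.

    For an edge ``(i, j)`` with ``i != j``,

        dP/dw[i->j] = P(Ω->i) * P(.|j),

    and for the self-loop ``(i, i)`` (absorption),

        dP/dw[i->i] = 1_i * P(Ω->i),

    holding all other raw weights fixed.  Matches central finite differences
    of :func:`forward_pass` because P is multilinear in the weights.
    """
    i, j = edge
    reach_i = reach_probability(graph, i)
    if i == j:
        g = np.zeros(graph.n_nodes)
        g[i] = reach_i
        return PeptideDistribution(graph, g)
    graph.edge_index(i, j)  # raises KeyError if absent
    cond_j = conditional_distribution(graph, j)
    return PeptideDistribution(graph, reach_i * cond_j.values_array)
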