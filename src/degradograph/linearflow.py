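"""Linear-programming reconstruction of degradation flows.

Treats inference as a network-flow feasibility problem: one non-negative
flow variable per edge, unit mass injected at the root Ω, and conservation
at every other node — incoming flow equals observed (absorbed) abundance
plus outgoing flow.  Solved with scipy's HiGHS backend; by default the small
regularizer ``min sum(F)`` is used for a deterministic solution.  Ratios of
flows convert back to transition probabilities, and the forward pass of the
converted graph reproduces Y exactly (up to solver tolerance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .graph import DegradationGraph, PeptideDistribution, forward_pass

logger = logging.getLogger(__name__)

__all__ = ["FlowSolution", "solve_flow", "flows_to_probabilities"]

#: post-hoc feasibility tolerance on conservation residuals
RESIDUAL_TOL = 1e-8


@dataclass
class FlowSolution:
    """Non-negative per-edge flows satisfying conservation.

    ``incoming_mass[u]`` is M_u, the total mass arriving at node u (1 at the
    root by the injection constraint).  ``observed`` is the (re)normalized Y
    the system was solved against.
    """

    graph: DegradationGraph
    flows: np.ndarray
    incoming_mass: np.ndarray
    observed: np.ndarray
    status: str

    @property
    def total_flow(self) -> float:
        return float(self.flows.sum())

    def conservation_residuals(self) -> np.ndarray:
        """Per-node residual of (incoming) - (observed + outgoing); 0 at Ω
        by convention (the root constraint is the injection sum)."""
        g = self.graph
        resid = np.zeros(g.n_nodes)
        inflow = np.zeros(g.n_nodes)
        outflow = np.zeros(g.n_nodes)
        np.add.at(inflow, g.edge_dst, self.flows)
        np.add.at(outflow, g.edge_src, self.flows)
        resid[1:] = inflow[1:] - outflow[1:] - self.observed[1:]
        resid[0] = outflow[0] - 1.0
        return resid


def _normalize_observed(graph: DegradationGraph, Y: PeptideDistribution) -> np.ndarray:
    y = Y.values_array.copy()
    if y[0] != 0.0:
        raise ValueError(
            "observed distribution assigns mass to the root; the flow system "
            "absorbs nothing at the intact protein"
        )
    total = y.sum()
    if total <= 0:
        raise ValueError("observed distribution is all zero")
    if abs(total - 1.0) > 1e-9:
        logger.warning(
            "observed distribution sums to %.6g; rescaling to 1 for the flow "
            "system (unit root injection requires unit absorbed mass)", total,
        )
        y = y / total
    return y


def solve_flow(
    graph: DegradationGraph,
    Y: PeptideDistribution,
    objective: str = "min-total-flow",
) -> FlowSolution:
    """Solve the flow LP for an observed distribution.

    ``objective`` is ``"min-total-flow"`` (default; deterministic up to LP
    degeneracy, flagged as potentially non-unique) or ``"none"`` for bare
    feasibility.  Raises on infeasibility, naming an observed peptide with
    no path from the root when one exists.
    """
    if objective not in {"min-total-flow", "none"}:
        raise ValueError(f"unknown objective {objective!r}")
    y = _normalize_observed(graph, Y)
    n, m = graph.n_nodes, graph.n_edges
    if m == 0:
        raise ValueError("graph has no edges")

    A = np.zeros((n, m))
    b = np.zeros(n)
    for e in range(m):
        u, v = int(graph.edge_src[e]), int(graph.edge_dst[e])
        if u == 0:
            A[0, e] += 1.0
        else:
            A[u, e] += 1.0  # outgoing from non-root u
        A[v, e] -= 1.0 if v != 0 else 0.0  # incoming (root has none)
    b[0] = 1.0
    b[1:] = -y[1:]
    c = np.ones(m) if objective == "min-total-flow" else np.zeros(m)

    res = linprog(c, A_eq=A, b_eq=b, bounds=(0, None), method="highs")
    if not res.success:
        # name a structurally unreachable positive-abundance node if any
        reachable = {0}
        for e in range(m):
            if int(graph.edge_src[e]) in reachable:
                reachable.add(int(graph.edge_dst[e]))
        for v in range(1, n):
            if y[v] > 0 and v not in reachable:
                node = graph.nodes[v]
                raise ValueError(
                    f"infeasible: peptide {node.sequence!r} "
                    f"[{node.start}, {node.end}) has positive abundance but no "
                    f"path from the root"
                )
        raise ValueError(f"flow LP failed: {res.message}")

    flows = np.maximum(res.x, 0.0)
    incoming = np.zeros(n)
    np.add.at(incoming, graph.edge_dst, flows)
    incoming[0] = 1.0  # injected mass
    sol = FlowSolution(
        graph=graph, flows=flows, incoming_mass=incoming, observed=y,
        status=res.message,
    )
    resid = np.abs(sol.conservation_residuals())
    if resid.max(initial=0.0) > RESIDUAL_TOL:
        raise ValueError(
            f"solver returned flows violating conservation by {resid.max():.3g}"
        )
    return sol


def flows_to_probabilities(
    solution: FlowSolution, graph: DegradationGraph | None = None
) -> DegradationGraph:
    """Convert flows to transition probabilities.

    ``w[u->v] = F[u->v] / M_u`` with M_u the total incoming mass at u (1 at
    the root); nodes with M_u = 0 get all-zero outgoing weights and
    absorption 1.  The forward pass of the returned graph reproduces the
    observed distribution the flows were solved against.
    """
    g = graph or solution.graph
    M = solution.incoming_mass
    w = np.zeros(g.n_edges)
    for e in range(g.n_edges):
        u = int(g.edge_src[e])
        if M[u] > 0:
            w[e] = solution.flows[e] / M[u]
    # guard against tiny numerical excess in outgoing sums
    out_sum = np.zeros(g.n_nodes)
    np.add.at(out_sum, g.edge_src, w)
    over = out_sum > 1.0
    if np.any(over):
        for e in range(g.n_edges):
            u = int(g.edge_src[e])
            if over[u]:
                w[e] /= out_sum[u]
    fitted = g.copy()
    fitted.set_weights(w, validate=True)
    return fitted


def fit_lp(
    graph: DegradationGraph,
    Y: PeptideDistribution,
    objective: str = "min-total-flow",
) -> tuple[DegradationGraph, FlowSolution]:
    """Convenience: solve the LP and return (probability graph, flows)."""
    sol = solve_flow(graph, Y, objective=objective)
    return flows_to_probabilities(sol), sol
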