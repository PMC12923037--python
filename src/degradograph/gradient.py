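"""Gradient-based inference of transition probabilities.

Each node ``u`` with children carries a logit vector ``theta_u`` — one entry
per child plus one absorption entry — mapped through a softmax to strictly
positive transition probabilities summing to one.  The fit minimizes

    L = sum_v (P(v) - Y(v))^2  +  l1 * sum ||theta_u||_1 + l2 * sum ||theta_u||_2^2

where P is the forward-pass marginal.  Gradients of the squared error with
respect to the raw weights follow the closed form

    dP/dw[i->j] = reach(i) * P(.|j)        (i != j)
    dP/dw[i->i] = 1_i * reach(i)

computed in one reverse sweep over the DAG (the adjoint of the forward
pass), then pushed through the softmax Jacobian.  Optimization uses plain
gradient descent or a numpy Adam; all randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph import DegradationGraph, PeptideDistribution, forward_pass

__all__ = [
    "FitConfig",
    "FitResult",
    "LogitParameterization",
    "loss",
    "fit",
    "stability_analysis",
    "StabilityReport",
]


class LogitParameterization:
    """Flattened raw logits for every node that has children.

    Per node the softmax of ``[theta_{u->child_1..k}, theta_{u->u}]`` yields
    the child transition probabilities and the absorption; childless nodes
    absorb with probability 1 and carry no parameters.
    """

    def __init__(self, graph: DegradationGraph):
        self.graph = graph
        self.param_nodes = [u for u in range(graph.n_nodes) if graph.out_edges[u]]
        self.slices: dict[int, slice] = {}
        entry_node: list[int] = []
        entry_edge: list[int] = []
        off = 0
        for u in self.param_nodes:
            k = len(graph.out_edges[u]) + 1
            self.slices[u] = slice(off, off + k)
            entry_node.extend([u] * k)
            entry_edge.extend([*graph.out_edges[u], -1])  # -1 = absorption entry
            off += k
        self.n_params = off
        self._node = np.array(entry_node, dtype=np.int64)
        self._edge = np.array(entry_edge, dtype=np.int64)
        self._is_edge = self._edge >= 0

    def zeros(self) -> np.ndarray:
        return np.zeros(self.n_params)

    def _softmax(self, theta: np.ndarray) -> np.ndarray:
        g = self.graph
        mx = np.full(g.n_nodes, -np.inf)
        np.maximum.at(mx, self._node, theta)
        ex = np.exp(theta - mx[self._node])
        denom = np.zeros(g.n_nodes)
        np.add.at(denom, self._node, ex)
        return ex / denom[self._node]

    def weights(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map logits to (edge weights, absorption)."""
        g = self.graph
        s = self._softmax(theta)
        w = np.zeros(g.n_edges)
        w[self._edge[self._is_edge]] = s[self._is_edge]
        absorb = np.ones(g.n_nodes)
        absorb[self._node[~self._is_edge]] = s[~self._is_edge]
        return w, absorb

    def chain_to_theta(
        self,
        theta: np.ndarray,
        grad_w: np.ndarray,
        grad_absorb: np.ndarray,
    ) -> np.ndarray:
        """Push raw-weight gradients through the softmax Jacobian
        (``dL/dtheta_k = s_k (g_k - sum_m s_m g_m)`` per node)."""
        s = self._softmax(theta)
        gv = np.where(
            self._is_edge,
            grad_w[np.maximum(self._edge, 0)],
            grad_absorb[self._node],
        )
        dot = np.zeros(self.graph.n_nodes)
        np.add.at(dot, self._node, s * gv)
        return s * (gv - dot[self._node])


@dataclass
class FitConfig:
    learning_rate: float = 0.01
    epochs: int = 2000
    l1: float = 0.0
    l2: float = 0.0
    seed: int = 0
    optimizer: str = "adam"  # or "gd"
    tol: float = 1e-10       # early stop: best-loss improvement within `patience`
    patience: int = 50
    init_sigma: float = 0.0  # 0 -> uniform init (theta = 0)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("regularization weights must be >= 0")


@dataclass
class FitResult:
    graph: DegradationGraph
    theta: np.ndarray
    loss_trajectory: list[float]
    converged: bool
    final_loss: float
    seed: int

    @property
    def marginal(self) -> PeptideDistribution:
        return forward_pass(self.graph)


def loss(
    P: PeptideDistribution,
    Y: PeptideDistribution,
    theta: np.ndarray | None = None,
    l1: float = 0.0,
    l2: float = 0.0,
) -> float:
    """Squared-error loss ``sum_v (P(v) - Y(v))^2`` plus L1/L2 penalties."""
    if len(P) != len(Y) or P.graph.n_nodes != Y.graph.n_nodes:
        raise ValueError("P and Y are over different node sets")
    mse = float(np.sum((P.values_array - Y.values_array) ** 2))
    reg = 0.0
    if theta is not None and (l1 > 0 or l2 > 0):
        reg = l1 * float(np.abs(theta).sum()) + l2 * float(np.sum(theta**2))
    return mse + reg


def _edge_levels(graph: DegradationGraph) -> list[np.ndarray]:
    """Edge indices grouped by the topological level of their source node.

    Level(v) = longest path length from the root; every edge goes from a
    lower to a strictly higher level, so each group can be propagated as one
    vectorized scatter-add.
    """
    n = graph.n_nodes
    level = np.zeros(n, dtype=np.int64)
    for e in range(graph.n_edges):
        u, v = int(graph.edge_src[e]), int(graph.edge_dst[e])
        level[v] = max(level[v], level[u] + 1)
    src_level = level[graph.edge_src]
    return [
        np.flatnonzero(src_level == l) for l in range(int(level.max(initial=0)) + 1)
    ]


def _mse_and_grads(
    graph: DegradationGraph,
    w: np.ndarray,
    absorb: np.ndarray,
    Y: np.ndarray,
    levels: list[np.ndarray],
) -> tuple[float, np.ndarray, np.ndarray]:
    """Forward pass + adjoint sweep: squared error and its raw-weight grads.

    The reverse accumulation computes, for every node v,
    ``q(v) = sum_t dL/dP(t) * P(t|v)`` without materializing each
    conditional distribution; ``dL/dw[u->v] = reach(u) * q(v)`` is then the
    closed-form edge gradient summed over the loss.
    """
    n = graph.n_nodes
    src, dst = graph.edge_src, graph.edge_dst
    reach = np.zeros(n)
    reach[0] = 1.0
    for eidx in levels:
        np.add.at(reach, dst[eidx], reach[src[eidx]] * w[eidx])
    P = reach * absorb
    diff = P - Y
    mse = float(diff @ diff)
    dP = 2.0 * diff
    q = dP * absorb
    for eidx in reversed(levels):
        np.add.at(q, src[eidx], w[eidx] * q[dst[eidx]])
    grad_w = reach[src] * q[dst]
    grad_absorb = reach * dP
    return mse, grad_w, grad_absorb


def fit(
    graph: DegradationGraph,
    Y: PeptideDistribution,
    config: FitConfig | None = None,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Fit transition probabilities so the modeled marginal matches ``Y``.

    Returns the parameters at the best (lowest-loss) recorded iterate; with
    adaptive optimizers the per-step loss need not be monotone.  The fitted
    weights always form a valid stochastic assignment (softmax by
    construction).
    """
    cfg = config or FitConfig()
    if graph.n_edges == 0:
        raise ValueError("graph has no edges to fit")
    if len(Y) != graph.n_nodes:
        raise ValueError("Y does not match the graph's node set")
    param = LogitParameterization(graph)
    rng = np.random.default_rng(cfg.seed)
    if theta0 is not None:
        theta = np.asarray(theta0, dtype=float).copy()
    elif cfg.init_sigma > 0:
        theta = rng.normal(0.0, cfg.init_sigma, size=param.n_params)
    else:
        theta = param.zeros()
    Yv = Y.values_array
    levels = _edge_levels(graph)

    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best_theta = theta.copy()
    best_loss = np.inf
    since_best = 0
    trajectory: list[float] = []
    converged = False
    for it in range(cfg.epochs):
        w, absorb = param.weights(theta)
        mse, grad_w, grad_absorb = _mse_and_grads(graph, w, absorb, Yv, levels)
        total = mse
        if cfg.l1 > 0 or cfg.l2 > 0:
            total += cfg.l1 * float(np.abs(theta).sum()) + cfg.l2 * float(
                np.sum(theta**2)
            )
        if not np.isfinite(total):
            raise FloatingPointError(f"non-finite loss at iteration {it}")
        trajectory.append(total)
        if total < best_loss - cfg.tol:
            best_loss = total
            best_theta = theta.copy()
            since_best = 0
        else:
            if total < best_loss:
                best_loss = total
                best_theta = theta.copy()
            since_best += 1
            if since_best >= cfg.patience:
                converged = True
                break
        grad = param.chain_to_theta(theta, grad_w, grad_absorb)
        if cfg.l1 > 0:
            grad += cfg.l1 * np.sign(theta)
        if cfg.l2 > 0:
            grad += 2.0 * cfg.l2 * theta
        if cfg.optimizer == "adam":
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            mh = m / (1 - beta1 ** (it + 1))
            vh = v / (1 - beta2 ** (it + 1))
            theta = theta - cfg.learning_rate * mh / (np.sqrt(vh) + eps)
        elif cfg.optimizer == "gd":
            theta = theta - cfg.learning_rate * grad
        else:
            raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    fitted = graph.copy()
    w, absorb = param.weights(best_theta)
    fitted.set_weights(w, validate=True)
    return FitResult(
        graph=fitted,
        theta=best_theta,
        loss_trajectory=trajectory,
        converged=converged,
        final_loss=best_loss,
        seed=cfg.seed,
    )


@dataclass
class StabilityReport:
    per_edge_cv: np.ndarray
    mean_cv: float
    top_k_overlap: float
    replicate_weights: np.ndarray  # (n_replicates, n_edges)
    failed_replicates: list[int] = field(default_factory=list)
    results: list[FitResult] = field(default_factory=list)


def stability_analysis(
    graph: DegradationGraph,
    Y: PeptideDistribution,
    config: FitConfig | None = None,
    n_replicates: int = 5,
    top_k: int = 5,
) -> StabilityReport:
    """Fit from ``n_replicates`` random initializations and summarize spread.

    Reports the per-edge coefficient of variation (sample std / mean) of the
    fitted weights, their mean, and the mean pairwise overlap of the top-k
    edges ranked by flow across replicates.  Replicates that fail to
    converge are flagged, not fatal.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    cfg = config or FitConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_replicates) % (2**31)
    sigma = cfg.init_sigma if cfg.init_sigma > 0 else 0.1
    results: list[FitResult] = []
    failed: list[int] = []
    for r in range(n_replicates):
        rep_cfg = FitConfig(
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            l1=cfg.l1,
            l2=cfg.l2,
            seed=int(seeds[r]),
            optimizer=cfg.optimizer,
            tol=cfg.tol,
            patience=cfg.patience,
            init_sigma=sigma,
        )
        res = fit(graph, Y, rep_cfg)
        results.append(res)
        if not res.converged:
            failed.append(r)

    W = np.vstack([res.graph.weights for res in results])
    mean = W.mean(axis=0)
    std = W.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, std / mean, 0.0)
    # top-k edges by flow, compared pairwise across replicates
    from .quantify import weights_to_flows

    k = min(top_k, graph.n_edges)
    tops = []
    for res in results:
        flows = weights_to_flows(res.graph)
        tops.append(set(np.argsort(-flows, kind="stable")[:k].tolist()))
    pairs = [
        len(a & b) / k
        for i, a in enumerate(tops)
        for b in tops[i + 1:]
    ]
    return StabilityReport(
        per_edge_cv=cv,
        mean_cv=float(cv.mean()),
        top_k_overlap=float(np.mean(pairs)) if pairs else 1.0,
        replicate_weights=W,
        failed_replicates=failed,
        results=results,
    )
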