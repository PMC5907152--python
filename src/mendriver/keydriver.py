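"""Key-driver scoring of subnetwork members.

The key driver of a disease-relevant subnetwork is its top node under
damped PageRank on the undirected weighted association graph: a node's
score is fed by its neighbours' scores in proportion to edge weight,
with teleportation mass ``1 - c`` spread by the teleport vector E
(uniform by default). The weighted-degree ranking serves as the baseline
the benchmark compares against.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["NodeScores", "pagerank", "degree_scores", "identify_key_drivers"]


@dataclass
class NodeScores:
    """Per-node scores for one subnetwork graph."""

    subnetwork_id: object
    scores: dict
    method: str
    damping: float | None = None
    teleport: dict | None = None
    n_iter: int | None = None

    def ranked(self) -> list:
        """Nodes by descending score; ties broken by node id."""
        return sorted(self.scores, key=lambda u: (-self.scores[u], str(u)))


def _graph_to_arrays(graph: nx.Graph):
    nodes = sorted(graph.nodes, key=str)
    index = {u: i for i, u in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("edge weights must be non-negative")
        W[index[u], index[v]] = W[index[v], index[u]] = w
    return nodes, W


def pagerank_weights(
    W: np.ndarray,
    c: float = 0.85,
    E: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int]:
    """Damped PageRank on a symmetric non-negative weight matrix.

    Power iteration on the weighted-degree-normalized transition operator
    with teleport mass ``1 - c`` distributed by E; mass on dangling nodes
    (zero weighted degree) is also redistributed by E, so the scores sum
    to 1. Convergence is successive L1 change below ``tol``.
    """
    n = W.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if not 0.0 < c < 1.0:
        raise ValueError("damping c must be in (0, 1)")
    if E is None:
        E = np.full(n, 1.0 / n)
    else:
        E = np.asarray(E, dtype=float)
        if E.shape != (n,) or (E < 0).any() or E.sum() <= 0:
            raise ValueError("teleport vector must be non-negative with positive sum")
        E = E / E.sum()
    deg = W.sum(axis=1)
    dangling = deg <= 0
    P = W / np.where(dangling, 1.0, deg)[:, None]
    P[dangling] = 0.0
    r = np.full(n, 1.0 / n)
    for it in range(1, max_iter + 1):
        r_new = c * (P.T @ r + r[dangling].sum() * E) + (1.0 - c) * E
        delta = float(np.abs(r_new - r).sum())
        r = r_new
        if delta < tol:
            return r / r.sum(), it
    raise RuntimeError(
        f"PageRank did not converge in {max_iter} iterations (residual {delta:.3e})"
    )


def pagerank(
    graph: nx.Graph,
    c: float = 0.85,
    E: dict | None = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> NodeScores:
    """PageRank scores for a subnetwork graph (see :func:`pagerank_weights`)."""
    nodes, W = _graph_to_arrays(graph)
    Evec = None
    if E is not None:
        Evec = np.array([E.get(u, 0.0) for u in nodes], dtype=float)
    r, n_iter = pagerank_weights(W, c=c, E=Evec, tol=tol, max_iter=max_iter)
    teleport = (
        {u: float(v) for u, v in zip(nodes, Evec / Evec.sum())}
        if Evec is not None
        else {u: 1.0 / len(nodes) for u in nodes}
    )
    return NodeScores(
        subnetwork_id=graph.graph.get("subnetwork_id"),
        scores={u: float(s) for u, s in zip(nodes, r)},
        method="pagerank",
        damping=c,
        teleport=teleport,
        n_iter=n_iter,
    )


def degree_scores(graph: nx.Graph) -> NodeScores:
    """Weighted degree (sum of incident edge weights) per node."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    scores = {u: float(d) for u, d in graph.degree(weight="weight")}
    return NodeScores(
        subnetwork_id=graph.graph.get("subnetwork_id"),
        scores=scores,
        method="degree",
    )


def identify_key_drivers(
    graph: nx.Graph,
    method: str = "pagerank",
    top_k: int = 1,
    **kwargs,
) -> list:
    """Top-``top_k`` nodes by the chosen scoring, deterministic ties.

    Ties are broken lexicographically by node id so reruns are stable.
    """
    if method == "pagerank":
        ns = pagerank(graph, **kwargs)
    elif method == "degree":
        ns = degree_scores(graph)
    else:
        raise ValueError("method must be 'pagerank' or 'degree'")
    return ns.ranked()[:top_k]
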