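"""Binary-graph topology metrics and degree-preserving null models.

Global metrics: clustering coefficient Cp, characteristic path length Lp,
their normalised counterparts gamma and lambda (ratios to the means of a
degree-matched Maslov–Sneppen rewired ensemble), small-worldness
sigma = gamma/lambda, global efficiency Eglob and local efficiency Eloc.
Nodal metrics: degree, nodal efficiency and betweenness centrality.

Conventions for possibly-disconnected graphs: Lp averages the finite
shortest-path lengths only (the number of unreachable ordered pairs is
available from :func:`distance_matrix`), while the efficiency metrics
handle disconnection natively through 1/inf = 0. No penalty constant is
invented for unreachable pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .network import BinaryNetwork

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "RandomEnsembleSpec",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "betweenness",
    "random_reference",
    "normalized_metrics",
    "global_metrics",
    "nodal_metrics",
    "small_world_sigma",
]


@dataclass(frozen=True)
class GlobalMetrics:
    """The seven global topology descriptors of one binary network."""

    cp: float
    lp: float
    gamma: float
    lambda_: float
    sigma: float
    eglob: float
    eloc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "cp": self.cp,
            "lp": self.lp,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
            "eglob": self.eglob,
            "eloc": self.eloc,
        }


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node centrality descriptors of one binary network."""

    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "degree": self.degree,
            "efficiency": self.efficiency,
            "betweenness": self.betweenness,
        }


@dataclass(frozen=True)
class RandomEnsembleSpec:
    """Degree-preserving random-reference ensemble configuration.

    ``swaps_per_edge`` Maslov–Sneppen double-edge swaps are attempted per
    edge for each of ``n_networks`` rewired surrogates.
    """

    n_networks: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_networks < 1 or self.swaps_per_edge < 1:
            raise ValueError("n_networks and swaps_per_edge must be positive")


def distance_matrix(net: BinaryNetwork) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf if unreachable)."""
    sparse = csr_matrix(net.adjacency)
    return shortest_path(sparse, method="D", unweighted=True, directed=False)


def clustering_coefficient(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering (triangle density among neighbours) and its mean.

    Nodes with degree < 2 have clustering 0. Returns ``(per_node, mean)``.
    """
    a = net.adjacency.astype(float)
    triangles = np.diag(a @ a @ a)  # 2 * triangle count per node
    k = net.degrees.astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_node = np.where(denom > 0, triangles / denom, 0.0)
    return per_node, float(per_node.mean())


def characteristic_path_length(net: BinaryNetwork) -> float:
    """Mean shortest-path length over mutually reachable node pairs."""
    d = distance_matrix(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("graph has no connected node pair")
    return float(d[finite].mean())


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean inverse shortest-path length over distinct pairs (1/inf = 0)."""
    d = distance_matrix(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def _subgraph_efficiency(adj: np.ndarray) -> float:
    m = adj.shape[0]
    if m < 2:
        return 0.0
    d = shortest_path(
        csr_matrix(adj), method="D", unweighted=True, directed=False
    )
    off = ~np.eye(m, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def local_efficiency(net: BinaryNetwork) -> float:
    """Mean, over nodes, of the efficiency of each node's neighbourhood."""
    a = net.adjacency
    vals = []
    for i in range(net.n_nodes):
        nbrs = np.flatnonzero(a[i])
        if len(nbrs) < 2:
            vals.append(0.0)
        else:
            vals.append(_subgraph_efficiency(a[np.ix_(nbrs, nbrs)]))
    return float(np.mean(vals))


def nodal_efficiency(net: BinaryNetwork) -> np.ndarray:
    """Per-node mean inverse distance to every other node."""
    d = distance_matrix(net)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (net.n_nodes - 1)


def betweenness(net: BinaryNetwork) -> np.ndarray:
    """Unnormalised betweenness centrality (Brandes), endpoints excluded.

    Each unordered source-target pair contributes once, so the maximum
    attainable value is (N-1)(N-2)/2 (a star's centre).
    """
    g = nx.from_numpy_array(net.adjacency)
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(net.n_nodes)])


def _is_connected(adj_sets: list[set[int]], n: int) -> bool:
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj_sets[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == n


def random_reference(
    net: BinaryNetwork,
    spec: RandomEnsembleSpec | None = None,
    *,
    seed=None,
) -> BinaryNetwork:
    """One degree-preserving Maslov–Sneppen rewiring of ``net``.

    Performs ``swaps_per_edge * E`` successful double-edge swaps
    (edges (a,b),(c,d) -> (a,d),(c,b)). The degree sequence is preserved
    exactly. If the input is connected, connectivity is preserved: swaps
    are applied in windows and any window that disconnects the graph is
    rolled back and retried swap-by-swap. If no valid swap can be found in
    100*E consecutive attempts the current state is returned with a warning.
    """
    spec = spec or RandomEnsembleSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = net.n_nodes
    edges = sorted(net.edge_set())
    e = len(edges)
    if e < 2:
        raise ValueError("need at least two edges to rewire")
    adj = [set(np.flatnonzero(net.adjacency[i]).tolist()) for i in range(n)]
    must_stay_connected = _is_connected(adj, n)

    target = spec.swaps_per_edge * e
    max_attempts = 100 * e
    done = 0
    attempts_since_success = 0
    window: list[tuple[int, int, int, int]] = []
    window_size = 32

    def apply_swap(a, b, c, d):
        adj[a].discard(b), adj[b].discard(a)
        adj[c].discard(d), adj[d].discard(c)
        adj[a].add(d), adj[d].add(a)
        adj[c].add(b), adj[b].add(c)

    def undo_swap(a, b, c, d):
        apply_swap(a, d, c, b)  # inverse: (a,d),(c,b) -> (a,b),(c,d)

    while done < target:
        if attempts_since_success >= max_attempts:
            warnings.warn(
                f"edge rewiring stalled after {done}/{target} swaps; "
                "returning current state",
                UserWarning,
                stacklevel=2,
            )
            break
        i, j = rng.integers(0, e, size=2)
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4 or d in adj[a] or b in adj[c]:
            attempts_since_success += 1
            continue
        apply_swap(a, b, c, d)
        edges[i], edges[j] = (min(a, d), max(a, d)), (min(c, b), max(c, b))
        window.append((a, b, c, d))
        done += 1
        attempts_since_success = 0
        if must_stay_connected and (len(window) >= window_size or done >= target):
            if _is_connected(adj, n):
                window.clear()
            else:
                # roll back the window, then redo it with per-swap checks
                for a2, b2, c2, d2 in reversed(window):
                    undo_swap(a2, b2, c2, d2)
                done -= len(window)
                edges = sorted(
                    (u, v) for u in range(n) for v in adj[u] if u < v
                )
                window.clear()
                window_size = max(1, window_size // 2)

    out = np.zeros((n, n), dtype=np.int8)
    for u in range(n):
        for v in adj[u]:
            out[u, v] = 1
    result = BinaryNetwork(
        adjacency=out, sparsity=net.sparsity, roi_labels=list(net.roi_labels)
    )
    assert sorted(result.degrees) == sorted(net.degrees)
    return result


def _ensemble(net: BinaryNetwork, spec: RandomEnsembleSpec):
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_networks)
    for s in seeds:
        yield random_reference(net, spec, seed=s)


def normalized_metrics(
    net: BinaryNetwork, spec: RandomEnsembleSpec | None = None
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against a degree-matched rewired ensemble.

    gamma = Cp / <Cp_rand>, lambda = Lp / <Lp_rand>, sigma = gamma/lambda.
    Warns when the largest connected component covers < 90% of nodes, where
    Lp (finite-pairs average) is least representative.
    """
    spec = spec or RandomEnsembleSpec()
    n_comp, labels = connected_components(
        csr_matrix(net.adjacency), directed=False
    )
    if np.bincount(labels).max() < 0.9 * net.n_nodes:
        warnings.warn(
            "largest connected component covers <90% of nodes; normalized "
            "metrics may be unstable",
            UserWarning,
            stacklevel=2,
        )
    _, cp = clustering_coefficient(net)
    lp = characteristic_path_length(net)
    cps, lps = [], []
    for rand in _ensemble(net, spec):
        cps.append(clustering_coefficient(rand)[1])
        lps.append(characteristic_path_length(rand))
    mean_cp, mean_lp = float(np.mean(cps)), float(np.mean(lps))
    if mean_cp == 0 or mean_lp == 0:
        raise ValueError("random ensemble has zero mean Cp or Lp")
    gamma = cp / mean_cp
    lam = lp / mean_lp
    return gamma, lam, gamma / lam


def small_world_sigma(
    net: BinaryNetwork, spec: RandomEnsembleSpec | None = None
) -> float:
    return normalized_metrics(net, spec)[2]


def global_metrics(
    net: BinaryNetwork, spec: RandomEnsembleSpec | None = None
) -> GlobalMetrics:
    """All seven global metrics of one network."""
    _, cp = clustering_coefficient(net)
    gamma, lam, sigma = normalized_metrics(net, spec)
    return GlobalMetrics(
        cp=cp,
        lp=characteristic_path_length(net),
        gamma=gamma,
        lambda_=lam,
        sigma=sigma,
        eglob=global_efficiency(net),
        eloc=local_efficiency(net),
    )


def nodal_metrics(net: BinaryNetwork) -> NodalMetrics:
    """Degree, nodal efficiency and betweenness of every node."""
    return NodalMetrics(
        degree=net.degrees,
        efficiency=nodal_efficiency(net),
        betweenness=betweenness(net),
    )
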