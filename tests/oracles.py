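"""Brute-force reference implementations for graph metrics.

Deliberately naive (triangle enumeration, Floyd-Warshall, shortest-path
counting by dynamic programming) and independent of the package's
implementation choices; used to validate the fast paths on small graphs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def oracle_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by Floyd-Warshall."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_clustering(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering by explicit triangle enumeration."""
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in combinations(nbrs, 2) if adj[a, b]
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out, float(out.mean())


def oracle_lp(adj: np.ndarray) -> float:
    d = oracle_distances(adj)
    vals = [
        d[i, j]
        for i in range(len(adj))
        for j in range(len(adj))
        if i != j and np.isfinite(d[i, j])
    ]
    if not vals:
        raise ValueError("no reachable pair")
    return float(np.mean(vals))


def oracle_global_efficiency(adj: np.ndarray) -> float:
    d = oracle_distances(adj)
    n = len(adj)
    vals = [
        1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    return float(np.mean(vals))


def oracle_local_efficiency(adj: np.ndarray) -> float:
    n = len(adj)
    vals = []
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        if len(nbrs) < 2:
            vals.append(0.0)
        else:
            vals.append(oracle_global_efficiency(adj[np.ix_(nbrs, nbrs)]))
    return float(np.mean(vals))


def oracle_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    d = oracle_distances(adj)
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        out[i] = np.mean(
            [
                1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
                for j in range(n)
                if j != i
            ]
        )
    return out


def _path_counts(adj: np.ndarray, d: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of distinct shortest s-t paths."""
    n = len(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(d[s])
        for t in order:
            if t == s or not np.isfinite(d[s, t]):
                continue
            preds = [
                u
                for u in np.flatnonzero(adj[:, t])
                if d[s, u] == d[s, t] - 1
            ]
            sigma[s, t] = sum(sigma[s, u] for u in preds)
    return sigma


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness by explicit shortest-path counting (unordered pairs)."""
    n = len(adj)
    d = oracle_distances(adj)
    sigma = _path_counts(adj, d)
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if (
                np.isfinite(d[s, v])
                and np.isfinite(d[v, t])
                and d[s, v] + d[v, t] == d[s, t]
            ):
                bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc
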