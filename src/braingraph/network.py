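"""Functional-network construction.

A subject's connectivity matrix is the absolute Pearson correlation between
every pair of ROI residual time courses. Binary networks are obtained by
sparsity thresholding: at sparsity ``s`` the ``round(s * N(N-1)/2)``
strongest connections become edges, so every subject's network has the same
edge count and group comparisons are not confounded by overall connectivity
strength. Analyses run over a grid of sparsities (default 0.05–0.36 in
steps of 0.01) rather than a single arbitrary threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "SparsityGrid",
    "connectivity",
    "binarize_at_sparsity",
    "threshold_series",
    "determine_sparsity_range",
]

DEFAULT_GRID = (0.05, 0.36, 0.01)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric absolute-correlation matrix with zero diagonal."""

    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("entries must be absolute correlations in [0,1]")
        if self.roi_labels and len(self.roi_labels) != v.shape[0]:
            raise ValueError("label count mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected, unweighted network at a fixed sparsity."""

    adjacency: np.ndarray
    sparsity: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        a = (a != 0).astype(np.int8)
        object.__setattr__(self, "adjacency", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not (0 < self.sparsity < 1):
            raise ValueError("sparsity must lie in (0,1)")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def edge_set(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return set(zip(i.tolist(), j.tolist()))


@dataclass(frozen=True)
class SparsityGrid:
    """Uniform grid of sparsity values ``s_min, s_min+step, ..., s_max``."""

    s_min: float = DEFAULT_GRID[0]
    s_max: float = DEFAULT_GRID[1]
    step: float = DEFAULT_GRID[2]

    def __post_init__(self):
        if not (0 < self.s_min < self.s_max < 1):
            raise ValueError("require 0 < s_min < s_max < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.step)) + 1
        return np.round(self.s_min + self.step * np.arange(n), 10)

    def __len__(self) -> int:
        return len(self.values)


def connectivity(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Absolute Pearson correlation between all ROI pairs (diagonal zeroed)."""
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError("need at least three time points for correlation")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.roi_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for ROI(s): {', '.join(bad)}")
    corr = np.abs(np.corrcoef(x, rowvar=False))
    corr = np.clip(corr, 0.0, 1.0)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 0.0)
    return ConnectivityMatrix(values=corr, roi_labels=list(ts.roi_labels))


def edge_count_at(s: float, n_nodes: int, mode: str = "round") -> int:
    """Number of edges retained at sparsity ``s`` on ``n_nodes`` nodes."""
    e_max = n_nodes * (n_nodes - 1) // 2
    raw = s * e_max
    if mode == "round":
        # half-up, not banker's rounding: round(0.10 * 4005) must be 401
        return int(math.floor(raw + 0.5))
    if mode == "floor":
        return int(math.floor(raw))
    if mode == "ceil":
        return int(math.ceil(raw))
    raise ValueError(f"unknown rounding mode {mode!r}")


def _ranked_edges(conn: ConnectivityMatrix) -> np.ndarray:
    """Upper-triangle edges sorted by descending weight.

    Ties are broken by (row, column) lexicographic order so that
    thresholding is deterministic and nested across sparsities.
    """
    n = conn.n_nodes
    iu, ju = np.triu_indices(n, 1)
    w = conn.values[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return np.column_stack([iu[order], ju[order]])


def binarize_at_sparsity(
    conn: ConnectivityMatrix, s: float, *, rounding: str = "round"
) -> BinaryNetwork:
    """Keep the strongest connections so that edge density equals ``s``."""
    if not (0 < s < 1):
        raise ValueError("sparsity must lie in (0,1)")
    n = conn.n_nodes
    n_edges = edge_count_at(s, n, rounding)
    if n_edges == 0:
        raise ValueError(
            f"sparsity {s} yields zero edges on {n} nodes; increase s"
        )
    ranked = _ranked_edges(conn)[:n_edges]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ranked[:, 0], ranked[:, 1]] = 1
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, sparsity=s, roi_labels=list(conn.roi_labels))


def threshold_series(
    conn: ConnectivityMatrix,
    grid: SparsityGrid | None = None,
    *,
    rounding: str = "round",
) -> list[BinaryNetwork]:
    """Binarize at every grid sparsity; edge sets are nested along the grid."""
    grid = grid or SparsityGrid()
    n = conn.n_nodes
    ranked = _ranked_edges(conn)
    networks = []
    adj = np.zeros((n, n), dtype=np.int8)
    placed = 0
    for s in grid.values:
        n_edges = edge_count_at(float(s), n, rounding)
        if n_edges == 0:
            raise ValueError(f"sparsity {s} yields zero edges")
        while placed < n_edges:
            i, j = ranked[placed]
            adj[i, j] = adj[j, i] = 1
            placed += 1
        networks.append(
            BinaryNetwork(
                adjacency=adj.copy(),
                sparsity=float(s),
                roi_labels=list(conn.roi_labels),
            )
        )
    return networks


def determine_sparsity_range(
    cohort_connectivity: list[ConnectivityMatrix],
    *,
    step: float = 0.01,
    sigma_floor: float = 1.1,
    degree_criterion: bool = True,
    sigma_criterion: bool = True,
    log_base: float | None = None,
    search_window: tuple[float, float] = (0.01, 0.50),
    ensemble=None,
    rng_seed: int = 0,
) -> SparsityGrid:
    """Data-driven sparsity range for a cohort.

    Returns the maximal contiguous grid (within ``search_window``, spacing
    ``step``) on which, for every subject, (a) mean degree ``2E/N`` exceeds
    ``log(N)`` (natural log by default; pass ``log_base`` to change) and
    (b) small-worldness sigma exceeds ``sigma_floor``, sigma being computed
    against a degree-preserving random ensemble. Either criterion can be
    disabled. Raises with per-criterion diagnostics if no sparsity passes.
    """
    from .metrics import RandomEnsembleSpec, small_world_sigma

    if not cohort_connectivity:
        raise ValueError("cohort is empty")
    if ensemble is None:
        ensemble = RandomEnsembleSpec(n_networks=10, seed=rng_seed)
    n = cohort_connectivity[0].n_nodes
    log_n = math.log(n) if log_base is None else math.log(n, log_base)
    lo = math.ceil(search_window[0] / step) * step
    candidates = np.round(np.arange(lo, search_window[1] + 1e-9, step), 10)

    ok = []
    diagnostics = {}
    for s in candidates:
        s = float(s)
        e = edge_count_at(s, n)
        if e == 0:
            diagnostics[s] = "zero edges"
            ok.append(False)
            continue
        if degree_criterion and 2 * e / n <= log_n:
            diagnostics[s] = (
                f"mean degree {2 * e / n:.3f} <= log(N) = {log_n:.3f}"
            )
            ok.append(False)
            continue
        if sigma_criterion:
            failed = None
            for idx, conn in enumerate(cohort_connectivity):
                net = binarize_at_sparsity(conn, s)
                sigma = small_world_sigma(net, ensemble)
                if sigma <= sigma_floor:
                    failed = f"subject {idx}: sigma {sigma:.3f} <= {sigma_floor}"
                    break
            if failed:
                diagnostics[s] = failed
                ok.append(False)
                continue
        ok.append(True)

    ok = np.asarray(ok)
    if not ok.any():
        lines = "\n".join(f"  s={s:.2f}: {msg}" for s, msg in diagnostics.items())
        raise ValueError(f"no sparsity satisfies the criteria:\n{lines}")
    # longest contiguous run of passing sparsities
    best_start = best_len = cur_start = cur_len = 0
    for k, flag in enumerate(ok):
        if flag:
            if cur_len == 0:
                cur_start = k
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0
    lo_s = float(candidates[best_start])
    hi_s = float(candidates[best_start + best_len - 1])
    if best_len == 1:
        raise ValueError(
            f"only a single sparsity ({lo_s:.2f}) satisfies the criteria; "
            "cannot form a grid"
        )
    return SparsityGrid(s_min=lo_s, s_max=hi_s, step=step)
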