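"""AUC integration of metric-vs-sparsity curves and hub identification.

Rather than reporting a metric at one arbitrary sparsity, each metric curve
Y(s) is summarised by its area under the curve over the grid,
``sum_k Y(k * ds) * ds`` (rectangle rule over the grid points, matching the
plain-summation definition of the integrated network parameter; a trapezoid
rule is available as an option).

Hubs are nodes whose normalised betweenness centrality Bi exceeds a
criterion multiple (default 1.5) of the network average: each subject's
integrated nodal betweenness is divided by that subject's across-node mean,
and Bi is the group average of these within-subject ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import SparsityGrid

__all__ = [
    "MetricCurve",
    "HubTable",
    "integrate_curve",
    "integrate_values",
    "integrate_nodal",
    "normalized_betweenness",
    "identify_hubs",
    "hub_table",
]

HUB_THRESHOLD = 1.5


@dataclass(frozen=True)
class MetricCurve:
    """One metric sampled along the sparsity grid."""

    grid: SparsityGrid
    values: np.ndarray
    metric_name: str = ""
    subject_id: str = ""
    node_index: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(v) != len(self.grid):
            raise ValueError(
                f"{len(v)} values for a grid of {len(self.grid)} points"
            )


def integrate_values(
    values: np.ndarray, step: float, *, rule: str = "rectangle"
) -> float:
    """AUC of samples spaced ``step`` apart (rectangle or trapezoid rule)."""
    values = np.asarray(values, dtype=float)
    if rule == "rectangle":
        return float(values.sum() * step)
    if rule == "trapezoid":
        return float(np.trapezoid(values, dx=step))
    raise ValueError(f"unknown integration rule {rule!r}")


def integrate_curve(curve: MetricCurve, *, rule: str = "rectangle") -> float:
    """Integrated (AUC) value of one metric curve."""
    return integrate_values(curve.values, curve.grid.step, rule=rule)


def integrate_nodal(
    curves: np.ndarray | list[MetricCurve],
    step: float | None = None,
    *,
    rule: str = "rectangle",
) -> np.ndarray:
    """Integrate one curve per node.

    Accepts either a list of :class:`MetricCurve` (all on one grid) or an
    (n_grid, n_nodes) array together with ``step``.
    """
    if isinstance(curves, (list, tuple)):
        if not curves:
            raise ValueError("no curves supplied")
        grids = {(c.grid.s_min, c.grid.s_max, c.grid.step) for c in curves}
        if len(grids) > 1:
            raise ValueError("all nodal curves must share the grid")
        step = curves[0].grid.step
        stacked = np.column_stack([c.values for c in curves])
    else:
        if step is None:
            raise ValueError("step is required for array input")
        stacked = np.asarray(curves, dtype=float)
    return np.array(
        [integrate_values(stacked[:, j], step, rule=rule)
         for j in range(stacked.shape[1])]
    )


def normalized_betweenness(
    group_betweenness: list[np.ndarray] | np.ndarray,
    *,
    order: str = "normalize_then_average",
) -> np.ndarray:
    """Group-level normalised betweenness Bi per node.

    Each subject's integrated betweenness vector is divided by its own
    across-node mean (so every subject contributes on the same scale), and
    Bi is the mean of these ratios across subjects. The alternative order
    (average raw vectors across subjects, then normalise by the grand mean)
    is available for sensitivity analysis via ``order="average_then_normalize"``.
    """
    stack = np.asarray(group_betweenness, dtype=float)
    if stack.ndim == 1:
        stack = stack[None, :]
    if stack.size == 0:
        raise ValueError("empty group")
    subject_means = stack.mean(axis=1)
    if np.any(subject_means == 0):
        bad = int(np.flatnonzero(subject_means == 0)[0])
        raise ValueError(
            f"subject {bad} has all-zero betweenness; cannot normalise"
        )
    if order == "normalize_then_average":
        return (stack / subject_means[:, None]).mean(axis=0)
    if order == "average_then_normalize":
        grand = stack.mean(axis=0)
        return grand / grand.mean()
    raise ValueError(f"unknown order {order!r}")


def identify_hubs(bi: np.ndarray, threshold: float = HUB_THRESHOLD) -> list[int]:
    """Indices of hub nodes: Bi strictly greater than ``threshold``."""
    bi = np.asarray(bi, dtype=float)
    if not np.all(np.isfinite(bi)):
        raise ValueError("Bi contains non-finite values")
    return np.flatnonzero(bi > threshold).tolist()


@dataclass(frozen=True)
class HubTable:
    """Normalised betweenness and hub flags for one group."""

    normalized_betweenness: np.ndarray
    threshold: float
    roi_labels: list[str] = field(default_factory=list)

    @property
    def hub_flags(self) -> np.ndarray:
        return self.normalized_betweenness > self.threshold

    @property
    def hub_indices(self) -> list[int]:
        return np.flatnonzero(self.hub_flags).tolist()

    @property
    def hub_labels(self) -> list[str]:
        if not self.roi_labels:
            return [str(i) for i in self.hub_indices]
        return [self.roi_labels[i] for i in self.hub_indices]

    def to_frame(self) -> pd.DataFrame:
        n = len(self.normalized_betweenness)
        labels = self.roi_labels or [str(i) for i in range(n)]
        return pd.DataFrame(
            {
                "region": labels,
                "bi": self.normalized_betweenness,
                "is_hub": self.hub_flags,
            }
        )


def hub_table(
    group_betweenness,
    threshold: float = HUB_THRESHOLD,
    roi_labels: list[str] | None = None,
    **kwargs,
) -> HubTable:
    """Build a :class:`HubTable` from per-subject integrated betweenness."""
    bi = normalized_betweenness(group_betweenness, **kwargs)
    return HubTable(
        normalized_betweenness=bi,
        threshold=threshold,
        roi_labels=roi_labels or [],
    )
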