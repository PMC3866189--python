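"""Group inference for integrated network metrics and edge-wise connectivity.

Provides the statistical toolkit of a two-group network study:

* nonparametric permutation tests on integrated metrics (labels shuffled,
  difference of group means recomputed, two-tailed p with the +1
  finite-sample correction so p is never exactly 0);
* Cohen's d effect sizes with the (n-1)-weighted pooled SD, computable
  from raw values or from printed (mean, sd, n) summaries;
* the network-based statistic (NBS): edge-wise two-sample t statistics,
  a primary cluster-defining threshold, connected-component extraction,
  and a permutation null of the maximal component size (in edges) giving
  family-wise-error-corrected component p-values;
* multiple linear regression of a metric on duration of use with age as a
  covariate (slope, partial correlation, two-tailed p);
* the demographic-table tests (pooled two-sample t, Fisher's exact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "PermutationResult",
    "EffectSize",
    "NBSResult",
    "RegressionResult",
    "permutation_test",
    "cohens_d",
    "edgewise_tstats",
    "nbs",
    "duration_association",
    "fisher_exact_2x2",
    "two_sample_t",
]


# --------------------------------------------------------------------------
# permutation test on a scalar metric


@dataclass(frozen=True)
class PermutationResult:
    """Two-tailed label-permutation test on a group mean difference."""

    observed_diff: float
    null_distribution: np.ndarray
    n_perm: int

    @property
    def p_two_tailed(self) -> float:
        exceed = int(
            np.sum(np.abs(self.null_distribution) >= abs(self.observed_diff))
        )
        return (exceed + 1) / (self.n_perm + 1)


def permutation_test(
    case_values,
    control_values,
    n_perm: int = 10_000,
    seed=None,
) -> PermutationResult:
    """Permutation test of the case-minus-control mean difference.

    Group labels are reallocated uniformly at random ``n_perm`` times
    (shuffling without replacement) and the mean difference recomputed,
    giving an empirical two-tailed null distribution.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("both groups need at least two values")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is very small; p-value resolution is "
            f"{1 / (n_perm + 1):.3f}",
            UserWarning,
            stacklevel=2,
        )
    pooled = np.concatenate([case, control])
    n_case = len(case)
    observed = float(case.mean() - control.mean())
    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.broadcast_to(pooled, (n_perm, len(pooled))).copy(), axis=1
    )
    null = perms[:, :n_case].mean(axis=1) - perms[:, n_case:].mean(axis=1)
    return PermutationResult(
        observed_diff=observed, null_distribution=null, n_perm=n_perm
    )


# --------------------------------------------------------------------------
# effect size


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d (pooled-SD standardised mean difference)."""

    d: float

    @property
    def magnitude_label(self) -> str:
        a = abs(self.d)
        if a >= 0.8:
            return "large"
        if a >= 0.5:
            return "medium"
        if a >= 0.2:
            return "small"
        return "negligible"


def _summaries(values_or_summary) -> tuple[float, float, int]:
    """(mean, sd, n) from raw values or an already-summarised triple."""
    if isinstance(values_or_summary, tuple) and len(values_or_summary) == 3:
        mean, sd, n = values_or_summary
        return float(mean), float(sd), int(n)
    x = np.asarray(values_or_summary, dtype=float)
    return float(x.mean()), float(x.std(ddof=1)), len(x)


def cohens_d(case, control) -> EffectSize:
    """|mean difference| / pooled SD, with (n-1)-weighted pooled variance.

    Accepts raw value arrays or ``(mean, sd, n)`` summary triples, so the
    printed group summaries of a results table can be fed in directly.
    """
    m1, s1, n1 = _summaries(case)
    m2, s2, n2 = _summaries(control)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    pooled_var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD; Cohen's d undefined")
    return EffectSize(d=abs(m1 - m2) / float(np.sqrt(pooled_var)))


# --------------------------------------------------------------------------
# classic two-group tests (demographics table)


def two_sample_t(a, b) -> tuple[float, float]:
    """Pooled-variance two-sample t test; returns ``(t, p_two_tailed)``.

    Accepts raw values or ``(mean, sd, n)`` summaries for either group.
    """
    m1, s1, n1 = _summaries(a)
    m2, s2, n2 = _summaries(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    t = (m1 - m2) / np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher's exact test p-value for a 2x2 count table.

    Two-sided by the standard convention: sum of hypergeometric
    probabilities of all tables no more likely than the observed one.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("both margins must be positive")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return float(p)


# --------------------------------------------------------------------------
# network-based statistic


def _stack_to_edges(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_subjects, n_edges) view of a stack of symmetric matrices."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("stack must be (n_subjects, N, N)")
    n = stack.shape[1]
    iu, ju = np.triu_indices(n, 1)
    return stack[:, iu, ju], iu, ju


def _edge_t(x: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column of ``x``.

    ``member`` is a boolean matrix (n_perm, n_subjects); one t vector per row.
    """
    b = member.astype(float)
    n1 = b.sum(axis=1, keepdims=True)
    n2 = b.shape[1] - n1
    df = b.shape[1] - 2
    x2 = x * x
    sum_t = x.sum(axis=0)
    sq_t = x2.sum(axis=0)
    sum1 = b @ x
    sq1 = b @ x2
    sum2 = sum_t - sum1
    diff = sum1 / n1
    diff -= sum2 / n2
    # pooled within-group sum of squares: total SS minus group-mean terms
    ss = sum1 * sum1
    ss /= n1
    ss += sum2 * sum2 / n2
    ss *= -1.0
    ss += sq_t
    denom = ss
    denom *= (1 / n1 + 1 / n2) / df
    np.sqrt(np.maximum(denom, 0.0, out=denom), out=denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    return t


def edgewise_tstats(case_stack, control_stack) -> np.ndarray:
    """Symmetric matrix of two-sample t statistics, one per edge."""
    case = np.asarray(case_stack, dtype=float)
    control = np.asarray(control_stack, dtype=float)
    if case.shape[0] < 2 or control.shape[0] < 2:
        raise ValueError("both groups need at least two subjects")
    if case.shape[1:] != control.shape[1:]:
        raise ValueError("matrix sizes differ between groups")
    x_case, iu, ju = _stack_to_edges(case)
    x_ctrl, _, _ = _stack_to_edges(control)
    x = np.vstack([x_case, x_ctrl])
    member = np.zeros((1, x.shape[0]), dtype=bool)
    member[0, : case.shape[0]] = True
    t = _edge_t(x, member)[0]
    n = case.shape[1]
    out = np.zeros((n, n))
    out[iu, ju] = t
    out += out.T
    return out


def _max_component_size(
    edge_mask: np.ndarray, iu: np.ndarray, ju: np.ndarray, n_nodes: int
) -> int:
    """Largest connected-component size (edge count) of a masked edge set."""
    idx = np.flatnonzero(edge_mask)
    if len(idx) == 0:
        return 0
    rows, cols = iu[idx], ju[idx]
    adj = csr_matrix(
        (np.ones(len(idx)), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    _, labels = connected_components(adj, directed=False)
    # component size = number of suprathreshold edges within each label
    return int(np.bincount(labels[rows]).max())


@dataclass(frozen=True)
class NBSComponent:
    """One suprathreshold connected component."""

    edges: list[tuple[int, int]]
    size: int  # edge count
    corrected_p: float

    @property
    def nodes(self) -> list[int]:
        return sorted({v for e in self.edges for v in e})


@dataclass(frozen=True)
class NBSResult:
    """Network-based-statistic inference output."""

    primary_threshold: float  # edge-level p threshold
    t_critical: float
    suprathreshold_edges: list[tuple[int, int]]
    components: list[NBSComponent] = field(default_factory=list)
    max_size_null: np.ndarray = field(default_factory=lambda: np.array([]))
    n_perm: int = 0

    def significant_components(self, alpha: float = 0.05) -> list[NBSComponent]:
        return [c for c in self.components if c.corrected_p < alpha]

    def min_corrected_p(self) -> float:
        return min((c.corrected_p for c in self.components), default=1.0)


def nbs(
    case_stack,
    control_stack,
    primary_p: float = 0.001,
    n_perm: int = 10_000,
    seed=None,
) -> NBSResult:
    """Network-based statistic on two stacks of connectivity matrices.

    Edges whose two-sample |t| exceeds the two-tailed critical value for
    ``primary_p`` form the suprathreshold graph; its connected components
    are scored by edge count. The null distribution of the maximal
    component size is built by relabelling subjects ``n_perm`` times, and
    each component's corrected p is
    ``(1 + #{null >= size}) / (n_perm + 1)``.

    An empty suprathreshold graph yields an empty (non-significant) result.
    """
    case = np.asarray(case_stack, dtype=float)
    control = np.asarray(control_stack, dtype=float)
    if case.shape[0] < 2 or control.shape[0] < 2:
        raise ValueError("both groups need at least two subjects")
    x_case, iu, ju = _stack_to_edges(case)
    x_ctrl, _, _ = _stack_to_edges(control)
    x = np.vstack([x_case, x_ctrl])
    n_case, n_total = case.shape[0], x.shape[0]
    n_nodes = case.shape[1]
    df = n_total - 2
    if primary_p >= 1.0:
        t_crit = 0.0
    else:
        t_crit = float(sps.t.isf(primary_p / 2, df))

    member_obs = np.zeros((1, n_total), dtype=bool)
    member_obs[0, :n_case] = True
    t_obs = _edge_t(x, member_obs)[0]
    supra = np.abs(t_obs) >= t_crit if primary_p >= 1.0 else np.abs(t_obs) > t_crit

    idx = np.flatnonzero(supra)
    supra_edges = [(int(iu[k]), int(ju[k])) for k in idx]
    if len(idx) == 0:
        return NBSResult(
            primary_threshold=primary_p,
            t_critical=t_crit,
            suprathreshold_edges=[],
            components=[],
            max_size_null=np.zeros(0, dtype=int),
            n_perm=n_perm,
        )

    # observed components
    rows, cols = iu[idx], ju[idx]
    adj = csr_matrix(
        (np.ones(len(idx)), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    _, labels = connected_components(adj, directed=False)
    comp_of_edge = labels[rows]
    comp_ids, comp_sizes = np.unique(comp_of_edge, return_counts=True)

    # permutation null of the maximal component size
    rng = np.random.default_rng(seed)
    member = np.zeros((n_perm, n_total), dtype=bool)
    for r in range(n_perm):
        member[r, rng.choice(n_total, size=n_case, replace=False)] = True
    t_null = _edge_t(x, member)
    null_sizes = np.empty(n_perm, dtype=int)
    for r in range(n_perm):
        mask = (
            np.abs(t_null[r]) >= t_crit
            if primary_p >= 1.0
            else np.abs(t_null[r]) > t_crit
        )
        null_sizes[r] = _max_component_size(mask, iu, ju, n_nodes)

    components = []
    for cid, size in zip(comp_ids, comp_sizes):
        edges = [
            (int(r), int(c))
            for r, c, l in zip(rows, cols, comp_of_edge)
            if l == cid
        ]
        p_corr = (int(np.sum(null_sizes >= size)) + 1) / (n_perm + 1)
        components.append(
            NBSComponent(edges=edges, size=int(size), corrected_p=p_corr)
        )
    components.sort(key=lambda c: -c.size)
    return NBSResult(
        primary_threshold=primary_p,
        t_critical=t_crit,
        suprathreshold_edges=supra_edges,
        components=components,
        max_size_null=null_sizes,
        n_perm=n_perm,
    )


# --------------------------------------------------------------------------
# clinical association


@dataclass(frozen=True)
class RegressionResult:
    """Duration-of-use association, age-controlled."""

    slope: float
    partial_r: float
    p_two_tailed: float
    covariates: list[str] = field(default_factory=lambda: ["age"])


def duration_association(values, duration, age) -> RegressionResult:
    """OLS of a metric on duration of use plus age (case group only).

    Reports the duration slope, the partial correlation of the metric with
    duration given age (from the t statistic of the slope), and its
    two-tailed p.
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    dur = np.asarray(duration, dtype=float)
    a = np.asarray(age, dtype=float)
    n = len(y)
    if not (len(dur) == len(a) == n):
        raise ValueError("values, duration and age must have equal length")
    if n < 4:
        raise ValueError("need at least four subjects")
    r_da = np.corrcoef(dur, a)[0, 1]
    if abs(r_da) > 0.99:
        raise ValueError(
            f"duration and age are collinear (r = {r_da:.3f})"
        )
    design = sm.add_constant(np.column_stack([dur, a]))
    fit = sm.OLS(y, design).fit()
    t = fit.tvalues[1]
    df = fit.df_resid
    partial_r = float(t / np.sqrt(t**2 + df))
    return RegressionResult(
        slope=float(fit.params[1]),
        partial_r=partial_r,
        p_two_tailed=float(fit.pvalues[1]),
    )
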