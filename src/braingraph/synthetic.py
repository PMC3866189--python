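"""Synthetic resting-state cohort generator.

Emulates the second-order structure of preprocessed ROI time series: each
subject's series is drawn from a zero-mean multivariate normal whose
correlation matrix has a modular (block) community structure, the signature
feature of resting-state functional connectivity. Because every downstream
stage of the analysis consumes only correlations, the multivariate normal
is a sufficient generative model — no hemodynamic convolution or temporal
autocorrelation is simulated.

Case/control differences are implanted directly into the case-group
correlation matrix: an arbitrary list of edge-wise deltas, a connected
component of edges sharing one delta (the target the network-based statistic
must recover), and a per-subject scaling of one node's connectivity by a
clinical "duration of use" covariate (the target of the age-controlled
regression stage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import labels_for
from .preprocess import RoiTimeSeries

__all__ = [
    "CovarianceSpec",
    "CohortSpec",
    "SubjectRecord",
    "Subject",
    "build_covariance",
    "perturb_covariance",
    "nearest_positive_definite",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
]

Edge = tuple[int, int]

#: Ten edges forming one connected path inside the first module; the
#: default implanted group difference (reduced connectivity in cases).
DEFAULT_IMPLANT: tuple[Edge, ...] = tuple((i, i + 1) for i in range(10))
DEFAULT_IMPLANT_DELTA = -0.3

#: Node 36 is HIP.L in AAL-90 ordering; its within-module connectivity is
#: scaled by the duration-of-use covariate (slope in correlation units/year).
DEFAULT_DURATION_LINK = (36, 0.025)
DURATION_CENTER_YEARS = 10.0

NUISANCE_COLUMNS = [
    "motion_tx", "motion_ty", "motion_tz",
    "motion_rx", "motion_ry", "motion_rz",
    "white_matter", "csf", "global_mean",
]


@dataclass(frozen=True)
class CovarianceSpec:
    """Block-modular correlation structure for the ROI signals.

    ROIs are split into ``n_modules`` contiguous, near-equal communities;
    correlation is ``within_corr`` inside a community and ``between_corr``
    across communities. ``noise_var`` sets the marginal variance of each
    series (the correlation structure is unaffected).
    """

    n_rois: int = 90
    n_modules: int = 6
    within_corr: float = 0.45
    between_corr: float = 0.1
    noise_var: float = 1.0

    def __post_init__(self):
        if self.n_rois < 2 or self.n_modules < 1:
            raise ValueError("need n_rois >= 2 and n_modules >= 1")
        if self.n_modules > self.n_rois:
            raise ValueError("more modules than ROIs")
        if not (0 <= self.between_corr <= self.within_corr < 1):
            raise ValueError(
                "require 0 <= between_corr <= within_corr < 1"
            )
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")

    def module_assignment(self) -> np.ndarray:
        """Module index of each ROI (contiguous near-equal blocks)."""
        blocks = np.array_split(np.arange(self.n_rois), self.n_modules)
        return np.concatenate(
            [np.full(len(block), m) for m, block in enumerate(blocks)]
        )


@dataclass(frozen=True)
class SubjectRecord:
    """Demographic/clinical metadata for one synthetic subject."""

    subject_id: str
    group: str  # "case" or "control"
    age: float
    sex: str  # "F" or "M"
    education: float
    duration_of_use: float | None = None  # years; cases only
    dosage: float | None = None  # grams/day; cases only

    def __post_init__(self):
        if self.group not in ("case", "control"):
            raise ValueError("group must be 'case' or 'control'")
        if self.group == "case":
            if self.duration_of_use is None or self.duration_of_use <= 0:
                raise ValueError("case subjects need a positive duration_of_use")
        elif self.duration_of_use is not None:
            raise ValueError("controls must not carry a duration_of_use")


@dataclass(frozen=True)
class Subject:
    """One simulated subject: metadata, ROI series, nuisance table."""

    record: SubjectRecord
    timeseries: RoiTimeSeries
    nuisance: pd.DataFrame


@dataclass(frozen=True)
class CohortSpec:
    """Full study design for a simulated two-group cohort.

    Defaults mirror the emulated study: 17 cases vs 15 controls, 230
    retained volumes at TR = 2 s over 90 ROIs, a 10-edge connected
    component of correlation reductions (|delta| = 0.3) implanted in the
    case group, and a positive link between duration of use and the
    connectivity of one hippocampus-like node.
    """

    covariance: CovarianceSpec = field(default_factory=CovarianceSpec)
    n_per_group: tuple[int, int] = (17, 15)  # (cases, controls)
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    group_effect: tuple[tuple[Edge, float], ...] = ()
    implanted_component: tuple[Edge, ...] = DEFAULT_IMPLANT
    implant_delta: float = DEFAULT_IMPLANT_DELTA
    duration_link: tuple[int, float] | None = DEFAULT_DURATION_LINK
    nuisance_leakage: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_group) < 1:
            raise ValueError("both groups need at least one subject")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints too small")
        if self.implanted_component and not _is_connected_edge_set(
            self.implanted_component
        ):
            raise ValueError(
                "implanted_component edges must form a single connected component"
            )

    def case_deltas(self) -> list[tuple[Edge, float]]:
        """All edge deltas applied to the case group's correlation matrix."""
        deltas = [(e, self.implant_delta) for e in self.implanted_component]
        deltas.extend(self.group_effect)
        return deltas


def _is_connected_edge_set(edges) -> bool:
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(edges)
    return g.number_of_nodes() > 0 and nx.is_connected(g)


def build_covariance(spec: CovarianceSpec) -> np.ndarray:
    """Block-modular correlation matrix implied by ``spec``.

    Raises if the result is not positive definite (possible only for
    extreme between/within combinations given the invariants).
    """
    modules = spec.module_assignment()
    same = modules[:, None] == modules[None, :]
    corr = np.where(same, spec.within_corr, spec.between_corr)
    np.fill_diagonal(corr, 1.0)
    min_eig = float(np.linalg.eigvalsh(corr)[0])
    if min_eig <= 0:
        raise ValueError(
            f"covariance spec {spec} yields a non-positive-definite matrix "
            f"(smallest eigenvalue {min_eig:.3e}); reduce between_corr or "
            f"module imbalance"
        )
    return corr


def nearest_positive_definite(
    matrix: np.ndarray, min_eig: float = 1e-8
) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation-like PD matrix.

    Eigenvalues are clipped at ``min_eig`` and the diagonal is rescaled
    back to 1 (alternating projections, run to convergence).
    """
    a = 0.5 * (matrix + matrix.T)
    for _ in range(50):
        vals, vecs = np.linalg.eigh(a)
        if vals[0] >= min_eig and np.allclose(np.diag(a), 1.0, atol=1e-12):
            break
        vals = np.clip(vals, min_eig, None)
        a = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = 0.5 * (a + a.T)
    return a


def perturb_covariance(
    base: np.ndarray,
    deltas: list[tuple[Edge, float]],
    *,
    repair_tol: float = 1e-6,
) -> np.ndarray:
    """Add edge-wise deltas to a correlation matrix, repairing PD-ness.

    Only the listed entries (and their transposes) are changed; if the
    perturbed matrix loses positive definiteness it is projected back to
    the nearest PD correlation matrix and a warning reports the largest
    collateral change to non-target entries (should stay near ``repair_tol``).
    """
    out = np.array(base, dtype=float, copy=True)
    mask = np.zeros(out.shape, dtype=bool)
    for (i, j), delta in deltas:
        if i == j:
            raise ValueError("cannot perturb the diagonal")
        new = out[i, j] + delta
        if abs(new) >= 1.0:
            raise ValueError(
                f"delta {delta:+.3f} on edge ({i},{j}) pushes |r| to "
                f"{abs(new):.3f} >= 1"
            )
        out[i, j] = out[j, i] = new
        mask[i, j] = mask[j, i] = True
    if np.linalg.eigvalsh(out)[0] <= 0:
        repaired = nearest_positive_definite(out)
        collateral = float(np.abs((repaired - out)[~mask]).max())
        warnings.warn(
            f"perturbed matrix repaired to nearest positive definite; "
            f"largest collateral change {collateral:.2e}",
            UserWarning,
            stacklevel=2,
        )
        if collateral > 100 * repair_tol:
            warnings.warn(
                f"collateral change {collateral:.2e} exceeds tolerance "
                f"{repair_tol:.0e}; implanted effects may be distorted",
                UserWarning,
                stacklevel=2,
            )
        out = repaired
    return out


def _nuisance_table(rng: np.random.Generator, n_timepoints: int) -> pd.DataFrame:
    """Nine nuisance series: six smooth motion traces, three broadband."""
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(n_timepoints, 6)), axis=0)
    broadband = rng.normal(0.0, 1.0, size=(n_timepoints, 3))
    table = np.column_stack([motion, broadband])
    return pd.DataFrame(table, columns=NUISANCE_COLUMNS)


def simulate_subject(
    cov: np.ndarray,
    n_timepoints: int = 230,
    tr_seconds: float = 2.0,
    seed: int | np.random.SeedSequence | None = None,
    *,
    roi_labels: list[str] | None = None,
    noise_var: float = 1.0,
    nuisance_leakage: float = 0.0,
) -> tuple[RoiTimeSeries, pd.DataFrame]:
    """Draw one subject's ROI series from a multivariate normal.

    ``nuisance_leakage`` > 0 mixes the nuisance series into the signal
    (coefficient per covariate drawn once), to exercise the nuisance
    regression stage; by default signals and nuisance are independent.
    """
    cov = np.asarray(cov, dtype=float)
    n_rois = cov.shape[0]
    if n_timepoints < n_rois + 2:
        warnings.warn(
            f"n_timepoints={n_timepoints} < n_rois+2={n_rois + 2}: sample "
            "correlation matrices will be rank deficient",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov * noise_var)
    signal = rng.standard_normal((n_timepoints, n_rois)) @ chol.T
    nuisance = _nuisance_table(rng, n_timepoints)
    if nuisance_leakage > 0:
        weights = rng.normal(0.0, nuisance_leakage, size=(9, n_rois))
        signal = signal + nuisance.to_numpy() @ weights
    labels = roi_labels if roi_labels is not None else labels_for(n_rois)
    ts = RoiTimeSeries(values=signal, tr_seconds=tr_seconds, roi_labels=labels)
    return ts, nuisance


# Demographics of the emulated cohort: mean (SD) and observed range per
# group, plus the female fraction (2/17 cases, 3/15 controls).
_AGE = {"case": (36.3, 6.9, 26.0, 50.0), "control": (31.3, 8.1, 20.0, 46.0)}
_EDU = {"case": (10.2, 3.2, 2.0, 15.0), "control": (11.1, 4.1, 5.0, 17.0)}
_FEMALE_FRACTION = {"case": 2 / 17, "control": 3 / 15}
_DURATION_RANGE = (1.0, 19.0)
_DOSAGE_RANGE = (0.1, 2.0)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def _make_records(
    rng: np.random.Generator, group: str, n: int, start_index: int
) -> list[SubjectRecord]:
    age = _truncated_normal(rng, *_AGE[group], size=n)
    edu = _truncated_normal(rng, *_EDU[group], size=n)
    n_female = int(round(_FEMALE_FRACTION[group] * n))
    sexes = ["F"] * n_female + ["M"] * (n - n_female)
    if group == "case":
        duration = rng.uniform(*_DURATION_RANGE, size=n)
        dosage = rng.uniform(*_DOSAGE_RANGE, size=n)
    records = []
    for k in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"sub-{start_index + k:03d}",
                group=group,
                age=float(round(age[k], 1)),
                sex=sexes[k],
                education=float(round(edu[k], 1)),
                duration_of_use=(
                    float(round(duration[k], 1)) if group == "case" else None
                ),
                dosage=float(round(dosage[k], 2)) if group == "case" else None,
            )
        )
    return records


def _duration_deltas(
    spec: CohortSpec, duration: float
) -> list[tuple[Edge, float]]:
    """Edge deltas scaling the linked node's within-module connectivity."""
    if spec.duration_link is None:
        return []
    node, slope = spec.duration_link
    if slope == 0.0:
        return []
    modules = spec.covariance.module_assignment()
    peers = np.flatnonzero(modules == modules[node])
    shift = slope * (duration - DURATION_CENTER_YEARS)
    return [((node, int(p)), shift) for p in peers if p != node]


def simulate_cohort(spec: CohortSpec) -> list[Subject]:
    """Simulate the full two-group cohort described by ``spec``.

    Controls share the base modular correlation matrix; cases receive the
    implanted-component and group-effect deltas, plus a per-subject
    duration-of-use scaling of the linked node's connectivity. Fully
    deterministic given ``spec.seed``.
    """
    base = build_covariance(spec.covariance)
    case_cov = (
        perturb_covariance(base, spec.case_deltas())
        if spec.case_deltas()
        else base
    )
    master = np.random.SeedSequence(spec.seed)
    meta_rng = np.random.default_rng(master.spawn(1)[0])
    n_case, n_control = spec.n_per_group
    records = _make_records(meta_rng, "case", n_case, 1)
    records += _make_records(meta_rng, "control", n_control, n_case + 1)
    subject_seeds = master.spawn(len(records) + 1)[1:]

    labels = labels_for(spec.covariance.n_rois)
    cohort: list[Subject] = []
    for record, sseed in zip(records, subject_seeds):
        if record.group == "case":
            cov = case_cov
            extra = _duration_deltas(spec, record.duration_of_use)
            if extra:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    cov = perturb_covariance(case_cov, extra)
        else:
            cov = base
        ts, nuisance = simulate_subject(
            cov,
            n_timepoints=spec.n_timepoints,
            tr_seconds=spec.tr_seconds,
            seed=sseed,
            roi_labels=labels,
            noise_var=spec.covariance.noise_var,
            nuisance_leakage=spec.nuisance_leakage,
        )
        cohort.append(Subject(record=record, timeseries=ts, nuisance=nuisance))
    return cohort


def cohort_metadata(cohort: list[Subject]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.record.subject_id,
            "group": s.record.group,
            "age": s.record.age,
            "sex": s.record.sex,
            "education": s.record.education,
            "duration_of_use": s.record.duration_of_use,
            "dosage": s.record.dosage,
        }
        for s in cohort
    ]
    return pd.DataFrame(rows)


def write_cohort(cohort: list[Subject], outdir) -> None:
    """Write per-subject ROI/nuisance CSVs and the cohort metadata CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in cohort:
        ts = s.timeseries
        pd.DataFrame(ts.values, columns=ts.roi_labels).to_csv(
            outdir / f"{s.record.subject_id}_roi.csv", index=False
        )
        s.nuisance.to_csv(
            outdir / f"{s.record.subject_id}_nuisance.csv", index=False
        )
    cohort_metadata(cohort).to_csv(outdir / "cohort.csv", index=False)
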