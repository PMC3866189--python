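"""Study-level model objects tying the pipeline stages together.

:class:`BrainNetworkStudy` is built from a two-group cohort of ROI time
series (simulated or read from CSV files); :meth:`BrainNetworkStudy.fit`
runs preprocessing, network construction over the sparsity grid, graph
metrics, AUC integration, hub identification and the full group-inference
battery, returning a :class:`StudyResults` carrying every estimate with a
``summary()`` table and CSV/JSON export.

The shape follows the fit/results convention of statistical modelling
packages: the model object holds data and configuration, the results
object holds everything computed from them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .integration import HUB_THRESHOLD, hub_table, integrate_values, HubTable
from .metrics import (
    RandomEnsembleSpec,
    clustering_coefficient,
    characteristic_path_length,
    global_efficiency,
    local_efficiency,
    nodal_metrics,
    normalized_metrics,
)
from .network import (
    ConnectivityMatrix,
    SparsityGrid,
    connectivity,
    threshold_series,
)
from .preprocess import BandSpec, RoiTimeSeries, bandpass, regress_nuisance
from .stats import (
    NBSResult,
    cohens_d,
    duration_association,
    nbs,
    permutation_test,
)
from .synthetic import CohortSpec, Subject, simulate_cohort

__all__ = ["BrainNetworkStudy", "StudyResults", "RunConfig", "run_pipeline"]

GLOBAL_TESTED = ["cp", "lp", "sigma", "eglob", "eloc"]
NODAL_TESTED = ["degree", "efficiency"]


@dataclass
class RunConfig:
    """Everything that affects the numbers a study run produces."""

    band: tuple[float, float] | None = (0.01, 0.08)
    grid: tuple[float, float, float] = (0.05, 0.36, 0.01)
    auto_grid: bool = False
    ensemble_size: int = 100
    swaps_per_edge: int = 10
    hub_threshold: float = HUB_THRESHOLD
    integration_rule: str = "rectangle"
    n_perm: int = 10_000
    nbs_primary_p: float = 0.001
    regress_nuisance: bool = True
    include_global_signal: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band", "grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band) if self.band else None
        d["grid"] = list(self.grid)
        return d


class BrainNetworkStudy:
    """Two-group resting-state network study.

    Parameters
    ----------
    subjects : list of Subject
        Cohort members (metadata + ROI series + nuisance table).
    config : RunConfig, optional
        Analysis configuration; defaults mirror the standard protocol
        (0.01–0.08 Hz band, sparsity 0.05–0.36 step 0.01, ensemble of 100
        rewired references, hub criterion 1.5, 10,000 permutations).
    """

    def __init__(self, subjects: list[Subject], config: RunConfig | None = None):
        if not subjects:
            raise ValueError("empty cohort")
        groups = {s.record.group for s in subjects}
        if groups != {"case", "control"}:
            raise ValueError(
                f"cohort must contain both groups, found {sorted(groups)}"
            )
        self.subjects = list(subjects)
        self.config = config or RunConfig()
        self.roi_labels = subjects[0].timeseries.roi_labels

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_simulation(
        cls, spec: CohortSpec | None = None, config: RunConfig | None = None
    ) -> "BrainNetworkStudy":
        """Simulate a synthetic cohort and wrap it as a study."""
        spec = spec or CohortSpec()
        return cls(simulate_cohort(spec), config=config)

    @classmethod
    def from_directory(
        cls, path, config: RunConfig | None = None
    ) -> "BrainNetworkStudy":
        """Load a cohort written by :func:`braingraph.synthetic.write_cohort`."""
        from .io import read_cohort

        return cls(read_cohort(path), config=config)

    # -- pipeline stages ----------------------------------------------------

    def _preprocess(self, subject: Subject) -> RoiTimeSeries:
        ts = subject.timeseries
        cfg = self.config
        if cfg.regress_nuisance and subject.nuisance is not None:
            cov = subject.nuisance.to_numpy(dtype=float)
            if not cfg.include_global_signal and "global_mean" in subject.nuisance:
                cov = subject.nuisance.drop(columns=["global_mean"]).to_numpy(
                    dtype=float
                )
            ts = regress_nuisance(ts, cov)
        if cfg.band is not None:
            ts = bandpass(ts, BandSpec(*cfg.band))
        return ts

    def connectivity_matrices(self) -> list[ConnectivityMatrix]:
        """Per-subject absolute-Pearson connectivity after preprocessing."""
        return [connectivity(self._preprocess(s)) for s in self.subjects]

    def _grid(self, conns: list[ConnectivityMatrix]) -> SparsityGrid:
        cfg = self.config
        if cfg.auto_grid:
            from .network import determine_sparsity_range

            return determine_sparsity_range(
                conns,
                step=cfg.grid[2],
                ensemble=RandomEnsembleSpec(
                    n_networks=max(5, cfg.ensemble_size // 10),
                    swaps_per_edge=cfg.swaps_per_edge,
                    seed=cfg.seed,
                ),
            )
        return SparsityGrid(*cfg.grid)

    def fit(self, seed: int | None = None) -> "StudyResults":
        """Run the full analysis and return its results object."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng_root = np.random.SeedSequence(seed)
        ens_seed, perm_seed, nbs_seed = rng_root.spawn(3)

        conns = self.connectivity_matrices()
        grid = self._grid(conns)
        s_values = grid.values
        n_nodes = conns[0].n_nodes
        n_grid = len(s_values)

        ensemble = RandomEnsembleSpec(
            n_networks=cfg.ensemble_size,
            swaps_per_edge=cfg.swaps_per_edge,
            seed=int(ens_seed.generate_state(1)[0] % (2**31)),
        )

        global_curves: dict[str, np.ndarray] = {
            m: np.zeros((len(self.subjects), n_grid))
            for m in ("cp", "lp", "gamma", "lambda", "sigma", "eglob", "eloc")
        }
        nodal_curves: dict[str, np.ndarray] = {
            m: np.zeros((len(self.subjects), n_grid, n_nodes))
            for m in ("degree", "efficiency", "betweenness")
        }

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for si, conn in enumerate(conns):
                nets = threshold_series(conn, grid)
                for gi, net in enumerate(nets):
                    _, cp = clustering_coefficient(net)
                    gamma, lam, sig = normalized_metrics(net, ensemble)
                    global_curves["cp"][si, gi] = cp
                    global_curves["lp"][si, gi] = characteristic_path_length(net)
                    global_curves["gamma"][si, gi] = gamma
                    global_curves["lambda"][si, gi] = lam
                    global_curves["sigma"][si, gi] = sig
                    global_curves["eglob"][si, gi] = global_efficiency(net)
                    global_curves["eloc"][si, gi] = local_efficiency(net)
                    nm = nodal_metrics(net)
                    nodal_curves["degree"][si, gi] = nm.degree
                    nodal_curves["efficiency"][si, gi] = nm.efficiency
                    nodal_curves["betweenness"][si, gi] = nm.betweenness

        step = grid.step
        rule = cfg.integration_rule
        integrated_global = pd.DataFrame(
            {
                m: [
                    integrate_values(global_curves[m][si], step, rule=rule)
                    for si in range(len(self.subjects))
                ]
                for m in global_curves
            },
            index=[s.record.subject_id for s in self.subjects],
        )
        integrated_nodal = {
            m: np.stack(
                [
                    np.array(
                        [
                            integrate_values(
                                nodal_curves[m][si, :, v], step, rule=rule
                            )
                            for v in range(n_nodes)
                        ]
                    )
                    for si in range(len(self.subjects))
                ]
            )
            for m in nodal_curves
        }

        is_case = np.array([s.record.group == "case" for s in self.subjects])

        # permutation inference on integrated global metrics
        perm_rng = perm_seed
        global_rows = []
        for m in GLOBAL_TESTED:
            vals = integrated_global[m].to_numpy()
            res = permutation_test(
                vals[is_case],
                vals[~is_case],
                n_perm=cfg.n_perm,
                seed=perm_rng.spawn(1)[0],
            )
            d = cohens_d(vals[is_case], vals[~is_case]).d
            global_rows.append(
                {
                    "metric": m,
                    "case_mean": vals[is_case].mean(),
                    "case_sd": vals[is_case].std(ddof=1),
                    "control_mean": vals[~is_case].mean(),
                    "control_sd": vals[~is_case].std(ddof=1),
                    "p_perm": res.p_two_tailed,
                    "cohens_d": d,
                }
            )
        global_tests = pd.DataFrame(global_rows).set_index("metric")

        # nodal comparisons (uncorrected, with effect sizes)
        nodal_rows = []
        for m in NODAL_TESTED:
            mat = integrated_nodal[m]
            for v in range(n_nodes):
                vals = mat[:, v]
                res = permutation_test(
                    vals[is_case],
                    vals[~is_case],
                    n_perm=cfg.n_perm,
                    seed=perm_rng.spawn(1)[0],
                )
                nodal_rows.append(
                    {
                        "metric": m,
                        "region": self.roi_labels[v],
                        "node": v,
                        "case_mean": vals[is_case].mean(),
                        "case_sd": vals[is_case].std(ddof=1),
                        "control_mean": vals[~is_case].mean(),
                        "control_sd": vals[~is_case].std(ddof=1),
                        "p_perm": res.p_two_tailed,
                        "cohens_d": cohens_d(vals[is_case], vals[~is_case]).d,
                    }
                )
        nodal_tests = pd.DataFrame(nodal_rows)

        # hubs per group from integrated betweenness
        bet = integrated_nodal["betweenness"]
        hubs = {
            "case": hub_table(
                bet[is_case], cfg.hub_threshold, roi_labels=self.roi_labels
            ),
            "control": hub_table(
                bet[~is_case], cfg.hub_threshold, roi_labels=self.roi_labels
            ),
        }

        # NBS on the connectivity matrices themselves
        conn_stack = np.stack([c.values for c in conns])
        nbs_result = nbs(
            conn_stack[is_case],
            conn_stack[~is_case],
            primary_p=cfg.nbs_primary_p,
            n_perm=cfg.n_perm,
            seed=nbs_seed,
        )

        # duration-of-use association (age-controlled), case group only,
        # for every region flagged p<0.05 in the nodal comparisons
        duration = np.array(
            [
                s.record.duration_of_use if s.record.group == "case" else np.nan
                for s in self.subjects
            ]
        )
        age = np.array([s.record.age for s in self.subjects])
        assoc_rows = []
        have_duration = np.isfinite(duration[is_case]).all() and is_case.sum() >= 4
        if have_duration:
            sig = nodal_tests[nodal_tests.p_perm < 0.05]
            for _, row in sig.iterrows():
                vals = integrated_nodal[row.metric][is_case, int(row.node)]
                try:
                    reg = duration_association(
                        vals, duration[is_case], age[is_case]
                    )
                except ValueError:
                    continue
                assoc_rows.append(
                    {
                        "metric": row.metric,
                        "region": row.region,
                        "node": int(row.node),
                        "slope": reg.slope,
                        "partial_r": reg.partial_r,
                        "p": reg.p_two_tailed,
                    }
                )
        duration_tests = pd.DataFrame(
            assoc_rows,
            columns=["metric", "region", "node", "slope", "partial_r", "p"],
        )

        return StudyResults(
            model=self,
            grid=grid,
            integrated_global=integrated_global,
            integrated_nodal=integrated_nodal,
            global_tests=global_tests,
            nodal_tests=nodal_tests,
            hubs=hubs,
            nbs=nbs_result,
            duration_tests=duration_tests,
            seed=seed,
        )


@dataclass
class StudyResults:
    """Everything :meth:`BrainNetworkStudy.fit` computes."""

    model: BrainNetworkStudy
    grid: SparsityGrid
    integrated_global: pd.DataFrame  # subjects x 7 global metrics
    integrated_nodal: dict[str, np.ndarray]  # metric -> (n_subj, n_nodes)
    global_tests: pd.DataFrame
    nodal_tests: pd.DataFrame
    hubs: dict[str, HubTable]
    nbs: NBSResult
    duration_tests: pd.DataFrame
    seed: int = 0

    def significant_nodal(self, alpha: float = 0.05) -> pd.DataFrame:
        """Regions with uncorrected permutation p below ``alpha``."""
        return self.nodal_tests[self.nodal_tests.p_perm < alpha].copy()

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Brain functional network study",
            "=" * 34,
            f"subjects: {len(self.model.subjects)} "
            f"({sum(s.record.group == 'case' for s in self.model.subjects)} case / "
            f"{sum(s.record.group == 'control' for s in self.model.subjects)} control)",
            f"sparsity grid: {self.grid.s_min:.2f}-{self.grid.s_max:.2f} "
            f"step {self.grid.step:.2f} ({len(self.grid)} thresholds)",
            f"permutations: {cfg.n_perm}, NBS primary p: {cfg.nbs_primary_p}, "
            f"hub criterion: Bi > {cfg.hub_threshold}",
            "",
            "Integrated global metrics (case vs control)",
            "-" * 44,
            self.global_tests.round(4).to_string(),
            "",
            f"Nodal differences (p < 0.05, uncorrected): "
            f"{len(self.significant_nodal())} region-metric pairs",
        ]
        sig = self.significant_nodal()
        if len(sig):
            lines.append(
                sig[["metric", "region", "p_perm", "cohens_d"]]
                .round(4)
                .to_string(index=False)
            )
        for group, table in self.hubs.items():
            lines.append(
                f"hubs ({group}): {', '.join(table.hub_labels) or 'none'}"
            )
        if self.nbs.components:
            c = self.nbs.components[0]
            lines.append(
                f"NBS: largest component {c.size} edges / "
                f"{len(c.nodes)} nodes, corrected p = {c.corrected_p:.4f}"
            )
        else:
            lines.append("NBS: no suprathreshold component")
        if len(self.duration_tests):
            lines.append("duration-of-use associations (age-controlled):")
            lines.append(self.duration_tests.round(4).to_string(index=False))
        return "\n".join(lines)

    def report_dict(self) -> dict:
        """JSON-serialisable run report (reproducible given config+seed)."""
        return {
            "version": _pkg_version,
            "seed": self.seed,
            "config": self.model.config.to_dict(),
            "grid": {
                "s_min": self.grid.s_min,
                "s_max": self.grid.s_max,
                "step": self.grid.step,
                "n_points": len(self.grid),
            },
            "n_subjects": len(self.model.subjects),
            "global_tests": self.global_tests.round(10).reset_index().to_dict(
                orient="records"
            ),
            "n_significant_nodal": int(len(self.significant_nodal())),
            "hubs": {g: t.hub_labels for g, t in self.hubs.items()},
            "nbs": {
                "primary_p": self.nbs.primary_threshold,
                "n_suprathreshold_edges": len(self.nbs.suprathreshold_edges),
                "components": [
                    {"size": c.size, "corrected_p": c.corrected_p}
                    for c in self.nbs.components
                ],
            },
            "duration_tests": self.duration_tests.round(10).to_dict(
                orient="records"
            ),
        }

    def save(self, outdir) -> None:
        """Write all result tables (CSV) and the run report (JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.integrated_global.to_csv(outdir / "integrated_global.csv")
        for m, mat in self.integrated_nodal.items():
            pd.DataFrame(
                mat,
                index=[s.record.subject_id for s in self.model.subjects],
                columns=self.model.roi_labels,
            ).to_csv(outdir / f"integrated_nodal_{m}.csv")
        self.global_tests.to_csv(outdir / "global_tests.csv")
        self.nodal_tests.to_csv(outdir / "nodal_tests.csv", index=False)
        for g, t in self.hubs.items():
            t.to_frame().to_csv(outdir / f"hubs_{g}.csv", index=False)
        edges = pd.DataFrame(
            [
                {
                    "roi_i": self.model.roi_labels[i],
                    "roi_j": self.model.roi_labels[j],
                    "component": k,
                }
                for k, c in enumerate(self.nbs.components)
                for i, j in c.edges
            ]
        )
        edges.to_csv(outdir / "nbs_components.csv", index=False)
        self.duration_tests.to_csv(outdir / "duration_tests.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.report_dict(), fh, indent=2)


def run_pipeline(
    config: RunConfig | None = None,
    *,
    cohort_dir=None,
    cohort_spec: CohortSpec | None = None,
    outdir=None,
) -> StudyResults:
    """End-to-end run: load or simulate a cohort, fit, optionally save."""
    config = config or RunConfig()
    if cohort_dir is not None:
        study = BrainNetworkStudy.from_directory(cohort_dir, config=config)
    else:
        spec = cohort_spec or CohortSpec(seed=config.seed)
        study = BrainNetworkStudy.from_simulation(spec, config=config)
    results = study.fit()
    if outdir is not None:
        results.save(outdir)
    return results
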