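"""Cohort CSV input: reading and validating the on-disk schema.

A cohort directory contains ``cohort.csv`` (subject metadata), one
``<subject_id>_roi.csv`` per subject (time points x ROI columns) and,
optionally, one ``<subject_id>_nuisance.csv`` (nine nuisance covariate
columns). The same schema is written by
:func:`braingraph.synthetic.write_cohort` and accepted for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .atlas import AAL90_LABELS
from .preprocess import RoiTimeSeries
from .synthetic import NUISANCE_COLUMNS, Subject, SubjectRecord

__all__ = ["read_cohort", "validate_inputs", "ValidationReport"]

METADATA_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "duration_of_use",
    "dosage",
]


def _record_from_row(row) -> SubjectRecord:
    dur = row.get("duration_of_use")
    dos = row.get("dosage")
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        age=float(row["age"]),
        sex=str(row["sex"]),
        education=float(row["education"]),
        duration_of_use=None if pd.isna(dur) else float(dur),
        dosage=None if pd.isna(dos) else float(dos),
    )


def read_cohort(path, tr_seconds: float = 2.0) -> list[Subject]:
    """Load a cohort directory into :class:`Subject` objects."""
    path = Path(path)
    meta = pd.read_csv(path / "cohort.csv")
    missing = set(METADATA_COLUMNS[:5]) - set(meta.columns)
    if missing:
        raise ValueError(f"cohort.csv lacks columns: {sorted(missing)}")
    subjects = []
    for _, row in meta.iterrows():
        record = _record_from_row(row)
        roi = pd.read_csv(path / f"{record.subject_id}_roi.csv")
        ts = RoiTimeSeries(
            values=roi.to_numpy(dtype=float),
            tr_seconds=tr_seconds,
            roi_labels=list(roi.columns),
        )
        nuis_path = path / f"{record.subject_id}_nuisance.csv"
        nuisance = pd.read_csv(nuis_path) if nuis_path.exists() else None
        subjects.append(Subject(record=record, timeseries=ts, nuisance=nuisance))
    return subjects


@dataclass
class ValidationReport:
    """Outcome of cohort-directory validation."""

    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    def __str__(self) -> str:
        lines = []
        for msg in self.fatal:
            lines.append(f"FATAL: {msg}")
        for msg in self.warnings:
            lines.append(f"warning: {msg}")
        if not lines:
            lines.append("cohort validated: no issues")
        return "\n".join(lines)


def validate_inputs(path, expect_aal90: bool = True) -> ValidationReport:
    """Check a cohort directory against the expected schema.

    Verifies metadata completeness (cases carry a positive duration of
    use), ROI column counts (90 for AAL), label consistency against the
    packaged AAL-90 list, per-subject time-point counts, and nuisance
    column naming. Issues are reported rather than raised.
    """
    path = Path(path)
    report = ValidationReport()
    meta_path = path / "cohort.csv"
    if not meta_path.exists():
        report.fatal.append(f"missing metadata table {meta_path}")
        return report
    meta = pd.read_csv(meta_path)
    missing = set(METADATA_COLUMNS[:5]) - set(meta.columns)
    if missing:
        report.fatal.append(f"cohort.csv lacks columns: {sorted(missing)}")
        return report

    n_timepoints_seen = set()
    for _, row in meta.iterrows():
        sid = str(row["subject_id"])
        group = str(row["group"])
        if group not in ("case", "control"):
            report.fatal.append(f"{sid}: unknown group {group!r}")
        if group == "case":
            dur = row.get("duration_of_use")
            if pd.isna(dur) or float(dur) <= 0:
                report.warnings.append(
                    f"{sid}: case subject missing a positive duration_of_use"
                )
        roi_path = path / f"{sid}_roi.csv"
        if not roi_path.exists():
            report.fatal.append(f"{sid}: missing ROI table {roi_path.name}")
            continue
        roi = pd.read_csv(roi_path)
        if expect_aal90 and roi.shape[1] != 90:
            report.fatal.append(
                f"{sid}: ROI table has {roi.shape[1]} columns, expected 90"
            )
        elif expect_aal90 and list(roi.columns) != AAL90_LABELS:
            bad = [c for c in roi.columns if c not in AAL90_LABELS][:5]
            report.fatal.append(
                f"{sid}: ROI labels do not match the AAL-90 list "
                f"(first unknown: {bad})"
            )
        n_timepoints_seen.add(len(roi))
        if roi.isna().any().any():
            report.fatal.append(f"{sid}: ROI table contains missing values")
        nuis_path = path / f"{sid}_nuisance.csv"
        if nuis_path.exists():
            nuis = pd.read_csv(nuis_path)
            if list(nuis.columns) != NUISANCE_COLUMNS:
                report.warnings.append(
                    f"{sid}: nuisance columns differ from the standard nine "
                    f"({NUISANCE_COLUMNS})"
                )
            if len(nuis) not in n_timepoints_seen:
                report.fatal.append(
                    f"{sid}: nuisance rows ({len(nuis)}) do not match the "
                    "ROI table"
                )
        else:
            report.warnings.append(f"{sid}: no nuisance table")
    if len(n_timepoints_seen) > 1:
        report.warnings.append(
            f"subjects differ in time-point counts: {sorted(n_timepoints_seen)}"
        )
    return report
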