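"""Cohort data containers and CSV/JSON serialization.

Two tables describe a cohort: ``registry`` rows carry the intraoperative /
registry ground truth per patient (what was actually found at surgery), and
``reports`` rows carry one 0/1 flag per catalog parameter recording whether
the preoperative CT report documented that parameter.

CSV dialect: UTF-8, comma-separated, header row required, booleans as 0/1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from .catalog import PARAMETER_IDS


class MeshPlane(str, Enum):
    ONLAY = "onlay"
    SUBLAY = "sublay"
    UNDERLAY = "underlay"


@dataclass(frozen=True)
class RegistryRecord:
    """Per-patient intraoperative/registry ground truth."""

    patient_id: str
    prior_mesh_present: bool
    mesh_plane: Optional[MeshPlane]
    mesh_fracture: bool
    mesh_migration: bool
    concurrent_inguinal: bool
    concurrent_parastomal: bool
    wall_abnormality: bool
    ongoing_sso: bool
    defect_width_cm: float
    defect_length_cm: float
    n_prior_repairs: int


@dataclass(frozen=True)
class ReportAbstraction:
    """Per-patient binary documentation flags, one per catalog parameter."""

    patient_id: str
    documented: dict[str, bool]


@dataclass
class CohortDataset:
    registry: list[RegistryRecord]
    reports: list[ReportAbstraction]
    provenance: dict = field(default_factory=dict)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, message: str) -> None:
        self.violations.append(message)

    def warn(self, message: str) -> None:
        self.warnings.append(message)


def validate_cohort(dataset: CohortDataset) -> ValidationReport:
    """Check every structural invariant of a cohort; list all violations.

    Checked: unique patient ids on both tables; identical id sets across
    tables; mesh_plane present iff prior mesh present; fracture/migration
    only with prior mesh; positive defect dimensions; non-negative repair
    counts; report flag keys exactly equal to the catalog ids.
    """
    report = ValidationReport()
    reg_ids = [r.patient_id for r in dataset.registry]
    rep_ids = [r.patient_id for r in dataset.reports]
    if len(set(reg_ids)) != len(reg_ids):
        report.add("duplicate patient_id in registry")
    if len(set(rep_ids)) != len(rep_ids):
        report.add("duplicate patient_id in reports")
    for orphan in sorted(set(rep_ids) - set(reg_ids)):
        report.add(f"report references unknown patient_id {orphan!r}")
    for missing in sorted(set(reg_ids) - set(rep_ids)):
        report.add(f"registry patient_id {missing!r} has no report row")

    for rec in dataset.registry:
        pid = rec.patient_id
        if rec.prior_mesh_present and rec.mesh_plane is None:
            report.add(f"{pid}: prior mesh present but mesh_plane missing")
        if not rec.prior_mesh_present and rec.mesh_plane is not None:
            report.add(f"{pid}: mesh_plane set without prior mesh")
        if (rec.mesh_fracture or rec.mesh_migration) and not rec.prior_mesh_present:
            report.add(f"{pid}: mesh fracture/migration without prior mesh")
        if rec.defect_width_cm <= 0 or rec.defect_length_cm <= 0:
            report.add(f"{pid}: non-positive defect dimension")
        if rec.n_prior_repairs < 0:
            report.add(f"{pid}: negative n_prior_repairs")

    expected_keys = set(PARAMETER_IDS)
    for rep in dataset.reports:
        if set(rep.documented) != expected_keys:
            report.add(
                f"{rep.patient_id}: report flags do not match catalog ids"
            )
    return report


# ---------------------------------------------------------------------------
# CSV serialization

REGISTRY_COLUMNS = [
    "patient_id",
    "prior_mesh_present",
    "mesh_plane",
    "mesh_fracture",
    "mesh_migration",
    "concurrent_inguinal",
    "concurrent_parastomal_or_stomal",
    "wall_abnormality",
    "ongoing_sso",
    "defect_width_cm",
    "defect_length_cm",
    "n_prior_repairs",
]


def _b(flag: bool) -> str:
    return "1" if flag else "0"


def _parse_bool(token: str, where: str) -> bool:
    if token == "1":
        return True
    if token == "0":
        return False
    raise ValueError(f"{where}: boolean field must be 0 or 1, got {token!r}")


def write_registry_csv(records: list[RegistryRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REGISTRY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    _b(r.prior_mesh_present),
                    r.mesh_plane.value if r.mesh_plane is not None else "",
                    _b(r.mesh_fracture),
                    _b(r.mesh_migration),
                    _b(r.concurrent_inguinal),
                    _b(r.concurrent_parastomal),
                    _b(r.wall_abnormality),
                    _b(r.ongoing_sso),
                    repr(r.defect_width_cm),
                    repr(r.defect_length_cm),
                    r.n_prior_repairs,
                ]
            )


def read_registry_csv(path: str | Path) -> list[RegistryRecord]:
    records: list[RegistryRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, header row required")
        if header != REGISTRY_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            if len(row) != len(REGISTRY_COLUMNS):
                raise ValueError(f"{where}: expected {len(REGISTRY_COLUMNS)} fields")
            records.append(
                RegistryRecord(
                    patient_id=row[0],
                    prior_mesh_present=_parse_bool(row[1], where),
                    mesh_plane=MeshPlane(row[2]) if row[2] else None,
                    mesh_fracture=_parse_bool(row[3], where),
                    mesh_migration=_parse_bool(row[4], where),
                    concurrent_inguinal=_parse_bool(row[5], where),
                    concurrent_parastomal=_parse_bool(row[6], where),
                    wall_abnormality=_parse_bool(row[7], where),
                    ongoing_sso=_parse_bool(row[8], where),
                    defect_width_cm=float(row[9]),
                    defect_length_cm=float(row[10]),
                    n_prior_repairs=int(row[11]),
                )
            )
    return records


def write_reports_csv(reports: list[ReportAbstraction], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", *PARAMETER_IDS])
        for rep in reports:
            writer.writerow(
                [rep.patient_id, *(_b(rep.documented[p]) for p in PARAMETER_IDS)]
            )


def read_reports_csv(path: str | Path) -> list[ReportAbstraction]:
    reports: list[ReportAbstraction] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, header row required")
        if header != ["patient_id", *PARAMETER_IDS]:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            if len(row) != 1 + len(PARAMETER_IDS):
                raise ValueError(f"{where}: wrong field count")
            reports.append(
                ReportAbstraction(
                    patient_id=row[0],
                    documented={
                        p: _parse_bool(tok, where)
                        for p, tok in zip(PARAMETER_IDS, row[1:])
                    },
                )
            )
    return reports
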