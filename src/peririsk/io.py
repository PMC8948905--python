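"""CSV schemas and typed readers/writers for patient and implant tables.

Two flat tables carry a cohort: one row per patient with the periodontal
score inputs and follow-up outcome, and one row per implant with the
implant/prosthesis state. Booleans are encoded 0/1; optional numeric fields
(cigarettes_per_day, rm_bone_mm) may be blank.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import ValidationError

from .records import (
    ImplantRecord,
    PatientRecord,
    PeriodontitisClassification,
    ProsthesisPlaqueStatus,
    SmokingStatus,
)
from .scoring import ScoreResult

PATIENT_COLUMNS = [
    "patient_id",
    "age_years",
    "bop_percent",
    "n_ppd_ge5",
    "bl_age_ratio",
    "tooth_loss",
    "systemic_factor",
    "smoking",
    "cigarettes_per_day",
    "history",
    "stage",
    "grade",
    "compliant",
    "followup_years",
    "event",
]

IMPLANT_COLUMNS = [
    "patient_id",
    "implant_id",
    "implant_type",
    "max_ppd_mm",
    "bop_or_sup",
    "bli_mm",
    "rm_bone_mm",
    "plaque_sites_pi_gt1",
    "fit",
    "cement_excess",
]


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class CohortValidationError(ValueError):
    """One or more rows failed validation; ``row_errors`` lists them."""

    def __init__(self, row_errors: list[tuple[str, str]]):
        self.row_errors = row_errors
        lines = "; ".join(f"[{rid}] {msg}" for rid, msg in row_errors[:10])
        more = "" if len(row_errors) <= 10 else f" (+{len(row_errors) - 10} more)"
        super().__init__(f"{len(row_errors)} invalid row(s): {lines}{more}")


def _check_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing mandatory column(s): {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{table} table has unknown column(s) {extra}; ignored", stacklevel=3)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and value != value) or value == "":
        return None
    return float(value)


def write_cohort(
    patients: Iterable[PatientRecord],
    patients_csv: str | Path,
    implants_csv: str | Path,
) -> None:
    """Write a cohort as the two-table CSV schema."""
    prow, irow = [], []
    for p in patients:
        prow.append(
            {
                "patient_id": p.patient_id,
                "age_years": p.age_years,
                "bop_percent": p.bop_percent,
                "n_ppd_ge5": p.n_ppd_ge5,
                "bl_age_ratio": p.bl_age_ratio,
                "tooth_loss": p.tooth_loss,
                "systemic_factor": int(p.systemic_factor),
                "smoking": p.smoking.habit.value,
                "cigarettes_per_day": p.smoking.cigarettes_per_day,
                "history": int(p.history_stage_II_IV),
                "stage": p.perio_class.stage.value,
                "grade": p.perio_class.grade.value,
                "compliant": int(p.compliant),
                "followup_years": p.followup_years,
                "event": int(p.event),
            }
        )
        for imp in p.implants:
            irow.append(
                {
                    "patient_id": p.patient_id,
                    "implant_id": imp.implant_id,
                    "implant_type": imp.implant_type.value,
                    "max_ppd_mm": imp.max_ppd_mm,
                    "bop_or_sup": int(imp.bop_or_suppuration),
                    "bli_mm": imp.bli_mm,
                    "rm_bone_mm": imp.rm_bone_mm,
                    "plaque_sites_pi_gt1": imp.prosthesis.plaque_sites_pi_gt1,
                    "fit": imp.prosthesis.fit.value,
                    "cement_excess": int(imp.prosthesis.cement_excess),
                }
            )
    pd.DataFrame(prow, columns=PATIENT_COLUMNS).to_csv(patients_csv, index=False)
    pd.DataFrame(irow, columns=IMPLANT_COLUMNS).to_csv(implants_csv, index=False)


def _implant_from_row(row: pd.Series) -> ImplantRecord:
    return ImplantRecord(
        implant_id=str(row["implant_id"]),
        implant_type=str(row["implant_type"]),
        max_ppd_mm=float(row["max_ppd_mm"]),
        bop_or_suppuration=bool(int(row["bop_or_sup"])),
        bli_mm=float(row["bli_mm"]),
        rm_bone_mm=_opt_float(row["rm_bone_mm"]),
        prosthesis=ProsthesisPlaqueStatus(
            plaque_sites_pi_gt1=int(row["plaque_sites_pi_gt1"]),
            fit=str(row["fit"]),
            cement_excess=bool(int(row["cement_excess"])),
        ),
    )


def _patient_from_row(row: pd.Series, implants: list[ImplantRecord]) -> PatientRecord:
    cpd = _opt_float(row["cigarettes_per_day"])
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        age_years=float(row["age_years"]),
        bop_percent=float(row["bop_percent"]),
        n_ppd_ge5=int(row["n_ppd_ge5"]),
        bl_age_ratio=float(row["bl_age_ratio"]),
        tooth_loss=int(row["tooth_loss"]),
        systemic_factor=bool(int(row["systemic_factor"])),
        smoking=SmokingStatus(
            habit=str(row["smoking"]),
            cigarettes_per_day=None if cpd is None else int(cpd),
        ),
        history_stage_II_IV=bool(int(row["history"])),
        perio_class=PeriodontitisClassification(
            stage=str(row["stage"]), grade=str(row["grade"])
        ),
        compliant=bool(int(row["compliant"])),
        implants=implants,
        followup_years=float(row["followup_years"]),
        event=bool(int(row["event"])),
    )


def read_cohort(
    patients_csv: str | Path, implants_csv: str | Path
) -> list[PatientRecord]:
    """Read and validate a cohort from the two-table CSV schema.

    Missing mandatory columns raise :class:`SchemaError`; rows violating the
    record invariants are collected and raised together as
    :class:`CohortValidationError` naming each offending patient/implant.
    """
    pdf = pd.read_csv(patients_csv, dtype={"patient_id": str})
    idf = pd.read_csv(implants_csv, dtype={"patient_id": str, "implant_id": str})
    _check_columns(pdf, PATIENT_COLUMNS, "patient")
    _check_columns(idf, IMPLANT_COLUMNS, "implant")

    errors: list[tuple[str, str]] = []
    implants_by_patient: dict[str, list[ImplantRecord]] = {}
    for _, row in idf.iterrows():
        rid = f"implant {row['patient_id']}/{row['implant_id']}"
        try:
            implants_by_patient.setdefault(str(row["patient_id"]), []).append(
                _implant_from_row(row)
            )
        except (ValidationError, ValueError) as exc:
            errors.append((rid, _short(exc)))

    patients: list[PatientRecord] = []
    for _, row in pdf.iterrows():
        pid = str(row["patient_id"])
        try:
            implants = implants_by_patient.get(pid, [])
            if not implants:
                raise ValueError("no implants found in implant table")
            patients.append(_patient_from_row(row, implants))
        except (ValidationError, ValueError) as exc:
            errors.append((f"patient {pid}", _short(exc)))
    if errors:
        raise CohortValidationError(errors)
    return patients


def _short(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        parts = [
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        return "; ".join(parts)
    return str(exc)


def scored_frame(
    patients: list[PatientRecord],
    pra: list[ScoreResult],
    ira: list[ScoreResult],
) -> pd.DataFrame:
    """Scored output table: overall and per-parameter categories per patient."""
    rows = []
    for p, rp, ri in zip(patients, pra, ira):
        row: dict[str, object] = {
            "patient_id": p.patient_id,
            "pra_category": rp.overall.label,
            "ira_category": ri.overall.label,
        }
        row.update({f"pra_{k}": v.label for k, v in rp.per_parameter.items()})
        row.update({f"ira_{k}": v.label for k, v in ri.per_parameter.items()})
        rows.append(row)
    return pd.DataFrame(rows)
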