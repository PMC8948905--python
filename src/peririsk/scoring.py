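"""Score computation: per-parameter categorization, aggregation, case definition.

Overall risk is a deterministic function of the per-parameter category counts:
high with at least two high-risk parameters; low with no high-risk parameter
and at most one moderate; moderate otherwise (this includes the published
clause placing one high-risk parameter with all others low in the moderate
overall category).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .records import ImplantRecord, PatientRecord, RiskCategory
from .rules import IRA_TABLE, PRA_TABLE, RuleTable

__all__ = [
    "ScoreResult",
    "aggregate_risk",
    "compute_pra",
    "compute_ira",
    "classify_peri_implantitis",
    "patient_has_peri_implantitis",
    "select_scoring_implant",
]


@dataclass(frozen=True)
class ScoreResult:
    """Per-parameter categories and aggregated overall risk for one score."""

    score_kind: str
    per_parameter: Mapping[str, RiskCategory]
    overall: RiskCategory

    @property
    def n_low(self) -> int:
        return sum(1 for c in self.per_parameter.values() if c is RiskCategory.LOW)

    @property
    def n_moderate(self) -> int:
        return sum(1 for c in self.per_parameter.values() if c is RiskCategory.MODERATE)

    @property
    def n_high(self) -> int:
        return sum(1 for c in self.per_parameter.values() if c is RiskCategory.HIGH)


def aggregate_risk(categories: Iterable[RiskCategory]) -> RiskCategory:
    """Aggregate per-parameter categories into the overall score level."""
    cats = list(categories)
    if not cats:
        raise ValueError("aggregate_risk requires at least one category")
    n_high = sum(1 for c in cats if c is RiskCategory.HIGH)
    n_moderate = sum(1 for c in cats if c is RiskCategory.MODERATE)
    if n_high >= 2:
        return RiskCategory.HIGH
    if n_high == 0 and n_moderate <= 1:
        return RiskCategory.LOW
    return RiskCategory.MODERATE


def _score(table: RuleTable, values: Mapping[str, object]) -> ScoreResult:
    per_parameter = {
        name: table.categorize(name, values[name]) for name in table.parameters
    }
    return ScoreResult(
        score_kind=table.score_kind,
        per_parameter=per_parameter,
        overall=aggregate_risk(per_parameter.values()),
    )


def compute_pra(patient: PatientRecord) -> ScoreResult:
    """Compute the six-parameter Periodontal Risk Assessment for one patient."""
    return _score(
        PRA_TABLE,
        {
            "bop_percent": patient.bop_percent,
            "n_ppd_ge5": patient.n_ppd_ge5,
            "bl_age": patient.bl_age_ratio,
            "tooth_loss": patient.tooth_loss,
            "systemic": patient.systemic_factor,
            "smoking": patient.smoking,
        },
    )


def compute_ira(patient: PatientRecord) -> ScoreResult:
    """Compute the eight-parameter Implant Risk Assessment for one patient.

    Implant-level parameters (restoration-margin-to-bone and
    prosthesis/plaque) come from the patient's highest-risk implant, chosen
    by :func:`select_scoring_implant`.
    """
    implant = select_scoring_implant(patient)
    return _score(
        IRA_TABLE,
        {
            "bop_percent": patient.bop_percent,
            "n_ppd_ge5": patient.n_ppd_ge5,
            "bl_age": patient.bl_age_ratio,
            "history": patient.history_stage_II_IV,
            "susceptibility": patient.perio_class,
            "compliance": patient.compliant,
            "rm_bone": implant,
            "prosthesis_plaque": implant.prosthesis,
        },
    )


def _implant_risk_key(implant: ImplantRecord) -> tuple[RiskCategory, RiskCategory]:
    return (
        IRA_TABLE.categorize("rm_bone", implant),
        IRA_TABLE.categorize("prosthesis_plaque", implant.prosthesis),
    )


def select_scoring_implant(patient: PatientRecord) -> ImplantRecord:
    """Pick the implant with the worst (RM-bone, prosthesis/plaque) categories.

    Lexicographic maximum under the low < moderate < high order; ties broken
    deterministically by the smallest ``implant_id``.
    """
    if not patient.implants:
        raise ValueError(f"patient {patient.patient_id} has no implants")
    best = None
    best_key: tuple[RiskCategory, RiskCategory] | None = None
    for implant in sorted(patient.implants, key=lambda i: i.implant_id):
        key = _implant_risk_key(implant)
        if best_key is None or key > best_key:
            best, best_key = implant, key
    assert best is not None
    return best


def classify_peri_implantitis(implant: ImplantRecord) -> bool:
    """Case definition without baseline radiographs: probing depth >= 6 mm
    with bleeding on probing or suppuration, and bone level >= 3 mm."""
    return (
        implant.max_ppd_mm >= 6
        and implant.bop_or_suppuration
        and implant.bli_mm >= 3
    )


def patient_has_peri_implantitis(patient: PatientRecord) -> bool:
    """Patient-level case status: any implant meets the case definition."""
    return any(classify_peri_implantitis(i) for i in patient.implants)
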