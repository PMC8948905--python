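"""Domain types for peri-implantitis risk assessment.

The records here mirror the clinical data collected during supportive
periodontal/implant therapy: one :class:`PatientRecord` per patient carrying
the periodontal score inputs and follow-up outcome, with one or more embedded
:class:`ImplantRecord` objects carrying the implant/prosthesis state used by
the implant-level score parameters and the peri-implantitis case definition.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator


class RiskCategory(enum.IntEnum):
    """Ordinal risk level: low < moderate < high."""

    LOW = 0
    MODERATE = 1
    HIGH = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "RiskCategory":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown risk category {label!r}") from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


class SmokingHabit(str, enum.Enum):
    NON_SMOKER = "non"
    FORMER_SMOKER = "former"
    CURRENT_SMOKER = "current"
    HEAVY_SMOKER = "heavy"


class SmokingStatus(BaseModel):
    """Smoking exposure at score-calculation time.

    Former smokers are patients who quit more than five years before the
    score was calculated; heavy smokers consume more than 19 cigarettes/day.
    """

    habit: SmokingHabit
    cigarettes_per_day: Optional[int] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _heavy_needs_count(self) -> "SmokingStatus":
        if self.habit is SmokingHabit.HEAVY_SMOKER:
            if self.cigarettes_per_day is None or self.cigarettes_per_day <= 19:
                raise ValueError(
                    "heavy smoker requires cigarettes_per_day > 19"
                )
        return self


class Stage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class Grade(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"


class PeriodontitisClassification(BaseModel):
    """2017 World Workshop staging (severity I-IV) and grading (rate A-C)."""

    stage: Stage
    grade: Grade


class ProsthesisFit(str, enum.Enum):
    ADEQUATE = "adequate"
    POOR_SUPRAMUCOSAL = "supra"
    POOR_SUBMUCOSAL = "sub"


class ProsthesisPlaqueStatus(BaseModel):
    """Prosthesis fit, cementation and plaque accumulation on one implant.

    ``plaque_sites_pi_gt1`` counts implant sites (six probed per implant)
    with a Plaque Index above 1.
    """

    plaque_sites_pi_gt1: int = Field(ge=0, le=6)
    fit: ProsthesisFit = ProsthesisFit.ADEQUATE
    cement_excess: bool = False


class ImplantType(str, enum.Enum):
    TISSUE_LEVEL = "tissue"
    BONE_LEVEL = "bone"


class ImplantRecord(BaseModel):
    """Per-implant clinical and radiographic state.

    ``bli_mm`` is the radiographic implant bone level: the distance from the
    implant reference point (smooth/rough surface junction for tissue-level
    implants, fixture shoulder for bone-level implants) to the first
    bone-to-implant contact, worst of mesial/distal. ``rm_bone_mm`` is the
    distance from the restoration margin to the marginal bone, when recorded.
    """

    implant_id: str
    implant_type: ImplantType
    max_ppd_mm: float = Field(ge=0)
    bop_or_suppuration: bool
    bli_mm: float = Field(ge=0)
    rm_bone_mm: Optional[float] = Field(default=None, ge=0)
    prosthesis: ProsthesisPlaqueStatus


class PatientRecord(BaseModel):
    """One patient: score inputs, implants, and follow-up outcome.

    ``followup_years`` runs from score calculation to the first
    peri-implantitis occurrence (``event`` true) or to censoring at the final
    examination (``event`` false). ``bl_age_ratio`` is worst-site radiographic
    periodontal bone loss (fraction of root length) divided by age.
    ``history_stage_II_IV`` records whether the initial periodontal diagnosis
    was stage II-IV periodontitis; ``perio_class`` is the staging/grading at
    follow-up used as periodontitis susceptibility. Non-compliant means no
    maintenance visit over a continuous two-year period.
    """

    patient_id: str
    age_years: float = Field(gt=0)
    bop_percent: float = Field(ge=0, le=100)
    n_ppd_ge5: int = Field(ge=0)
    bl_age_ratio: float = Field(ge=0)
    tooth_loss: int = Field(ge=0)
    systemic_factor: bool
    smoking: SmokingStatus
    history_stage_II_IV: bool
    perio_class: PeriodontitisClassification
    compliant: bool
    implants: list[ImplantRecord] = Field(min_length=1)
    followup_years: float = Field(ge=0)
    event: bool

    @model_validator(mode="after")
    def _unique_implant_ids(self) -> "PatientRecord":
        ids = [i.implant_id for i in self.implants]
        if len(set(ids)) != len(ids):
            raise ValueError("implant_id values must be unique within a patient")
        return self
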