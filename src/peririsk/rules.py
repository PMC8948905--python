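"""Declarative rule tables for the PRA and IRA risk scores.

The PRA (Periodontal Risk Assessment) combines six periodontal parameters;
the IRA (Implant Risk Assessment, a modified IDRA) combines eight periodontal
and implant/prosthesis parameters. Each parameter maps its admissible input
domain onto the ordinal categories low/moderate/high; the tables below encode
the published thresholds.

Numeric bands are closed on their printed upper bound ("0 to 9%" means
value <= 9 -> low; 25% BOP is still moderate). Values falling between two
printed integer bounds (e.g. BOP 9.5%) take the category of the smallest
printed upper bound that is >= the value, i.e. bands behave as
(previous bound, bound].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Optional, Sequence, Union

from .records import (
    Grade,
    ImplantRecord,
    ImplantType,
    PeriodontitisClassification,
    ProsthesisFit,
    ProsthesisPlaqueStatus,
    RiskCategory,
    SmokingHabit,
    SmokingStatus,
    Stage,
)

LOW, MODERATE, HIGH = RiskCategory.LOW, RiskCategory.MODERATE, RiskCategory.HIGH


class UnknownParameterError(KeyError):
    """Parameter name not present in the rule table of the requested score."""


class DomainError(ValueError):
    """Parameter value outside its admissible domain."""


@dataclass(frozen=True)
class NumericBands:
    """Ordered closed upper bounds; anything above the last bound -> ``top``.

    ``lower`` / ``upper`` delimit the admissible domain (upper=None means
    unbounded above, as for site counts).
    """

    bounds: Sequence[tuple[float, RiskCategory]]
    top: RiskCategory
    lower: float = 0.0
    upper: Optional[float] = None
    integral: bool = False

    def categorize(self, value: float, name: str) -> RiskCategory:
        try:
            x = float(value)
        except (TypeError, ValueError):
            raise DomainError(f"{name}: expected a number, got {value!r}") from None
        if x != x:  # NaN
            raise DomainError(f"{name}: value is NaN")
        if x < self.lower or (self.upper is not None and x > self.upper):
            raise DomainError(
                f"{name}: value {x} outside admissible domain "
                f"[{self.lower}, {self.upper if self.upper is not None else 'inf'}]"
            )
        if self.integral and x != int(x):
            raise DomainError(f"{name}: expected an integer count, got {value!r}")
        for bound, category in self.bounds:
            if x <= bound:
                return category
        return self.top


@dataclass(frozen=True)
class CategoricalRule:
    """Categorize via a total function over a non-numeric input type."""

    func: Callable[[Any], RiskCategory]
    typename: str

    def categorize(self, value: Any, name: str) -> RiskCategory:
        try:
            return self.func(value)
        except DomainError:
            raise
        except (AttributeError, TypeError, KeyError) as exc:
            raise DomainError(
                f"{name}: expected {self.typename}, got {value!r} ({exc})"
            ) from None


Rule = Union[NumericBands, CategoricalRule]


def _smoking_category(value: SmokingStatus) -> RiskCategory:
    if isinstance(value, str):
        value = SmokingStatus(habit=SmokingHabit(value))
    if value.habit in (SmokingHabit.NON_SMOKER, SmokingHabit.FORMER_SMOKER):
        return LOW
    cpd = value.cigarettes_per_day
    if value.habit is SmokingHabit.HEAVY_SMOKER or (cpd is not None and cpd > 19):
        return HIGH
    return MODERATE


def _boolean(value: Any, name: str) -> bool:
    if isinstance(value, bool):
        return value
    if value in (0, 1):
        return bool(value)
    raise DomainError(f"{name}: expected a boolean, got {value!r}")


def _susceptibility_category(value: PeriodontitisClassification) -> RiskCategory:
    stage, grade = value.stage, value.grade
    # Stage IV is high regardless of grade; grade C escalates to high at any
    # stage >= II; stage I stays low at any grade (only "IA" is tabulated low,
    # grades B/C at stage I fall back to low as the least-bad reading).
    if stage is Stage.IV:
        return HIGH
    if stage is Stage.I:
        return LOW
    if grade is Grade.C:
        return HIGH
    return MODERATE


def _rm_bone_category(value: Any) -> RiskCategory:
    """Tissue-level implants are low risk; bone-level implants, or a recorded
    restoration-margin-to-bone distance below 1.5 mm, are high risk."""
    if isinstance(value, ImplantRecord):
        implant_type, rm = value.implant_type, value.rm_bone_mm
    elif isinstance(value, (tuple, list)) and len(value) == 2:
        implant_type, rm = ImplantType(value[0]), value[1]
    else:
        implant_type, rm = ImplantType(value), None
    if implant_type is ImplantType.BONE_LEVEL:
        return HIGH
    if rm is not None:
        if rm < 0:
            raise DomainError(f"rm_bone: negative distance {rm}")
        if rm < 1.5:
            return HIGH
    return LOW


def _prosthesis_category(value: ProsthesisPlaqueStatus) -> RiskCategory:
    if value.plaque_sites_pi_gt1 > 3:
        return HIGH
    if value.fit is ProsthesisFit.POOR_SUBMUCOSAL or value.cement_excess:
        return HIGH
    if value.fit is ProsthesisFit.POOR_SUPRAMUCOSAL:
        return MODERATE
    return LOW


_BOP = NumericBands(bounds=((9, LOW), (25, MODERATE)), top=HIGH, lower=0, upper=100)
_BL_AGE = NumericBands(bounds=((0.5, LOW), (1, MODERATE)), top=HIGH, lower=0)

PRA_RULES: Mapping[str, Rule] = {
    "bop_percent": _BOP,
    "n_ppd_ge5": NumericBands(bounds=((4, LOW), (8, MODERATE)), top=HIGH, integral=True),
    "bl_age": _BL_AGE,
    "tooth_loss": NumericBands(bounds=((4, LOW), (8, MODERATE)), top=HIGH, integral=True),
    "systemic": CategoricalRule(
        lambda v: HIGH if _boolean(v, "systemic") else LOW, "boolean"
    ),
    "smoking": CategoricalRule(_smoking_category, "SmokingStatus"),
}

IRA_RULES: Mapping[str, Rule] = {
    "bop_percent": _BOP,
    "n_ppd_ge5": NumericBands(bounds=((2, LOW), (6, MODERATE)), top=HIGH, integral=True),
    "bl_age": _BL_AGE,
    # history of stage II-IV periodontitis: moderate at most, never high
    "history": CategoricalRule(
        lambda v: MODERATE if _boolean(v, "history") else LOW, "boolean"
    ),
    "susceptibility": CategoricalRule(
        _susceptibility_category, "PeriodontitisClassification"
    ),
    # two levels only: compliant -> low, non-compliant -> high
    "compliance": CategoricalRule(
        lambda v: LOW if _boolean(v, "compliance") else HIGH, "boolean"
    ),
    "rm_bone": CategoricalRule(_rm_bone_category, "ImplantRecord or (type, rm_mm)"),
    "prosthesis_plaque": CategoricalRule(_prosthesis_category, "ProsthesisPlaqueStatus"),
}

#: Display-name aliases accepted by :func:`categorize_parameter`.
PARAMETER_ALIASES: Mapping[str, str] = {
    "BOP%": "bop_percent",
    "%BOP": "bop_percent",
    "Nb PPD>=5mm": "n_ppd_ge5",
    "Nb of PPD >= 5 mm": "n_ppd_ge5",
    "Nb PPD≥5mm": "n_ppd_ge5",
    "Nb of PPD ≥ 5 mm": "n_ppd_ge5",
    "BL/age": "bl_age",
    "Tooth loss": "tooth_loss",
    "Systemic status": "systemic",
    "Smoking status": "smoking",
    "History of stage II, III, and IV periodontitis": "history",
    "Periodontitis susceptibility": "susceptibility",
    "Compliance level": "compliance",
    "RM-bone": "rm_bone",
    "Prosthesis/plaque score": "prosthesis_plaque",
}


@dataclass(frozen=True)
class RuleTable:
    """Machine-readable encoding of one score's parameter -> category rules."""

    score_kind: str
    rules: Mapping[str, Rule] = field(repr=False)

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.rules)

    def categorize(self, name: str, value: Any) -> RiskCategory:
        key = PARAMETER_ALIASES.get(name, name)
        rule = self.rules.get(key)
        if rule is None:
            raise UnknownParameterError(
                f"parameter {name!r} is not part of the {self.score_kind} rule table"
            )
        return rule.categorize(value, key)


PRA_TABLE = RuleTable(score_kind="PRA", rules=PRA_RULES)
IRA_TABLE = RuleTable(score_kind="IRA", rules=IRA_RULES)

_TABLES = {"PRA": PRA_TABLE, "IRA": IRA_TABLE}


def rule_table(score_kind: str) -> RuleTable:
    try:
        return _TABLES[score_kind.upper()]
    except KeyError:
        raise ValueError(f"unknown score kind {score_kind!r}; expected PRA or IRA") from None


def categorize_parameter(name: str, value: Any, score_kind: str) -> RiskCategory:
    """Assign one parameter value to its low/moderate/high risk category.

    ``name`` may be the canonical snake_case key or the table display name;
    ``score_kind`` is ``"PRA"`` or ``"IRA"`` (thresholds differ between the
    two scores for the deep-pocket count).
    """
    return rule_table(score_kind).categorize(name, value)
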