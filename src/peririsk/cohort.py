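"""Seeded synthetic patient cohorts for peri-implantitis risk-score studies.

The generator emulates a periodontally treated implant-maintenance population:
marginal distributions of the score parameters default to the published
cohort summary (n = 73 patients, 232 implants), and each patient's
time-to-peri-implantitis follows a configurable category-dependent hazard with
administrative censoring uniform over a 3-14-year follow-up window.

Numeric marginals use truncated normals (BOP%, BL/age, age) and
moment-matched negative binomials (tooth loss, deep-pocket count); only means
and SDs are published, not shapes. Parameters are sampled independently by
default; ``latent_correlation`` > 0 couples them through a single Gaussian
factor (a one-factor Gaussian copula) because real risk factors co-occur.

All randomness flows through one ``numpy.random.Generator`` seeded from
``CohortConfig.seed``; identical configs produce identical cohorts.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats as sps

from .records import (
    Grade,
    ImplantRecord,
    ImplantType,
    PatientRecord,
    PeriodontitisClassification,
    ProsthesisFit,
    ProsthesisPlaqueStatus,
    RiskCategory,
    SmokingHabit,
    SmokingStatus,
    Stage,
)
from .scoring import compute_ira, compute_pra

__all__ = ["CohortConfig", "Marginals", "generate_cohort", "sample_event_times"]


class TruncNormalSpec(BaseModel):
    """Normal(mean, sd) truncated to [lower, upper]."""

    mean: float
    sd: float = Field(gt=0)
    lower: float
    upper: float

    def ppf(self, u: np.ndarray) -> np.ndarray:
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return sps.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


class CountSpec(BaseModel):
    """Non-negative count with given mean/SD.

    Negative binomial when over-dispersed (sd^2 > mean), Poisson otherwise.
    """

    mean: float = Field(gt=0)
    sd: float = Field(gt=0)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        var = self.sd**2
        if var > self.mean:
            r = self.mean**2 / (var - self.mean)
            p = r / (r + self.mean)
            return sps.nbinom.ppf(u, r, p)
        return sps.poisson.ppf(u, self.mean)


class CategoricalSpec(BaseModel):
    """Ordered categories with probabilities (normalized to sum to 1).

    Order matters when a latent correlation is used: later categories are
    reached by larger latent severity.
    """

    levels: list[str]
    probs: list[float]

    @model_validator(mode="after")
    def _normalize(self) -> "CategoricalSpec":
        if len(self.levels) != len(self.probs):
            raise ValueError("levels and probs must have equal length")
        if any(p < 0 for p in self.probs):
            raise ValueError("probabilities must be non-negative")
        total = sum(self.probs)
        if not math.isclose(total, 1.0, abs_tol=0.01):
            raise ValueError(f"probabilities sum to {total}, expected ~1")
        self.probs = [p / total for p in self.probs]
        return self

    def draw(self, u: np.ndarray) -> np.ndarray:
        cum = np.cumsum(self.probs)
        idx = np.searchsorted(cum, u, side="left")
        return np.clip(idx, 0, len(self.levels) - 1)


class Marginals(BaseModel):
    """Default marginal distributions of the score parameters.

    Defaults reproduce the published cohort table at score-calculation time
    (compliant 83.56%, tissue-level-only 95.89%, periodontitis history
    89.04%, smokers 23.29%, BOP% mean 24.29 SD 21.25, ...).
    """

    age: TruncNormalSpec = TruncNormalSpec(mean=60.08, sd=7.96, lower=25, upper=95)
    bop_percent: TruncNormalSpec = TruncNormalSpec(
        mean=24.29, sd=21.25, lower=0, upper=100
    )
    bl_age: TruncNormalSpec = TruncNormalSpec(mean=0.59, sd=0.23, lower=0, upper=3)
    tooth_loss: CountSpec = CountSpec(mean=8.44, sd=4.24)
    n_ppd_ge5: CountSpec = CountSpec(mean=7.85, sd=11.41)
    smoking: CategoricalSpec = CategoricalSpec(
        levels=["non", "former", "current"], probs=[0.4932, 0.2740, 0.2329]
    )
    p_heavy_given_current: float = Field(default=1 / 17, ge=0, le=1)
    p_systemic: float = Field(default=3 / 73, ge=0, le=1)
    p_history: float = Field(default=0.8904, ge=0, le=1)
    susceptibility: CategoricalSpec = CategoricalSpec(
        levels=["II_AB", "III_AB", "III_C", "IV"],
        probs=[0.1781, 0.6849, 0.0822, 0.0548],
    )
    p_compliant: float = Field(default=0.8356, ge=0, le=1)
    p_tissue_level_only: float = Field(default=0.9589, ge=0, le=1)
    prosthesis: CategoricalSpec = CategoricalSpec(
        levels=["clean", "supra", "high_plaque"], probs=[0.6575, 0.3014, 0.0411]
    )


class CohortConfig(BaseModel):
    """Cohort size, marginals, hazards, censoring window and RNG seed."""

    n_patients: int = Field(default=73, gt=0)
    seed: int = 0
    marginals: Marginals = Field(default_factory=Marginals)
    #: annual peri-implantitis hazard per overall risk category; defaults give
    #: a true high vs low/moderate hazard ratio of 4.782
    hazard_by_category: dict[str, float] = Field(
        default_factory=lambda: {
            "low": 0.006,
            "moderate": 0.006,
            "high": 0.006 * 4.782,
        }
    )
    followup_window_years: tuple[float, float] = (3.0, 14.0)
    #: Weibull shape for event times; 1.0 = constant hazard (exponential)
    weibull_shape: float = Field(default=1.0, gt=0)
    #: implants per patient = 1 + Poisson(mean - 1); cohort mean 232/73
    implants_per_patient_mean: float = Field(default=232 / 73, ge=1)
    #: one-factor Gaussian copula coupling across parameters; 0 = independent
    latent_correlation: float = Field(default=0.0, ge=0, lt=1)
    #: which score's overall category drives the event hazard
    hazard_score: str = "PRA"

    @field_validator("hazard_by_category")
    @classmethod
    def _hazards(cls, v: dict[str, float]) -> dict[str, float]:
        missing = {"low", "moderate", "high"} - set(v)
        if missing:
            raise ValueError(f"hazard_by_category missing categories: {sorted(missing)}")
        if any(rate < 0 for rate in v.values()):
            raise ValueError("hazard rates must be non-negative")
        return v

    @field_validator("followup_window_years")
    @classmethod
    def _window(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if lo < 3:
            raise ValueError("follow-up window must start at >= 3 years")
        if hi <= lo:
            raise ValueError("follow-up window must have max > min")
        return v

    @field_validator("hazard_score")
    @classmethod
    def _score(cls, v: str) -> str:
        if v.upper() not in ("PRA", "IRA"):
            raise ValueError("hazard_score must be PRA or IRA")
        return v.upper()

    def hazard_for(self, category: RiskCategory) -> float:
        return self.hazard_by_category[category.label]


def sample_event_times(
    category: RiskCategory, config: CohortConfig, rng: np.random.Generator
) -> tuple[float, bool]:
    """Draw (followup_years, event) for one scored patient.

    Event time ~ Weibull(shape k, scale 1/rate) — exponential with the
    category's annual rate when k = 1; censoring ~ Uniform over the follow-up
    window. The event fires iff it precedes censoring.
    """
    rate = config.hazard_for(category)
    lo, hi = config.followup_window_years
    censor = rng.uniform(lo, hi)
    if rate <= 0:
        return float(censor), False
    t_event = rng.exponential(1.0) ** (1.0 / config.weibull_shape) / rate
    if t_event <= censor:
        return float(t_event), True
    return float(censor), False


# column order of the latent uniform matrix; orientation: larger u = worse
_COLUMNS = (
    "age",
    "bop",
    "bl_age",
    "tooth_loss",
    "ppd",
    "smoking",
    "heavy",
    "systemic",
    "history",
    "suscept",
    "compliant",
    "tissue_only",
    "prosthesis",
)


def _uniforms(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    k = len(_COLUMNS)
    if rho <= 0:
        return rng.uniform(size=(n, k))
    z = math.sqrt(rho) * rng.standard_normal((n, 1)) + math.sqrt(
        1 - rho
    ) * rng.standard_normal((n, k))
    return sps.norm.cdf(z)


_STAGE_GRADE = {
    "II_AB": (Stage.II, (Grade.A, Grade.B)),
    "III_AB": (Stage.III, (Grade.A, Grade.B)),
    "III_C": (Stage.III, (Grade.C,)),
    "IV": (Stage.IV, (Grade.B, Grade.C)),
}


def _build_implants(
    pid: str,
    n_implants: int,
    tissue_only: bool,
    prosthesis_level: str,
    rng: np.random.Generator,
) -> list[ImplantRecord]:
    implants = []
    bone_idx = -1 if tissue_only else int(rng.integers(n_implants))
    worst_idx = int(rng.integers(n_implants))
    for j in range(n_implants):
        itype = ImplantType.BONE_LEVEL if j == bone_idx else ImplantType.TISSUE_LEVEL
        if j == worst_idx and prosthesis_level == "high_plaque":
            pros = ProsthesisPlaqueStatus(
                plaque_sites_pi_gt1=int(rng.integers(4, 7)),
                fit=ProsthesisFit.ADEQUATE,
                cement_excess=False,
            )
        elif j == worst_idx and prosthesis_level == "supra":
            pros = ProsthesisPlaqueStatus(
                plaque_sites_pi_gt1=int(rng.integers(0, 4)),
                fit=ProsthesisFit.POOR_SUPRAMUCOSAL,
                cement_excess=False,
            )
        else:
            pros = ProsthesisPlaqueStatus(
                plaque_sites_pi_gt1=int(rng.integers(0, 4)),
                fit=ProsthesisFit.ADEQUATE,
                cement_excess=False,
            )
        rm_bone = (
            float(np.round(rng.uniform(0.5, 3.0), 2))
            if itype is ImplantType.BONE_LEVEL
            else None
        )
        implants.append(
            ImplantRecord(
                implant_id=f"{pid}-i{j + 1:02d}",
                implant_type=itype,
                # healthy baseline: below the case-definition thresholds
                max_ppd_mm=float(np.round(rng.uniform(1.5, 5.5), 1)),
                bop_or_suppuration=bool(rng.uniform() < 0.25),
                bli_mm=float(np.round(rng.uniform(0.0, 2.5), 2)),
                rm_bone_mm=rm_bone,
                prosthesis=pros,
            )
        )
    return implants


def _mark_peri_implantitis(
    implants: list[ImplantRecord], rng: np.random.Generator
) -> list[ImplantRecord]:
    """Make one implant meet the case definition (event patients)."""
    idx = int(rng.integers(len(implants)))
    diseased = implants[idx].model_copy(
        update={
            "max_ppd_mm": float(np.round(rng.uniform(6.0, 9.0), 1)),
            "bop_or_suppuration": True,
            "bli_mm": float(np.round(rng.uniform(3.0, 6.0), 2)),
        }
    )
    return implants[:idx] + [diseased] + implants[idx + 1 :]


def generate_cohort(config: Optional[CohortConfig] = None) -> list[PatientRecord]:
    """Generate a seeded synthetic cohort of scored-parameter patients.

    Deterministic given ``config`` (including its seed). Each patient is
    scored, assigned an event/censoring time from the category-dependent
    hazard, and — for event patients — given one implant whose clinical state
    meets the peri-implantitis case definition, so that the implant-level
    classifier agrees with the patient-level event flag.
    """
    config = config or CohortConfig()
    m = config.marginals
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    u = _uniforms(rng, n, config.latent_correlation)
    col = {name: u[:, i] for i, name in enumerate(_COLUMNS)}

    age = m.age.ppf(col["age"])
    bop = m.bop_percent.ppf(col["bop"])
    bl_age = m.bl_age.ppf(col["bl_age"])
    tooth_loss = m.tooth_loss.ppf(col["tooth_loss"]).astype(int)
    ppd = m.n_ppd_ge5.ppf(col["ppd"]).astype(int)
    smoking_idx = m.smoking.draw(col["smoking"])
    systemic = col["systemic"] > 1 - m.p_systemic
    history = col["history"] > 1 - m.p_history
    suscept_idx = m.susceptibility.draw(col["suscept"])
    compliant = col["compliant"] < m.p_compliant
    tissue_only = col["tissue_only"] < m.p_tissue_level_only
    prosthesis_idx = m.prosthesis.draw(col["prosthesis"])
    n_implants = 1 + rng.poisson(config.implants_per_patient_mean - 1, size=n)

    width = len(str(n))
    patients: list[PatientRecord] = []
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        habit = SmokingHabit(m.smoking.levels[smoking_idx[i]])
        cpd: Optional[int] = None
        if habit is SmokingHabit.CURRENT_SMOKER:
            if col["heavy"][i] < m.p_heavy_given_current:
                habit = SmokingHabit.HEAVY_SMOKER
                cpd = int(rng.integers(20, 41))
            else:
                cpd = int(rng.integers(1, 20))
        stage, grades = _STAGE_GRADE[m.susceptibility.levels[suscept_idx[i]]]
        grade = grades[int(rng.integers(len(grades)))]
        implants = _build_implants(
            pid,
            int(n_implants[i]),
            bool(tissue_only[i]),
            m.prosthesis.levels[prosthesis_idx[i]],
            rng,
        )
        patient = PatientRecord(
            patient_id=pid,
            age_years=float(np.round(age[i], 1)),
            bop_percent=float(np.round(bop[i], 2)),
            n_ppd_ge5=int(ppd[i]),
            bl_age_ratio=float(np.round(bl_age[i], 3)),
            tooth_loss=int(tooth_loss[i]),
            systemic_factor=bool(systemic[i]),
            smoking=SmokingStatus(habit=habit, cigarettes_per_day=cpd),
            history_stage_II_IV=bool(history[i]),
            perio_class=PeriodontitisClassification(stage=stage, grade=grade),
            compliant=bool(compliant[i]),
            implants=implants,
            followup_years=0.0,
            event=False,
        )
        score = compute_pra(patient) if config.hazard_score == "PRA" else compute_ira(patient)
        followup, event = sample_event_times(score.overall, config, rng)
        if event:
            implants = _mark_peri_implantitis(implants, rng)
        patient = patient.model_copy(
            update={
                "implants": implants,
                "followup_years": float(np.round(followup, 4)),
                "event": event,
            }
        )
        patients.append(patient)
    return patients
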