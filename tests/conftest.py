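import pytest

from peririsk import (
    CohortConfig,
    ImplantRecord,
    PatientRecord,
    PeriodontitisClassification,
    ProsthesisPlaqueStatus,
    SmokingStatus,
    generate_cohort,
)


def make_implant(**kw) -> ImplantRecord:
    base = dict(
        implant_id="i1",
        implant_type="tissue",
        max_ppd_mm=4.0,
        bop_or_suppuration=False,
        bli_mm=1.0,
        rm_bone_mm=None,
        prosthesis=ProsthesisPlaqueStatus(plaque_sites_pi_gt1=1),
    )
    base.update(kw)
    return ImplantRecord(**base)


def make_patient(**kw) -> PatientRecord:
    base = dict(
        patient_id="P1",
        age_years=60.0,
        bop_percent=5.0,
        n_ppd_ge5=0,
        bl_age_ratio=0.3,
        tooth_loss=0,
        systemic_factor=False,
        smoking=SmokingStatus(habit="non"),
        history_stage_II_IV=False,
        perio_class=PeriodontitisClassification(stage="I", grade="A"),
        compliant=True,
        implants=[make_implant()],
        followup_years=6.5,
        event=False,
    )
    base.update(kw)
    return PatientRecord(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """120 simulated patients with the default marginals, fixed seed."""
    return generate_cohort(CohortConfig(n_patients=120, seed=11))
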