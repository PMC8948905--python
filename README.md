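# peririsk

Rule-based peri-implantitis risk scoring and validation for patients with
treated periodontitis in long-term implant maintenance.

Clinicians following periodontitis patients with implants need a way to rank
who is likely to develop peri-implantitis, so that recall intervals and
preventive effort can be targeted. Two stratification tools exist for this:
the **Periodontal Risk Assessment (PRA)**, which combines six periodontal
parameters, and the **Implant Risk Assessment (IRA)**, an adaptation of the
IDRA that combines eight periodontal and implant/prosthesis parameters. This
package implements both scores as declarative rule tables, the
peri-implantitis case definition, a synthetic-cohort simulator, and the
survival-analysis machinery used to validate such scores against
time-to-event follow-up data.

## The scores

Each parameter is mapped to an ordinal category (low < moderate < high):

| parameter | low | moderate | high | score |
|---|---|---|---|---|
| BOP% | 0–9 | 10–25 | >25 | both |
| sites with PPD ≥ 5 mm | 0–4 | 5–8 | >8 | PRA |
| sites with PPD ≥ 5 mm | 0–2 | 3–6 | >6 | IRA |
| BL/age (worst site) | 0–0.5 | >0.5–1 | >1 | both |
| tooth loss (periodontal) | 0–4 | 5–8 | >8 | PRA |
| systemic/genetic factor | no | — | yes | PRA |
| smoking | non/former | <20 cig/day | >19 cig/day | PRA |
| history of stage II–IV periodontitis | no | yes | — | IRA |
| periodontitis susceptibility | stage I A | II A/B, III A/B | III C, IV | IRA |
| compliance | compliant | — | no visit ≥ 2 y | IRA |
| RM–bone | tissue-level | — | bone-level or <1.5 mm | IRA |
| prosthesis/plaque | <4 sites PI>1, good fit | poor fit supramucosal | poor fit submucosal, cement excess, >3 sites PI>1 | IRA |

Printed bands are closed on their upper bound (BOP 25% is still moderate).
The overall score is **high** with ≥2 high-risk parameters, **low** with no
high-risk parameter and ≤1 moderate, and **moderate** otherwise. With
multiple implants, the implant-level IRA parameters come from the
highest-risk implant. Peri-implantitis at an implant is PPD ≥ 6 mm with
BOP/suppuration and radiographic bone level ≥ 3 mm; a patient is a case if
any implant qualifies.

Validation treats the patient as the statistical unit: Kaplan–Meier curves
per risk category, the log-rank test, a univariable Cox model for the
high-risk group against the pooled low/moderate group (hazard ratio
HR = exp(β) with Wald 95% CI), ROC/AUC of the ordinal score (tie-corrected
Mann–Whitney), sensitivity/specificity/PPV/NPV, and Cohen's kappa between the
two scores' high-risk classifications.

## Worked example

```python
from peririsk import *

patient = PatientRecord(
    patient_id="P01", age_years=62, bop_percent=24.0, n_ppd_ge5=7,
    bl_age_ratio=0.59, tooth_loss=8, systemic_factor=False,
    smoking=SmokingStatus(habit="former"), history_stage_II_IV=True,
    perio_class=PeriodontitisClassification(stage="III", grade="A"),
    compliant=False,
    implants=[ImplantRecord(implant_id="i1", implant_type="tissue",
        max_ppd_mm=4.0, bop_or_suppuration=False, bli_mm=1.2,
        prosthesis=ProsthesisPlaqueStatus(plaque_sites_pi_gt1=2))],
    followup_years=6.5, event=False)

pra, ira = compute_pra(patient), compute_ira(patient)
print("PRA:", pra.overall.label, {k: v.label for k, v in pra.per_parameter.items()})
print("IRA:", ira.overall.label, {k: v.label for k, v in ira.per_parameter.items()})
```

prints

```
PRA: moderate {'bop_percent': 'moderate', 'n_ppd_ge5': 'moderate', 'bl_age': 'moderate', 'tooth_loss': 'moderate', 'systemic': 'low', 'smoking': 'low'}
IRA: high {'bop_percent': 'moderate', 'n_ppd_ge5': 'high', 'bl_age': 'moderate', 'history': 'moderate', 'susceptibility': 'moderate', 'compliance': 'high', 'rm_bone': 'low', 'prosthesis_plaque': 'low'}
```

Four moderate periodontal parameters make this patient moderate-risk under
PRA. Under IRA the same deep-pocket count (7) crosses the stricter threshold
(>6 → high), and two years without maintenance adds a second high-risk
parameter, so the patient is high-risk overall.

The same works from the shell on CSV cohorts:

```bash
peririsk simulate --n 200 --seed 7 --out-dir cohort/     # synthetic cohort
peririsk score    --patients cohort/patients.csv --implants cohort/implants.csv --out scored.csv
peririsk validate --patients cohort/patients.csv --implants cohort/implants.csv --out-dir results/ --plots
peririsk reconstruct --n 73 --events 13 --n-positive 27 --sensitivity 0.692
```

The last command inverts a published metric row back into its 2×2 table:

```
{"tp": 9, "fp": 18, "fn": 4, "tn": 42, "sensitivity": 0.692, "specificity": 0.7, "ppv": 0.333, "npv": 0.913}
```

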