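"""End-to-end validation pipeline: cohort -> scores -> survival validation.

Scores every patient with both PRA and IRA, treats the patient as the
statistical unit throughout, pools low and moderate patients into one group
against the high-risk group for Cox regression and the 2x2 confusion table,
and summarizes Kaplan-Meier curves per risk category, the log-rank test,
ordinal-score ROC/AUC and the kappa agreement between the two scores into a
JSON-serializable :class:`ValidationReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .cohort import CohortConfig, generate_cohort
from .io import read_cohort, scored_frame, write_cohort
from .records import PatientRecord, RiskCategory
from .scoring import ScoreResult, compute_ira, compute_pra
from . import stats as st

__all__ = ["RunConfig", "ValidationReport", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Input source (CSV paths or a simulation config) and output options."""

    patients_csv: Optional[str | Path] = None
    implants_csv: Optional[str | Path] = None
    simulation: Optional[CohortConfig] = None
    out_dir: Optional[str | Path] = None
    make_plots: bool = False
    score_kinds: tuple[str, ...] = ("PRA", "IRA")

    def __post_init__(self) -> None:
        from_files = self.patients_csv is not None and self.implants_csv is not None
        if from_files == (self.simulation is not None):
            raise ValueError(
                "provide exactly one input source: (patients_csv, implants_csv) "
                "or a simulation config"
            )


def _percent(k: int, n: int) -> float:
    return round(100.0 * k / n, 2) if n else 0.0


@dataclass
class ScoreSection:
    distribution: dict
    km: dict
    logrank: Optional[dict]
    cox: Optional[dict]
    roc: Optional[dict]
    confusion: Optional[dict]
    notes: list = field(default_factory=list)


@dataclass
class ValidationReport:
    n_patients: int
    n_events: int
    incidence_percent: float
    mean_followup_years: float
    scores: dict  # score kind -> ScoreSection as plain dict
    kappa_high_risk: Optional[float]
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_events": self.n_events,
            "incidence_percent": self.incidence_percent,
            "mean_followup_years": self.mean_followup_years,
            "scores": self.scores,
            "kappa_high_risk": self.kappa_high_risk,
            "notes": self.notes,
        }


def _km_section(
    times: np.ndarray, events: np.ndarray, cats: np.ndarray
) -> dict:
    out = {}
    for cat in RiskCategory:
        mask = cats == int(cat)
        if not mask.any():
            continue
        curve = st.km_estimate(times[mask], events[mask])
        out[cat.label] = {
            "n": int(mask.sum()),
            "times": curve.times.tolist(),
            "survival": curve.survival.tolist(),
            "at_risk": curve.at_risk.tolist(),
        }
    return out


def _score_section(
    times: np.ndarray, events: np.ndarray, cats: np.ndarray, n: int
) -> ScoreSection:
    notes: list[str] = []
    distribution = {
        cat.label: {"n": int((cats == int(cat)).sum()), "percent": _percent(int((cats == int(cat)).sum()), n)}
        for cat in RiskCategory
    }
    n_events = int(events.sum())
    km = _km_section(times, events, cats)

    logrank = None
    present = [c for c in RiskCategory if (cats == int(c)).any()]
    if n_events == 0:
        notes.append("no events: log-rank, Cox, ROC and confusion metrics unavailable")
    elif len(present) < 2:
        notes.append("all patients in one risk category: log-rank unavailable")
    else:
        res = st.logrank_test(times, events, cats)
        logrank = {"statistic": res.statistic, "p_value": res.p_value, "df": res.df}

    cox = None
    high = (cats == int(RiskCategory.HIGH)).astype(int)
    if n_events > 0 and 0 < high.sum() < n:
        try:
            res_cox = st.cox_fit(times, events, high)
            cox = {
                "hr": res_cox.hr,
                "ci_low": res_cox.ci_low,
                "ci_high": res_cox.ci_high,
                "p_value": res_cox.p_value,
                "coefficient": res_cox.coefficient,
                "se": res_cox.se,
            }
        except st.ConvergenceError as exc:
            notes.append(f"Cox fit unavailable: {exc}")
    elif n_events > 0:
        notes.append("high-risk group empty or exhaustive: Cox unavailable")

    roc = None
    if 0 < n_events < n:
        res_roc = st.auc_ordinal(cats, events)
        roc = {
            "auc": res_roc.auc,
            "fpr": res_roc.fpr.tolist(),
            "tpr": res_roc.tpr.tolist(),
        }

    confusion = None
    if n_events > 0:
        tp = int((high.astype(bool) & events).sum())
        fp = int((high.astype(bool) & ~events).sum())
        fn = int((~high.astype(bool) & events).sum())
        tn = int((~high.astype(bool) & ~events).sum())
        cm = st.ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        confusion = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        try:
            metrics = st.confusion_metrics(cm)
            confusion.update(
                sensitivity=metrics.sensitivity,
                specificity=metrics.specificity,
                ppv=metrics.ppv,
                npv=metrics.npv,
            )
        except st.UndefinedMetricError as exc:
            notes.append(f"confusion metrics partially unavailable: {exc}")

    return ScoreSection(
        distribution=distribution,
        km=km,
        logrank=logrank,
        cox=cox,
        roc=roc,
        confusion=confusion,
        notes=notes,
    )


def validate_cohort(
    patients: list[PatientRecord],
    score_kinds: tuple[str, ...] = ("PRA", "IRA"),
) -> tuple[ValidationReport, list[ScoreResult], list[ScoreResult]]:
    """Score a cohort and compute the full validation report."""
    if not patients:
        raise ValueError("empty cohort")
    n = len(patients)
    times = np.array([p.followup_years for p in patients])
    events = np.array([p.event for p in patients], dtype=bool)
    pra = [compute_pra(p) for p in patients]
    ira = [compute_ira(p) for p in patients]
    by_kind = {"PRA": pra, "IRA": ira}

    scores = {}
    for kind in score_kinds:
        cats = np.array([int(r.overall) for r in by_kind[kind]])
        section = _score_section(times, events, cats, n)
        scores[kind] = {
            "distribution": section.distribution,
            "km": section.km,
            "logrank": section.logrank,
            "cox": section.cox,
            "roc": section.roc,
            "confusion": section.confusion,
            "notes": section.notes,
        }

    kappa = None
    if {"PRA", "IRA"} <= set(score_kinds):
        a = [int(r.overall is RiskCategory.HIGH) for r in pra]
        b = [int(r.overall is RiskCategory.HIGH) for r in ira]
        kappa = st.cohens_kappa(a, b)

    report = ValidationReport(
        n_patients=n,
        n_events=int(events.sum()),
        incidence_percent=_percent(int(events.sum()), n),
        mean_followup_years=round(float(times.mean()), 4),
        scores=scores,
        kappa_high_risk=kappa,
    )
    return report, pra, ira


def write_report(report: ValidationReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def run_pipeline(config: RunConfig) -> ValidationReport:
    """Load or simulate a cohort, score it, validate, and emit artifacts.

    With ``out_dir`` set, writes ``report.json``, ``scored.csv`` and — for a
    simulated cohort — the generated ``patients.csv``/``implants.csv``;
    ``make_plots`` additionally saves KM and ROC figures.
    """
    if config.simulation is not None:
        patients = generate_cohort(config.simulation)
    else:
        patients = read_cohort(config.patients_csv, config.implants_csv)

    report, pra, ira = validate_cohort(patients, config.score_kinds)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.simulation is not None:
            write_cohort(patients, out / "patients.csv", out / "implants.csv")
        scored_frame(patients, pra, ira).to_csv(out / "scored.csv", index=False)
        write_report(report, out / "report.json")
        if config.make_plots:
            from .plots import km_plot, roc_plot

            km_plot(report, out / "km.png")
            roc_plot(report, out / "roc.png")
    return report
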