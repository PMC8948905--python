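"""Validation statistics for risk-score prognosis studies.

Kaplan-Meier estimation, the log-rank test and Cox proportional-hazards
fitting are delegated to lifelines; ROC/AUC for the ordinal three-level score
uses scikit-learn (tie-corrected Mann-Whitney). Confusion-matrix metrics,
Cohen's kappa and the 2x2 reconstruction from published summary counts are
closed forms implemented here.

The reconstruction inverts a printed metric row: given the cohort size, the
number of events, the number of score-positive (high-risk) patients and the
printed sensitivity, the four cells of the 2x2 table are determined (true
positives = sensitivity x events, rounded half away from zero), from which
specificity, PPV and NPV follow exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CoxResult",
    "RocResult",
    "ConfusionMatrix",
    "ConfusionMetrics",
    "UndefinedMetricError",
    "InconsistentSummariesError",
    "ConvergenceError",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "auc_ordinal",
    "confusion_metrics",
    "reconstruct_confusion",
    "cohens_kappa",
]


class UndefinedMetricError(ZeroDivisionError):
    """A requested metric has a zero denominator for this table."""


class InconsistentSummariesError(ValueError):
    """Printed summary counts do not form a valid 2x2 table."""


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (e.g. complete separation)."""


def _as_survival_arrays(
    times: Sequence[float], events: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-D and of equal length")
    if t.size == 0:
        raise ValueError("empty survival sample")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate evaluated at observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    df: int


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    coefficient: float
    se: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InconsistentSummariesError(
                f"negative cell in 2x2 table: tp={self.tp} fp={self.fp} "
                f"fn={self.fn} tn={self.tn}"
            )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    The curve is reported only at observed event times; censoring tied with
    an event time is handled events-first (the standard convention).
    """
    t, e = _as_survival_arrays(times, events)
    if not e.any():
        return KMCurve(
            times=np.array([]), survival=np.array([]), at_risk=np.array([], dtype=int)
        )
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    mask = table["observed"] > 0
    event_times = table.index[mask].to_numpy(dtype=float)
    survival = np.array(
        [float(kmf.survival_function_at_times(x).iloc[0]) for x in event_times]
    )
    at_risk = table.loc[mask, "at_risk"].to_numpy(dtype=int)
    return KMCurve(times=event_times, survival=survival, at_risk=at_risk)


def logrank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> LogrankResult:
    """Unweighted log-rank test across two or more groups.

    Returns the chi-square statistic, its p-value on k-1 degrees of freedom,
    and k-1.
    """
    t, e = _as_survival_arrays(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must parallel times")
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test requires at least two groups")
    if counts.min() == 0:  # pragma: no cover - unique() never yields 0
        raise ValueError("empty group")
    if not e.any():
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=len(labels) - 1,
    )


def cox_fit(
    times: Sequence[float], events: Sequence[bool], covariate: Sequence[int]
) -> CoxResult:
    """Univariable Cox proportional-hazards fit for a binary covariate.

    Partial-likelihood maximization with Efron tie handling; the confidence
    interval is Wald on the log scale, exp(coef +/- 1.96 se). Typical use:
    covariate = 1 for high-risk patients, 0 for the pooled low/moderate group.
    """
    t, e = _as_survival_arrays(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise ValueError("covariate must parallel times")
    if len(np.unique(x)) < 2:
        raise ValueError("covariate must take two values")
    if not e.any():
        raise ValueError("Cox fit requires at least one event")
    df = pd.DataFrame({"time": t, "event": e.astype(int), "x": x})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            cph.fit(df, duration_col="time", event_col="event")
    except (_LLConvergenceError, RuntimeWarning, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"Cox fit did not converge: {exc}") from exc
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not (math.isfinite(coef) and math.isfinite(se)) or abs(coef) > 20:
        raise ConvergenceError(
            f"Cox fit degenerate (coef={coef}, se={se}); likely complete separation"
        )
    p = float(cph.summary.loc["x", "p"])
    return CoxResult(
        hr=math.exp(coef),
        ci_low=math.exp(coef - 1.96 * se),
        ci_high=math.exp(coef + 1.96 * se),
        p_value=p,
        coefficient=coef,
        se=se,
    )


def auc_ordinal(scores: Sequence[int], outcomes: Sequence[bool]) -> RocResult:
    """ROC curve and AUC for an ordinal predictor (low < moderate < high).

    AUC is the Mann-Whitney probability that an event patient outranks a
    non-event patient, ties counted one half — equivalently the trapezoidal
    area over the score's interior thresholds.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be 1-D and of equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes required to compute a ROC curve")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr)


def confusion_metrics(cm: ConfusionMatrix) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV and NPV of a 2x2 table."""

    def ratio(num: int, den: int, metric: str) -> float:
        if den == 0:
            raise UndefinedMetricError(f"{metric} undefined: zero denominator")
        return num / den

    return ConfusionMetrics(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        ppv=ratio(cm.tp, cm.tp + cm.fp, "ppv"),
        npv=ratio(cm.tn, cm.tn + cm.fn, "npv"),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_confusion(
    n: int, d: int, n_positive: int, sensitivity: float
) -> ConfusionMatrix:
    """Rebuild the 2x2 table behind a published metric row.

    ``n`` patients, ``d`` events, ``n_positive`` score-positive patients and
    the printed sensitivity determine tp = round(sensitivity * d) (half away
    from zero) and hence all four cells. Raises
    :class:`InconsistentSummariesError` if any cell would be negative.
    """
    if not 0 <= d <= n:
        raise InconsistentSummariesError(f"events d={d} outside [0, n={n}]")
    if not 0 <= n_positive <= n:
        raise InconsistentSummariesError(f"n_positive={n_positive} outside [0, {n}]")
    if not 0.0 <= sensitivity <= 1.0:
        raise InconsistentSummariesError(f"sensitivity {sensitivity} outside [0, 1]")
    tp = _round_half_away(sensitivity * d)
    fn = d - tp
    fp = n_positive - tp
    tn = n - d - fp
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def cohens_kappa(rater_a: Sequence, rater_b: Sequence) -> float:
    """Unweighted Cohen's kappa between two categorical ratings.

    (p_o - p_e) / (1 - p_e); returns 1.0 in the degenerate case where chance
    agreement is 1 (both raters constant and identical).
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("empty ratings")
    n = a.size
    labels = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    p_e = sum(
        float(np.mean(a == lab)) * float(np.mean(b == lab)) for lab in labels
    )
    if math.isclose(p_e, 1.0):
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_from_table(both: int, a_only: int, b_only: int, neither: int) -> float:
    """Cohen's kappa from a 2x2 agreement table of two binary ratings."""
    a = [1] * both + [1] * a_only + [0] * b_only + [0] * neither
    b = [1] * both + [0] * a_only + [1] * b_only + [0] * neither
    return cohens_kappa(a, b)
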