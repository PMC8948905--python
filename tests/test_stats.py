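"""Survival/diagnostic statistics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from sklearn.metrics import cohen_kappa_score

from peririsk.stats import (
    ConfusionMatrix,
    ConvergenceError,
    InconsistentSummariesError,
    UndefinedMetricError,
    auc_ordinal,
    cohens_kappa,
    confusion_metrics,
    cox_fit,
    kappa_from_table,
    km_estimate,
    logrank_test,
    reconstruct_confusion,
)

# ---------------------------------------------------------------- Kaplan-Meier


def test_km_all_censored_is_flat_one():
    curve = km_estimate([1, 2, 3], [False, False, False])
    assert curve.times.size == 0
    assert curve.survival_at(2.5) == 1.0


def test_km_hand_computed_no_censoring():
    curve = km_estimate([1, 2, 3], [True, True, True])
    assert curve.times.tolist() == [1, 2, 3]
    assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
    assert curve.at_risk.tolist() == [3, 2, 1]


def test_km_censoring_tied_with_event_handled_events_first():
    # at t=1: 3 at risk, 1 event -> S=2/3; the tied censoring leaves at t=1,
    # so at t=2 only one subject is at risk -> S=0
    curve = km_estimate([1, 1, 2], [True, False, True])
    assert curve.survival == pytest.approx([2 / 3, 0.0])
    assert curve.at_risk.tolist() == [3, 1]


def test_km_worked_mixed_example():
    # events at 2 (4 at risk) and 5 (2 at risk); censored at 3 and 6
    curve = km_estimate([2, 3, 5, 6], [True, False, True, False])
    assert curve.times.tolist() == [2, 5]
    assert curve.survival == pytest.approx([3 / 4, 3 / 8])


@settings(max_examples=60, deadline=None)
@given(
    times=st.lists(
        st.floats(min_value=0.01, max_value=50, allow_nan=False), min_size=1, max_size=40
    )
)
def test_km_without_censoring_equals_empirical_survivor(times):
    n = len(times)
    curve = km_estimate(times, [True] * n)
    t = np.asarray(times)
    for x, s in zip(curve.times, curve.survival):
        assert s == pytest.approx(np.mean(t > x), abs=1e-12)


def test_km_rejects_negative_times():
    with pytest.raises(ValueError):
        km_estimate([-1, 2], [True, True])


# -------------------------------------------------------------------- log-rank


def _two_group_logrank_oracle(times, events, groups):
    """Hand-rolled O-E / V chi-square for two groups (hypergeometric variance)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & (groups == g0)).sum()
        d = (events & (times == t)).sum()
        d0 = (events & (times == t) & (groups == g0)).sum()
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_logrank_identical_groups_is_null():
    times = [1, 2, 3, 4, 1, 2, 3, 4]
    events = [True, True, False, True] * 2
    groups = ["a"] * 4 + ["b"] * 4
    res = logrank_test(times, events, groups)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1


def test_logrank_matches_hand_table():
    rng = np.random.default_rng(99)
    times = np.concatenate([rng.exponential(5, 25), rng.exponential(2, 25)])
    events = rng.uniform(size=50) < 0.8
    groups = np.repeat(["a", "b"], 25)
    res = logrank_test(times, events, groups)
    assert res.statistic == pytest.approx(
        _two_group_logrank_oracle(times, events, groups), rel=1e-6
    )


def test_logrank_invariant_under_monotone_time_rescaling():
    rng = np.random.default_rng(5)
    times = rng.exponential(4, 60)
    events = rng.uniform(size=60) < 0.7
    groups = np.repeat([0, 1], 30)
    a = logrank_test(times, events, groups)
    b = logrank_test(np.exp(times / 10), events, groups)
    assert a.statistic == pytest.approx(b.statistic, rel=1e-9)


def test_logrank_requires_two_groups_and_an_event():
    with pytest.raises(ValueError):
        logrank_test([1, 2], [True, True], ["a", "a"])
    with pytest.raises(ValueError):
        logrank_test([1, 2], [False, False], ["a", "b"])


# ------------------------------------------------------------------------- Cox


def _partial_loglik(beta, times, events, x):
    """Independent Breslow partial log-likelihood (no ties in the data used)."""
    ll = 0.0
    for i in np.where(events)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


def test_cox_coefficient_matches_brute_force_on_tiny_data():
    times = np.array([1.0, 2.5, 3.0, 4.2, 5.1, 6.3, 7.7, 9.0])
    events = np.array([1, 1, 0, 1, 1, 0, 1, 1], bool)
    x = np.array([1, 0, 1, 1, 0, 0, 1, 0])
    res = cox_fit(times, events, x)
    opt = minimize_scalar(
        lambda b: -_partial_loglik(b, times, events, x), bounds=(-5, 5), method="bounded"
    )
    assert res.coefficient == pytest.approx(opt.x, abs=1e-4)
    assert res.hr == pytest.approx(math.exp(opt.x), rel=1e-3)
    assert res.ci_low <= res.hr <= res.ci_high


def test_cox_recovers_known_rate_ratio():
    rng = np.random.default_rng(12)
    n = 4000
    x = (rng.uniform(size=n) < 0.4).astype(int)
    rates = np.where(x == 1, 0.03, 0.01)
    t_event = rng.exponential(1 / rates)
    censor = rng.uniform(3, 14, n)
    events = t_event <= censor
    res = cox_fit(np.minimum(t_event, censor), events, x)
    assert res.hr == pytest.approx(3.0, rel=0.25)
    assert res.ci_low <= 3.0 <= res.ci_high


def test_cox_input_validation():
    with pytest.raises(ValueError):
        cox_fit([1, 2, 3], [True, True, False], [1, 1, 1])  # one covariate level
    with pytest.raises(ValueError):
        cox_fit([1, 2, 3], [False, False, False], [0, 1, 1])  # no events


def test_cox_complete_separation_raises_not_silent():
    # all events in one group while the other group is censored first: the
    # partial likelihood increases without bound in |beta|
    times = np.array([5.0, 6.0, 7.0, 8.0, 1.0, 1.1, 1.2, 1.3])
    events = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
    x = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    with pytest.raises((ConvergenceError, ValueError)):
        cox_fit(times, events, x)


# ------------------------------------------------------------------------- ROC


def _auc_all_pairs(scores, outcomes):
    scores = np.asarray(scores)
    outcomes = np.asarray(outcomes, bool)
    pos = scores[outcomes]
    neg = scores[~outcomes]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_perfect_and_constant():
    assert auc_ordinal([2, 2, 0, 0], [1, 1, 0, 0]).auc == 1.0
    assert auc_ordinal([1, 1, 1, 1], [1, 0, 1, 0]).auc == 0.5


def test_auc_hand_case_matches_pairwise_count():
    scores = [0, 1, 1, 2, 2, 0]
    outcomes = [0, 0, 1, 1, 0, 1]
    res = auc_ordinal(scores, outcomes)
    assert res.auc == pytest.approx(_auc_all_pairs(scores, outcomes))


def test_auc_curve_endpoints():
    res = auc_ordinal([0, 1, 2, 1], [0, 0, 1, 1])
    assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
    assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)
    assert res.auc == pytest.approx(float(np.trapezoid(res.tpr, res.fpr)))


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc_ordinal([0, 1, 2], [1, 1, 1])


@settings(max_examples=100, deadline=None)
@given(data=st.data())
def test_auc_equals_mann_whitney_on_random_instances(data):
    n = data.draw(st.integers(4, 30))
    scores = data.draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
    outcomes = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
    if not (any(outcomes) and not all(outcomes)):
        outcomes[0], outcomes[-1] = True, False
    res = auc_ordinal(scores, outcomes)
    assert res.auc == pytest.approx(_auc_all_pairs(scores, outcomes), abs=1e-12)


# --------------------------------------------------- confusion & reconstruction


def test_confusion_metrics_all_correct():
    m = confusion_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=7))
    assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1, 1, 1, 1)


def test_confusion_metrics_zero_denominator_signalled():
    with pytest.raises(UndefinedMetricError):
        confusion_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))


def test_reconstruct_perfect_score():
    cm = reconstruct_confusion(50, 10, 10, 1.0)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (10, 0, 0, 40)


def test_reconstruct_negative_cell_rejected():
    with pytest.raises(InconsistentSummariesError):
        reconstruct_confusion(73, 13, 5, 0.692)  # fp would be negative
    with pytest.raises(InconsistentSummariesError):
        reconstruct_confusion(10, 12, 5, 0.5)


def test_confusion_matrix_invariants():
    cm = ConfusionMatrix(tp=9, fp=18, fn=4, tn=42)
    assert cm.tp + cm.fn == 13
    assert cm.fp + cm.tn == 60
    assert cm.n == 73
    with pytest.raises(InconsistentSummariesError):
        ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


# ----------------------------------------------------------------------- kappa


def test_kappa_identical_and_chance():
    assert cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)
    assert cohens_kappa([1, 1, 0, 0], [1, 1, 1, 1]) == pytest.approx(0.0)


def test_kappa_degenerate_perfect_agreement():
    assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0


def test_kappa_matches_sklearn_on_random_vectors():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 3, 40)
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


def test_kappa_from_agreement_table_closed_form():
    # po = 58/73, pe = (27*20 + 46*53)/73^2
    got = kappa_from_table(both=16, a_only=11, b_only=4, neither=42)
    po = 58 / 73
    pe = (27 * 20 + 46 * 53) / 73**2
    assert got == pytest.approx((po - pe) / (1 - pe), abs=1e-12)


def test_kappa_length_mismatch():
    with pytest.raises(ValueError):
        cohens_kappa([1, 0], [1])
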