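"""Tests for endpoint derivation, exclusion filtering, KM, Cox and stepwise AIC."""

import itertools

import numpy as np
import pytest

from iarisk import (
    BcrOutcome,
    aic,
    backward_stepwise,
    cox_fit,
    derive_bcr,
    km_estimate,
    stard_filter,
)
from iarisk.scoring import InvalidInputError
from iarisk.survival import null_log_partial_likelihood


# ---------------------------------------------------------------------------
# biochemical-recurrence derivation
# ---------------------------------------------------------------------------

def test_derive_bcr_censored_never_crosses():
    out = derive_bcr([(0.1, 0.05), (1.0, 0.1), (2.0, 0.15)])
    assert not out.event and not out.persistent_psa
    assert out.time_years == 2.0


def test_derive_bcr_event_at_first_crossing():
    out = derive_bcr([(0.1, 0.05), (1.0, 0.25)])
    assert out.event and out.time_years == 1.0


def test_derive_bcr_persistent_psa():
    out = derive_bcr([(0.1, 0.5), (1.0, 0.6)])
    assert out.persistent_psa and not out.event


def test_derive_bcr_nadir_window_selection():
    # nadir inside 28-42 d window is used even if later values dip lower
    series = [(30 / 365.25, 0.1), (0.5, 0.05), (1.0, 0.25)]
    out = derive_bcr(series)
    assert out.event and out.time_years == 1.0


def test_derive_bcr_input_errors():
    with pytest.raises(InvalidInputError):
        derive_bcr([])
    with pytest.raises(InvalidInputError):
        derive_bcr([(1.0, 0.1), (0.5, 0.1)])


# ---------------------------------------------------------------------------
# exclusion filtering
# ---------------------------------------------------------------------------

def test_stard_filter_reasons_and_idempotence():
    records = [
        ({"id": 1}, BcrOutcome(event=False, time_years=2.0)),
        ({"id": 2}, BcrOutcome(event=False, time_years=0.1, persistent_psa=True)),
        ({"id": 3}, BcrOutcome(event=False, time_years=0.4)),  # < 180 d, censored
        ({"id": 4}, BcrOutcome(event=True, time_years=0.4)),   # early event is kept
        ({"id": 5, "psa": None}, BcrOutcome(event=False, time_years=3.0)),
    ]
    kept, tally = stard_filter(records)
    assert [p["id"] for p, _ in kept] == [1, 4]
    assert tally["persistent PSA"] == 1
    assert tally["follow-up < 180 days"] == 1
    assert tally["missing data"] == 1
    kept2, tally2 = stard_filter(kept)
    assert kept2 == kept and sum(tally2.values()) == 0


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_no_censoring_closed_form():
    curve = km_estimate([1, 2, 3], [1, 1, 1])
    assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
    assert list(curve.at_risk) == [3, 2, 1]


def test_km_hand_product_limit_with_censoring():
    curve = km_estimate([1, 2, 3], [1, 0, 1])
    # S(1) = 2/3; censored at 2; S(3) = 2/3 * (1 - 1/1) = 0... at-risk at 3 is 1
    assert curve.survival_at(3.0) == pytest.approx((2 / 3) * (1 - 1 / 1))
    assert curve.survival_at(1.5) == pytest.approx(2 / 3)


def test_km_six_patient_fixture():
    # hand product-limit: events at 1 (n=6), 3 (n=4), censor at 2, 4; events 5
    times = [1, 2, 3, 4, 5, 5]
    events = [1, 0, 1, 0, 1, 1]
    curve = km_estimate(times, events)
    s1 = 5 / 6
    s3 = s1 * (3 / 4)
    s5 = s3 * (0 / 2)
    assert np.allclose(curve.survival, [s1, s3, s5])


def test_km_all_censored_is_flat_one():
    curve = km_estimate([1, 2, 3], [0, 0, 0])
    assert curve.times.size == 0
    assert curve.survival_at(10.0) == 1.0


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(1)
    t = rng.exponential(size=50)
    curve = km_estimate(t, np.ones(50, dtype=bool))
    for tt, s in zip(curve.times, curve.survival):
        assert s == pytest.approx(np.mean(t > tt))


def test_km_rejects_negative_times():
    with pytest.raises(InvalidInputError):
        km_estimate([-1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _breslow_loglik(beta, x, times, events):
    """Independent O(n^2) Breslow log partial likelihood (test oracle)."""
    beta = np.atleast_1d(beta)
    x = np.atleast_2d(x.T).T
    ll = 0.0
    for tt in np.unique(times[events]):
        d_idx = np.flatnonzero((times == tt) & events)
        risk = np.flatnonzero(times >= tt)
        eta = x @ beta
        ll += eta[d_idx].sum() - len(d_idx) * np.log(np.exp(eta[risk]).sum())
    return ll


def test_cox_matches_lifelines(survival_data):
    import pandas as pd
    from lifelines import CoxPHFitter

    x, times, events = survival_data
    fit = cox_fit(x, times, events)
    assert fit.converged
    df = pd.DataFrame({"x": x, "T": times, "E": events})
    oracle = CoxPHFitter().fit(df, "T", "E")  # continuous times: Efron == Breslow
    assert fit.coefficients[0] == pytest.approx(oracle.params_.iloc[0], abs=1e-6)
    assert fit.standard_errors[0] == pytest.approx(oracle.standard_errors_.iloc[0], rel=1e-5)
    assert fit.log_partial_likelihood == pytest.approx(oracle.log_likelihood_, abs=1e-6)


def test_cox_score_equation_at_optimum(survival_data):
    """Numerical gradient of an independent Breslow likelihood vanishes at the fit."""
    x, times, events = survival_data
    fit = cox_fit(x, times, events)
    beta = fit.coefficients[0]
    h = 1e-5
    grad = (_breslow_loglik(beta + h, x, times, events)
            - _breslow_loglik(beta - h, x, times, events)) / (2 * h)
    assert abs(grad) < 1e-4


def test_cox_recovers_true_coefficient(survival_data):
    x, times, events = survival_data
    fit = cox_fit(x, times, events)
    assert abs(fit.coefficients[0] - 0.7) < 2 * fit.standard_errors[0]


def test_cox_breslow_ties_match_sksurv(survival_data):
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    x, times, events = survival_data
    tied = np.ceil(times * 4) / 4  # force heavy ties
    fit = cox_fit(x, tied, events)
    y = np.array(list(zip(events, tied)), dtype=[("e", bool), ("t", float)])
    oracle = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-9).fit(x[:, None], y)
    assert fit.coefficients[0] == pytest.approx(oracle.coef_[0], abs=1e-6)


def test_cox_separation_returns_unconverged():
    fit = cox_fit(np.array([1.0, 0.0]), np.array([1.0, 2.0]), np.array([True, True]))
    assert not fit.converged


def test_cox_input_errors():
    with pytest.raises(InvalidInputError):
        cox_fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.array([False, False]))
    with pytest.raises(InvalidInputError):  # constant covariate
        cox_fit(np.ones(10), np.arange(1, 11.0), np.ones(10, dtype=bool))
    with pytest.raises(InvalidInputError):  # collinear
        x = np.random.default_rng(0).normal(size=10)
        cox_fit(np.column_stack([x, 2 * x]), np.arange(1, 11.0), np.ones(10, dtype=bool))


def test_cox_null_coverage():
    """Under beta = 0 the estimate stays within 2 SE in most replicates."""
    rng = np.random.default_rng(3)
    hits = 0
    reps = 40
    for _ in range(reps):
        x = rng.normal(size=300)
        t = rng.exponential(size=300)
        c = rng.exponential(2.0, size=300)
        fit = cox_fit(x, np.minimum(t, c), t <= c)
        if abs(fit.coefficients[0]) < 2 * fit.standard_errors[0]:
            hits += 1
    assert hits / reps >= 0.9


# ---------------------------------------------------------------------------
# AIC and backward stepwise selection
# ---------------------------------------------------------------------------

def test_aic_arithmetic(survival_data):
    x, times, events = survival_data
    fit = cox_fit(x, times, events)
    assert aic(fit) == pytest.approx(-2 * fit.log_partial_likelihood + 2)


def test_aic_requires_convergence():
    fit = cox_fit(np.array([1.0, 0.0]), np.array([1.0, 2.0]), np.array([True, True]))
    with pytest.raises(InvalidInputError):
        aic(fit)


def test_null_log_partial_likelihood_closed_form():
    # all events, no ties: -sum log(n - i)
    assert null_log_partial_likelihood([1, 2, 3], [1, 1, 1]) == pytest.approx(
        -(np.log(3) + np.log(2) + np.log(1))
    )


def test_stepwise_drops_pure_noise_covariate():
    rng = np.random.default_rng(5)
    n = 300
    x = rng.normal(size=n)
    t = rng.exponential(size=n)
    trace = backward_stepwise(x[:, None], t, np.ones(n, dtype=bool), ["noise"])
    assert trace.final_names == ()
    assert trace.final_aic == pytest.approx(-2 * null_log_partial_likelihood(t, np.ones(n, bool)))


def test_stepwise_greedy_path_matches_bruteforce():
    """On 5 covariates every greedy candidate AIC equals direct recomputation."""
    rng = np.random.default_rng(8)
    n = 250
    X = rng.normal(size=(n, 5))
    lp = X @ np.array([0.8, 0.0, -0.6, 0.0, 0.0])
    t = rng.exponential(np.exp(-lp))
    c = rng.exponential(2.0, n)
    times, events = np.minimum(t, c), t <= c
    names = list("abcde")
    trace = backward_stepwise(X, times, events, names)

    current = list(names)
    for step in trace.steps:
        assert tuple(current) == step.current_names
        for cand, recorded in step.candidate_aics.items():
            keep = [names.index(k) for k in current if k != cand]
            if keep:
                direct = aic(cox_fit(X[:, keep], times, events))
            else:
                direct = -2 * null_log_partial_likelihood(times, events)
            assert recorded == pytest.approx(direct, abs=1e-8)
        if step.dropped is not None:
            assert step.candidate_aics[step.dropped] == min(step.candidate_aics.values())
            current.remove(step.dropped)
    assert tuple(current) == trace.final_names
    # selection never worsens AIC and keeps the strong effects here
    full_aic = trace.steps[0].current_aic
    assert trace.final_aic <= full_aic
    assert {"a", "c"} <= set(trace.final_names)


def test_stepwise_reports_wald_p_values():
    rng = np.random.default_rng(9)
    n = 300
    X = rng.normal(size=(n, 2))
    t = rng.exponential(np.exp(-0.9 * X[:, 0]))
    c = rng.exponential(2.0, n)
    trace = backward_stepwise(X, np.minimum(t, c), t <= c, ["signal", "noise"])
    p = trace.final_p_values()
    assert set(p) == set(trace.final_names)
    assert p["signal"] < 0.01
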