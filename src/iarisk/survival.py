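"""Time-to-event machinery for biochemical recurrence after prostatectomy.

Covers the full outcome side of the analysis: deriving the biochemical-
recurrence (BCR) endpoint from a post-operative PSA series (event when PSA
rises above 0.2 ng/ml after the post-surgical nadir), the stepwise cohort
exclusion filter, Kaplan–Meier estimation, Cox proportional-hazards fitting
with Breslow tie handling, and backward stepwise model selection by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .scoring import InvalidInputError

__all__ = [
    "BcrOutcome",
    "KmCurve",
    "CoxFit",
    "StepwiseTrace",
    "BCR_THRESHOLD_NG_ML",
    "derive_bcr",
    "stard_filter",
    "km_estimate",
    "km_incidence_at",
    "cox_fit",
    "aic",
    "backward_stepwise",
]

#: Post-nadir serum PSA level (ng/ml) above which BCR is declared.
BCR_THRESHOLD_NG_ML = 0.2

#: Default nadir window after surgery, in days (4–6 weeks).
DEFAULT_NADIR_WINDOW_DAYS = (28, 42)

#: Minimum follow-up for censored patients, in days.
MIN_FOLLOWUP_DAYS = 180

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class BcrOutcome:
    """Biochemical-recurrence endpoint for one patient.

    ``persistent_psa`` marks a patient whose PSA never reached nadir below
    the threshold; such patients are excluded from analysis, not counted as
    events.
    """

    event: bool
    time_years: float
    persistent_psa: bool = False


def derive_bcr(
    psa_series: Sequence[Tuple[float, float]],
    nadir_window_days: Tuple[int, int] = DEFAULT_NADIR_WINDOW_DAYS,
) -> BcrOutcome:
    """Derive the BCR endpoint from a post-operative PSA series.

    The nadir is the measurement inside the 4–6-week window (configurable);
    when no measurement falls in the window, the minimum over the first 90
    days is used.  A nadir at or above 0.2 ng/ml flags persistent PSA.
    Otherwise the event time is the first post-nadir measurement strictly
    above 0.2 ng/ml; a patient who never crosses is censored at the last
    measurement time.
    """
    if len(psa_series) == 0:
        raise InvalidInputError("PSA series is empty")
    times = np.asarray([t for t, _ in psa_series], dtype=float)
    values = np.asarray([v for _, v in psa_series], dtype=float)
    if np.any(np.diff(times) < 0):
        raise InvalidInputError("PSA series times must be sorted")

    lo, hi = (nadir_window_days[0] / _DAYS_PER_YEAR, nadir_window_days[1] / _DAYS_PER_YEAR)
    in_window = (times >= lo) & (times <= hi)
    if in_window.any():
        nadir_idx = int(np.flatnonzero(in_window)[np.argmin(values[in_window])])
    else:
        early = times <= 90.0 / _DAYS_PER_YEAR
        if not early.any():
            early = np.zeros_like(in_window)
            early[0] = True  # fall back to the first measurement
        nadir_idx = int(np.flatnonzero(early)[np.argmin(values[early])])

    if values[nadir_idx] >= BCR_THRESHOLD_NG_ML:
        return BcrOutcome(event=False, time_years=float(times[nadir_idx]), persistent_psa=True)

    post = np.flatnonzero((np.arange(len(times)) > nadir_idx) & (values > BCR_THRESHOLD_NG_ML))
    if post.size:
        return BcrOutcome(event=True, time_years=float(times[post[0]]))
    return BcrOutcome(event=False, time_years=float(times[-1]))


def stard_filter(
    records: Sequence[Tuple[object, BcrOutcome]],
    min_followup_days: int = MIN_FOLLOWUP_DAYS,
) -> Tuple[List[Tuple[object, BcrOutcome]], Dict[str, int]]:
    """Stepwise cohort exclusion with a per-reason tally.

    Exclusions are applied in order: persistent post-operative PSA, then
    event-free follow-up shorter than ``min_followup_days``, then records
    with any missing field.  Each record is a ``(payload, outcome)`` pair;
    a payload with a None attribute or None value counts as missing.
    Idempotent by construction.
    """
    min_fu = min_followup_days / _DAYS_PER_YEAR
    tally: Dict[str, int] = {
        "persistent PSA": 0,
        "follow-up < %d days" % min_followup_days: 0,
        "missing data": 0,
    }
    short_key = "follow-up < %d days" % min_followup_days
    kept: List[Tuple[object, BcrOutcome]] = []
    for payload, outcome in records:
        if outcome.persistent_psa:
            tally["persistent PSA"] += 1
            continue
        if not outcome.event and outcome.time_years < min_fu:
            tally[short_key] += 1
            continue
        if _has_missing(payload):
            tally["missing data"] += 1
            continue
        kept.append((payload, outcome))
    return kept, tally


def _has_missing(payload: object) -> bool:
    if payload is None:
        return True
    if hasattr(payload, "_asdict"):  # namedtuple rows
        values = payload._asdict().values()
    elif hasattr(payload, "__dict__"):
        values = vars(payload).values()
    elif isinstance(payload, dict):
        values = payload.values()
    else:
        values = [payload]
    for v in values:
        if v is None:
            return True
        if isinstance(v, float) and np.isnan(v):
            return True
    return False


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival estimate, defined at observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation: S(t) with S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KmCurve:
    """Kaplan–Meier product-limit estimator with right censoring.

    Ties are handled by processing deaths before censorings at equal times
    (the standard convention).  Delegates to lifelines and reports the curve
    only at observed event times.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape:
        raise InvalidInputError("times and events must have equal length")
    if (t < 0).any():
        raise InvalidInputError("times must be non-negative")

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    mask = table["observed"] > 0
    event_times = table.index.values[mask].astype(float)
    surv = kmf.survival_function_at_times(event_times).values
    at_risk = table["at_risk"].values[mask].astype(int)
    return KmCurve(times=event_times, survival=np.asarray(surv, dtype=float), at_risk=at_risk)


def km_incidence_at(times, events, horizon_years: float) -> float:
    """Cumulative incidence 1 - S(horizon) from the Kaplan–Meier estimate."""
    return 1.0 - km_estimate(times, events).survival_at(horizon_years)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton iteration)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxFit:
    """Fitted Cox proportional-hazards model."""

    coefficients: np.ndarray
    covariance: np.ndarray
    log_partial_likelihood: float
    n_events: int
    converged: bool
    names: Tuple[str, ...] = ()

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def wald_p_values(self) -> np.ndarray:
        from scipy import stats

        se = self.standard_errors
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coefficients / se
        return 2.0 * stats.norm.sf(np.abs(z))


def _prepare_cox(X, times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if t.shape[0] != n or e.shape[0] != n:
        raise InvalidInputError("covariates, times and events must share length")
    if e.sum() == 0:
        raise InvalidInputError("no events in the data")
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < p:
        raise InvalidInputError("covariate matrix is rank deficient (constant or collinear column)")
    # sort by descending time; at tied times events carry the full risk set
    order = np.argsort(-t, kind="stable")
    ts = t[order]
    es = e[order]
    return X, Xc, t, e, order, ts, es


def cox_fit(
    covariate_matrix,
    times,
    events,
    names: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Maximise the Breslow-tie Cox partial likelihood by Newton iteration.

    Converges when the gradient infinity-norm drops below ``tol``.  When the
    partial likelihood has no finite maximiser (complete separation) the fit
    is returned with ``converged=False`` rather than raising.
    """
    X, Xc, t, e, order, ts, es = _prepare_cox(covariate_matrix, times, events)
    n, p = X.shape
    if names is None:
        names = tuple(f"x{i}" for i in range(p))

    # tie structure on the descending-time ordering: tied event times are
    # adjacent; the Breslow risk set at time t is every row with time >= t,
    # i.e. the sorted prefix ending at the last index tied with t
    Xs_all = X[order]
    event_rows = []  # per distinct event time: risk-set end index, x-sum
    tie_counts = []  # number of events at that time
    event_pos = np.flatnonzero(es)
    i = 0
    while i < event_pos.size:
        tt = ts[event_pos[i]]
        j = i
        while j + 1 < event_pos.size and ts[event_pos[j + 1]] == tt:
            j += 1
        g = event_pos[i : j + 1]
        risk_end = int(np.searchsorted(-ts, -tt, side="right") - 1)
        event_rows.append({"risk_end": risk_end, "x_sum": Xs_all[g].sum(axis=0)})
        tie_counts.append(g.size)
        i = j + 1

    def evaluate(beta):
        Xs = Xs_all
        eta = Xs @ beta
        m = eta.max()
        w = np.exp(eta - m)
        cw = np.cumsum(w)
        cwx = np.cumsum(w[:, None] * Xs, axis=0)
        cwxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for rows, d in zip(event_rows, tie_counts):
            s0 = cw[rows["risk_end"]]
            s1 = cwx[rows["risk_end"]]
            s2 = cwxx[rows["risk_end"]]
            xbar = s1 / s0
            ll += float(rows["x_sum"] @ beta) - d * (np.log(s0) + m)
            grad += rows["x_sum"] - d * xbar
            hess += d * (s2 / s0 - np.outer(xbar, xbar))
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = evaluate(beta)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # step halving to guarantee ascent
        new_ll, new_grad, new_hess = evaluate(beta + step)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step *= 0.5
            new_ll, new_grad, new_hess = evaluate(beta + step)
            halvings += 1
        beta = beta + step
        ll, grad, hess = new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > 50:  # likelihood monotone in beta
            break
    else:
        converged = np.max(np.abs(grad)) < tol
    # a coefficient drifting to +/- infinity (complete separation) drives the
    # gradient to zero as well; flag it as non-convergence, as R's coxph warns
    if np.max(np.abs(beta)) > 15 or not np.all(np.isfinite(beta)):
        converged = False

    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return CoxFit(
        coefficients=beta,
        covariance=cov,
        log_partial_likelihood=float(ll),
        n_events=int(e.sum()),
        converged=bool(converged),
        names=tuple(names),
    )


def null_log_partial_likelihood(times, events) -> float:
    """Breslow log partial likelihood of the empty (no-covariate) model."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if e.sum() == 0:
        raise InvalidInputError("no events in the data")
    order = np.argsort(-t, kind="stable")
    ts = t[order]
    es = e[order]
    ll = 0.0
    for tt in np.unique(ts[es]):
        d = int(((ts == tt) & es).sum())
        risk = int(np.searchsorted(-ts, -tt, side="right"))
        ll -= d * np.log(risk)
    return float(ll)


def aic(fit: CoxFit) -> float:
    """Akaike information criterion: -2 logPL + 2k.  Requires a converged fit."""
    if not fit.converged:
        raise InvalidInputError("AIC is undefined for an unconverged fit")
    return -2.0 * fit.log_partial_likelihood + 2.0 * len(fit.coefficients)


@dataclass
class StepwiseStep:
    """One backward-elimination step: candidate AICs and the drop taken."""

    current_names: Tuple[str, ...]
    current_aic: float
    candidate_aics: Dict[str, float]
    dropped: Optional[str]


@dataclass
class StepwiseTrace:
    """Record of a backward stepwise AIC selection."""

    steps: List[StepwiseStep]
    final_names: Tuple[str, ...]
    final_fit: Optional[CoxFit]
    final_aic: float

    def final_p_values(self) -> Dict[str, float]:
        if self.final_fit is None:
            return {}
        return dict(zip(self.final_fit.names, self.final_fit.wald_p_values()))


def backward_stepwise(
    covariate_matrix,
    times,
    events,
    covariate_names: Sequence[str],
) -> StepwiseTrace:
    """Backward elimination on the Cox model, minimising AIC greedily.

    Starting from the full model, at each step the single covariate whose
    removal most decreases AIC is dropped; the procedure stops when no
    removal decreases AIC.  The empty model (AIC = -2 null logPL) is a valid
    endpoint.  Covariates whose Wald p-values exceed 0.05 may legitimately
    survive: stopping is purely AIC-based.
    """
    X = np.asarray(covariate_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = list(covariate_names)
    if X.shape[1] != len(names):
        raise InvalidInputError("covariate_names length must match matrix columns")

    def fit_subset(keep: List[str]) -> Tuple[Optional[CoxFit], float]:
        if not keep:
            return None, -2.0 * null_log_partial_likelihood(times, events)
        idx = [names.index(k) for k in keep]
        f = cox_fit(X[:, idx], times, events, names=keep)
        if not f.converged:
            return f, np.inf
        return f, aic(f)

    current = list(names)
    fit, current_aic = fit_subset(current)
    steps: List[StepwiseStep] = []
    while True:
        candidates = {}
        for name in current:
            _, a = fit_subset([k for k in current if k != name])
            candidates[name] = a
        if not candidates:
            steps.append(StepwiseStep(tuple(current), current_aic, {}, None))
            break
        best = min(candidates, key=candidates.get)
        if candidates[best] < current_aic:
            steps.append(StepwiseStep(tuple(current), current_aic, dict(candidates), best))
            current = [k for k in current if k != best]
            fit, current_aic = fit_subset(current)
        else:
            steps.append(StepwiseStep(tuple(current), current_aic, dict(candidates), None))
            break
    return StepwiseTrace(
        steps=steps, final_names=tuple(current), final_fit=fit, final_aic=current_aic
    )
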