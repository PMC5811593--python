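"""Discrimination and clinical-utility comparison of risk stratifiers.

ROC / AUC with DeLong confidence intervals, the DeLong test for two
correlated AUCs (midrank formulation, appropriate for heavily tied ordinal
markers), decision-curve analysis (net benefit), risk-group reallocation
matrices and per-group outcome tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import InvalidInputError, RiskGroup
from .survival import km_estimate

__all__ = [
    "RocResult",
    "auc_mann_whitney",
    "delong_test",
    "net_benefit",
    "group_risk_to_probability",
    "ReallocationMatrix",
    "reallocation",
    "risk_table",
]


@dataclass(frozen=True)
class RocResult:
    """ROC curve with its Mann–Whitney AUC and DeLong 95% CI."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: Tuple[float, float]


def _check_binary(outcomes) -> np.ndarray:
    y = np.asarray(outcomes).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise InvalidInputError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise InvalidInputError("both outcome classes must be present")
    return y


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """DeLong structural components via midranks.

    Returns (auc, v_cases, v_controls): the placement values whose means are
    the AUC and whose empirical variances give the DeLong variance.
    """
    cases = scores[y == 1]
    controls = scores[y == 0]
    m, n = len(cases), len(controls)
    all_r = stats.rankdata(np.concatenate([cases, controls]))
    r_cases = stats.rankdata(cases)
    r_controls = stats.rankdata(controls)
    v_cases = (all_r[:m] - r_cases) / n  # P(score_control < case) + half ties
    v_controls = 1.0 - (all_r[m:] - r_controls) / m
    auc = float(v_cases.mean())
    return auc, v_cases, v_controls


def auc_mann_whitney(scores, outcomes) -> RocResult:
    """AUC as normalised pairwise concordance, with the full ROC curve.

    AUC = P(score_case > score_control) + 0.5 * P(tie), computed exactly
    through midranks; the 95% CI uses the DeLong variance.
    """
    y = _check_binary(outcomes)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise InvalidInputError("scores and outcomes must have equal length")

    auc, v_cases, v_controls = _structural_components(s, y)
    m, n = int(y.sum()), int((1 - y).sum())
    var = (np.var(v_cases, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v_controls, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    # ROC curve over the distinct score values (descending), padded so the
    # curve runs from (0, 0) to (1, 1) in (1 - specificity, sensitivity)
    thr = np.concatenate([[np.inf], np.unique(s)[::-1], [-np.inf]])
    sens = np.array([np.mean(s[y == 1] >= t) for t in thr])
    spec = np.array([np.mean(s[y == 0] < t) for t in thr])
    return RocResult(thresholds=thr, sensitivity=sens, specificity=spec, auc=auc, auc_ci=ci)


def delong_test(scores_a, scores_b, outcomes) -> Tuple[float, float, float, float]:
    """DeLong's test for two correlated AUCs measured on the same subjects.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value.  The
    covariance of the paired AUCs comes from the empirical covariance of the
    structural components.
    """
    y = _check_binary(outcomes)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise InvalidInputError("paired scores and outcomes must share length")

    auc_a, va1, va0 = _structural_components(a, y)
    auc_b, vb1, vb0 = _structural_components(b, y)
    m, n = len(va1), len(va0)

    s10 = np.cov(np.vstack([va1, vb1]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va0, vb0]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0
        p = 1.0
    else:
        z = diff / np.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def net_benefit(predicted_risk, outcomes, threshold_grid) -> pd.DataFrame:
    """Decision-curve analysis: net benefit over a threshold-probability grid.

    NB(pt) = TP/n - (FP/n) * pt / (1 - pt) for the "classify positive when
    predicted risk >= pt" rule, alongside the treat-all and treat-none
    reference strategies.
    """
    y = np.asarray(outcomes).astype(int)
    r = np.asarray(predicted_risk, dtype=float)
    pt = np.asarray(threshold_grid, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise InvalidInputError("predicted risks must be in [0, 1]")
    if np.any((pt <= 0) | (pt >= 1)):
        raise InvalidInputError("thresholds must be strictly inside (0, 1)")
    n = len(y)
    prevalence = y.mean()
    rows = []
    for t in pt:
        treat = r >= t
        tp = np.sum(treat & (y == 1)) / n
        fp = np.sum(treat & (y == 0)) / n
        odds = t / (1.0 - t)
        rows.append(
            {
                "threshold": t,
                "net_benefit": tp - fp * odds,
                "treat_all": prevalence - (1.0 - prevalence) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def group_risk_to_probability(
    groups: Sequence[RiskGroup],
    times,
    events,
    horizon_years: float = 2.0,
) -> np.ndarray:
    """Per-patient predicted risk: the group's KM cumulative incidence at a horizon.

    Puts an ordinal three-level stratifier on the probability scale decision
    curves require.  A group with zero members contributes no predictions
    (its would-be members do not exist); NaN is never emitted for observed
    patients.
    """
    g = np.asarray([grp.value for grp in groups])
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    risk = np.empty(len(g), dtype=float)
    for level in np.unique(g):
        mask = g == level
        if not e[mask].any():
            risk[mask] = 0.0
            continue
        km = km_estimate(t[mask], e[mask])
        risk[mask] = 1.0 - km.survival_at(horizon_years)
    return risk


@dataclass(frozen=True)
class ReallocationMatrix:
    """3x3 cross-tabulation of base risk group (rows) vs adjusted group (columns)."""

    counts: pd.DataFrame  # index/columns: low, intermediate, high

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    def moved_up_fraction(self, base: RiskGroup) -> float:
        """Fraction of a base group reallocated to any higher group."""
        row = self.counts.loc[base.label]
        denom = row.sum()
        if denom == 0:
            return float("nan")
        higher = [g.label for g in RiskGroup if g.value > base.value]
        return float(row[higher].sum() / denom)

    def moved_down_fraction(self, base: RiskGroup) -> float:
        row = self.counts.loc[base.label]
        denom = row.sum()
        if denom == 0:
            return float("nan")
        lower = [g.label for g in RiskGroup if g.value < base.value]
        return float(row[lower].sum() / denom)


_GROUP_LABELS = [g.label for g in RiskGroup]


def reallocation(
    base_groups: Sequence[RiskGroup], adjusted_groups: Sequence[RiskGroup]
) -> ReallocationMatrix:
    """Cross-tabulate base vs image-adjusted group membership."""
    if len(base_groups) != len(adjusted_groups):
        raise InvalidInputError("group vectors must share length")
    counts = pd.DataFrame(0, index=_GROUP_LABELS, columns=_GROUP_LABELS, dtype=int)
    for b, a in zip(base_groups, adjusted_groups):
        counts.loc[b.label, a.label] += 1
    return ReallocationMatrix(counts=counts)


def risk_table(groups: Sequence[RiskGroup], outcomes) -> pd.DataFrame:
    """Per-group event counts, totals and rates ("events/total", percentage)."""
    y = np.asarray(outcomes).astype(int)
    g = np.asarray([grp.label for grp in groups])
    rows = []
    for label in _GROUP_LABELS:
        mask = g == label
        n_total = int(mask.sum())
        n_events = int(y[mask].sum())
        rate = n_events / n_total if n_total else float("nan")
        rows.append(
            {
                "group": label,
                "n_total": n_total,
                "n_events": n_events,
                "event_rate": rate,
                "display": f"{n_events}/{n_total}"
                + (f" ({100 * rate:.1f}%)" if n_total else " (—)"),
            }
        )
    return pd.DataFrame(rows)
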