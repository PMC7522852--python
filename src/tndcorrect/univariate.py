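"""Corrected odds ratio and confidence interval for 2x2 TND tables.

The corrected odds ratio inverts the classification matrix within each
vaccination stratum and forms the odds ratio of the reconstructed true counts;
it is the maximum-likelihood estimator of the relative risk gamma under the
misclassified observation model. The log odds ratio is treated as normal with
a delta-method variance under independent Poisson counts, giving the
confidence interval on VE = 1 - gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classification import (
    CountTable2x2,
    NonIdentifiableTestError,
    TestPerformance,
)

__all__ = [
    "EffectEstimate",
    "CorrectedORResult",
    "corrected_odds_ratio",
    "corrected_ve_interval",
    "sensitivity_grid",
]


@dataclass(frozen=True)
class CorrectedORResult:
    """Corrected odds ratio with its four reconstructed components.

    ``components`` holds (A_V, B_V, A_U, B_U): the reconstructed true
    case/non-case counts per stratum, up to the positive factor 1/c.  When any
    component is negative the point estimate is truncated to 0 or +inf and
    ``truncated`` is set; such estimates correspond to boundary MLEs (VE of
    exactly 100% or -100% on the odds-ratio scale) and carry no interval.
    """

    odds_ratio: float
    components: tuple[float, float, float, float]
    truncated: bool


@dataclass(frozen=True)
class EffectEstimate:
    """VE point estimate with log-odds-ratio scale uncertainty.

    ``ve_point`` is on the fraction scale (0.8 means 80% effectiveness).
    ``log_or_se`` is the shape parameter sigma of the log-normal odds-ratio
    distribution.  Truncated estimates (a reconstructed component was
    negative) report ve_point 1.0 or -inf and NaN uncertainty, and must be
    summarised separately downstream.
    """

    ve_point: float
    log_or: float
    log_or_se: float
    ci_lower: float
    ci_upper: float
    level: float
    truncated: bool


def _stratum_components(pos: float, neg: float, perf: TestPerformance) -> tuple[float, float]:
    a, b = perf.sensitivity, perf.specificity
    A = b * pos - (1.0 - b) * neg  # proportional to reconstructed true cases
    B = a * neg - (1.0 - a) * pos  # proportional to reconstructed true non-cases
    return A, B


def corrected_odds_ratio(
    observed: CountTable2x2, perf: TestPerformance
) -> CorrectedORResult:
    """Misclassification-corrected odds ratio from an observed 2x2 table.

    gamma* = [(beta*X_V - (1-beta)*Y_V) * (alpha*Y_U - (1-alpha)*X_U)]
             / [(alpha*Y_V - (1-alpha)*X_V) * (beta*X_U - (1-beta)*Y_U)]

    With a perfect test this reduces to the crude odds ratio.  Negative
    components are truncated to zero (true counts cannot be negative), making
    the estimate 0 or +inf with the ``truncated`` flag set rather than raising:
    these are legitimate boundary MLEs, though increasing the sample size or
    redesigning the study is advisable when they occur.
    """
    perf.require_invertible()
    t = observed
    if min(t.pos_vacc, t.neg_vacc, t.pos_unvacc, t.neg_unvacc) < 0:
        raise ValueError("observed counts must be non-negative")
    if t.total_vacc == 0 or t.total_unvacc == 0:
        raise ValueError("each vaccination stratum needs at least one observation")
    A_V, B_V = _stratum_components(t.pos_vacc, t.neg_vacc, perf)
    A_U, B_U = _stratum_components(t.pos_unvacc, t.neg_unvacc, perf)
    components = (A_V, B_V, A_U, B_U)
    if min(components) < 0:
        num = max(A_V, 0.0) * max(B_U, 0.0)
        den = max(B_V, 0.0) * max(A_U, 0.0)
        or_trunc = 0.0 if num == 0.0 else math.inf
        return CorrectedORResult(odds_ratio=or_trunc, components=components, truncated=True)
    if A_V * B_U == 0.0 and B_V * A_U == 0.0:
        return CorrectedORResult(odds_ratio=math.nan, components=components, truncated=True)
    if B_V * A_U == 0.0:
        return CorrectedORResult(odds_ratio=math.inf, components=components, truncated=True)
    odds_ratio = (A_V * B_U) / (B_V * A_U)
    return CorrectedORResult(
        odds_ratio=odds_ratio, components=components, truncated=(odds_ratio == 0.0)
    )


def log_or_sigma(observed: CountTable2x2, perf: TestPerformance) -> float:
    """Delta-method standard error of log gamma* under Poisson counts.

    Each observed count is treated as an independent Poisson draw; the partial
    derivatives of log gamma* with respect to the four counts give

        sigma^2 = X_V*(beta/A_V + (1-alpha)/B_V)^2
                + Y_V*((1-beta)/A_V + alpha/B_V)^2
                + X_U*(beta/A_U + (1-alpha)/B_U)^2
                + Y_U*((1-beta)/A_U + alpha/B_U)^2

    which reduces to the classical Woolf variance 1/X_V + 1/Y_V + 1/X_U + 1/Y_U
    for a perfect test.  Requires all four components strictly positive.
    """
    a, b = perf.sensitivity, perf.specificity
    t = observed
    A_V, B_V = _stratum_components(t.pos_vacc, t.neg_vacc, perf)
    A_U, B_U = _stratum_components(t.pos_unvacc, t.neg_unvacc, perf)
    if min(A_V, B_V, A_U, B_U) <= 0:
        raise ValueError("all reconstructed components must be strictly positive")
    var = (
        t.pos_vacc * (b / A_V + (1.0 - a) / B_V) ** 2
        + t.neg_vacc * ((1.0 - b) / A_V + a / B_V) ** 2
        + t.pos_unvacc * (b / A_U + (1.0 - a) / B_U) ** 2
        + t.neg_unvacc * ((1.0 - b) / A_U + a / B_U) ** 2
    )
    return math.sqrt(var)


def corrected_ve_interval(
    observed: CountTable2x2,
    perf: TestPerformance,
    level: float = 0.95,
) -> EffectEstimate:
    """Corrected VE with a log-normal confidence interval.

    Assumes log-normality of the corrected odds ratio with the delta-method
    shape parameter of :func:`log_or_sigma`; the interval on VE is
    ``1 - exp(log gamma* -/+ z*sigma)``.  If the point estimate is truncated
    no interval is available: the estimate is returned flagged, with NaN
    bounds, since the boundary MLE carries no usable normal approximation —
    increasing sample size or redesigning the study is recommended.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    res = corrected_odds_ratio(observed, perf)
    if res.truncated:
        ve = 1.0 if res.odds_ratio == 0.0 else -math.inf
        if math.isnan(res.odds_ratio):
            ve = math.nan
        return EffectEstimate(
            ve_point=ve,
            log_or=math.log(res.odds_ratio) if res.odds_ratio > 0 else -math.inf,
            log_or_se=math.nan,
            ci_lower=math.nan,
            ci_upper=math.nan,
            level=level,
            truncated=True,
        )
    sigma = log_or_sigma(observed, perf)
    log_or = math.log(res.odds_ratio)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return EffectEstimate(
        ve_point=1.0 - res.odds_ratio,
        log_or=log_or,
        log_or_se=sigma,
        ci_lower=1.0 - math.exp(log_or + z * sigma),
        ci_upper=1.0 - math.exp(log_or - z * sigma),
        level=level,
        truncated=False,
    )


def sensitivity_grid(
    observed: CountTable2x2,
    alpha_grid: np.ndarray,
    beta_grid: np.ndarray,
) -> pd.DataFrame:
    """Corrected VE over a lattice of assumed sensitivity/specificity values.

    Useful as a post-hoc sensitivity analysis when the true test performance
    is uncertain: the corrected odds ratio is monotone in both sensitivity and
    specificity while all reconstructed components stay positive, so the
    extreme assumed values bound the plausible VE range.  The cell at
    sensitivity = specificity = 1 reproduces the crude VE.

    Returns a long-format frame with columns ``alpha, beta, ve, truncated,
    evaluable``; grid points with Youden index <= 0 are marked not evaluable.
    """
    rows = []
    for a in np.atleast_1d(alpha_grid):
        for b in np.atleast_1d(beta_grid):
            if not (0.0 < a <= 1.0 and 0.0 < b <= 1.0):
                raise ValueError("grid values must lie in (0, 1]")
            try:
                res = corrected_odds_ratio(observed, TestPerformance(float(a), float(b)))
            except NonIdentifiableTestError:
                rows.append(dict(alpha=a, beta=b, ve=np.nan, truncated=False, evaluable=False))
                continue
            rows.append(
                dict(
                    alpha=a,
                    beta=b,
                    ve=1.0 - res.odds_ratio,
                    truncated=res.truncated,
                    evaluable=True,
                )
            )
    return pd.DataFrame(rows)
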