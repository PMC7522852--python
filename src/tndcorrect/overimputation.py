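"""Multiple overimputation (MO) bias correction with parametric bootstrapping.

The direct-likelihood fit requires re-defining the estimation tool's
likelihood, which is impractical with off-the-shelf software. MO instead
corrects the data: the estimator is fitted once to the raw line list to obtain
a predicted positive probability per record, the Bayes flipping probabilities
are computed through the inverted classification matrix, and J copies of the
dataset are generated in which each observed test result is stochastically
flipped. Re-fitting the unmodified estimator on each copy and pooling the J
estimates with Rubin's rules yields a bias-corrected VE without touching the
estimator's internals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import TestPerformance, flip_probabilities

__all__ = [
    "AdapterResult",
    "PooledEstimate",
    "logistic_adapter",
    "impute_outcomes",
    "run_overimputation",
]

_PROB_EPS = 1e-9


@dataclass(frozen=True)
class AdapterResult:
    """What an estimation tool must return to participate in overimputation.

    Attributes
    ----------
    log_or : float
        Point estimate of the vaccination log odds ratio (VE = 1 - exp(log_or)).
    log_or_var : float
        Its sampling variance (squared standard error), used as the
        within-imputation variance in Rubin's rules.
    predicted_positive : ndarray or None
        Per-record predicted probability of a positive outcome; required when
        the adapter is fitted to the raw data (the parametric-bootstrap step),
        ignored on imputed copies.
    """

    log_or: float
    log_or_var: float
    predicted_positive: np.ndarray | None = None


Adapter = Callable[[pd.DataFrame], AdapterResult]


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules pooled VE over J overimputed datasets.

    Pooling is done on the log-odds-ratio scale, where approximate normality
    holds; the total variance is within + (1 + 1/J) * between, and the CI uses
    a t reference with the standard small-sample degrees of freedom
    (J - 1) * (1 + within / ((1 + 1/J) * between))^2.
    """

    estimates: np.ndarray
    log_or: float
    within_var: float
    between_var: float
    total_var: float
    ve: float
    ci_lower: float
    ci_upper: float
    level: float
    n_imputations: int
    n_failed: int

    @property
    def log_or_se(self) -> float:
        return float(np.sqrt(self.total_var))


def logistic_adapter(
    covariates: Sequence[str] = (),
    outcome_col: str = "outcome",
    vaccinated_col: str = "vaccinated",
) -> Adapter:
    """Adapter wrapping ordinary (misclassification-naive) logistic regression.

    This is the canonical "existing tool" the MO corrector is designed around:
    it knows nothing about test error, and all correction happens in the data.
    """
    import statsmodels.api as sm

    cols = [vaccinated_col, *covariates]

    def _fit(data: pd.DataFrame) -> AdapterResult:
        X = sm.add_constant(data[cols].to_numpy(dtype=float), has_constant="add")
        y = data[outcome_col].to_numpy(dtype=float)
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("logistic regression did not converge")
        return AdapterResult(
            log_or=float(fit.params[1]),
            log_or_var=float(fit.bse[1] ** 2),
            predicted_positive=np.asarray(fit.predict(X)),
        )

    return _fit


def impute_outcomes(
    data: pd.DataFrame,
    predicted_probs: np.ndarray,
    perf: TestPerformance,
    rng: np.random.Generator,
    outcome_col: str = "outcome",
) -> pd.DataFrame:
    """One overimputed copy of the line list: observed outcomes stochastically
    flipped at the Bayes probability that the test result is wrong.

    ``predicted_probs`` is the estimator's predicted positive probability per
    record, used as a proxy for the observed-positive probability when
    inverting the classification matrix. Covariates are untouched; with a
    perfect test the copy equals the input.
    """
    z = data[outcome_col].to_numpy()
    p = np.clip(np.asarray(predicted_probs, dtype=float), _PROB_EPS, 1.0 - _PROB_EPS)
    phi_plus, phi_minus = flip_probabilities(p, perf)
    flip_prob = np.where(z == 1, phi_plus, phi_minus)
    flipped = rng.random(len(z)) < flip_prob
    out = data.copy()
    out[outcome_col] = np.where(flipped, 1 - z, z)
    return out


def run_overimputation(
    data: pd.DataFrame,
    estimator: Adapter,
    perf: TestPerformance,
    n_imputations: int = 100,
    rng: np.random.Generator | int | None = None,
    level: float = 0.95,
    outcome_col: str = "outcome",
    max_failure_fraction: float = 0.2,
) -> PooledEstimate:
    """Full MO bias correction: parametric bootstrap, J imputations, pooling.

    Steps: (1) fit the estimator to the raw data once to obtain predicted
    positive probabilities; (2) generate an imputed dataset with
    :func:`impute_outcomes` and refit; (3) repeat J times and pool the log-OR
    estimates by Rubin's rules. Reproducible given the ``rng`` seed.

    Estimator failures on individual imputed copies are skipped and counted;
    more than ``max_failure_fraction`` of failures aborts with an error.
    """
    if n_imputations < 2:
        raise ValueError("at least 2 imputations are required for Rubin pooling")
    perf.require_invertible()
    rng = np.random.default_rng(rng)

    base = estimator(data)
    if base.predicted_positive is None:
        raise ValueError(
            "the estimator must return per-record predicted positive "
            "probabilities when fitted to the raw data"
        )
    p_hat = np.asarray(base.predicted_positive, dtype=float)
    if len(p_hat) != len(data):
        raise ValueError("predicted probabilities must have one entry per record")

    points, variances = [], []
    n_failed = 0
    for _ in range(n_imputations):
        imputed = impute_outcomes(data, p_hat, perf, rng, outcome_col=outcome_col)
        try:
            res = estimator(imputed)
        except Exception:
            n_failed += 1
            continue
        points.append(res.log_or)
        variances.append(res.log_or_var)
    if n_failed > max_failure_fraction * n_imputations or len(points) < 2:
        raise RuntimeError(
            f"{n_failed}/{n_imputations} imputed refits failed; the pooled "
            "estimate would be unreliable"
        )

    est = np.asarray(points)
    j = len(est)
    q_bar = float(est.mean())
    within = float(np.mean(variances))
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / j) * between

    if between > 0.0:
        df = (j - 1) * (1.0 + within / ((1.0 + 1.0 / j) * between)) ** 2
        q = stats.t.ppf(0.5 + level / 2.0, df)
    else:
        q = stats.norm.ppf(0.5 + level / 2.0)
    half = q * np.sqrt(total)
    return PooledEstimate(
        estimates=est,
        log_or=q_bar,
        within_var=within,
        between_var=between,
        total_var=total,
        ve=1.0 - np.exp(q_bar),
        ci_lower=1.0 - np.exp(q_bar + half),
        ci_upper=1.0 - np.exp(q_bar - half),
        level=level,
        n_imputations=j,
        n_failed=n_failed,
    )
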