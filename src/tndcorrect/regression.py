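"""Misclassification-aware logistic regression (direct likelihood method).

An ordinary logistic TND analysis models the probability ``p1(xi; theta)``
that a patient with covariates xi truly has the target disease and assumes
the test result equals the true state. With an imperfect test the observed
positive probability is instead

    pi_plus(xi) = alpha * p1(xi) + (1 - beta) * (1 - p1(xi))

and the maximum-likelihood estimate of theta comes from maximising the
Bernoulli likelihood of the observed results under pi_plus. The vaccination
coefficient theta_1 gives VE = 1 - exp(theta_1), identical across covariate
profiles because of the linear predictor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from statsmodels.tools import numdiff

from .classification import TestPerformance

__all__ = [
    "observed_positive_prob",
    "MisclassifiedLogisticRegression",
    "fit_misclassified_logistic",
    "ve_for_covariates",
]

_PROB_EPS = 1e-12


def observed_positive_prob(
    p1: np.ndarray | float, perf: TestPerformance
) -> np.ndarray | float:
    """Probability of an observed positive test given the true-state probability.

    pi_plus = alpha*p1 + (1-beta)*(1-p1): affine in p1, with floor 1-beta
    (false positives) and ceiling alpha (sensitivity), strictly increasing in
    p1 whenever the Youden index is positive.
    """
    a, b = perf.sensitivity, perf.specificity
    return a * np.asarray(p1, dtype=float) + (1.0 - b) * (1.0 - np.asarray(p1, dtype=float))


def _design(X: np.ndarray, fit_intercept: bool) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if fit_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    return X


def _neg_loglik_and_grad(
    theta: np.ndarray,
    X: np.ndarray,
    z: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood of observed outcomes and its analytic gradient."""
    eta = X @ theta
    p1 = special.expit(eta)
    c = alpha + beta - 1.0
    pi_plus = np.clip((1.0 - beta) + c * p1, _PROB_EPS, 1.0 - _PROB_EPS)
    pi_minus = 1.0 - pi_plus
    ll = np.sum(z * np.log(pi_plus) + (1.0 - z) * np.log(pi_minus))
    # d pi_plus / d theta = c * p1 * (1 - p1) * x
    w = (z / pi_plus - (1.0 - z) / pi_minus) * c * p1 * (1.0 - p1)
    grad = X.T @ w
    return -ll, -grad


class MisclassifiedLogisticRegression(BaseEstimator):
    """Logistic regression whose binary outcome is observed through an
    imperfect diagnostic test.

    The model is fit by directly maximising the misclassification-aware
    likelihood with a quasi-Newton optimiser and analytic gradient, warm
    started at the ordinary logistic fit. With a perfect test it coincides
    with ordinary logistic regression.

    Parameters
    ----------
    sensitivity, specificity : float, default 1.0
        Assumed test performance. Per-record values may be supplied to
        :meth:`fit` instead (e.g. for datasets mixing several test kinds);
        the Youden index must be positive for every record.
    fit_intercept : bool, default True
        Prepend an intercept column to the design matrix.
    vaccination_col : int, default 0
        Index (into the covariate matrix, excluding the intercept) of the
        binary vaccination-history covariate used for the VE estimate.
    confidence_level : float, default 0.95
        Level of the Wald interval on VE.

    Attributes
    ----------
    theta_ : ndarray
        Full coefficient vector (intercept first when fitted).
    coef_, intercept_ : coefficient split in scikit-learn convention.
    cov_ : ndarray
        Inverse observed information at the optimum.
    ve_, ve_se_log_or_, ve_ci_ : VE point estimate ``1 - exp(theta_1)``, the
        standard error of theta_1, and the Wald interval on VE.
    converged_ : bool, loglik_ : float
        Optimiser diagnostics.
    """

    def __init__(
        self,
        sensitivity: float = 1.0,
        specificity: float = 1.0,
        fit_intercept: bool = True,
        vaccination_col: int = 0,
        confidence_level: float = 0.95,
        max_iter: int = 500,
        tol: float = 1e-10,
    ):
        self.sensitivity = sensitivity
        self.specificity = specificity
        self.fit_intercept = fit_intercept
        self.vaccination_col = vaccination_col
        self.confidence_level = confidence_level
        self.max_iter = max_iter
        self.tol = tol

    def _resolve_perf(self, n: int, sensitivity, specificity) -> tuple[np.ndarray, np.ndarray]:
        a = self.sensitivity if sensitivity is None else sensitivity
        b = self.specificity if specificity is None else specificity
        a = np.broadcast_to(np.asarray(a, dtype=float), (n,)).copy()
        b = np.broadcast_to(np.asarray(b, dtype=float), (n,)).copy()
        if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
            raise ValueError("sensitivity and specificity must lie in [0, 1]")
        if np.any(a + b - 1.0 <= 0.0):
            raise ValueError(
                "every record needs Youden index sensitivity + specificity - 1 > 0; "
                "consider swapping the positive/negative test definitions"
            )
        return a, b

    def fit(self, X, y, sensitivity=None, specificity=None):
        """Fit by direct maximisation of the misclassified likelihood.

        Parameters
        ----------
        X : array-like of shape (n, p)
            Covariates; column ``vaccination_col`` must be binary vaccination
            history.
        y : array-like of shape (n,)
            Observed test results (1 = positive).
        sensitivity, specificity : float or array-like, optional
            Per-record test performance overriding the constructor scalars.
        """
        Xd = _design(X, self.fit_intercept)
        z = np.asarray(y, dtype=float).ravel()
        if len(z) != len(Xd):
            raise ValueError("X and y have inconsistent lengths")
        if not np.all(np.isin(z, [0.0, 1.0])):
            raise ValueError("outcomes must be binary 0/1")
        if len(z) < Xd.shape[1]:
            raise ValueError("need at least as many records as coefficients")
        a, b = self._resolve_perf(len(z), sensitivity, specificity)

        starts = [self._warm_start(Xd, z), np.zeros(Xd.shape[1])]
        best = None
        for theta0 in starts:
            res = optimize.minimize(
                _neg_loglik_and_grad,
                theta0,
                args=(Xd, z, a, b),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None
        if not best.success and np.linalg.norm(best.jac, ord=np.inf) > 1e-4 * len(z):
            raise RuntimeError(
                f"misclassified-likelihood optimisation failed to converge: {best.message}"
            )
        theta = best.x
        if np.max(np.abs(theta)) > 15.0:
            warnings.warn(
                "extreme coefficients suggest (quasi-)separation; estimates and "
                "Wald intervals may be unreliable",
                stacklevel=2,
            )
        hess = numdiff.approx_hess(
            theta, lambda t: _neg_loglik_and_grad(t, Xd, z, a, b)[0]
        )
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.full_like(hess, np.nan)

        self.theta_ = theta
        self.cov_ = cov
        self.converged_ = bool(best.success)
        self.loglik_ = -best.fun
        self.n_features_in_ = Xd.shape[1] - int(self.fit_intercept)
        if self.fit_intercept:
            self.intercept_ = theta[0]
            self.coef_ = theta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = theta
        k = self.vaccination_col
        log_or = self.coef_[k]
        se = float(np.sqrt(cov[k + int(self.fit_intercept), k + int(self.fit_intercept)]))
        z_q = stats.norm.ppf(0.5 + self.confidence_level / 2.0)
        self.ve_ = 1.0 - np.exp(log_or)
        self.ve_se_log_or_ = se
        self.ve_ci_ = (1.0 - np.exp(log_or + z_q * se), 1.0 - np.exp(log_or - z_q * se))
        self._fit_alpha = a
        self._fit_beta = b
        return self

    @staticmethod
    def _warm_start(Xd: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Ordinary logistic fit, used as the optimiser starting point."""
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(z, Xd).fit(disp=0, maxiter=100)
            theta = np.asarray(fit.params, dtype=float)
            if np.all(np.isfinite(theta)):
                return np.clip(theta, -10.0, 10.0)
        except Exception:
            pass
        return np.zeros(Xd.shape[1])

    def predict_true_proba(self, X) -> np.ndarray:
        """Model probability that the true disease state is the target disease."""
        return special.expit(_design(X, self.fit_intercept) @ self.theta_)

    def predict_proba(self, X, sensitivity=None, specificity=None) -> np.ndarray:
        """Probability of each observed test result, columns (negative, positive).

        The positive column is pi_plus = alpha*p1 + (1-beta)*(1-p1) under the
        test performance the model was fitted with (or per-record overrides).
        """
        p1 = self.predict_true_proba(X)
        a = self._fit_alpha.mean() if sensitivity is None else sensitivity
        b = self._fit_beta.mean() if specificity is None else specificity
        pi_plus = np.asarray(a) * p1 + (1.0 - np.asarray(b)) * (1.0 - p1)
        return np.column_stack([1.0 - pi_plus, pi_plus])

    def score(self, X, y) -> float:
        """Mean log-likelihood of observed outcomes under the fitted model."""
        Xd = _design(X, self.fit_intercept)
        z = np.asarray(y, dtype=float).ravel()
        a, b = self._resolve_perf(len(z), None, None)
        nll, _ = _neg_loglik_and_grad(self.theta_, Xd, z, a, b)
        return -nll / len(z)


def fit_misclassified_logistic(
    data: pd.DataFrame,
    perf: TestPerformance | None = None,
    covariates: list[str] | None = None,
    outcome_col: str = "outcome",
    vaccinated_col: str = "vaccinated",
    sensitivity=None,
    specificity=None,
    confidence_level: float = 0.95,
) -> MisclassifiedLogisticRegression:
    """Fit the direct-likelihood model from a line-list data frame.

    ``covariates`` lists additional adjustment columns (the vaccination column
    is always included first). Per-record performance can be given as column
    names or arrays via ``sensitivity``/``specificity``; otherwise ``perf``
    supplies scalars.
    """
    covariates = covariates or []
    cols = [vaccinated_col] + list(covariates)
    X = data[cols].to_numpy(dtype=float)
    y = data[outcome_col].to_numpy(dtype=float)

    def _col_or_value(v):
        if isinstance(v, str):
            return data[v].to_numpy(dtype=float)
        return v

    a = _col_or_value(sensitivity)
    b = _col_or_value(specificity)
    if a is None and perf is not None:
        a = perf.sensitivity
    if b is None and perf is not None:
        b = perf.specificity
    model = MisclassifiedLogisticRegression(
        sensitivity=1.0 if a is None else 1.0,
        specificity=1.0 if b is None else 1.0,
        confidence_level=confidence_level,
    )
    return model.fit(X, y, sensitivity=a, specificity=b)


def ve_for_covariates(fit: MisclassifiedLogisticRegression, covariate_profile=None) -> float:
    """VE for an individual with the given (non-vaccination) covariate profile.

    Under the logistic model the vaccination odds ratio does not depend on the
    other covariates, so the profile is accepted for interface generality but
    the returned VE equals ``1 - exp(theta_1)`` for every profile.
    """
    return float(fit.ve_)
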