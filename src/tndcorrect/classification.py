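"""Classification-matrix algebra for outcome misclassification in TND studies.

A diagnostic test with sensitivity ``alpha`` and specificity ``beta`` maps the
true disease state (target disease vs. non-target disease) of each
medically-attended patient to an observed test result through the
column-stochastic classification matrix

    C = [[alpha, 1 - beta],
         [1 - alpha, beta]]

whose determinant ``c = alpha + beta - 1`` is the Youden index of the test.
All bias-correction estimators in this package reduce to linear algebra on C:
the forward model multiplies true counts by C, and every correction inverts it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

_log = logging.getLogger(__name__)

__all__ = [
    "TestPerformance",
    "CountTable2x2",
    "BiasQuery",
    "NonIdentifiableTestError",
    "classification_matrix",
    "misclassify_expected",
    "invert_counts",
    "expected_bias",
    "flip_probabilities",
]


class NonIdentifiableTestError(ValueError):
    """Raised when an inverse operation is requested with Youden index <= 0."""


@dataclass(frozen=True)
class TestPerformance:
    """Sensitivity/specificity pair of a diagnostic test.

    Parameters
    ----------
    sensitivity : float
        Probability that a true target-disease case tests positive (alpha).
    specificity : float
        Probability that a non-target-disease case tests negative (beta).

    Notes
    -----
    The Youden index ``c = alpha + beta - 1`` measures the information the
    test retains; ``c = 0`` means test results are uninformative and ``c < 0``
    means the positive/negative labels are anti-predictive.  Construction with
    ``c <= 0`` is permitted (the forward model is still well defined) but
    every inverse operation raises :class:`NonIdentifiableTestError`.
    """

    __test__ = False  # name starts with "Test" but this is not a test case

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError(f"sensitivity must be in [0, 1], got {self.sensitivity}")
        if not (0.0 <= self.specificity <= 1.0):
            raise ValueError(f"specificity must be in [0, 1], got {self.specificity}")

    @property
    def youden(self) -> float:
        """Youden index c = sensitivity + specificity - 1."""
        return self.sensitivity + self.specificity - 1.0

    @property
    def is_perfect(self) -> bool:
        return self.sensitivity == 1.0 and self.specificity == 1.0

    def require_invertible(self) -> None:
        """Raise unless the classification matrix can be inverted (c > 0)."""
        if self.youden <= 0.0:
            raise NonIdentifiableTestError(
                f"Youden index {self.youden:.4g} <= 0: the test is not predictive "
                "and misclassification cannot be inverted. If the index is "
                "negative, swapping the positive/negative test definitions "
                "yields a usable test."
            )


@dataclass(frozen=True)
class CountTable2x2:
    """2x2 table of TND counts: test result (pos/neg) by vaccination status.

    ``is_observed`` distinguishes observed (possibly misclassified) counts
    from latent true counts; reconstructed tables may carry non-integer and
    even negative entries, which callers decide how to truncate.
    """

    pos_vacc: float
    pos_unvacc: float
    neg_vacc: float
    neg_unvacc: float
    is_observed: bool = True

    @property
    def total(self) -> float:
        return self.pos_vacc + self.pos_unvacc + self.neg_vacc + self.neg_unvacc

    @property
    def total_vacc(self) -> float:
        return self.pos_vacc + self.neg_vacc

    @property
    def total_unvacc(self) -> float:
        return self.pos_unvacc + self.neg_unvacc

    def as_array(self) -> np.ndarray:
        """Return the table as a 2x2 array: rows pos/neg, columns vacc/unvacc."""
        return np.array(
            [[self.pos_vacc, self.pos_unvacc], [self.neg_vacc, self.neg_unvacc]],
            dtype=float,
        )

    @classmethod
    def from_array(cls, arr: np.ndarray, is_observed: bool = True) -> "CountTable2x2":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (2, 2):
            raise ValueError(f"expected a 2x2 array, got shape {arr.shape}")
        return cls(
            pos_vacc=arr[0, 0],
            pos_unvacc=arr[0, 1],
            neg_vacc=arr[1, 0],
            neg_unvacc=arr[1, 1],
            is_observed=is_observed,
        )

    def crude_odds_ratio(self) -> float:
        """Raw odds ratio (pos_vacc/neg_vacc) / (pos_unvacc/neg_unvacc)."""
        return (self.pos_vacc * self.neg_unvacc) / (self.neg_vacc * self.pos_unvacc)


@dataclass(frozen=True)
class BiasQuery:
    """Parameters of the analytic expected-bias function.

    ``gamma`` is the relative risk of the target disease in vaccinated vs.
    unvaccinated (VE = 1 - gamma) and ``delta`` the odds of medically-attended
    target disease among unvaccinated attendees; the case ratio is
    delta / (1 + delta).
    """

    gamma: float
    delta: float
    performance: TestPerformance = field(default_factory=lambda: TestPerformance(1.0, 1.0))

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")

    @property
    def case_ratio(self) -> float:
        return self.delta / (1.0 + self.delta)


def classification_matrix(perf: TestPerformance) -> np.ndarray:
    """Column-stochastic matrix mapping true disease state to test result.

    Row/column order is (positive, negative): entry [0, 0] is the probability
    that a true case tests positive (sensitivity), entry [1, 1] that a true
    non-case tests negative (specificity).
    """
    a, b = perf.sensitivity, perf.specificity
    return np.array([[a, 1.0 - b], [1.0 - a, b]])


def misclassify_expected(true_counts: CountTable2x2, perf: TestPerformance) -> CountTable2x2:
    """Expected observed table after pushing true counts through the test.

    Applies (X, Y)^T = C (x, y)^T within each vaccination stratum; the
    classification only relabels patients, so stratum totals are conserved
    exactly.
    """
    if true_counts.is_observed:
        raise ValueError("misclassify_expected expects a table of true counts "
                         "(is_observed=False)")
    C = classification_matrix(perf)
    observed = C @ true_counts.as_array()
    return CountTable2x2.from_array(observed, is_observed=True)


def invert_counts(observed: CountTable2x2, perf: TestPerformance) -> CountTable2x2:
    """Reconstruct true counts by inverting the classification matrix.

    Per stratum, ``x = (beta*X - (1-beta)*Y)/c`` and
    ``y = (alpha*Y - (1-alpha)*X)/c``.  The reconstruction is real-valued and
    may contain negative entries under sampling noise; negative values are
    returned as-is so the caller can decide on truncation.

    Raises
    ------
    NonIdentifiableTestError
        If the Youden index is not strictly positive.
    """
    perf.require_invertible()
    if not observed.is_observed:
        raise ValueError("invert_counts expects an observed table")
    C_inv = np.linalg.inv(classification_matrix(perf))
    true = C_inv @ observed.as_array()
    return CountTable2x2.from_array(true, is_observed=False)


def expected_bias(query: BiasQuery) -> float:
    """Expected misclassification bias in the VE estimate, VE_obs - VE_true.

    The bias is a function of only four parameters: sensitivity, specificity,
    the relative risk gamma and the case odds delta (it does not depend on
    attendance probabilities or the sampling fraction).  It is expressed on
    the VE fraction scale (multiply by 100 for percentage points); the sign is
    negative whenever an imperfect test makes VE underestimated, which is the
    generic situation for gamma < 1.

    The closed form arises from forming the expected observed counts in each
    stratum (vaccinated stratum proportional to (gamma*delta, 1), unvaccinated
    to (delta, 1)), passing them through the classification matrix and taking
    1 - OR of the result.
    """
    a, b = query.performance.sensitivity, query.performance.specificity
    g, d = query.gamma, query.delta
    or_obs = ((a * g * d + (1.0 - b)) / ((1.0 - a) * g * d + b)) / (
        (a * d + (1.0 - b)) / ((1.0 - a) * d + b)
    )
    ve_obs = 1.0 - or_obs
    ve_true = 1.0 - g
    return ve_obs - ve_true


def flip_probabilities(
    predicted_positive_prob: np.ndarray | float,
    perf: TestPerformance,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probabilities that an observed test result is wrong.

    Given a model-predicted probability ``pi_plus`` of observing a positive
    result for a record, reconstructs the true-state probabilities through the
    inverted classification matrix,

        p1 = (beta*pi_plus - (1-beta)*pi_minus) / c
        p0 = (alpha*pi_minus - (1-alpha)*pi_plus) / c

    and returns the Bayes flipping probabilities

        phi_plus  = Pr(true negative | observed positive) = (1-beta)*p0 / pi_plus
        phi_minus = Pr(true positive | observed negative) = (1-alpha)*p1 / pi_minus

    Sampling noise in the predicted probability can push the reconstructed
    p0/p1 slightly outside [0, 1]; both outputs are clamped to [0, 1].

    Returns
    -------
    (phi_plus, phi_minus) : pair of arrays broadcast to the input shape.
    """
    perf.require_invertible()
    a, b = perf.sensitivity, perf.specificity
    c = perf.youden
    pi_plus = np.asarray(predicted_positive_prob, dtype=float)
    if np.any((pi_plus <= 0.0) | (pi_plus >= 1.0)):
        raise ValueError("predicted positive probabilities must lie strictly in (0, 1)")
    pi_minus = 1.0 - pi_plus
    p1 = (b * pi_plus - (1.0 - b) * pi_minus) / c
    p0 = (a * pi_minus - (1.0 - a) * pi_plus) / c
    raw_plus = (1.0 - b) * p0 / pi_plus
    raw_minus = (1.0 - a) * p1 / pi_minus
    n_clamped = int(np.sum((raw_plus < 0) | (raw_plus > 1))) + int(
        np.sum((raw_minus < 0) | (raw_minus > 1))
    )
    if n_clamped:
        _log.debug("clamped %d flip probabilities to [0, 1]", n_clamped)
    return np.clip(raw_plus, 0.0, 1.0), np.clip(raw_minus, 0.0, 1.0)
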