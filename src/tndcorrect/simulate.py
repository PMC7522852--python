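"""Synthetic TND data generators and the simulation experiments built on them.

Univariate datasets are drawn as four independent Poisson counts — true target
disease (TD) and non-target disease (ND) cases in the vaccinated and
unvaccinated strata — parameterised by the "baseline medical attendance"
lambda_V, lambda_U (the mean attendee counts under a null-effect vaccine), the
relative risk gamma and the case odds delta.  Each true case is then
independently relabelled through the classification matrix (binomial
thinning), so misclassification conserves stratum totals exactly.

Multivariate datasets add covariates with multiplicative effects on the TD and
ND attendance rates.  The attendee process is a marked Poisson process, which
is sampled exactly by superposition: TD and ND attendee counts are Poisson
with means proportional to the population-averaged rates, and the covariates
of each attendee follow the population law exponentially tilted by that
disease's rate factors (a Bernoulli prevalence p with rate ratio rho tilts to
p*rho/(1-p+p*rho); a standard-normal covariate with per-unit rate ratio rho
tilts to N(ln rho, 1)).  This is distributionally identical to drawing a
Poisson total and giving each attendee a rate-weighted covariate profile and a
Bernoulli true outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import CountTable2x2, TestPerformance
from .overimputation import logistic_adapter, run_overimputation
from .regression import MisclassifiedLogisticRegression
from .univariate import corrected_odds_ratio

__all__ = [
    "CovariateSpec",
    "Scenario",
    "default_covariates",
    "default_scenario_grid",
    "simulate_univariate",
    "simulate_multivariate",
    "replicate_scenario_grid",
]


@dataclass(frozen=True)
class CovariateSpec:
    """A confounder with multiplicative effects on TD and ND attendance rates.

    Categorical covariates are Bernoulli(prevalence) in the population with
    rate ratios ``rr_td``/``rr_nd`` for level 1 vs 0; continuous covariates
    are standard normal with rate multiplied by ``rr_td ** x`` (``rr_nd ** x``
    for ND).  Vaccination is handled separately and never listed here.
    """

    name: str
    kind: str  # "categorical" | "continuous"
    rr_td: float
    rr_nd: float = 1.0
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise ValueError("categorical covariates need a prevalence in (0, 1)")
        if self.rr_td <= 0 or self.rr_nd <= 0:
            raise ValueError("rate ratios must be positive")

    def mean_factor(self, disease: str) -> float:
        """Population mean of the rate factor, used to normalise rates."""
        rr = self.rr_td if disease == "td" else self.rr_nd
        if self.kind == "categorical":
            assert self.prevalence is not None
            return 1.0 - self.prevalence + self.prevalence * rr
        return math.exp(math.log(rr) ** 2 / 2.0)

    def sample_tilted(self, disease: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Covariate values among attendees of the given disease."""
        rr = self.rr_td if disease == "td" else self.rr_nd
        if self.kind == "categorical":
            assert self.prevalence is not None
            p = self.prevalence * rr / (1.0 - self.prevalence + self.prevalence * rr)
            return (rng.random(n) < p).astype(float)
        return rng.normal(loc=math.log(rr), scale=1.0, size=n)


def default_covariates() -> list[CovariateSpec]:
    """The default confounder set: age group and pre-infection antibody titre.

    Children (population ratio children:adults 1:2) have relative attendance
    risk 2 for TD and 1.5 for ND; a unit increase in the standardised antibody
    titre halves the TD risk and leaves ND unaffected.
    """
    return [
        CovariateSpec("age_child", "categorical", rr_td=2.0, rr_nd=1.5, prevalence=1.0 / 3.0),
        CovariateSpec("titre", "continuous", rr_td=0.5, rr_nd=1.0),
    ]


@dataclass(frozen=True)
class Scenario:
    """Full parameterisation of the TND data-generating process.

    ``delta`` is the odds of medically-attended TD among unvaccinated
    attendees (case ratio delta/(1+delta)); covariate rate factors are
    normalised by their population means so this interpretation is preserved
    in the multivariate generator.  ``attendance_ratio`` is lambda_V/lambda_U,
    the relative baseline attendance of vaccinated vs unvaccinated patients;
    the pair is solved from the mean-total constraint
    mean_total = ((1 + gamma*delta)/(1 + delta)) * lambda_V + lambda_U.
    """

    true_ve: float
    delta: float
    performance: TestPerformance
    mean_total: float = 3000.0
    attendance_ratio: float = 1.0
    covariates: tuple[CovariateSpec, ...] = field(default_factory=tuple)
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.true_ve < 1.0:
            raise ValueError("true_ve must be < 1 (gamma must be positive)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.mean_total <= 0 or self.attendance_ratio <= 0:
            raise ValueError("mean_total and attendance_ratio must be positive")
        # analytic consistency of the attendance calibration
        lv, lu = self.lambdas
        shrink = (1.0 + self.gamma * self.delta) / (1.0 + self.delta)
        if not math.isclose(shrink * lv + lu, self.mean_total, rel_tol=1e-9):
            raise AssertionError("attendance calibration violated")

    @property
    def gamma(self) -> float:
        return 1.0 - self.true_ve

    @property
    def case_ratio(self) -> float:
        return self.delta / (1.0 + self.delta)

    @property
    def lambdas(self) -> tuple[float, float]:
        """(lambda_V, lambda_U) solved from the mean-total constraint."""
        shrink = (1.0 + self.gamma * self.delta) / (1.0 + self.delta)
        lambda_u = self.mean_total / (shrink * self.attendance_ratio + 1.0)
        return self.attendance_ratio * lambda_u, lambda_u

    @property
    def vacc_coverage(self) -> float:
        """Fraction of baseline attendance from vaccinated patients."""
        return self.attendance_ratio / (1.0 + self.attendance_ratio)

    def with_covariates(self, covariates: Sequence[CovariateSpec]) -> "Scenario":
        return replace(self, covariates=tuple(covariates))


def default_scenario_grid(
    ve_values: Sequence[float] = (0.8, 0.4),
    performances: Sequence[tuple[float, float]] = ((0.95, 0.97), (0.85, 0.95), (0.80, 0.90)),
    case_ratios: Sequence[float] = (0.2, 0.4, 0.6),
    mean_total: float = 3000.0,
    covariates: Sequence[CovariateSpec] = (),
) -> list[Scenario]:
    """The default simulation-study grid: VE 80%/40%, three test performance
    levels and case ratios 0.2/0.4/0.6 at mean total sample size 3000."""
    scenarios = []
    for ve in ve_values:
        for a, b in performances:
            for cr in case_ratios:
                scenarios.append(
                    Scenario(
                        true_ve=ve,
                        delta=cr / (1.0 - cr),
                        performance=TestPerformance(a, b),
                        mean_total=mean_total,
                        covariates=tuple(covariates),
                        name=f"ve{ve:g}_a{a:g}_b{b:g}_cr{cr:g}",
                    )
                )
    return scenarios


def _thin_counts(
    true_pos: int, true_neg: int, perf: TestPerformance, rng: np.random.Generator
) -> tuple[int, int]:
    """Relabel true cases through the test: binomial thinning per stratum."""
    obs_pos = rng.binomial(true_pos, perf.sensitivity) + rng.binomial(
        true_neg, 1.0 - perf.specificity
    )
    return int(obs_pos), int(true_pos + true_neg - obs_pos)


def simulate_univariate(
    scenario: Scenario, rng: np.random.Generator | int | None = None
) -> tuple[CountTable2x2, CountTable2x2]:
    """One univariate TND dataset: (observed table, latent true table).

    True counts are independent Poisson draws with means
    x_V ~ lambda_V*gamma*delta/(1+delta), y_V ~ lambda_V/(1+delta),
    x_U ~ lambda_U*delta/(1+delta),       y_U ~ lambda_U/(1+delta);
    the observed table results from classifying each case through the test.
    The latent truth is returned for validation only.
    """
    rng = np.random.default_rng(rng)
    lam_v, lam_u = scenario.lambdas
    g, d = scenario.gamma, scenario.delta
    x_v = rng.poisson(lam_v * g * d / (1.0 + d))
    y_v = rng.poisson(lam_v / (1.0 + d))
    x_u = rng.poisson(lam_u * d / (1.0 + d))
    y_u = rng.poisson(lam_u / (1.0 + d))
    true = CountTable2x2(x_v, x_u, y_v, y_u, is_observed=False)
    X_v, Y_v = _thin_counts(x_v, y_v, scenario.performance, rng)
    X_u, Y_u = _thin_counts(x_u, y_u, scenario.performance, rng)
    observed = CountTable2x2(X_v, X_u, Y_v, Y_u, is_observed=True)
    return observed, true


def _poisson_means(scenario: Scenario) -> tuple[float, float]:
    """Mean TD and ND attendee counts implied by the scenario."""
    rho = scenario.vacc_coverage
    g, d = scenario.gamma, scenario.delta
    # normalised covariate factors have population mean 1, so the marginal
    # unvaccinated case odds remain delta as in the univariate model
    mean_td = scenario.mean_total * d * (1.0 - rho + rho * g) / (
        d * (1.0 - rho + rho * g) + 1.0
    )
    return mean_td, scenario.mean_total - mean_td


def simulate_multivariate(
    scenario: Scenario, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """One multivariate TND line list with latent true outcomes.

    Returns a frame with columns ``vaccinated``, one column per covariate,
    ``true_outcome`` and the (possibly misclassified) ``outcome``.  Sampled
    exactly from the marked-Poisson attendee process by disease-stratified
    superposition (see the module docstring).
    """
    rng = np.random.default_rng(rng)
    mean_td, mean_nd = _poisson_means(scenario)
    n_td = rng.poisson(mean_td)
    n_nd = rng.poisson(mean_nd)
    rho = scenario.vacc_coverage
    g = scenario.gamma

    cols: dict[str, np.ndarray] = {}
    vacc_td = (rng.random(n_td) < rho * g / (1.0 - rho + rho * g)).astype(float)
    vacc_nd = (rng.random(n_nd) < rho).astype(float)
    cols["vaccinated"] = np.concatenate([vacc_td, vacc_nd])
    for cov in scenario.covariates:
        cols[cov.name] = np.concatenate(
            [cov.sample_tilted("td", n_td, rng), cov.sample_tilted("nd", n_nd, rng)]
        )
    true_outcome = np.concatenate([np.ones(n_td), np.zeros(n_nd)]).astype(int)
    cols["true_outcome"] = true_outcome

    a, b = scenario.performance.sensitivity, scenario.performance.specificity
    u = rng.random(n_td + n_nd)
    observed = np.where(true_outcome == 1, (u < a).astype(int), (u < 1.0 - b).astype(int))
    cols["outcome"] = observed
    df = pd.DataFrame(cols)
    # shuffle so record order carries no disease information
    return df.sample(frac=1.0, random_state=rng).reset_index(drop=True)


def _estimate_univariate(
    method: str, observed: CountTable2x2, perf: TestPerformance
) -> tuple[float, bool]:
    if method == "uncorrected":
        try:
            return 1.0 - observed.crude_odds_ratio(), False
        except ZeroDivisionError:
            return math.nan, True
    if method == "corrected":
        res = corrected_odds_ratio(observed, perf)
        return 1.0 - res.odds_ratio, res.truncated
    raise ValueError(f"unknown univariate method {method!r}")


def _estimate_multivariate(
    method: str,
    data: pd.DataFrame,
    perf: TestPerformance,
    covariate_names: list[str],
    n_imputations: int,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    adapter = logistic_adapter(covariates=covariate_names)
    if method == "uncorrected":
        res = adapter(data)
        return 1.0 - math.exp(res.log_or), False
    if method == "direct_likelihood":
        X = data[["vaccinated", *covariate_names]].to_numpy(dtype=float)
        fit = MisclassifiedLogisticRegression(
            sensitivity=perf.sensitivity, specificity=perf.specificity
        ).fit(X, data["outcome"].to_numpy())
        return float(fit.ve_), False
    if method == "overimputation":
        pooled = run_overimputation(
            data, adapter, perf, n_imputations=n_imputations, rng=rng
        )
        return float(pooled.ve), False
    raise ValueError(f"unknown multivariate method {method!r}")


def replicate_scenario_grid(
    scenarios: Sequence[Scenario],
    methods: Sequence[str] = ("uncorrected", "corrected"),
    n_replicates: int = 500,
    rng: np.random.Generator | int | None = None,
    n_imputations: int = 100,
) -> pd.DataFrame:
    """Run estimators over replicated draws of each scenario.

    Univariate methods ("uncorrected", "corrected") run on scenarios without
    covariates; multivariate methods ("uncorrected", "direct_likelihood",
    "overimputation") on scenarios with covariates.  Returns a long-format
    frame with columns scenario, replicate, method, ve, truncated; replicate
    failures are recorded as NaN rows rather than aborting the grid.  Results
    are deterministic given the seed.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for scenario in scenarios:
        label = scenario.name or f"ve{scenario.true_ve:g}_cr{scenario.case_ratio:g}"
        multivariate = len(scenario.covariates) > 0
        cov_names = [c.name for c in scenario.covariates]
        for rep, sub_rng in enumerate(rng.spawn(n_replicates)):
            if multivariate:
                data = simulate_multivariate(scenario, sub_rng)
            else:
                observed, _ = simulate_univariate(scenario, sub_rng)
            for method in methods:
                try:
                    if multivariate:
                        ve, truncated = _estimate_multivariate(
                            method, data, scenario.performance, cov_names,
                            n_imputations, sub_rng,
                        )
                    else:
                        ve, truncated = _estimate_univariate(
                            method, observed, scenario.performance
                        )
                except Exception:
                    ve, truncated = math.nan, True
                rows.append(
                    dict(scenario=label, replicate=rep, method=method,
                         ve=ve, truncated=truncated)
                )
    return pd.DataFrame(rows)
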