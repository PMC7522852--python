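# Methods

## Observation model

Every estimator in this package rests on one linear observation model. Within
each vaccination stratum, let (x, y) be the true counts of target-disease (TD)
and non-target-disease (ND) patients among medically-attended, tested
individuals, and (X, Y) the counts by observed test result. A test with
sensitivity α and specificity β gives

    E[(X, Y)ᵀ] = C (x, y)ᵀ,   C = [[α, 1−β], [1−α, β]].

C is column-stochastic, so classification relabels patients without changing
stratum totals; its determinant c = α + β − 1 (the Youden index) measures the
information the test retains. All inverse operations require c > 0; c ≤ 0
raises an error whose message suggests swapping the positive/negative test
definitions (which maps c to −c). The key design feature of the TND that makes
this inversion valid is that cases and controls are recruited at a common
sampling fraction, so the same C applies to both margins — the differential
recruitment that blocks this correction in classical case–control studies is
absent.

α and β are treated as known inputs throughout; estimating them, and
misclassification of covariates such as vaccination history, are out of scope.

## Expected bias of the uncorrected estimate

With δ the odds of medically-attended TD among unvaccinated attendees
(case ratio δ/(1+δ)) and γ the relative risk (VE = 1 − γ), the expected
stratum counts are proportional to (γδ, 1) and (δ, 1). Pushing these through
C and taking 1 − OR gives the expected bias

    B(α, β, γ, δ) = VE_obs − VE_true
                  = [1 − ((αγδ + 1−β)/((1−α)γδ + β)) / ((αδ + 1−β)/((1−α)δ + β))] − (1 − γ),

independent of attendance probabilities and the sampling fraction. B is
reported signed (the absolute value is trivially recoverable): signed output
preserves the direction of the distortion, which is systematically downward
for protective vaccines. The closed form is guarded in the tests by an
independent oracle that builds the four expected counts numerically with
arbitrary attendance factors.

## Corrected odds ratio and interval (2×2 tables)

Left-multiplying the observation model by C⁻¹ reconstructs the true counts;
the corrected odds ratio is the odds ratio of the reconstruction:

    γ* = (A_V B_U)/(B_V A_U),  A = βX − (1−β)Y,  B = αY − (1−α)X  per stratum.

γ* is also the MLE of the misclassified binomial likelihood whenever the
unconstrained per-stratum solutions lie inside (0, 1) — the tests verify this
equivalence against direct numerical maximisation. Sampling noise can make a
component negative; since negative true counts are impossible, the component
is truncated at zero and the point estimate becomes 0 or +∞ on the OR scale.
This is reported as a flagged boundary estimate, never an exception and never
a silently ordinary number: downstream summaries must count flagged estimates
separately, and no interval is attached to them.

The confidence interval assumes log-normality of γ*. Treating the four
observed counts as independent Poisson draws (the same observation model the
simulator uses) and applying the delta method to log γ* gives the shape
parameter

    σ² = X_V(β/A_V + (1−α)/B_V)² + Y_V((1−β)/A_V + α/B_V)²
       + X_U(β/A_U + (1−α)/B_U)² + Y_U((1−β)/A_U + α/B_U)²,

which collapses to the Woolf variance 1/X_V + 1/Y_V + 1/X_U + 1/Y_U for a
perfect test. Because σ is derived rather than transcribed, its calibration is
validated empirically: the 95% interval's coverage over 2000 simulated
replicates is required to fall in [0.93, 0.97]. The confidence level is
configurable (default 0.95, normal quantile).

The sensitivity-grid operation re-evaluates γ* over a lattice of assumed
(α, β) for post-hoc sensitivity analysis; γ* is monotone in each argument
while all components stay positive, so lattice extremes bound the plausible
VE. Grid points with c ≤ 0 are marked not-evaluable rather than failing the
grid.

## Direct-likelihood logistic regression

For covariate-adjusted VE the true-state probability is modelled as logistic,
logit p₁(ξ; θ) = θ₀ + θ₁ξ¹ + … with ξ¹ vaccination history, and the observed
result follows a Bernoulli with

    π₊(ξ; θ) = α p₁(ξ; θ) + (1 − β)(1 − p₁(ξ; θ)).

θ maximises Σ Z log π₊ + (1−Z) log π₋. Numerical choices: L-BFGS-B on the
analytic negative log-likelihood and gradient (chain rule through the affine
π₊), warm-started at the ordinary logistic fit with a zero-vector fallback
start, the better optimum kept; π₊ is clamped away from {0, 1} by 1e−12
before logs; the covariance is the inverse of a numerically differentiated
observed information, and the VE interval is Wald on θ₁ mapped through
VE = 1 − exp(θ₁). Coefficients beyond ±15 trigger a separation warning.
Per-record (α, β) are accepted (datasets mixing test kinds); scalars
broadcast. With α = β = 1 the fit reproduces ordinary logistic regression,
and on a 2×2 table encoded as a line list it reproduces γ*.

## Multiple overimputation with parametric bootstrapping

To correct VE from an estimation tool M whose likelihood cannot be modified:

1. Fit M to the raw data once; keep the predicted positive probability p̂ᵢ per
   record as a proxy for π₊(ξᵢ).
2. Reconstruct the true-state probabilities through C⁻¹ and form the Bayes
   flipping probabilities
   φ̂₊ = (1−β)p̂₀/π̂₊ (observed positive is wrong) and
   φ̂₋ = (1−α)p̂₁/π̂₋ (observed negative is wrong). Because p̂ᵢ is a noisy
   proxy, the reconstruction can leave [0, 1]; flip probabilities are clamped
   to [0, 1], with clamped counts emitted on the debug log.
3. Generate J dataset copies, flipping each outcome with its applicable
   probability; refit M on each; pool.

p̂ᵢ is computed exactly once from the raw fit and not refreshed between
imputations (this is what makes the scheme a parametric bootstrap). Pooling
uses Rubin's rules on the log-OR scale — where approximate normality holds —
never on the VE scale: point = mean of the J log-ORs, total variance
= within + (1 + 1/J)·between, CI from a t reference with the standard
small-sample degrees of freedom (J−1)(1 + W/((1+1/J)B))², falling back to the
normal quantile when B = 0 (e.g. a perfect test, where MO reduces exactly to
the raw estimate). J defaults to 100.

The adapter contract requires M to return the log-OR point estimate, its
variance (the within-imputation component Rubin's rules need), and — on the
raw fit — per-record predicted probabilities. A built-in adapter wraps
ordinary logistic regression. Estimator failures on individual copies are
skipped and counted; more than 20% failures aborts, since a pooled estimate
over a selected minority of copies would be biased.

## Synthetic-data generators

**Univariate.** True counts are independent Poissons with means
x_V ~ λ_V γδ/(1+δ), y_V ~ λ_V/(1+δ), x_U ~ λ_U δ/(1+δ), y_U ~ λ_U/(1+δ),
where the baseline attendances λ_V, λ_U are the mean stratum sizes under a
null-effect vaccine. The pair is solved from the calibration
mean_total = ((1+γδ)/(1+δ))λ_V + λ_U with default mean_total = 3000 and
λ_V = λ_U (the vaccinated:unvaccinated attendance split is not otherwise
determined; the ratio is an explicit knob). Observed tables arise by
binomial thinning of each true count through C, conserving stratum totals
record-for-record. The default scenario grid crosses VE ∈ {80%, 40%},
(α, β) ∈ {(0.95, 0.97), (0.85, 0.95), (0.80, 0.90)} and case ratio
∈ {0.2, 0.4, 0.6}.

**Multivariate.** Covariates multiply the TD and ND attendance rates.
Defaults: a child/adult age group (population ratio 1:2) with TD relative
risk 2 and ND relative risk 1.5, and a standard-normal antibody titre that
halves TD risk per unit and leaves ND unchanged; covariates are mutually
independent with no interactions, and the vaccine never affects ND risk. Each
covariate's rate factor is normalised by its population mean so that δ keeps
its univariate meaning (marginal case odds among unvaccinated attendees) and
the mean-total calibration is preserved. The attendee stream is a marked
Poisson process, sampled exactly by superposition: TD and ND attendee counts
are Poisson with the population-averaged means, and each attendee's
covariates follow the population law exponentially tilted by that disease's
rate factors (Bernoulli p tilts to pρ/(1−p+pρ); N(0,1) with per-unit ratio ρ
tilts to N(ln ρ, 1)). This is distributionally identical to drawing a Poisson
total and assigning rate-weighted profiles with Bernoulli true outcomes, but
involves no accept/reject step. Observed outcomes flip through C per record.
The confounder-count experiment clones the age-like and titre-like
specifications to (1 categorical + 1 continuous), (3+3) and (5+5).

What the generators deliberately do not emulate: seasonality or any time
structure, correlated covariates or interaction effects, test performance
varying with covariates or time (per-record (α, β) are supported by the
estimators but the generators draw a single test), and imperfect vaccination
records. Passing tests therefore demonstrate correctness of the inversion
machinery under the stated sampling model, not robustness to these realities.

## Problem sizes and reproducibility

The validation experiments use 500 replicates for univariate recovery, 2000
for the calibration and coverage checks, 100 replicates × J = 100 for the MO
recovery, and a 10⁶-attendee draw for the generator effect sizes — sizes at
which the Monte-Carlo error is comfortably inside each check's tolerance.
Each run derives all randomness from one seed; replicate substreams are
spawned deterministically, so results tables are byte-identical across
re-runs with the same seed.

## Known limitations

- Corrections inherit any error in the assumed (α, β); misspecifying them
  mis-corrects, and nothing in the data identifies them internally.
- Truncated (boundary) 2×2 estimates carry no interval; their frequency
  falls with sample size but is nonzero for small studies with high VE.
- Wald/log-normal intervals degrade near boundaries (components near zero,
  VE near 100%); a Bayesian or profile-likelihood interval would behave
  better there and is not provided.
- The MO corrector assumes the wrapped model predicts the observed-positive
  probability sensibly; a badly misspecified M degrades the flip
  probabilities along with the estimate.
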