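"""Synthetic-data generators: calibration, effect sizes, experiment harness."""

import math

import numpy as np
import pytest

from tndcorrect import (
    CovariateSpec,
    Scenario,
    TestPerformance,
    corrected_odds_ratio,
    default_covariates,
    default_scenario_grid,
    replicate_scenario_grid,
    simulate_multivariate,
    simulate_univariate,
)


class TestScenario:
    def test_lambda_calibration_identity(self, scenario_high_ve):
        lam_v, lam_u = scenario_high_ve.lambdas
        g, d = scenario_high_ve.gamma, scenario_high_ve.delta
        assert ((1 + g * d) / (1 + d)) * lam_v + lam_u == pytest.approx(3000.0)

    def test_equal_attendance_split_by_default(self, scenario_high_ve):
        lam_v, lam_u = scenario_high_ve.lambdas
        assert lam_v == pytest.approx(lam_u)
        assert scenario_high_ve.vacc_coverage == pytest.approx(0.5)

    def test_attendance_ratio_knob(self, perf_default):
        sc = Scenario(true_ve=0.5, delta=1.0, performance=perf_default, attendance_ratio=3.0)
        lam_v, lam_u = sc.lambdas
        assert lam_v / lam_u == pytest.approx(3.0)

    def test_invalid_scenarios_rejected(self, perf_default):
        with pytest.raises(ValueError):
            Scenario(true_ve=1.0, delta=1.0, performance=perf_default)
        with pytest.raises(ValueError):
            Scenario(true_ve=0.5, delta=-1.0, performance=perf_default)

    def test_default_grid_shape(self):
        grid = default_scenario_grid()
        assert len(grid) == 2 * 3 * 3
        assert {s.performance.sensitivity for s in grid} == {0.95, 0.85, 0.80}
        assert all(s.mean_total == 3000.0 for s in grid)


class TestUnivariateGenerator:
    def test_totals_conserved_by_misclassification(self, scenario_high_ve, rng):
        for _ in range(50):
            obs, true = simulate_univariate(scenario_high_ve, rng)
            assert obs.total_vacc == true.total_vacc
            assert obs.total_unvacc == true.total_unvacc

    def test_mean_total_matches_calibration(self, scenario_high_ve, rng):
        totals = [simulate_univariate(scenario_high_ve, rng)[0].total for _ in range(400)]
        se = np.std(totals, ddof=1) / math.sqrt(len(totals))
        assert abs(np.mean(totals) - 3000.0) < 3 * se

    def test_null_effect_mean_totals_are_lambdas(self, perf_perfect, rng):
        sc = Scenario(true_ve=0.0, delta=1.0, performance=perf_perfect)
        lam_v, lam_u = sc.lambdas
        vacc, unvacc = [], []
        for _ in range(400):
            obs, _ = simulate_univariate(sc, rng)
            vacc.append(obs.total_vacc)
            unvacc.append(obs.total_unvacc)
        assert abs(np.mean(vacc) - lam_v) < 3 * np.std(vacc, ddof=1) / 20
        assert abs(np.mean(unvacc) - lam_u) < 3 * np.std(unvacc, ddof=1) / 20

    def test_true_case_ratio(self, rng, perf_default):
        sc = Scenario(true_ve=0.0, delta=0.25 / 0.75, performance=perf_default)
        cases = total = 0
        for _ in range(300):
            _, true = simulate_univariate(sc, rng)
            cases += true.pos_vacc + true.pos_unvacc
            total += true.total
        ratio = cases / total
        assert abs(ratio - 0.25) < 3 * math.sqrt(0.25 * 0.75 / total)

    def test_perfect_test_observed_equals_true(self, perf_perfect, rng):
        sc = Scenario(true_ve=0.6, delta=1.0, performance=perf_perfect)
        obs, true = simulate_univariate(sc, rng)
        assert obs.as_array().tolist() == true.as_array().tolist()


class TestMultivariateGenerator:
    def test_null_effects_constant_p1(self, rng):
        sc = Scenario(
            true_ve=0.0,
            delta=2 / 3,
            performance=TestPerformance(1.0, 1.0),
            mean_total=30_000,
            covariates=(
                CovariateSpec("flag", "categorical", rr_td=1.0, rr_nd=1.0, prevalence=0.3),
                CovariateSpec("score", "continuous", rr_td=1.0, rr_nd=1.0),
            ),
        )
        data = simulate_multivariate(sc, rng)
        p_hat = data["true_outcome"].mean()
        assert abs(p_hat - 0.4) < 3 * math.sqrt(0.4 * 0.6 / len(data))
        # covariates follow the untilted population law
        assert abs(data["flag"].mean() - 0.3) < 0.02
        assert abs(data["score"].mean()) < 0.03

    def test_child_attendance_rate_ratios(self, scenario_multivariate):
        sc = Scenario(
            true_ve=scenario_multivariate.true_ve,
            delta=scenario_multivariate.delta,
            performance=TestPerformance(1.0, 1.0),
            mean_total=200_000,
            covariates=scenario_multivariate.covariates,
        )
        data = simulate_multivariate(sc, 12345)
        child = data["age_child"] == 1
        # per-capita rate ratio: attendee count ratio corrected for the 1:2
        # child:adult population ratio
        td = data[data["true_outcome"] == 1]
        nd = data[data["true_outcome"] == 0]
        td_ratio = ((td["age_child"] == 1).sum() / (td["age_child"] == 0).sum()) * 2
        nd_ratio = ((nd["age_child"] == 1).sum() / (nd["age_child"] == 0).sum()) * 2
        assert td_ratio == pytest.approx(2.0, abs=0.1)
        assert nd_ratio == pytest.approx(1.5, abs=0.1)
        assert child.any()

    def test_latent_truth_recovers_generating_coefficients(self, scenario_multivariate):
        import statsmodels.api as sm

        sc = Scenario(
            true_ve=scenario_multivariate.true_ve,
            delta=scenario_multivariate.delta,
            performance=TestPerformance(1.0, 1.0),
            mean_total=40_000,
            covariates=scenario_multivariate.covariates,
        )
        data = simulate_multivariate(sc, 777)
        X = sm.add_constant(data[["vaccinated", "age_child", "titre"]].to_numpy())
        fit = sm.Logit(data["true_outcome"].to_numpy(), X).fit(disp=0)
        assert fit.params[3] == pytest.approx(math.log(0.5), abs=3 * fit.bse[3])
        assert fit.params[2] == pytest.approx(math.log(2 / 1.5), abs=3 * fit.bse[2])
        assert fit.params[1] == pytest.approx(math.log(sc.gamma), abs=3 * fit.bse[1])

    def test_observed_outcomes_follow_test_performance(self, scenario_multivariate):
        data = simulate_multivariate(scenario_multivariate, 55)
        td = data[data["true_outcome"] == 1]
        nd = data[data["true_outcome"] == 0]
        n_td, n_nd = len(td), len(nd)
        assert abs(td["outcome"].mean() - 0.95) < 3 * math.sqrt(0.95 * 0.05 / n_td)
        assert abs((1 - nd["outcome"]).mean() - 0.97) < 3 * math.sqrt(0.97 * 0.03 / n_nd)

    def test_mean_total_attendees(self, scenario_multivariate):
        rng = np.random.default_rng(9)
        totals = [len(simulate_multivariate(scenario_multivariate, rng)) for _ in range(200)]
        se = np.std(totals, ddof=1) / math.sqrt(len(totals))
        assert abs(np.mean(totals) - 3000.0) < 3 * se


class TestReplicateGrid:
    def test_deterministic_given_seed(self, scenario_high_ve):
        a = replicate_scenario_grid([scenario_high_ve], n_replicates=20, rng=5)
        b = replicate_scenario_grid([scenario_high_ve], n_replicates=20, rng=5)
        assert a.equals(b)

    def test_long_format_columns(self, scenario_high_ve):
        res = replicate_scenario_grid([scenario_high_ve], n_replicates=5, rng=1)
        assert list(res.columns) == ["scenario", "replicate", "method", "ve", "truncated"]
        assert set(res.method) == {"uncorrected", "corrected"}
        assert len(res) == 5 * 2

    def test_perfect_test_methods_coincide(self, perf_perfect):
        sc = Scenario(true_ve=0.6, delta=1.0, performance=perf_perfect)
        res = replicate_scenario_grid([sc], n_replicates=30, rng=2)
        wide = res.pivot(index="replicate", columns="method", values="ve")
        assert np.allclose(wide["uncorrected"], wide["corrected"])

    def test_corrected_unbiased_uncorrected_low(self, scenario_high_ve):
        res = replicate_scenario_grid([scenario_high_ve], n_replicates=150, rng=11)
        med = res.groupby("method")["ve"].median()
        assert abs(med["corrected"] - 0.8) < 0.02
        assert med["uncorrected"] < 0.8 - 0.01

    def test_multivariate_methods(self, scenario_multivariate):
        res = replicate_scenario_grid(
            [scenario_multivariate],
            methods=("uncorrected", "direct_likelihood"),
            n_replicates=10,
            rng=4,
        )
        med = res.groupby("method")["ve"].median()
        assert med["direct_likelihood"] > med["uncorrected"]

    def test_truncation_rate_falls_with_sample_size(self, perf_default):
        # small samples at high VE produce occasional negative components
        small = Scenario(true_ve=0.9, delta=0.25, performance=perf_default,
                         mean_total=300, name="small")
        large = Scenario(true_ve=0.9, delta=0.25, performance=perf_default,
                         mean_total=6000, name="large")
        res = replicate_scenario_grid(
            [small, large], methods=("corrected",), n_replicates=300, rng=17
        )
        rate = res.groupby("scenario")["truncated"].mean()
        assert rate["small"] > rate["large"]
        assert rate["large"] < 0.02
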