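import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import aadm
from aadm.regression import (
    exgauss_density,
    exgauss_logpdf,
    fit_exgauss_ml,
    fit_exgauss_regression,
    fit_gee_binomial,
    scale_2sd,
    sum_code,
    sum_design,
)
from aadm.synth import default_scenario, generate_dataset


def exgauss_sample(rng, mu, sigma, tau, n):
    return rng.normal(mu, sigma, n) + rng.exponential(tau, n)


class TestSumCoding:
    def test_two_levels_map_to_plus_minus_one(self):
        col = sum_code(["angry", "happy", "angry", "happy"])
        np.testing.assert_array_equal(col, [1.0, -1.0, 1.0, -1.0])
        assert col.mean() == 0.0

    def test_three_levels_rejected(self):
        with pytest.raises(ValueError):
            sum_code(["a", "b", "c"])

    def test_interaction_columns_are_products(self, clean_trials):
        design = sum_design(clean_trials)
        prod = (
            design["expression"]
            * design["required_response"]
            * design["face_gender"]
        )
        np.testing.assert_array_equal(
            design["expression x required_response x face_gender"], prod
        )

    def test_balanced_design_columns_orthogonal(self):
        # fully balanced factorial: Gram matrix is n * identity
        from itertools import product

        rows = [
            {"expression": e, "required_response": r, "face_gender": f,
             "participant_gender": g}
            for e, r, f, g in product(
                ("angry", "happy"), ("push", "pull"), ("male", "female"),
                ("male", "female"),
            )
        ]
        X = sum_design(pd.DataFrame(rows)).to_numpy()
        np.testing.assert_allclose(X.T @ X, len(rows) * np.eye(X.shape[1]),
                                   atol=1e-12)


class TestGee:
    def test_singleton_clusters_equal_ordinary_logistic(self, rng):
        import statsmodels.api as sm

        n = 400
        x = rng.normal(size=n)
        table = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "expression": np.where(x > 0, "angry", "happy"),
                "required_response": rng.choice(["push", "pull"], n),
                "face_gender": rng.choice(["male", "female"], n),
                "participant_gender": rng.choice(["male", "female"], n),
            }
        )
        logit = 0.5 + 0.8 * sum_code(table["expression"])
        table["correct"] = rng.random(n) < 1 / (1 + np.exp(-logit))
        fit = fit_gee_binomial(table)
        X = sum_design(table)
        X.insert(0, "intercept", 1.0)
        glm = sm.GLM(
            table["correct"].astype(float), X.to_numpy(),
            family=sm.families.Binomial(),
        ).fit()
        np.testing.assert_allclose(fit.params, glm.params, atol=1e-6)

    def test_null_effects_rarely_significant(self):
        """With exchangeable cluster correlation and no true effects, Wald
        z statistics should look standard normal."""
        flags = []
        for seed in (3, 4):
            r = np.random.default_rng(seed)
            rows = []
            for i in range(40):
                u = r.normal(0, 0.3)
                for j in range(32):
                    rows.append(
                        {
                            "participant_id": f"P{i}",
                            "expression": ("angry", "happy")[j % 2],
                            "required_response": ("push", "pull")[(j // 2) % 2],
                            "face_gender": ("male", "female")[(j // 4) % 2],
                            "participant_gender": ("male", "female")[i % 2],
                            "correct": r.random() < 1 / (1 + np.exp(-(1.5 + u))),
                        }
                    )
            fit = fit_gee_binomial(pd.DataFrame(rows))
            coefs = fit.coefficients[fit.coefficients["name"] != "intercept"]
            flags += list(np.abs(coefs["z"]) > 1.96)
        assert np.mean(flags) <= 0.15

    def test_angry_accuracy_below_happy_on_default_scenario(self, clean_trials):
        fit = fit_gee_binomial(clean_trials[clean_trials["block"] != "practice"])
        expr = fit.coefficients.set_index("name").loc["expression"]
        # sum coding puts angry at +1; the generator's lower angry drift
        # means lower accuracy, hence a negative coefficient
        assert expr["estimate"] < 0

    def test_single_cluster_rejected(self):
        table = pd.DataFrame(
            {
                "participant_id": ["P1"] * 4,
                "expression": ["angry", "happy"] * 2,
                "required_response": ["push"] * 4,
                "face_gender": ["male"] * 4,
                "participant_gender": ["female"] * 4,
                "correct": [True, False, True, True],
            }
        )
        with pytest.raises(ValueError):
            fit_gee_binomial(table)


class TestExgaussDensity:
    def test_integrates_to_one(self):
        val, _ = integrate.quad(
            lambda t: exgauss_density(t, 0.45, 0.05, 0.15), -1.0, 6.0
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("t", [0.3, 0.5, 0.8, 1.5])
    def test_matches_convolution_quadrature(self, t):
        mu, sigma, tau = 0.45, 0.05, 0.15

        def integrand(x):
            return stats.norm.pdf(x, mu, sigma) * stats.expon.pdf(t - x, scale=tau)

        oracle, _ = integrate.quad(integrand, -np.inf, t)
        assert exgauss_density(t, mu, sigma, tau) == pytest.approx(oracle, rel=1e-6)

    def test_matches_scipy_exponnorm(self):
        t = np.linspace(0.0, 2.0, 9)
        ref = stats.exponnorm.logpdf(t, K=0.15 / 0.05, loc=0.45, scale=0.05)
        np.testing.assert_allclose(exgauss_logpdf(t, 0.45, 0.05, 0.15), ref,
                                   rtol=1e-10)

    def test_sample_moments(self, rng):
        x = exgauss_sample(rng, 0.45, 0.05, 0.15, 200_000)
        assert x.mean() == pytest.approx(0.60, abs=0.005)
        assert x.var() == pytest.approx(0.05**2 + 0.15**2, rel=0.05)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            exgauss_density(0.5, 0.4, -0.1, 0.2)
        with pytest.raises(ValueError):
            exgauss_density(0.5, 0.4, 0.1, 0.0)


class TestExgaussMl:
    def test_recovery_within_5_percent(self, rng):
        x = exgauss_sample(rng, 0.45, 0.05, 0.15, 10_000)
        fit = fit_exgauss_ml(x)
        assert fit.converged
        assert fit.mu == pytest.approx(0.45, rel=0.05)
        assert fit.sigma == pytest.approx(0.05, rel=0.05)
        assert fit.tau == pytest.approx(0.15, rel=0.05)

    def test_location_equivariance(self, rng):
        x = exgauss_sample(rng, 0.45, 0.05, 0.15, 2_000)
        a, b = fit_exgauss_ml(x), fit_exgauss_ml(x + 0.25)
        assert b.mu == pytest.approx(a.mu + 0.25, abs=1e-4)
        assert b.sigma == pytest.approx(a.sigma, rel=1e-3)
        assert b.tau == pytest.approx(a.tau, rel=1e-3)

    def test_loglik_is_sum_of_log_densities(self, rng):
        x = exgauss_sample(rng, 0.4, 0.06, 0.12, 500)
        fit = fit_exgauss_ml(x)
        assert fit.loglik == pytest.approx(
            exgauss_logpdf(x, fit.mu, fit.sigma, fit.tau).sum(), abs=1e-6
        )

    def test_recovery_error_shrinks_with_n(self):
        errs = {}
        for n in (500, 2000, 10_000):
            sq = []
            for seed in range(8):
                r = np.random.default_rng(100 + seed)
                fit = fit_exgauss_ml(exgauss_sample(r, 0.45, 0.05, 0.15, n))
                sq.append(
                    (fit.mu - 0.45) ** 2 + (fit.sigma - 0.05) ** 2
                    + (fit.tau - 0.15) ** 2
                )
            errs[n] = np.sqrt(np.mean(sq))
        assert errs[10_000] < errs[2000] < errs[500]

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_exgauss_ml(np.full(50, 0.5))
        with pytest.raises(ValueError):
            fit_exgauss_ml([0.4, 0.5])


class TestScale2sd:
    def test_mean_zero_sd_half(self, rng):
        z = scale_2sd(rng.normal(10, 3, 500))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(0.5, abs=1e-12)

    def test_known_values(self):
        z = scale_2sd([1.0, 2.0, 3.0, 4.0, 5.0])
        sd = np.std([1, 2, 3, 4, 5], ddof=1)
        np.testing.assert_allclose(z, (np.arange(1, 6) - 3) / (2 * sd))
        assert z[0] == pytest.approx(-0.6324555, abs=1e-6)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            scale_2sd([2.0, 2.0, 2.0])


@pytest.fixture(scope="module")
def bis_fit():
    trials, participants, _ = generate_dataset(
        default_scenario(n_per_gender=8, seed=5)
    )
    trials, _ = aadm.exclude_participants(trials)
    trials, _ = aadm.filter_rts(trials)
    main = trials[trials["block"] != "practice"]
    return fit_exgauss_regression(main, participants, covariate="bis")


class TestExgaussRegression:
    def test_recovers_positive_bis_moderation(self, bis_fit):
        """The generator couples high BIS to slower female happy/pull
        responses; the 4-way slope must come out positive."""
        coef = bis_fit.coefficients.set_index("name")
        slope = coef.loc["happy x pull x female x cov"]
        assert slope["estimate"] > 0
        assert slope["p"] < 0.05

    def test_null_covariate_slope_covers_zero(self):
        scenario = default_scenario(n_per_gender=8, seed=6)
        scenario.bis_ter_coupling = 0.0
        trials, participants, _ = generate_dataset(scenario)
        trials, _ = aadm.filter_rts(trials)
        fit = fit_exgauss_regression(
            trials[trials["block"] != "practice"], participants, covariate="bis"
        )
        slope = fit.coefficients.set_index("name").loc[
            "happy x pull x female x cov"
        ]
        assert abs(slope["estimate"]) < 1.96 * slope["se"]

    def test_covariate_rescaling_invariance(self):
        """Because the covariate is standardised to 2 SD inside the fit,
        rescaling the raw questionnaire totals changes nothing."""
        trials, participants, _ = generate_dataset(
            default_scenario(n_per_gender=4, seed=7)
        )
        main = trials[trials["block"] != "practice"]
        a = fit_exgauss_regression(main, participants, covariate="bis")
        participants2 = participants.assign(bis=participants["bis"] * 10.0)
        b = fit_exgauss_regression(main, participants2, covariate="bis")
        np.testing.assert_allclose(
            a.coefficients["estimate"], b.coefficients["estimate"], atol=1e-4
        )

    def test_design_matrix_full_rank(self, bis_fit):
        assert bis_fit.converged
        assert bis_fit.sigma > 0 and bis_fit.tau > 0

    def test_too_few_participants_rejected(self, small_dataset):
        trials, participants, _ = small_dataset
        only_f = participants[participants["participant_gender"] == "female"]
        with pytest.raises(ValueError):
            fit_exgauss_regression(
                trials[trials["participant_id"].isin(only_f["participant_id"])],
                only_f,
            )
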