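"""Factorial design: coefficients, ANOVA, contributions, reduction, prediction.

Reference values come from the bundled spring-heath study tables; derived
expectations come from brute-force least squares (normal equations) and a
direct contrast-sum decomposition.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from ecx import datasets, doe
from ecx.config import DesignError, FitError, RunConfig


def _normal_equation_fit(coded, run_means):
    """Independent oracle: solve X'X beta = X'y for the saturated model."""
    cols = [np.ones(len(coded))]
    k = coded.shape[1]
    for size in range(1, k + 1):
        for combo in itertools.combinations(range(k), size):
            cols.append(np.prod(coded[:, list(combo)], axis=1))
    X = np.column_stack(cols)
    return np.linalg.solve(X.T @ X, X.T @ run_means)


class TestCoefficients:
    def test_reference_run_means_reproduce_published_effects(self, hep2c_fit):
        # only the internally consistent published coefficients are checked
        assert hep2c_fit.params["b0"] == pytest.approx(0.5535, abs=1e-12)
        assert hep2c_fit.params["b1"] == pytest.approx(-0.0142, abs=1e-4)
        assert hep2c_fit.params["b3"] == pytest.approx(0.1007, abs=1e-4)
        assert hep2c_fit.params["b13"] == pytest.approx(-0.0075, abs=1e-4)

    def test_constant_response_gives_pure_intercept(self):
        coded = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))
        model = doe.FactorialModel(coded, np.full((8, 2), 0.37))
        res = model.fit()
        assert res.params["b0"] == pytest.approx(0.37)
        assert np.allclose(res.params.drop("b0"), 0.0)

    def test_matches_normal_equation_oracle_on_random_data(self, rng):
        coded = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))
        responses = rng.normal(0.5, 0.1, size=(8, 2))
        res = doe.FactorialModel(coded, responses).fit()
        beta = _normal_equation_fit(coded, responses.mean(axis=1))
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_incomplete_design_lists_missing_combinations(self):
        coded = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))[:-1]
        with pytest.raises(DesignError, match=r"missing"):
            doe.FactorialModel(coded, np.zeros((7, 2)))

    def test_single_replicate_without_override_refused(self):
        coded = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))
        with pytest.raises(FitError, match="pure-error"):
            doe.FactorialModel(coded, np.zeros(8)).fit()


class TestAnova:
    def test_reference_f_statistic_for_dominant_term(self, hep2c_fit):
        assert hep2c_fit.anova.loc["x3", "F"] == pytest.approx(4060.0, abs=1)
        assert hep2c_fit.anova.loc["x3", "MS"] == pytest.approx(0.08120, abs=5e-5)

    def test_zero_noise_replicates_flag_infinite_f(self):
        coded = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))
        y = coded @ np.array([0.1, 0.2, 0.3]) + 0.5
        with pytest.warns(UserWarning, match="infinite"):
            res = doe.FactorialModel(coded, np.column_stack([y, y])).fit()
        assert np.isinf(res.anova.loc["x1", "F"])

    def test_decomposition_matches_contrast_sums(self, rng):
        """SS from coefficients equals SS from raw contrast sums, and the
        decomposition is exhaustive under the total-observations convention."""
        coded = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))
        responses = rng.normal(0.5, 0.05, size=(8, 3))
        cfg = RunConfig(ss_convention="total_observations")
        res = doe.FactorialModel(coded, responses).fit(config=cfg)
        n_obs = responses.size
        y = responses.flatten()
        coded_full = np.repeat(coded, 3, axis=0)
        for size in range(1, 4):
            for combo in itertools.combinations(range(3), size):
                contrast = np.prod(coded_full[:, list(combo)], axis=1)
                ss_oracle = np.sum(contrast * y) ** 2 / n_obs
                label = "".join(f"x{i+1}" for i in combo)
                assert res.anova.loc[label, "SS"] == pytest.approx(ss_oracle, rel=1e-10)
        ss_direct_total = np.sum((y - y.mean()) ** 2)
        assert res.anova.loc["Total", "SS"] == pytest.approx(ss_direct_total, rel=1e-10)

    def test_runs_convention_scales_ss_by_replicates(self, rng):
        coded = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))
        responses = rng.normal(0.5, 0.05, size=(8, 2))
        model = doe.FactorialModel(coded, responses)
        ss_runs = model.fit(config=RunConfig(ss_convention="paper_runs")).anova.loc["x1", "SS"]
        ss_total = model.fit(config=RunConfig(ss_convention="total_observations")).anova.loc["x1", "SS"]
        assert ss_total == pytest.approx(2 * ss_runs, rel=1e-12)


class TestPercentageContribution:
    @pytest.mark.parametrize(
        "line, term, expected",
        [("hep2c", "b3", 67.67), ("rd", "b1", 30.83), ("rd", "b3", 48.27), ("l2ob", "b1", 31.28)],
    )
    def test_published_coefficients_reproduce_published_shares(self, line, term, expected):
        pc = doe.percentage_contribution(datasets.POLYNOMIAL_COEFFICIENTS[line])
        assert pc[term] == pytest.approx(expected, abs=0.02)

    def test_single_nonzero_effect_takes_all(self):
        params = {t: 0.0 for t in doe.term_names(3)}
        params["b2"] = -0.4
        params["b0"] = 1.0
        pc = doe.percentage_contribution(params)
        assert pc["b2"] == 100.0

    def test_normalisation_is_exact(self, hep2c_fit):
        assert hep2c_fit.pc_percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_effects_warns_uniform(self):
        params = {t: 0.0 for t in doe.term_names(3)}
        params["b0"] = 1.0
        with pytest.warns(UserWarning, match="undefined"):
            pc = doe.percentage_contribution(params)
        assert np.allclose(pc, 100.0 / 7)


class TestReductionAndPrediction:
    def test_published_hep2c_model_drops_only_x1x2(self, hep2c_published):
        assert set(hep2c_published.retained_terms) == {"b0", "b1", "b2", "b3", "b13", "b23", "b123"}

    def test_rd_run_means_retain_main_effects_and_x1x3(self):
        model = doe.FactorialModel.from_dataframe(datasets.factorial_design("rd"), datasets.FACTORS)
        ss, dfe = datasets.ERROR_SS["rd"]
        res = model.fit(error_ss=ss, error_df=dfe)
        assert set(res.retained_terms) == {"b0", "b1", "b2", "b3", "b13"}

    def test_alpha_one_retains_everything(self, hep2c_published):
        res = hep2c_published.reduce(alpha=1.0)
        assert set(res.retained_terms) == set(res.params.index)
        res.reduce()  # restore session fixture to its default alpha

    def test_reduced_prediction_at_low_corner(self, hep2c_published):
        assert hep2c_published.predict([-1, -1, -1]) == pytest.approx(0.452, abs=1e-3)

    def test_center_point_prediction_is_intercept(self, hep2c_published):
        assert hep2c_published.predict([0, 0, 0]) == pytest.approx(
            hep2c_published.params["b0"], abs=1e-12
        )

    def test_saturated_model_interpolates_run_means(self, hep2c_fit):
        means = datasets.run_means("hep2c")
        corners = datasets.factorial_design()
        pts = np.column_stack(
            [f.code(corners[f.name].to_numpy()) for f in datasets.FACTORS]
        )
        pred = hep2c_fit.predict(pts, reduced=False)
        np.testing.assert_allclose(pred, means, atol=1e-12)

    def test_extrapolation_outside_cube_warns(self, hep2c_published):
        with pytest.warns(UserWarning, match="extrapolat"):
            hep2c_published.predict([2.0, 0.0, 0.0])

    def test_orthogonality_coefficients_stable_under_subset_refit(self, rng):
        """Refitting with any single term's column removed leaves the other
        least-squares coefficients unchanged (orthogonal design)."""
        coded = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))
        y = rng.normal(0.5, 0.1, size=8)
        full = _normal_equation_fit(coded, y)
        cols = [np.ones(8)]
        for size in range(1, 4):
            for combo in itertools.combinations(range(3), size):
                cols.append(np.prod(coded[:, list(combo)], axis=1))
        X = np.column_stack(cols)
        for drop in range(1, 8):
            keep = [i for i in range(8) if i != drop]
            sub = np.linalg.solve(X[:, keep].T @ X[:, keep], X[:, keep].T @ y)
            np.testing.assert_allclose(sub, full[keep], atol=1e-12)


class TestDiagnostics:
    def test_reference_goodness_of_fit(self, hep2c_fit):
        assert hep2c_fit.rsquared == pytest.approx(0.9981, abs=0.005)
        assert hep2c_fit.rsquared_adj == pytest.approx(0.9964, abs=0.005)
        assert hep2c_fit.cv_percent == pytest.approx(0.81, abs=0.005)

    def test_r2adj_never_exceeds_r2(self, hep2c_fit):
        assert hep2c_fit.rsquared_adj <= hep2c_fit.rsquared

    def test_perfect_fit_limits(self):
        coded = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))
        y = coded @ np.array([0.1, 0.2, 0.3]) + 0.5
        with pytest.warns(UserWarning):
            res = doe.FactorialModel(coded, np.column_stack([y, y])).fit()
        assert res.rsquared == pytest.approx(1.0)
        assert res.cv_percent == pytest.approx(0.0)

    def test_summary_mentions_key_quantities(self, hep2c_fit):
        text = hep2c_fit.summary()
        assert "R2" in text and "intercept" in text and "x1x2x3" in text


def test_parameter_recovery_is_unbiased():
    """Coefficient estimates on noisy synthetic designs are unbiased:
    the mean over 500 seeds stays within 3 sigma/sqrt(N_total) of truth."""
    from ecx.simulate import FactorialSpec, gen_factorial

    beta = dict(datasets.POLYNOMIAL_COEFFICIENTS["hep2c"])
    sigma = 0.005
    spec = FactorialSpec(beta, n_replicates=2, sigma_rep=sigma)
    n_seeds = 500
    est = np.zeros((n_seeds, 8))
    for s in range(n_seeds):
        est[s] = gen_factorial(spec, s).fit().params.to_numpy()
    truth = np.array([beta[t] for t in doe.term_names(3)])
    np.testing.assert_allclose(est.mean(axis=0), truth, atol=3 * sigma / np.sqrt(16))
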