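"""Maximum-likelihood fitting, deviance, goodness of fit, model comparison."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

from apcrate import (
    APCModel,
    BandScheme,
    RateTable,
    ReferenceSpec,
    build_design,
    compare_models,
    deviance,
    fit,
    gof_pvalue,
)
from apcrate.errors import ConfigurationError, DomainError
from apcrate.model import format_pvalue
from apcrate.simulate import SimConfig, simulate_events, simulate_miners
from apcrate.cohort import tabulate

from conftest import random_rate_table


def single_cell_table(cases=5.0, pyears=1000.0):
    return RateTable(BandScheme(30, 5, 1), BandScheme(1960, 5, 1),
                     np.array([[cases]]), np.array([[pyears]]))


class TestFit:
    def test_single_cell_closed_form_mle(self):
        """One cell, age-only model: mu-hat = ln(cases/pyears), zero deviance."""
        res = APCModel(single_cell_table(), "A").fit()
        assert res.mu == pytest.approx(np.log(0.005), abs=1e-10)
        assert res.deviance == pytest.approx(0.0, abs=1e-10)
        assert res.converged

    def test_saturated_fit_reproduces_observations(self):
        """On a 2x2 grid the constrained APC design is saturated: fitted = observed."""
        rng = np.random.default_rng(3)
        table = random_rate_table(rng, a=2, p=2, mean_pyears=2000.0, base_log_rate=-5)
        assert table.cases.min() > 0
        res = APCModel(table, "APC").fit()
        assert res.design.df_resid == 0
        np.testing.assert_allclose(
            res.fitted_count, res.model.endog, rtol=1e-8
        )
        assert res.deviance == pytest.approx(0.0, abs=1e-8)

    def test_intercept_score_equation(self, rng):
        """Total fitted cases equal total observed cases after convergence."""
        table = random_rate_table(rng)
        res = APCModel(table, "APC").fit()
        assert res.fitted_count.sum() == pytest.approx(
            res.model.endog.sum(), rel=1e-8
        )

    def test_reference_effects_exactly_zero(self, rng):
        table = random_rate_table(rng, a=4, p=5)
        refs = ReferenceSpec.study_default(table)
        res = APCModel(table, "APC", refs).fit()
        assert res.alpha[refs.age_ref] == 0.0
        assert res.beta[refs.period_ref] == 0.0
        assert res.gamma[refs.cohort_refs[0]] == 0.0
        assert res.gamma[refs.cohort_refs[1]] == 0.0
        assert res.df_resid == res.design.n_cells - res.design.n_columns

    def test_separation_flagged_per_level(self):
        table = random_rate_table(np.random.default_rng(11), a=3, p=3)
        table.cases[2, :] = 0.0  # last age level has no cases anywhere
        res = APCModel(table, "A").fit()
        assert ("age", table.age_scheme.label(3)) in res.separated_levels
        assert res.alpha.iloc[2] < -5  # driven strongly negative

    def test_no_cases_rejected(self):
        with pytest.raises(ConfigurationError):
            APCModel(single_cell_table(cases=0.0), "A").fit()

    def test_functional_entry_point_matches_class(self, rng):
        table = random_rate_table(rng, a=3, p=4)
        design = build_design("AP", table)
        res_fn = fit(design, table)
        res_cls = APCModel(table, "AP").fit()
        np.testing.assert_allclose(res_fn.params, res_cls.params, atol=1e-12)

    def test_summary_mentions_model_and_deviance(self, rng):
        res = APCModel(random_rate_table(rng, a=3, p=3), "AP").fit()
        text = res.summary()
        assert "AP" in text and "Deviance" in text and "intercept" in text


class TestDeviance:
    def test_perfect_fit_is_zero(self):
        assert deviance([3.0, 0.0, 7.0], [3.0, 0.0, 7.0]) == 0.0

    def test_single_cell_closed_form(self):
        assert deviance([2.0], [1.0]) == pytest.approx(2 * (2 * np.log(2) - 1), abs=1e-10)

    def test_additive_over_disjoint_cells(self, rng):
        obs = rng.poisson(5.0, size=10).astype(float)
        fitted = rng.uniform(1.0, 9.0, size=10)
        total = deviance(obs, fitted)
        assert total == pytest.approx(
            deviance(obs[:4], fitted[:4]) + deviance(obs[4:], fitted[4:]), rel=1e-12
        )

    def test_zero_observed_cells_use_zero_log_zero(self):
        assert deviance([0.0], [2.0]) == pytest.approx(4.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            deviance([-1.0], [1.0])
        with pytest.raises(DomainError):
            deviance([1.0], [-1.0])


class TestGofPvalue:
    def test_zero_deviance_gives_one(self):
        assert gof_pvalue(0.0, 10) == 1.0

    @pytest.mark.parametrize(
        "D,df,expected",
        [(45.68, 42, 0.32), (60.93, 56, 0.30), (60.34, 48, 0.11)],
    )
    def test_chi_square_upper_tail(self, D, df, expected):
        assert gof_pvalue(D, df) == pytest.approx(expected, abs=0.005)

    def test_invalid_df_rejected(self):
        with pytest.raises(DomainError):
            gof_pvalue(5.0, 0)

    def test_display_convention(self):
        assert format_pvalue(0.321) == "0.32"
        assert format_pvalue(0.004) == "<0.01"


class TestOracleEquivalence:
    """The hand-written IRLS against two independent routes on the same design."""

    @pytest.mark.parametrize("trial", range(6))
    def test_agrees_with_glm_and_generic_maximizer(self, trial):
        rng = np.random.default_rng(100 + trial)
        table = random_rate_table(
            rng, a=int(rng.integers(3, 6)), p=int(rng.integers(3, 6)),
            mean_pyears=5000.0, base_log_rate=-5.0,
        )
        res = APCModel(table, "APC").fit()
        if res.separated_levels:
            pytest.skip("separated draw: MLE not finite, comparison undefined")
        X, off, y = res.design.matrix, res.design.offset, res.model.endog

        glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        np.testing.assert_allclose(res.params, glm.params, atol=1e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(res.cov_matrix)), glm.bse, atol=1e-6
        )

        def nll(b):
            eta = X @ b + off
            return np.sum(np.exp(eta)) - y @ eta

        def grad(b):
            return X.T @ (np.exp(X @ b + off) - y)

        def hess(b):
            return X.T @ (X * np.exp(X @ b + off)[:, None])

        opt = minimize(nll, np.zeros(X.shape[1]), jac=grad, hess=hess,
                       method="Newton-CG", options={"xtol": 1e-14})
        np.testing.assert_allclose(res.params, opt.x, atol=1e-6)


class TestNestingAndComparison:
    def test_deviance_never_increases_with_added_factors(self, rng):
        table = random_rate_table(rng, a=5, p=5)
        dev = {
            name: APCModel(table, name).fit().deviance
            for name in ("A", "P", "C", "AP", "AC", "PC", "APC")
        }
        tol = 1e-8
        for sub, sup in [("A", "AP"), ("A", "AC"), ("P", "AP"), ("P", "PC"),
                         ("C", "AC"), ("C", "PC"), ("AP", "APC"),
                         ("AC", "APC"), ("PC", "APC")]:
            assert dev[sup] <= dev[sub] + tol

    def test_study_grid_df_column(self):
        table = random_rate_table(np.random.default_rng(5), a=8, p=9)
        refs = ReferenceSpec.study_default(table)
        comparison = compare_models(table, refs)
        assert comparison.frame["df"].tolist() == [64, 63, 56, 56, 49, 48, 42]

    def test_selection_under_pure_age_truth(self):
        """Data from an age-only rate: A (or a superset) is adequate and selected."""
        cfg = SimConfig(
            n_miners=20000, seed=97,
            true_beta=np.zeros(9), true_gamma=np.zeros(16),
        )
        records = simulate_events(simulate_miners(cfg), cfg)
        table = tabulate(records, cfg.age_scheme, cfg.period_scheme)
        comparison = compare_models(table, cfg.reference_spec())
        assert comparison.selected is not None
        assert "A" in comparison.selected or comparison.frame.loc["A", "p_value"] > 0.05
        d = comparison.frame["deviance"]
        assert d["APC"] <= d["AP"] + 1e-8 <= d["A"] + 2e-8

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_models(single_cell_table())
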