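"""Effect extrapolation, density prediction, and case projection."""

import numpy as np
import pandas as pd
import pytest

from apcrate import (
    APCModel,
    BandScheme,
    ExtrapolationConfig,
    expected_cases,
    extrapolate_effects,
    incidence_density,
    predict_density,
    project,
    round_persons,
)
from apcrate.errors import ConfigurationError, DomainError
from apcrate.simulate import SimConfig, make_future_pyears, simulate_events, simulate_miners
from apcrate.cohort import tabulate

from conftest import random_rate_table


@pytest.fixture(scope="module")
def fitted():
    """A converged full-model fit on a fully populated random study-sized grid."""
    rng = np.random.default_rng(12)
    table = random_rate_table(rng, a=8, p=9, mean_pyears=4000.0, base_log_rate=-5.5)
    return APCModel(table, "APC").fit()


def uniform_future(fitted, value=1000.0, n=4):
    scheme = fitted.model.table.period_scheme
    age = fitted.model.table.age_scheme
    rows = []
    for j in range(n):
        lo = scheme.end + j * scheme.width
        for i in range(1, age.count + 1):
            rows.append(
                {"age_lo": age.lower(i), "age_hi": age.upper_inclusive(i),
                 "period_lo": lo, "period_hi": lo + scheme.width - 1,
                 "person_years": value}
            )
    return pd.DataFrame(rows)


class TestExtrapolateEffects:
    def test_carry_last_repeats_final_period_effect(self, fitted):
        cfg = ExtrapolationConfig(period_method="carry-last", n_future_periods=4)
        eff = extrapolate_effects(fitted, cfg)
        last = fitted.beta.iloc[-1]
        future = eff.beta.iloc[-4:]
        assert np.allclose(future, last)

    def test_linear_trend_exact_on_collinear_effects(self, fitted):
        """A least-squares line through collinear points extrapolates them exactly."""
        eff = extrapolate_effects(
            fitted, ExtrapolationConfig(period_method="linear-trend", n_future_periods=2)
        )
        beta = fitted.beta.to_numpy()
        slope, intercept = np.polyfit(np.arange(1, len(beta) + 1), beta, 1)
        p = len(beta)
        assert eff.beta.iloc[p] == pytest.approx(intercept + slope * (p + 1), rel=1e-9)
        # and exactly linear inputs give the exact next point
        collinear = pd.Series([0.0, 0.1, 0.2], index=["a", "b", "c"])
        from apcrate.project import _trend_extend
        out = _trend_extend(collinear, 1, ["d"])
        assert out["d"] == pytest.approx(0.3, abs=1e-12)

    def test_zero_future_periods_rejected(self):
        with pytest.raises(ConfigurationError):
            ExtrapolationConfig(n_future_periods=0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            ExtrapolationConfig(period_method="spline")

    def test_cohort_effects_cover_future_diagonals(self, fitted):
        cfg = ExtrapolationConfig(n_future_periods=4)
        eff = extrapolate_effects(fitted, cfg)
        table = fitted.model.table
        a, p = table.shape
        assert len(eff.gamma) == a + p + 4 - 1
        assert not eff.gamma.isna().any()


class TestPredictDensity:
    def test_intercept_only_closed_form(self, fitted):
        """With all effects zeroed the density is 100000 * exp(mu)."""
        cfg = ExtrapolationConfig(n_future_periods=1)
        eff = extrapolate_effects(fitted, cfg)
        eff.alpha[:] = 0.0
        eff.beta[:] = 0.0
        eff.gamma[:] = 0.0
        from dataclasses import replace

        params = fitted.params.copy()
        params[0] = -5.07
        shifted = replace(fitted, params=params)
        age_label = fitted.model.table.age_scheme.labels[0]
        period_label = eff.period_scheme.labels[-1]
        dens = predict_density(shifted, eff, age_label, period_label)
        assert dens == pytest.approx(100000 * np.exp(-5.07), rel=1e-12)
        assert dens == pytest.approx(628.24, abs=0.005)

    def test_monotone_in_each_effect(self, fitted):
        cfg = ExtrapolationConfig(n_future_periods=1)
        eff = extrapolate_effects(fitted, cfg)
        age_label = fitted.model.table.age_scheme.labels[2]
        period_label = eff.period_scheme.labels[-1]
        base = predict_density(fitted, eff, age_label, period_label)
        eff.alpha[age_label] += 0.5
        assert predict_density(fitted, eff, age_label, period_label) > base

    def test_missing_effect_level_named(self, fitted):
        cfg = ExtrapolationConfig(n_future_periods=1)
        eff = extrapolate_effects(fitted, cfg)
        age_label = fitted.model.table.age_scheme.labels[0]
        eff.alpha[age_label] = np.nan
        with pytest.raises(LookupError, match=age_label):
            predict_density(fitted, eff, age_label, eff.period_scheme.labels[-1])


class TestExpectedCasesAndRounding:
    @pytest.mark.parametrize(
        "density,pyears,expected",
        [(100.66, 155517.46, 156.54), (132.82, 77796.49, 103.33)],
    )
    def test_printed_per_period_products(self, density, pyears, expected):
        assert expected_cases(density, pyears) == pytest.approx(expected, abs=0.005)

    def test_zero_person_years(self):
        assert expected_cases(50.0, 0.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            expected_cases(-1.0, 10.0)

    def test_density_case_round_trip(self):
        for d in (0.0, 13.7, 108.65):
            assert incidence_density(expected_cases(d, 4521.0), 4521.0) == pytest.approx(d, abs=1e-9)

    @pytest.mark.parametrize("x,expected", [(491.37, 492), (216.44, 217), (5.0, 5)])
    def test_ceiling_rule(self, x, expected):
        assert round_persons(x) == expected


class TestProject:
    def test_totals_are_sums_of_rows(self, fitted):
        cfg = ExtrapolationConfig(n_future_periods=4)
        out = project(fitted, uniform_future(fitted), cfg)
        by_period = out.rows.groupby("period_band")["expected_cases"].sum()
        merged = out.period_totals.set_index("period_band")["expected_cases"]
        pd.testing.assert_series_equal(by_period, merged, rtol=1e-9, check_names=False)
        assert out.total_cases == pytest.approx(out.rows["expected_cases"].sum(), rel=1e-9)
        assert out.overall_density == pytest.approx(
            incidence_density(out.total_cases, out.total_person_years), rel=1e-12
        )

    def test_overall_density_is_pyear_weighted_mean(self, fitted):
        cfg = ExtrapolationConfig(n_future_periods=2)
        future = uniform_future(fitted, n=2)
        future.loc[3:10, "person_years"] = 250.0
        out = project(fitted, future, cfg)
        t = out.period_totals
        weighted = (t["density"] * t["person_years"]).sum() / t["person_years"].sum()
        assert out.overall_density == pytest.approx(weighted, rel=1e-9)

    def test_doubling_person_years_doubles_cases_not_density(self, fitted):
        cfg = ExtrapolationConfig(n_future_periods=4)
        base = project(fitted, uniform_future(fitted), cfg)
        double = project(fitted, uniform_future(fitted, value=2000.0), cfg)
        np.testing.assert_allclose(
            double.rows["expected_cases"], 2 * base.rows["expected_cases"], rtol=1e-12
        )
        np.testing.assert_allclose(double.rows["density"], base.rows["density"], rtol=1e-12)

    def test_all_zero_person_years_projects_zero_cases(self, fitted):
        cfg = ExtrapolationConfig(n_future_periods=4)
        out = project(fitted, uniform_future(fitted, value=0.0), cfg)
        assert (out.rows["expected_cases"] == 0).all()
        assert out.total_cases == 0.0

    def test_horizon_mismatch_rejected(self, fitted):
        cfg = ExtrapolationConfig(n_future_periods=3)
        with pytest.raises(ConfigurationError, match="horizon"):
            project(fitted, uniform_future(fitted, n=4), cfg)

    def test_future_cohort_diagonals(self, fitted):
        """Future cells sit on diagonals k = a - i + j with j beyond the window."""
        cfg = ExtrapolationConfig(n_future_periods=4)
        out = project(fitted, uniform_future(fitted), cfg)
        table = fitted.model.table
        a = table.age_scheme.count
        eff = extrapolate_effects(fitted, cfg)
        for row in out.rows.itertuples(index=False):
            i = table.age_scheme.label_index(row.age_band)
            j = eff.period_scheme.label_index(row.period_band)
            assert j > table.period_scheme.count
            assert row.cohort_band == eff.cohort_scheme.label(a - i + j)
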