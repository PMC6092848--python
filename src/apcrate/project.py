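"""Forward projection of incidence density and expected case counts.

Given a fitted age/period/cohort rate model, projection evaluates
``100000 * exp(mu + alpha_i + beta_j + gamma_k)`` for age bands crossed
with *future* period bands appended after the fitting window, and converts
densities into expected cases with a supplied table of future person-years
(a quantity the model cannot produce itself: it reflects how many ex-dust
miners remain under observation).

Period effects beyond the fitted window, and cohort effects on diagonals
never observed, must be extrapolated; the rule is an explicit, recorded
choice (:class:`ExtrapolationConfig`), either a least-squares linear trend
through the estimated effects or carrying the last / nearest estimated
level forward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BandScheme, cohort_index
from .cohort import PER, incidence_density
from .errors import ConfigurationError, DomainError
from .model import APCResults

__all__ = [
    "ExtrapolationConfig",
    "ExtendedEffects",
    "ProjectionTable",
    "extrapolate_effects",
    "predict_density",
    "expected_cases",
    "round_persons",
    "project",
]

PERIOD_METHODS = ("linear-trend", "carry-last")
COHORT_METHODS = ("nearest-estimated", "linear-trend")


@dataclass(frozen=True)
class ExtrapolationConfig:
    """How to extend period and cohort effects beyond the fitted window."""

    period_method: str = "linear-trend"
    cohort_method: str = "nearest-estimated"
    n_future_periods: int = 4

    def __post_init__(self) -> None:
        if self.period_method not in PERIOD_METHODS:
            raise ConfigurationError(
                f"period_method must be one of {PERIOD_METHODS}, got {self.period_method!r}"
            )
        if self.cohort_method not in COHORT_METHODS:
            raise ConfigurationError(
                f"cohort_method must be one of {COHORT_METHODS}, got {self.cohort_method!r}"
            )
        if self.n_future_periods < 1:
            raise ConfigurationError("n_future_periods must be >= 1")


@dataclass
class ExtendedEffects:
    """Effect vectors extended over the projection horizon.

    ``beta`` is indexed by period band label over the fitted window plus the
    horizon; ``gamma`` over every cohort diagonal reachable by (age band,
    horizon period) cells.
    """

    alpha: pd.Series
    beta: pd.Series
    gamma: pd.Series
    period_scheme: BandScheme  # fitted + future periods
    cohort_scheme: BandScheme  # extended accordingly


def _trend_extend(values: pd.Series, n_new: int, new_labels: list[str]) -> pd.Series:
    """Extend by the least-squares line through (index position, value)."""
    est = values.dropna()
    if len(est) < 2:
        raise ConfigurationError(
            "linear-trend extrapolation needs at least 2 estimated levels"
        )
    pos = np.array([values.index.get_loc(lab) + 1 for lab in est.index], dtype=float)
    slope, intercept = np.polyfit(pos, est.to_numpy(), 1)
    n_old = len(values)
    new_pos = np.arange(n_old + 1, n_old + n_new + 1)
    return pd.Series(intercept + slope * new_pos, index=new_labels)


def extrapolate_effects(
    results: APCResults, config: ExtrapolationConfig
) -> ExtendedEffects:
    """Extend the fitted effects over ``config.n_future_periods`` extra periods."""
    if not results.converged:
        raise ConfigurationError("cannot project from a non-converged fit")
    table = results.model.table
    ps, cs = table.period_scheme, table.cohort_scheme
    n = config.n_future_periods
    ext_ps = BandScheme(ps.start, ps.width, ps.count + n)
    ext_cs = BandScheme(cs.start, cs.width, cs.count + n)
    future_labels = ext_ps.labels[ps.count:]
    new_cohort_labels = ext_cs.labels[cs.count:]

    beta = results.beta
    if config.period_method == "carry-last":
        last = beta.dropna().iloc[-1]
        beta_new = pd.Series(last, index=future_labels)
    else:
        beta_new = _trend_extend(beta, n, future_labels)

    gamma = results.gamma
    if config.cohort_method == "nearest-estimated":
        nearest = gamma.dropna().iloc[-1]
        gamma_new = pd.Series(nearest, index=new_cohort_labels)
        gamma_filled = gamma.copy()
    else:
        gamma_new = _trend_extend(gamma, n, new_cohort_labels)
        gamma_filled = gamma.copy()
    # interior diagonals that were unpopulated in the fit: nearest estimated level
    if gamma_filled.isna().any():
        gamma_filled = gamma_filled.ffill().bfill()

    return ExtendedEffects(
        alpha=results.alpha,
        beta=pd.concat([beta, beta_new]),
        gamma=pd.concat([gamma_filled, gamma_new]),
        period_scheme=ext_ps,
        cohort_scheme=ext_cs,
    )


def predict_density(
    results: APCResults,
    effects: ExtendedEffects,
    age_label: str,
    period_label: str,
) -> float:
    """Projected incidence density per 100,000 person-years for one cell."""
    table = results.model.table
    a = table.age_scheme.count
    i = table.age_scheme.label_index(age_label)
    j = effects.period_scheme.label_index(period_label)
    k = cohort_index(i, j, a)
    cohort_label = effects.cohort_scheme.label(k)
    for name, series, lab in (
        ("age", effects.alpha, age_label),
        ("period", effects.beta, period_label),
        ("cohort", effects.gamma, cohort_label),
    ):
        if lab not in series.index or pd.isna(series[lab]):
            raise LookupError(f"no {name} effect available for band {lab!r}")
    return PER * math.exp(
        results.mu
        + effects.alpha[age_label]
        + effects.beta[period_label]
        + effects.gamma[cohort_label]
    )


def expected_cases(density: float, person_years: float) -> float:
    """Expected case count implied by a density per 100,000 person-years."""
    if density < 0 or person_years < 0:
        raise DomainError("density and person-years must be non-negative")
    return density * person_years / PER


def round_persons(x: float) -> int:
    """Round a predicted number of persons up to the next whole person (ceiling)."""
    if x < 0:
        raise DomainError(f"cannot round a negative person count: {x}")
    return math.ceil(round(x, 9))


@dataclass
class ProjectionTable:
    """Projected incidence per (age band, future period band) plus totals.

    ``rows``: age_band, period_band, cohort_band, density, person_years,
    expected_cases.  ``period_totals`` adds rounded_cases (ceiling rule);
    ``overall_density`` is the person-year-weighted mean of the per-period
    densities.
    """

    rows: pd.DataFrame
    period_totals: pd.DataFrame
    total_cases: float
    total_person_years: float
    overall_density: float
    rounded_total: int
    config: ExtrapolationConfig = field(default=None)

    def __str__(self) -> str:
        return (
            self.period_totals.to_string(index=False)
            + f"\nTotal: {self.total_cases:.2f} cases / "
            f"{self.total_person_years:.2f} person-years "
            f"(density {self.overall_density:.2f}, rounded {self.rounded_total})"
        )


def project(
    results: APCResults,
    future_pyears: pd.DataFrame,
    config: ExtrapolationConfig | None = None,
) -> ProjectionTable:
    """Project expected cases over a horizon of future periods.

    ``future_pyears`` must have columns age_lo, age_hi, period_lo,
    period_hi, person_years, covering exactly the ``n_future_periods``
    5-year bands after the fitted window (the person-years of remaining
    ex-dust miners are an input, not a model output).
    """
    if config is None:
        config = ExtrapolationConfig()
    table = results.model.table
    ps = table.period_scheme
    required = {"age_lo", "age_hi", "period_lo", "period_hi", "person_years"}
    missing = required - set(future_pyears.columns)
    if missing:
        raise ConfigurationError(f"future person-years table lacks columns {sorted(missing)}")

    effects = extrapolate_effects(results, config)
    future_starts = {
        effects.period_scheme.lower(j)
        for j in range(ps.count + 1, ps.count + config.n_future_periods + 1)
    }
    got_starts = set(future_pyears["period_lo"].astype(int))
    if got_starts != future_starts:
        raise ConfigurationError(
            f"horizon mismatch: config implies period starts {sorted(future_starts)}, "
            f"table has {sorted(got_starts)}"
        )

    a_scheme = table.age_scheme
    rows = []
    for rec in future_pyears.itertuples(index=False):
        i = a_scheme.index_of(int(rec.age_lo))
        if i is None or a_scheme.lower(i) != int(rec.age_lo):
            raise ConfigurationError(f"age band starting {rec.age_lo} not in the age scheme")
        age_label = a_scheme.label(i)
        j = effects.period_scheme.index_of(int(rec.period_lo))
        period_label = effects.period_scheme.label(j)
        k = cohort_index(i, j, a_scheme.count)
        dens = predict_density(results, effects, age_label, period_label)
        rows.append(
            {
                "age_band": age_label,
                "period_band": period_label,
                "cohort_band": effects.cohort_scheme.label(k),
                "density": dens,
                "person_years": float(rec.person_years),
                "expected_cases": expected_cases(dens, float(rec.person_years)),
            }
        )
    frame = pd.DataFrame(rows)

    totals = (
        frame.groupby("period_band", sort=True)[["expected_cases", "person_years"]]
        .sum()
        .reset_index()
    )
    totals["density"] = [
        incidence_density(c, n) if n > 0 else float("nan")
        for c, n in zip(totals["expected_cases"], totals["person_years"])
    ]
    totals["rounded_cases"] = [round_persons(c) for c in totals["expected_cases"]]
    total_cases = float(frame["expected_cases"].sum())
    total_py = float(frame["person_years"].sum())
    overall = incidence_density(total_cases, total_py) if total_py > 0 else float("nan")
    return ProjectionTable(
        rows=frame,
        period_totals=totals,
        total_cases=total_cases,
        total_person_years=total_py,
        overall_density=overall,
        rounded_total=round_persons(total_cases),
        config=config,
    )
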