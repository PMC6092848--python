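"""Synthetic opencast-miner cohorts with a known log-linear rate structure.

The generator emulates the occupational structure of a mid-century Chinese
opencast-mine workforce: birth years uniform over a configurable range,
age at first dust exposure and exposure duration drawn from truncated
normal distributions (rounded to whole years), and pneumoconiosis
diagnoses generated year by year from the same log-linear
age/period/cohort rate the fitting module estimates.  Because the true
effect vectors satisfy the two-reference-cohort constraint, the fitted
coefficients are directly comparable with the truth, which is what the
parameter-recovery harness exploits.

Event generation uses an annual Bernoulli hazard 1 - exp(-rate), matching
the whole-calendar-year discretization of the tabulation step; the first
event censors the miner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bands import BandScheme, derive_cohort_scheme
from .cohort import MinerRecord, RateTable, tabulate
from .design import ReferenceSpec, build_design
from .errors import ConfigurationError
from .model import APCModel

__all__ = [
    "STUDY_AGE_SCHEME",
    "STUDY_PERIOD_SCHEME",
    "SimConfig",
    "simulate_miners",
    "simulate_events",
    "make_future_pyears",
    "recovery_experiment",
    "RecoveryReport",
]

# the study design: ages 30-69 in 8 bands, periods 1960-2004 in 9 bands
STUDY_AGE_SCHEME = BandScheme(start=30, width=5, count=8)
STUDY_PERIOD_SCHEME = BandScheme(start=1960, width=5, count=9)


def _default_true_effects(
    age_scheme: BandScheme, period_scheme: BandScheme
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int, tuple[int, int]]]:
    """Smooth default effect vectors satisfying the constraint scheme.

    Age effects rise linearly with age band (pneumoconiosis risk grows with
    cumulative exposure), period effects carry a gentle upward trend, and
    cohort effects follow a concave quadratic vanishing at both reference
    diagonals.  References: middle age band, middle period band, cohort
    diagonals 5 and a+p-1 (the study's 45-49 / 1975-1979 / 1913-1917 &
    1968-1972 on the default schemes).
    """
    a, p = age_scheme.count, period_scheme.count
    n_c = a + p - 1
    i_ref = max(1, a // 2)
    j_ref = max(1, p // 2)
    k_ref = (min(5, n_c - 1) if n_c > 1 else 1, n_c)
    alpha = 0.3 * (np.arange(1, a + 1) - i_ref)
    beta = 0.05 * (np.arange(1, p + 1) - j_ref)
    gamma = -0.012 * (np.arange(1, n_c + 1) - k_ref[0]) * (np.arange(1, n_c + 1) - k_ref[1])
    return alpha, beta, gamma, (i_ref, j_ref, k_ref)


@dataclass
class SimConfig:
    """Cohort-generator settings.

    The demographic defaults mirror a real opencast workforce: about 8,000
    miners, first exposed around age 21 (SD ~5), exposed for about 28 years
    (SD ~8).  ``true_mu`` and the effect vectors define the log-linear rate
    that generates diagnoses; defaults give an overall caseload of a few
    hundred in a cohort of this size.
    """

    n_miners: int = 8191
    seed: int = 20180814
    birth_year_range: tuple[int, int] = (1891, 1974)
    start_age_mean: float = 21.22
    start_age_sd: float = 4.90
    min_start_age: int = 16
    duration_mean: float = 27.79
    duration_sd: float = 8.25
    min_duration: int = 1
    true_mu: float = -5.5
    true_alpha: np.ndarray | None = None
    true_beta: np.ndarray | None = None
    true_gamma: np.ndarray | None = None
    age_scheme: BandScheme = field(default_factory=lambda: STUDY_AGE_SCHEME)
    period_scheme: BandScheme = field(default_factory=lambda: STUDY_PERIOD_SCHEME)
    age_ref_index: int | None = None
    period_ref_index: int | None = None
    cohort_ref_indices: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_miners < 0:
            raise ConfigurationError("n_miners must be >= 0")
        if self.birth_year_range[1] < self.birth_year_range[0]:
            raise ConfigurationError("birth_year_range upper bound below lower bound")
        if self.min_start_age > self.start_age_mean + 6 * self.start_age_sd:
            raise ConfigurationError("start-age truncation bound excludes nearly all mass")
        if self.min_duration > self.duration_mean + 6 * self.duration_sd:
            raise ConfigurationError("duration truncation bound excludes nearly all mass")
        a, p = self.age_scheme.count, self.period_scheme.count
        alpha, beta, gamma, (i_ref, j_ref, k_ref) = _default_true_effects(
            self.age_scheme, self.period_scheme
        )
        if self.true_alpha is None:
            self.true_alpha = alpha
        if self.true_beta is None:
            self.true_beta = beta
        if self.true_gamma is None:
            self.true_gamma = gamma
        if self.age_ref_index is None:
            self.age_ref_index = i_ref
        if self.period_ref_index is None:
            self.period_ref_index = j_ref
        if self.cohort_ref_indices is None:
            self.cohort_ref_indices = k_ref
        self.true_alpha = np.asarray(self.true_alpha, dtype=float)
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        self.true_gamma = np.asarray(self.true_gamma, dtype=float)
        if len(self.true_alpha) != a or len(self.true_beta) != p:
            raise ConfigurationError("effect vector lengths must match the schemes")
        if len(self.true_gamma) != a + p - 1:
            raise ConfigurationError("true_gamma must have a+p-1 levels")
        if self.true_mu > 0:
            raise ConfigurationError(
                f"true_mu={self.true_mu} implies rates above 1/person-year"
            )
        for name, vec, idx in (
            ("true_alpha", self.true_alpha, (self.age_ref_index,)),
            ("true_beta", self.true_beta, (self.period_ref_index,)),
            ("true_gamma", self.true_gamma, self.cohort_ref_indices),
        ):
            for r in idx:
                if vec[r - 1] != 0.0:
                    raise ConfigurationError(
                        f"{name} must be 0 at its reference level {r}"
                    )

    def reference_spec(self) -> ReferenceSpec:
        """Reference labels matching the zeros of the true effect vectors."""
        cs = derive_cohort_scheme(self.age_scheme, self.period_scheme)
        k1, k2 = self.cohort_ref_indices
        return ReferenceSpec(
            age_ref=self.age_scheme.label(self.age_ref_index),
            period_ref=self.period_scheme.label(self.period_ref_index),
            cohort_refs=(cs.label(k1), cs.label(k2)),
        )

    def truth_frame(self) -> pd.DataFrame:
        """True effects, one row per factor level (for truth.csv)."""
        cs = derive_cohort_scheme(self.age_scheme, self.period_scheme)
        rows = [{"factor": "intercept", "band": "", "value": self.true_mu}]
        for factor, scheme, vec in (
            ("age", self.age_scheme, self.true_alpha),
            ("period", self.period_scheme, self.true_beta),
            ("cohort", cs, self.true_gamma),
        ):
            rows += [
                {"factor": factor, "band": scheme.label(idx + 1), "value": v}
                for idx, v in enumerate(vec)
            ]
        return pd.DataFrame(rows)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, size: int
) -> np.ndarray:
    a = (lo - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_miners(config: SimConfig) -> list[MinerRecord]:
    """Draw exposure histories (no diagnoses); reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_miners
    if n == 0:
        return []
    lo, hi = config.birth_year_range
    births = rng.integers(lo, hi + 1, size=n)
    start_age = np.rint(
        _truncated_normal(rng, config.start_age_mean, config.start_age_sd,
                          config.min_start_age - 0.5, n)
    ).astype(int)
    duration = np.rint(
        _truncated_normal(rng, config.duration_mean, config.duration_sd,
                          config.min_duration - 0.5, n)
    ).astype(int)
    duration = np.maximum(duration, config.min_duration)
    start_age = np.maximum(start_age, config.min_start_age)
    width = len(str(n))
    records = []
    for m in range(n):
        s = int(births[m] + start_age[m])
        e = s + int(duration[m]) - 1
        records.append(
            MinerRecord(
                miner_id=f"M{m + 1:0{width}d}",
                birth_year=int(births[m]),
                exposure_segments=((s, e),),
            )
        )
    return records


def _cell_rates(config: SimConfig, years: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Rate per miner-year from the true effects, nearest band outside the grid."""
    a_s, p_s = config.age_scheme, config.period_scheme
    a = a_s.count
    i = np.clip((ages - a_s.start) // a_s.width + 1, 1, a_s.count)
    j = np.clip((years - p_s.start) // p_s.width + 1, 1, p_s.count)
    k = np.clip(a - i + j, 1, a + p_s.count - 1)
    log_rate = (
        config.true_mu
        + config.true_alpha[i - 1]
        + config.true_beta[j - 1]
        + config.true_gamma[k - 1]
    )
    if np.any(log_rate > 0):
        raise ConfigurationError("configured effects imply rates above 1/person-year")
    return np.exp(log_rate)


def simulate_events(records: list[MinerRecord], config: SimConfig) -> list[MinerRecord]:
    """Assign diagnosis years by an annual Bernoulli hazard 1 - exp(-rate).

    The per-year event probability is driven by the cell of (attained age,
    calendar year); the first event censors the miner's remaining exposure.
    Uses a seed offset so miners and events are independent streams.
    """
    rng = np.random.default_rng((config.seed + 1_000_003) % 2**31)
    if not records:
        return []
    lengths = np.array([len(r.exposure_years()) for r in records])
    years = np.concatenate([r.exposure_years() for r in records])
    births = np.repeat([r.birth_year for r in records], lengths)
    ages = years - births
    rates = _cell_rates(config, years, ages)
    hit = rng.random(len(years)) < -np.expm1(-rates)
    out = []
    pos = 0
    for rec, ln in zip(records, lengths):
        sl = slice(pos, pos + ln)
        pos += ln
        hits = np.flatnonzero(hit[sl])
        if hits.size:
            out.append(replace(rec, diagnosis_year=int(years[sl][hits[0]])))
        else:
            out.append(rec)
    return out


def make_future_pyears(
    records: list[MinerRecord],
    config: SimConfig,
    horizon: BandScheme,
) -> pd.DataFrame:
    """Person-years table for the projection horizon.

    Each undiagnosed miner carries their accumulated exposure duration as a
    frozen annual weight for every horizon year in which their attained age
    falls inside the age scheme.  This is one defensible reading of how an
    ex-dust cohort's 'person-years of dust exposure' continue after mine
    closure; the projection step deliberately takes this table as an input.
    """
    fit_end = config.period_scheme.end
    if horizon.start < fit_end:
        raise ConfigurationError(
            f"horizon starting {horizon.start} overlaps the fitted window (ends {fit_end})"
        )
    a_s = config.age_scheme
    weights = np.zeros((a_s.count, horizon.count))
    for rec in records:
        if rec.diagnosis_year is not None:
            continue
        w = float(rec.total_exposure_years)
        for y in range(horizon.start, horizon.end):
            age = y - rec.birth_year
            i = a_s.index_of(age)
            if i is not None:
                j = horizon.index_of(y)
                weights[i - 1, j - 1] += w
    rows = []
    for i in range(1, a_s.count + 1):
        for j in range(1, horizon.count + 1):
            rows.append(
                {
                    "age_lo": a_s.lower(i),
                    "age_hi": a_s.upper_inclusive(i),
                    "period_lo": horizon.lower(j),
                    "period_hi": horizon.upper_inclusive(j),
                    "person_years": weights[i - 1, j - 1],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """Parameter-recovery summary over simulation replicates.

    ``by_coefficient``: per design column the truth, mean estimate, bias,
    and empirical coverage of the 95% Wald interval, pooled over the
    replicates in which the column was estimable and not separated.
    """

    by_coefficient: pd.DataFrame
    pooled_coverage: float
    mean_deviance_ratio: float
    n_reps: int
    n_failed: int
    n_separated: int

    @property
    def empty(self) -> bool:
        return self.n_reps == 0


def _true_value(config: SimConfig, factor: str, band: str | None) -> float:
    if factor == "intercept":
        return config.true_mu
    cs = derive_cohort_scheme(config.age_scheme, config.period_scheme)
    scheme, vec = {
        "age": (config.age_scheme, config.true_alpha),
        "period": (config.period_scheme, config.true_beta),
        "cohort": (cs, config.true_gamma),
    }[factor]
    return float(vec[scheme.label_index(band) - 1])


def recovery_experiment(config: SimConfig, n_reps: int) -> RecoveryReport:
    """Simulate, tabulate and refit ``n_reps`` cohorts; summarise recovery.

    Replicate seeds are derived deterministically from ``config.seed``.
    Coefficients whose factor level had zero observed cases in a replicate
    (their MLE diverges) are excluded from the bias/coverage pooling and
    counted in ``n_separated``; replicates whose fit fails outright are
    counted in ``n_failed``.
    """
    if n_reps == 0:
        return RecoveryReport(pd.DataFrame(), float("nan"), float("nan"), 0, 0, 0)
    refs = config.reference_spec()
    z = stats.norm.ppf(0.975)
    acc: dict[tuple[str, str | None], list[tuple[float, bool]]] = {}
    dev_ratios = []
    n_failed = 0
    n_separated = 0
    for rep in range(n_reps):
        rep_seed = (config.seed + 7919 * (rep + 1)) % 2**31
        cfg = replace(config, seed=rep_seed)
        records = simulate_events(simulate_miners(cfg), cfg)
        table = tabulate(records, cfg.age_scheme, cfg.period_scheme)
        try:
            res = APCModel(table, "APC", refs).fit()
        except Exception:
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        dev_ratios.append(res.deviance_ratio)
        separated = set(res.separated_levels)
        bse = res.bse.to_numpy()
        for (f, lab), est, se in zip(res.design.column_map, res.params, bse):
            if (f, lab) in separated:
                n_separated += 1
                continue
            truth = _true_value(cfg, f, lab)
            covered = abs(est - truth) <= z * se
            acc.setdefault((f, lab), []).append((est - truth, covered))
    rows = []
    n_cov = 0
    n_tot = 0
    for (f, lab), draws in sorted(acc.items()):
        errs = np.array([d[0] for d in draws])
        cov = np.array([d[1] for d in draws])
        n_cov += int(cov.sum())
        n_tot += len(cov)
        rows.append(
            {
                "factor": f,
                "band": lab if lab is not None else "",
                "true": _true_value(config, f, lab),
                "mean_estimate": _true_value(config, f, lab) + errs.mean(),
                "bias": errs.mean(),
                "mean_abs_error": np.abs(errs).mean(),
                "coverage_95": cov.mean(),
                "n_reps_used": len(cov),
            }
        )
    return RecoveryReport(
        by_coefficient=pd.DataFrame(rows),
        pooled_coverage=n_cov / n_tot if n_tot else float("nan"),
        mean_deviance_ratio=float(np.mean(dev_ratios)) if dev_ratios else float("nan"),
        n_reps=n_reps,
        n_failed=n_failed,
        n_separated=n_separated,
    )
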