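"""Miner exposure histories and their tabulation onto the Lexis grid.

The unit record is a miner's occupational history: birth year, one or more
dust-exposure intervals (whole calendar years, inclusive at both ends), and
an optional pneumoconiosis diagnosis year.  Tabulation accrues one
person-year of dust exposure per exposed calendar year into the (age band,
period band) cell attained in that year, censoring after the diagnosis year
(the diagnosis year itself still accrues), and adds one case to the cell of
the diagnosis.  Age attained in year ``y`` is ``y - birth_year``; sub-year
precision is unobservable in whole-year occupational records and is not
modelled.

Years falling outside the configured band schemes are not silently lost:
they are counted in the table's out-of-window remainder so that person-years
and cases are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BandScheme, cohort_index, derive_cohort_scheme
from .errors import ConfigurationError, DomainError, ValidationError

__all__ = [
    "MinerRecord",
    "RateTable",
    "tabulate",
    "incidence_density",
    "crude_incidence_by_group",
]

PER = 100_000  # incidence density denominator: per 100,000 person-years


@dataclass(frozen=True)
class MinerRecord:
    """One miner's exposure history.

    ``exposure_segments`` are (start_year, end_year) calendar intervals,
    inclusive at both ends, chronologically ordered and non-overlapping.
    """

    miner_id: str
    birth_year: int
    exposure_segments: tuple[tuple[int, int], ...]
    diagnosis_year: int | None = None

    def validate(self) -> None:
        """Raise :class:`ValidationError` (naming the miner) on any broken invariant."""
        mid = self.miner_id
        if not self.exposure_segments:
            raise ValidationError(f"miner {mid}: no exposure segments")
        prev_end = None
        total = 0
        for s, e in self.exposure_segments:
            if e < s:
                raise ValidationError(f"miner {mid}: segment ({s}, {e}) ends before it starts")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(f"miner {mid}: segments overlap or are out of order")
            total += e - s + 1
            prev_end = e
        if total < 1:
            raise ValidationError(f"miner {mid}: total exposure under 1 year")
        first = self.exposure_segments[0][0]
        if self.birth_year >= first:
            raise ValidationError(
                f"miner {mid}: birth year {self.birth_year} not before first exposure {first}"
            )
        if self.diagnosis_year is not None and self.diagnosis_year < first:
            raise ValidationError(
                f"miner {mid}: diagnosis {self.diagnosis_year} before first exposure {first}"
            )

    def exposure_years(self) -> np.ndarray:
        """Calendar years of exposure, censored after the diagnosis year.

        The diagnosis year itself accrues, so a miner never contributes a
        case without the matching person-year.
        """
        years = np.concatenate(
            [np.arange(s, e + 1) for s, e in self.exposure_segments]
        )
        if self.diagnosis_year is not None:
            years = years[years <= self.diagnosis_year]
        return years

    @property
    def total_exposure_years(self) -> int:
        """Uncensored total duration of dust exposure in whole years."""
        return sum(e - s + 1 for s, e in self.exposure_segments)


@dataclass
class RateTable:
    """Age x period grid of case counts and person-years of dust exposure.

    ``cases[i-1, j-1]`` and ``pyears[i-1, j-1]`` hold cell (i, j); the cohort
    (diagonal) index of a cell is ``k = a - i + j``.  ``remainder_pyears``
    and ``remainder_cases`` count exposure years and diagnoses falling
    outside the band schemes, so totals are conserved exactly.
    """

    age_scheme: BandScheme
    period_scheme: BandScheme
    cases: np.ndarray
    pyears: np.ndarray
    remainder_pyears: float = 0.0
    remainder_cases: int = 0
    cohort_scheme: BandScheme = field(init=False)

    def __post_init__(self) -> None:
        a, p = self.age_scheme.count, self.period_scheme.count
        self.cases = np.asarray(self.cases, dtype=float)
        self.pyears = np.asarray(self.pyears, dtype=float)
        if self.cases.shape != (a, p) or self.pyears.shape != (a, p):
            raise ConfigurationError(
                f"cases/pyears must be {a}x{p} arrays, got {self.cases.shape}/{self.pyears.shape}"
            )
        self.cohort_scheme = derive_cohort_scheme(self.age_scheme, self.period_scheme)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cases.shape

    @property
    def cohort_indices(self) -> np.ndarray:
        """k = a - i + j per cell, as an a x p integer array."""
        a, p = self.shape
        i = np.arange(1, a + 1)[:, None]
        j = np.arange(1, p + 1)[None, :]
        return a - i + j

    @property
    def total_cases(self) -> float:
        return float(self.cases.sum())

    @property
    def total_pyears(self) -> float:
        return float(self.pyears.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per Lexis cell with band bounds."""
        a, p = self.shape
        rows = []
        for i in range(1, a + 1):
            for j in range(1, p + 1):
                k = cohort_index(i, j, a)
                rows.append(
                    {
                        "age_lo": self.age_scheme.lower(i),
                        "age_hi": self.age_scheme.upper_inclusive(i),
                        "period_lo": self.period_scheme.lower(j),
                        "period_hi": self.period_scheme.upper_inclusive(j),
                        "cohort_lo": self.cohort_scheme.lower(k),
                        "cohort_hi": self.cohort_scheme.upper_inclusive(k),
                        "cases": self.cases[i - 1, j - 1],
                        "person_years": self.pyears[i - 1, j - 1],
                    }
                )
        return pd.DataFrame(rows)


def tabulate(
    records: list[MinerRecord],
    age_scheme: BandScheme,
    period_scheme: BandScheme,
) -> RateTable:
    """Tabulate miner histories into a :class:`RateTable`.

    Each miner contributes one person-year to the cell of (age attained,
    calendar year) for every exposed year up to and including the diagnosis
    year; each in-window diagnosis adds one case to the cell of (age at
    diagnosis, diagnosis year).  Out-of-window years and diagnoses are
    accumulated in the remainder fields.
    """
    a, p = age_scheme.count, period_scheme.count
    cases = np.zeros((a, p))
    pyears = np.zeros((a, p))
    rem_py = 0.0
    rem_cases = 0
    for rec in records:
        rec.validate()
    if records:
        per_rec = [rec.exposure_years() for rec in records]
        years = np.concatenate(per_rec)
        births = np.repeat([rec.birth_year for rec in records],
                           [len(y) for y in per_rec])
        ages = years - births
        i_idx = (ages - age_scheme.start) // age_scheme.width
        j_idx = (years - period_scheme.start) // period_scheme.width
        valid = (
            (ages >= age_scheme.start) & (ages < age_scheme.end)
            & (years >= period_scheme.start) & (years < period_scheme.end)
        )
        np.add.at(pyears, (i_idx[valid], j_idx[valid]), 1.0)
        rem_py = float((~valid).sum())
    for rec in records:
        if rec.diagnosis_year is not None:
            dy = rec.diagnosis_year
            i = age_scheme.index_of(dy - rec.birth_year)
            j = period_scheme.index_of(dy)
            if i is None or j is None:
                rem_cases += 1
            else:
                cases[i - 1, j - 1] += 1
    return RateTable(
        age_scheme=age_scheme,
        period_scheme=period_scheme,
        cases=cases,
        pyears=pyears,
        remainder_pyears=rem_py,
        remainder_cases=rem_cases,
    )


def incidence_density(cases: float, pyears: float) -> float:
    """Incidence density per 100,000 person-years: ``100000 * cases / pyears``.

    Accepts fractional (projected) case counts.
    """
    if pyears <= 0:
        raise DomainError(f"person-years must be positive, got {pyears}")
    if cases < 0:
        raise DomainError(f"cases must be non-negative, got {cases}")
    return PER * cases / pyears


def crude_incidence_by_group(
    records: list[MinerRecord],
    scheme: BandScheme,
    axis: str = "age-at-diagnosis",
) -> pd.Series:
    """Crude incidence per 100,000 miners, by age-at-diagnosis or diagnosis-period band.

    The numerator of a band is the number of miners diagnosed in it.  The
    denominator is the number of miners *observed* in the band: for the age
    axis, miners whose diagnosis age (cases) or attained-age range during
    exposure (non-cases) intersects the band; for the period axis, the same
    with calendar years.  Bands with no members are returned as NaN
    (undefined), not zero.
    """
    if not records:
        raise ConfigurationError("crude incidence requires a non-empty record list")
    if axis not in ("age-at-diagnosis", "diagnosis-period"):
        raise ConfigurationError(f"unknown axis {axis!r}")
    num = np.zeros(scheme.count)
    den = np.zeros(scheme.count)
    for rec in records:
        rec.validate()
        years = rec.exposure_years()
        if axis == "age-at-diagnosis":
            values = years - rec.birth_year
            diag_value = (
                rec.diagnosis_year - rec.birth_year if rec.diagnosis_year is not None else None
            )
        else:
            values = years
            diag_value = rec.diagnosis_year
        if diag_value is not None:
            member_bands = {scheme.index_of(diag_value)} - {None}
        else:
            member_bands = {scheme.index_of(int(v)) for v in values} - {None}
        for b in member_bands:
            den[b - 1] += 1
        if diag_value is not None:
            b = scheme.index_of(diag_value)
            if b is not None:
                num[b - 1] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(den > 0, PER * num / np.where(den > 0, den, 1), np.nan)
    return pd.Series(rate, index=scheme.labels, name=f"crude_incidence[{axis}]")
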