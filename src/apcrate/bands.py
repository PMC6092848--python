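"""Five-year (or general fixed-width) band schemes for the Lexis grid.

A :class:`BandScheme` describes a contiguous sequence of half-open intervals
``[lo, lo + width)``.  Bands are labelled with their inclusive endpoints, the
convention used in epidemiological tables: the period band ``[1975, 1980)``
is labelled ``"1975-1979"``.

Birth cohorts run along the anti-diagonals of an age x period grid.  For an
``a x p`` grid the diagonal index is ``k = a - i + j`` (age index ``i``,
period index ``j``, both 1-based), ranging over ``1 .. a + p - 1``.  Because
a 5-year age band crossed with a 5-year period band spans nine birth years,
each cell is assigned the cohort band containing the *median* birth year of
the cell; when both schemes share one width that median band is the same for
every cell on a diagonal, so diagonals and cohort bands coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, DomainError

__all__ = [
    "BandScheme",
    "cohort_index",
    "derive_cohort_scheme",
    "cohort_band_label",
]


@dataclass(frozen=True)
class BandScheme:
    """Contiguous fixed-width half-open bands ``[lo, lo + width)``.

    Parameters
    ----------
    start : int
        Lower bound of the first band.
    width : int
        Band width in years (5 in the study design).
    count : int
        Number of bands.
    """

    start: int
    width: int = 5
    count: int = 1

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ConfigurationError(f"band width must be >= 1, got {self.width}")
        if self.count < 1:
            raise ConfigurationError(f"band count must be >= 1, got {self.count}")

    @property
    def end(self) -> int:
        """Exclusive upper bound of the last band."""
        return self.start + self.width * self.count

    def lower(self, idx: int) -> int:
        """Lower bound of band ``idx`` (1-based)."""
        self._check_index(idx)
        return self.start + (idx - 1) * self.width

    def upper_inclusive(self, idx: int) -> int:
        """Inclusive upper bound of band ``idx`` (1-based)."""
        return self.lower(idx) + self.width - 1

    def label(self, idx: int) -> str:
        """Human-readable label ``"lo-hi"`` with inclusive endpoints."""
        lo = self.lower(idx)
        return f"{lo}-{lo + self.width - 1}"

    @property
    def labels(self) -> list[str]:
        return [self.label(i) for i in range(1, self.count + 1)]

    def contains(self, value: int) -> bool:
        return self.start <= value < self.end

    def index_of(self, value: int) -> int | None:
        """1-based band index containing ``value``, or None if outside."""
        if not self.contains(value):
            return None
        return (value - self.start) // self.width + 1

    def nearest_index(self, value: int) -> int:
        """Band index containing ``value``, clipped to the scheme's range."""
        if value < self.start:
            return 1
        if value >= self.end:
            return self.count
        return (value - self.start) // self.width + 1

    def label_index(self, label: str) -> int:
        """1-based index of the band with the given label."""
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise ConfigurationError(
                f"band label {label!r} not in scheme {self.labels[0]}..{self.labels[-1]}"
            ) from None

    def _check_index(self, idx: int) -> None:
        if not 1 <= idx <= self.count:
            raise DomainError(f"band index {idx} outside 1..{self.count}")


def cohort_index(i: int, j: int, a: int) -> int:
    """Diagonal (cohort) index ``k = a - i + j`` of cell ``(i, j)``.

    ``i`` is the 1-based age-band index (of ``a`` bands), ``j`` the 1-based
    period-band index.  For an ``a x p`` grid ``k`` ranges over
    ``1 .. a + p - 1``.
    """
    if not 1 <= i <= a:
        raise DomainError(f"age index {i} outside 1..{a}")
    if j < 1:
        raise DomainError(f"period index {j} must be >= 1")
    return a - i + j


def _median_birth_year(
    age_lo: int, age_hi: int, period_lo: int, period_hi: int
) -> int:
    """Median of the birth years compatible with an (age band, period band) cell.

    With age attained ``age`` in year ``y`` the birth year is ``y - age``;
    over the cell the birth years form the contiguous range
    ``period_lo - age_hi .. period_hi - age_lo``.  Equal band widths make the
    range odd-length, so the median is a whole year.
    """
    lo = period_lo - age_hi
    hi = period_hi - age_lo
    n = hi - lo + 1
    assert n % 2 == 1, "equal-width age/period bands must give an odd birth range"
    return (lo + hi) // 2


def derive_cohort_scheme(age_scheme: BandScheme, period_scheme: BandScheme) -> BandScheme:
    """Cohort band scheme implied by the age and period schemes.

    The k-th cohort band is the median-birth-year band of the k-th diagonal;
    bands are centred on the diagonal medians and step by the common width,
    giving ``a + p - 1`` bands.
    """
    if age_scheme.width != period_scheme.width:
        raise ConfigurationError(
            "age and period schemes must share one band width "
            f"({age_scheme.width} != {period_scheme.width})"
        )
    a = age_scheme.count
    # first diagonal: oldest age band crossed with the first period band
    med = _median_birth_year(
        age_scheme.lower(a),
        age_scheme.upper_inclusive(a),
        period_scheme.lower(1),
        period_scheme.upper_inclusive(1),
    )
    width = age_scheme.width
    return BandScheme(
        start=med - (width - 1) // 2,
        width=width,
        count=a + period_scheme.count - 1,
    )


def cohort_band_label(
    age_band: tuple[int, int],
    period_band: tuple[int, int],
    cohort_scheme: BandScheme,
) -> str:
    """Cohort band label for a Lexis cell, by the median-birth-year rule.

    ``age_band`` and ``period_band`` are (lo, hi) with inclusive endpoints.
    """
    med = _median_birth_year(age_band[0], age_band[1], period_band[0], period_band[1])
    idx = cohort_scheme.index_of(med)
    if idx is None:
        raise ConfigurationError(
            f"median birth year {med} outside cohort scheme "
            f"{cohort_scheme.labels[0]}..{cohort_scheme.labels[-1]}"
        )
    return cohort_scheme.label(idx)
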