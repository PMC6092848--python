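"""Constrained regression designs for the seven age/period/cohort models.

The log-linear rate model decomposes ln E(cases / person-years) into an
intercept plus age, period and birth-cohort effects.  Because cohort =
period - age, the three factors are linearly dependent on the Lexis grid,
and the full three-factor model needs one more constraint than the usual
one-reference-per-factor dummy coding.  The scheme implemented here fixes
*two* cohort bands to zero in the full model (and one in every other model
that includes cohort), which removes the dependence and yields a full-rank
indicator design; the resulting parameter counts on the study's 8x9 grid
are 1 + 7 + 8 + 14 = 30 columns for the full model, hence 72 - 30 = 42
residual degrees of freedom.

Factor levels with no populated (person-years > 0) cells are dropped from
the design and listed in ``dropped_levels``: a dummy column of zeros would
be rank-deficient and its effect is not estimable from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandScheme, cohort_band_label, cohort_index, derive_cohort_scheme
from .cohort import RateTable
from .errors import ConfigurationError, FitError

__all__ = [
    "FACTORS",
    "MODEL_NAMES",
    "ModelSpec",
    "ReferenceSpec",
    "APCDesign",
    "cohort_index",
    "cohort_band_label",
    "derive_cohort_scheme",
    "build_design",
    "reporting_cohorts",
]

FACTORS = ("age", "period", "cohort")
MODEL_NAMES = ("A", "P", "C", "AP", "AC", "PC", "APC")
_NAME_TO_FACTORS = {
    "A": ("age",),
    "P": ("period",),
    "C": ("cohort",),
    "AP": ("age", "period"),
    "AC": ("age", "cohort"),
    "PC": ("period", "cohort"),
    "APC": ("age", "period", "cohort"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the seven legal factor subsets A, P, C, AP, AC, PC, APC."""

    factors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.factors or any(f not in FACTORS for f in self.factors):
            raise ConfigurationError(f"factors must be a non-empty subset of {FACTORS}")
        if len(set(self.factors)) != len(self.factors):
            raise ConfigurationError("duplicate factor")

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            return cls(_NAME_TO_FACTORS[name.upper()])
        except KeyError:
            raise ConfigurationError(
                f"unknown model {name!r}; expected one of {MODEL_NAMES}"
            ) from None

    @property
    def name(self) -> str:
        return "".join(f[0].upper() for f in FACTORS if f in self.factors)

    @property
    def is_full(self) -> bool:
        return len(self.factors) == 3

    def __contains__(self, factor: str) -> bool:
        return factor in self.factors


@dataclass(frozen=True)
class ReferenceSpec:
    """Reference (zero-constrained) band labels per factor.

    ``cohort_refs`` holds two distinct labels; the full three-factor model
    constrains both, while any other model including cohort uses
    ``single_cohort_ref`` (defaulting to the middle cohort band).
    """

    age_ref: str
    period_ref: str
    cohort_refs: tuple[str, str]
    single_cohort_ref: str | None = None

    @classmethod
    def study_default(cls, table: RateTable) -> "ReferenceSpec":
        """Middle age/period bands; cohort refs at diagonal indices 5 and a+p-1.

        On the study's 8x9 grid starting at age 30 / period 1960 this gives
        45-49, 1975-1979 and cohorts 1913-1917 & 1968-1972.
        """
        a, p = table.shape
        cs = table.cohort_scheme
        n_c = cs.count
        first = min(5, n_c - 1) if n_c > 1 else 1
        return cls(
            age_ref=table.age_scheme.label(max(1, a // 2)),
            period_ref=table.period_scheme.label(max(1, p // 2)),
            cohort_refs=(cs.label(first), cs.label(n_c)),
            single_cohort_ref=cs.label(max(1, n_c // 2)),
        )

    def cohort_refs_for(self, model: ModelSpec, cohort_scheme: BandScheme) -> tuple[str, ...]:
        if "cohort" not in model:
            return ()
        if model.is_full:
            if len(set(self.cohort_refs)) != 2:
                raise ConfigurationError(
                    "the full three-factor model needs two distinct cohort references"
                )
            return self.cohort_refs
        single = self.single_cohort_ref
        if single is None:
            single = cohort_scheme.label((cohort_scheme.count + 1) // 2)
        return (single,)


@dataclass
class APCDesign:
    """Coded regression design for one model on one rate table.

    ``matrix`` has one row per populated Lexis cell (ordered by (i, j)) and
    one column per parameter; ``column_map`` maps each column to
    ``("intercept", None)`` or ``(factor, band label)``.  ``offset`` is
    ln(person-years) per row.  Cells with zero person-years are excluded and
    listed in ``excluded_cells``; factor levels with no populated cells are
    listed in ``dropped_levels``.
    """

    model: ModelSpec
    cells: list[tuple[int, int, int]]
    labels: list[tuple[str, str, str]]
    matrix: np.ndarray
    column_map: list[tuple[str, str | None]]
    offset: np.ndarray
    refs: ReferenceSpec
    excluded_cells: list[tuple[int, int]] = field(default_factory=list)
    dropped_levels: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def df_resid(self) -> int:
        """Residual degrees of freedom: populated cells minus parameters."""
        return self.n_cells - self.n_columns

    def column_names(self) -> list[str]:
        return [
            "intercept" if f == "intercept" else f"{f}[{lab}]"
            for f, lab in self.column_map
        ]


def _cell_labels(table: RateTable, i: int, j: int) -> tuple[str, str, str]:
    a = table.age_scheme.count
    k = cohort_index(i, j, a)
    return (
        table.age_scheme.label(i),
        table.period_scheme.label(j),
        table.cohort_scheme.label(k),
    )


def build_design(
    model: ModelSpec | str,
    table: RateTable,
    refs: ReferenceSpec | None = None,
) -> APCDesign:
    """Build the constrained indicator-coded design for ``model`` on ``table``.

    Reference levels' indicator columns are omitted (their effects fixed at
    0); the full three-factor model omits both cohort reference columns.
    The intercept column is always present and rows are ordered by (i, j).
    """
    if isinstance(model, str):
        model = ModelSpec.from_name(model)
    if refs is None:
        refs = ReferenceSpec.study_default(table)
    a, p = table.shape
    cs = table.cohort_scheme

    ref_labels: dict[str, tuple[str, ...]] = {
        "age": (refs.age_ref,) if "age" in model else (),
        "period": (refs.period_ref,) if "period" in model else (),
        "cohort": refs.cohort_refs_for(model, cs),
    }
    scheme_labels = {"age": table.age_scheme.labels, "period": table.period_scheme.labels,
                     "cohort": cs.labels}
    for factor in model.factors:
        for lab in ref_labels[factor]:
            if lab not in scheme_labels[factor]:
                raise ConfigurationError(
                    f"{factor} reference {lab!r} not a band of the table's scheme"
                )

    cells: list[tuple[int, int, int]] = []
    labels: list[tuple[str, str, str]] = []
    excluded: list[tuple[int, int]] = []
    for i in range(1, a + 1):
        for j in range(1, p + 1):
            if table.pyears[i - 1, j - 1] > 0:
                cells.append((i, j, cohort_index(i, j, a)))
                labels.append(_cell_labels(table, i, j))
            else:
                excluded.append((i, j))
    if not cells:
        raise ConfigurationError("no populated cells: all person-years are zero")

    # candidate columns per factor: non-reference levels with >= 1 populated cell
    present: dict[str, set[str]] = {f: set() for f in model.factors}
    for lab_age, lab_per, lab_coh in labels:
        by_factor = {"age": lab_age, "period": lab_per, "cohort": lab_coh}
        for f in model.factors:
            present[f].add(by_factor[f])

    column_map: list[tuple[str, str | None]] = [("intercept", None)]
    dropped: list[tuple[str, str]] = []
    for f in model.factors:
        for lab in scheme_labels[f]:
            if lab in ref_labels[f]:
                continue
            if lab not in present[f]:
                dropped.append((f, lab))
            else:
                column_map.append((f, lab))

    n = len(cells)
    X = np.zeros((n, len(column_map)))
    X[:, 0] = 1.0
    col_index = {fl: c for c, fl in enumerate(column_map)}
    for r, (lab_age, lab_per, lab_coh) in enumerate(labels):
        by_factor = {"age": lab_age, "period": lab_per, "cohort": lab_coh}
        for f in model.factors:
            c = col_index.get((f, by_factor[f]))
            if c is not None:
                X[r, c] = 1.0

    if np.linalg.matrix_rank(X) != X.shape[1]:
        raise FitError(
            "design matrix is rank-deficient; the two-reference cohort "
            "constraint should make this impossible on a populated grid"
        )

    offset = np.log(np.array([table.pyears[i - 1, j - 1] for i, j, _ in cells]))
    return APCDesign(
        model=model,
        cells=cells,
        labels=labels,
        matrix=X,
        column_map=column_map,
        offset=offset,
        refs=refs,
        excluded_cells=excluded,
        dropped_levels=dropped,
    )


def reporting_cohorts(table: RateTable) -> list[str]:
    """Cohort band labels shown in reports: all diagonals minus the two extremes.

    The first and last diagonals each contain a single Lexis cell, so their
    effects rest on one observation; they stay in the fit but are omitted
    from reported effect tables.
    """
    cs = table.cohort_scheme
    if cs.count < 3:
        raise ConfigurationError(
            f"grid too small: {cs.count} cohort diagonals, need at least 3"
        )
    return cs.labels[1:-1]
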