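"""Poisson rate model with log link and person-years offset.

The model for cell (i, j) with cohort diagonal k is

    ln E(theta_ijk) = ln N_ijk + mu + alpha_i + beta_j + gamma_k

with theta the case count, N the person-years of dust exposure, and the
effects identified by the reference constraints of :mod:`apcrate.design`.
Fitting is by maximum likelihood via iteratively reweighted least squares
(IRLS), the canonical Newton scoring algorithm for the Poisson log-linear
model; the residual term of the rate equation is pure Poisson sampling
variation (no dispersion parameter).

Goodness of fit is judged by the deviance referred to a chi-square
distribution on the residual degrees of freedom; deviance/df close to 1
indicates an adequate model.  :func:`compare_models` fits all seven
age/period/cohort factor subsets and applies the selection rule used in
this literature: among adequate models (p > 0.05) prefer the smaller
deviance, with the full three-factor model preferred when adequate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort import RateTable
from .design import (
    MODEL_NAMES,
    APCDesign,
    ModelSpec,
    ReferenceSpec,
    build_design,
)
from .errors import ConfigurationError, DomainError

__all__ = [
    "APCModel",
    "APCResults",
    "ModelComparison",
    "fit",
    "deviance",
    "gof_pvalue",
    "compare_models",
]


def deviance(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Poisson deviance ``2 * sum[obs*ln(obs/fit) - (obs - fit)]``.

    Uses the convention 0*ln(0) = 0; additive over disjoint cell sets.
    """
    obs = np.asarray(observed, dtype=float)
    fit_ = np.asarray(fitted, dtype=float)
    if np.any(obs < 0) or np.any(fit_ < 0):
        raise DomainError("observed and fitted counts must be non-negative")
    if np.any((obs > 0) & (fit_ == 0)):
        raise DomainError("fitted count is zero where observed count is positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = special.xlogy(obs, obs) - special.xlogy(obs, fit_)
    return float(2.0 * np.sum(term - (obs - fit_)))


def gof_pvalue(D: float, df: int) -> float:
    """Upper-tail chi-square probability of deviance ``D`` on ``df`` degrees of freedom."""
    if df < 1:
        raise DomainError(f"degrees of freedom must be >= 1, got {df}")
    if D < 0:
        raise DomainError(f"deviance must be non-negative, got {D}")
    return float(stats.chi2.sf(D, df))


def format_pvalue(p: float) -> str:
    """Display convention of epidemiological model-comparison tables: 2 d.p., '<0.01' below."""
    return "<0.01" if p < 0.005 else f"{p:.2f}"


class APCModel:
    """Poisson rate model on a :class:`~apcrate.cohort.RateTable`.

    Parameters
    ----------
    table : RateTable
        Cases and person-years on the Lexis grid.
    model : str or ModelSpec, default "APC"
        Which factor subset to include (A, P, C, AP, AC, PC or APC).
    refs : ReferenceSpec, optional
        Reference (zero) levels; defaults to the middle age/period bands and
        the two-reference cohort constraint of the study design.

    Examples
    --------
    >>> res = APCModel(table).fit()           # doctest: +SKIP
    >>> print(res.summary())                  # doctest: +SKIP
    """

    def __init__(
        self,
        table: RateTable,
        model: str | ModelSpec = "APC",
        refs: ReferenceSpec | None = None,
    ) -> None:
        self.table = table
        self.design = build_design(model, table, refs)
        self.spec = self.design.model
        self.endog = np.array(
            [table.cases[i - 1, j - 1] for i, j, _ in self.design.cells]
        )

    def fit(self, tol: float = 1e-10, maxiter: int = 100) -> "APCResults":
        """Maximum-likelihood fit by IRLS.

        Starting values are zero for all coefficients except the intercept,
        initialised at ln(total cases / total person-years), which makes the
        first step finite.  Convergence is declared when the relative change
        in deviance falls below ``tol`` (default 1e-10), within ``maxiter``
        iterations.
        """
        X = self.design.matrix
        off = self.design.offset
        y = self.endog
        if y.sum() <= 0:
            raise ConfigurationError("cannot fit: no cases in the table")

        beta = np.zeros(X.shape[1])
        beta[0] = np.log(y.sum() / np.exp(off).sum())
        dev = np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            eta = X @ beta + off
            mu = np.exp(eta)
            # working response and weights of Newton scoring for the log link
            z = eta - off + (y - mu) / mu
            w = np.sqrt(mu)
            coef, *_ = np.linalg.lstsq(X * w[:, None], z * w, rcond=None)
            beta = coef
            new_dev = deviance(y, np.exp(X @ beta + off))
            if abs(dev - new_dev) <= tol * (abs(new_dev) + 0.1):
                dev = new_dev
                converged = True
                break
            dev = new_dev
        if not converged:
            warnings.warn(
                f"IRLS did not converge in {maxiter} iterations "
                f"(model {self.spec.name})",
                RuntimeWarning,
                stacklevel=2,
            )

        mu_hat = np.exp(X @ beta + off)
        W = mu_hat
        xtwx = X.T @ (X * W[:, None])
        try:
            cov = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(xtwx)
        return APCResults(
            model=self,
            params=beta,
            cov_matrix=cov,
            deviance=dev,
            converged=converged,
            n_iter=n_iter,
        )


def fit(design: APCDesign, table: RateTable, **kwargs) -> "APCResults":
    """Functional entry point: fit a prebuilt design against its table."""
    m = APCModel.__new__(APCModel)
    m.table = table
    m.design = design
    m.spec = design.model
    m.endog = np.array([table.cases[i - 1, j - 1] for i, j, _ in design.cells])
    return m.fit(**kwargs)


@dataclass
class APCResults:
    """Fitted Poisson rate model.

    Effect accessors (:attr:`alpha`, :attr:`beta`, :attr:`gamma`) return a
    Series over *all* band labels of the factor, with reference levels at
    exactly 0 and unestimable (empty) levels as NaN.
    """

    model: APCModel
    params: np.ndarray
    cov_matrix: np.ndarray
    deviance: float
    converged: bool
    n_iter: int

    # -- parameter views ---------------------------------------------------

    @property
    def design(self) -> APCDesign:
        return self.model.design

    @property
    def param_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.design.column_names())

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_matrix)), index=self.design.column_names()
        )

    @property
    def cov_params(self) -> pd.DataFrame:
        names = self.design.column_names()
        return pd.DataFrame(self.cov_matrix, index=names, columns=names)

    @property
    def mu(self) -> float:
        """Model intercept (log rate at the reference levels)."""
        return float(self.params[0])

    def _effect(self, factor: str, labels: list[str]) -> pd.Series:
        values = pd.Series(np.nan, index=labels, name=factor)
        if factor in self.design.model:
            refs = {
                "age": (self.design.refs.age_ref,),
                "period": (self.design.refs.period_ref,),
                "cohort": self.design.refs.cohort_refs_for(
                    self.design.model, self.model.table.cohort_scheme
                ),
            }[factor]
            for lab in refs:
                values[lab] = 0.0
            for (f, lab), est in zip(self.design.column_map, self.params):
                if f == factor:
                    values[lab] = est
        else:
            values[:] = 0.0
        return values

    @property
    def alpha(self) -> pd.Series:
        """Age effects per band (0 at the reference)."""
        return self._effect("age", self.model.table.age_scheme.labels)

    @property
    def beta(self) -> pd.Series:
        """Period effects per band (0 at the reference)."""
        return self._effect("period", self.model.table.period_scheme.labels)

    @property
    def gamma(self) -> pd.Series:
        """Cohort effects per band (0 at the reference(s))."""
        return self._effect("cohort", self.model.table.cohort_scheme.labels)

    # -- fitted values and fit statistics ----------------------------------

    @property
    def fitted_rate(self) -> np.ndarray:
        """Fitted rate exp(mu + alpha + beta + gamma) per populated cell (cases/person-year)."""
        return np.exp(self.design.matrix @ self.params)

    @property
    def fitted_count(self) -> np.ndarray:
        """Fitted expected case count (rate x person-years) per populated cell."""
        return np.exp(self.design.matrix @ self.params + self.design.offset)

    @property
    def df_resid(self) -> int:
        return self.design.df_resid

    @property
    def deviance_ratio(self) -> float:
        return self.deviance / self.df_resid

    @property
    def p_value(self) -> float:
        """Goodness-of-fit p: deviance against chi-square on the residual df."""
        return gof_pvalue(self.deviance, self.df_resid)

    @property
    def separated_levels(self) -> list[tuple[str, str]]:
        """Factor levels whose observed cases are all zero (MLE diverges to -inf)."""
        y = self.model.endog
        out = []
        for c, (f, lab) in enumerate(self.design.column_map):
            if f == "intercept":
                continue
            mask = self.design.matrix[:, c] == 1.0
            if mask.any() and y[mask].sum() == 0:
                out.append((f, lab))
        return out

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        est = self.param_series
        se = self.bse
        return pd.DataFrame({"lower": est - z * se, "upper": est + z * se})

    def to_frame(self) -> pd.DataFrame:
        """One row per parameter: factor, band label, estimate, SE, is_reference."""
        rows = [
            {
                "factor": f if f != "intercept" else "intercept",
                "band": lab if lab is not None else "",
                "estimate": est,
                "std_error": se,
                "is_reference": False,
            }
            for (f, lab), est, se in zip(
                self.design.column_map, self.params, self.bse.to_numpy()
            )
        ]
        refs = self.design.refs
        ref_pairs = []
        if "age" in self.design.model:
            ref_pairs.append(("age", refs.age_ref))
        if "period" in self.design.model:
            ref_pairs.append(("period", refs.period_ref))
        for lab in refs.cohort_refs_for(self.design.model, self.model.table.cohort_scheme):
            ref_pairs.append(("cohort", lab))
        for f, lab in ref_pairs:
            rows.append(
                {"factor": f, "band": lab, "estimate": 0.0, "std_error": 0.0,
                 "is_reference": True}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary table in the style of GLM result objects."""
        d = self.design
        lines = [
            f"{'Poisson rate model':^60}",
            "=" * 60,
            f"Model: {d.model.name:<12} Cells: {d.n_cells:<8} Parameters: {d.n_columns}",
            f"Deviance: {self.deviance:<12.4f} df: {self.df_resid:<6} "
            f"Deviance/df: {self.deviance_ratio:.4f}",
            f"GoF p-value: {format_pvalue(self.p_value):<8} "
            f"Converged: {self.converged} ({self.n_iter} iterations)",
            "-" * 60,
            f"{'parameter':<24}{'estimate':>12}{'std err':>12}",
            "-" * 60,
        ]
        for name, est, se in zip(
            d.column_names(), self.params, self.bse.to_numpy()
        ):
            lines.append(f"{name:<24}{est:>12.4f}{se:>12.4f}")
        if d.dropped_levels:
            lines.append("-" * 60)
            lines.append(
                "not estimable (no populated cells): "
                + ", ".join(f"{f}[{lab}]" for f, lab in d.dropped_levels)
            )
        lines.append("=" * 60)
        return "\n".join(lines)

    # -- downstream conveniences -------------------------------------------

    def project(self, future_pyears, config=None):
        """Project incidence density and expected cases; see :func:`apcrate.project.project`."""
        from .project import project as _project

        return _project(self, future_pyears, config)


@dataclass
class ModelComparison:
    """Deviance comparison of the seven factor-subset models."""

    frame: pd.DataFrame
    selected: str | None

    def __str__(self) -> str:
        return self.frame.to_string() + f"\nselected: {self.selected}"


def compare_models(
    table: RateTable,
    refs: ReferenceSpec | None = None,
) -> ModelComparison:
    """Fit all seven models and compare deviance, df, deviance/df and GoF p.

    Selection rule: among adequate models (p > 0.05) prefer the lowest
    deviance, with the full three-factor model preferred whenever it is
    adequate.  A failed fit is reported as a flagged row; the other models
    are still compared.
    """
    if table.cohort_scheme.count < 2:
        raise ConfigurationError("model comparison needs a grid larger than 1x1")
    if refs is None:
        refs = ReferenceSpec.study_default(table)
    rows = []
    for name in MODEL_NAMES:
        try:
            res = APCModel(table, name, refs).fit()
            rows.append(
                {
                    "model": name,
                    "deviance": res.deviance,
                    "df": res.df_resid,
                    "deviance_ratio": res.deviance_ratio,
                    "p_value": res.p_value,
                    "p_display": format_pvalue(res.p_value),
                    "converged": res.converged,
                }
            )
        except Exception as exc:  # single failure must not sink the table
            warnings.warn(f"model {name} failed: {exc}", RuntimeWarning, stacklevel=2)
            rows.append(
                {
                    "model": name,
                    "deviance": np.nan,
                    "df": np.nan,
                    "deviance_ratio": np.nan,
                    "p_value": np.nan,
                    "p_display": "failed",
                    "converged": False,
                }
            )
    frame = pd.DataFrame(rows).set_index("model")
    adequate = frame[(frame["p_value"] > 0.05) & frame["converged"]]
    if "APC" in adequate.index:
        selected = "APC"
    elif len(adequate):
        selected = str(adequate["deviance"].idxmin())
    else:
        selected = None
    return ModelComparison(frame=frame, selected=selected)
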