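"""Regression of percent eGFR reduction on clinical covariates.

The analysis mirrors the standard functional-outcome workflow after partial
nephrectomy: each candidate predictor (age, gender, tumor size, invasion
depth, ischemia time, pre-operative eGFR, nephrometry scores, RAIV, PRAIV)
is first screened in a univariate ordinary-least-squares model, then all
covariates of interest enter a single multivariate OLS model.  Coefficients
are reported both raw (outcome units per covariate unit) and as standardized
betas (coefficients after z-scoring outcome and covariates; binary
covariates are coded 0/1 before standardization), so effect strengths are
comparable across covariates.  In a univariate model the standardized beta
equals the Pearson correlation and its square equals R².

The model object follows the statsmodels idiom: build
:class:`EgfrReductionModel` from a DataFrame, call :meth:`~EgfrReductionModel.fit`,
and read estimates off the returned :class:`EgfrReductionResults` (or print
``summary()``).  ``fit_univariate`` / ``fit_multivariate`` are the matching
one-call conveniences.  Missing data are handled by complete-case analysis
per model; the number of dropped rows is recorded on the results.

Literature-derived univariate models (intercept/slope/R² as published) are
shipped as :data:`PUBLISHED_PRAIV_MODEL` and :data:`PUBLISHED_AGE_MODEL` for
prediction and for calibrating the synthetic-cohort generator; they are
carried verbatim, never refitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "StatisticsError",
    "InsufficientDataError",
    "DegenerateDesignError",
    "CollinearityError",
    "ModelSpec",
    "EgfrReductionModel",
    "EgfrReductionResults",
    "fit_univariate",
    "fit_multivariate",
    "PublishedUnivariateModel",
    "PUBLISHED_PRAIV_MODEL",
    "PUBLISHED_AGE_MODEL",
]


class StatisticsError(ValueError):
    """Base class for statistical-analysis failures."""


class InsufficientDataError(StatisticsError):
    """Too few complete cases to fit the requested model."""


class DegenerateDesignError(StatisticsError):
    """A covariate has zero variance in the complete cases."""


class CollinearityError(StatisticsError):
    """The design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )


@dataclass(frozen=True)
class ModelSpec:
    """Outcome column, ordered covariate list, and standardization flag."""

    outcome: str
    covariates: tuple[str, ...]
    standardize: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if not self.covariates:
            raise StatisticsError("covariate list must be non-empty")
        if self.outcome in self.covariates:
            raise StatisticsError(f"outcome {self.outcome!r} cannot also be a covariate")


def _rank_deficient_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that QR-with-pivoting places beyond the numerical rank."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


class EgfrReductionModel:
    """OLS model of a functional outcome on clinical covariates.

    Parameters
    ----------
    data
        Cohort table, one row per patient.
    outcome
        Name of the outcome column (typically ``pct_reduction``).
    covariates
        Ordered covariate column names.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, covariates: Sequence[str]):
        self.spec = ModelSpec(outcome=outcome, covariates=tuple(covariates))
        missing = [c for c in (outcome, *covariates) if c not in data.columns]
        if missing:
            raise StatisticsError(f"columns not in data: {', '.join(missing)}")
        self.data = data

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome: str, covariates: Sequence[str]
    ) -> "EgfrReductionModel":
        return cls(data, outcome, covariates)

    def fit(self) -> "EgfrReductionResults":
        spec = self.spec
        cols = [spec.outcome, *spec.covariates]
        frame = self.data[cols].apply(pd.to_numeric, errors="coerce")
        complete = frame.dropna()
        n_dropped = len(frame) - len(complete)
        n = len(complete)
        min_n = max(3, len(spec.covariates) + 2)
        if n < min_n:
            raise InsufficientDataError(
                f"{n} complete cases; at least {min_n} required for "
                f"{len(spec.covariates)} covariate(s)"
            )
        y = complete[spec.outcome].to_numpy(dtype=float)
        X = complete[list(spec.covariates)].to_numpy(dtype=float)

        degenerate = [
            name
            for name, col in zip(spec.covariates, X.T)
            if np.ptp(col) == 0.0
        ]
        if degenerate:
            raise DegenerateDesignError(
                "zero-variance covariate(s): " + ", ".join(degenerate)
            )
        design = sm.add_constant(pd.DataFrame(X, columns=list(spec.covariates)))
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            raise CollinearityError(_rank_deficient_columns(X, list(spec.covariates)))

        res = sm.OLS(y, design).fit()
        sd_y = float(np.std(y, ddof=1))
        sd_x = np.std(X, axis=0, ddof=1)
        std_betas = pd.Series(
            res.params[list(spec.covariates)].to_numpy() * sd_x / sd_y,
            index=list(spec.covariates),
        )
        return EgfrReductionResults(
            model=self,
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            std_betas=std_betas,
            rsquared=float(res.rsquared),
            nobs=n,
            n_dropped=n_dropped,
            _sm_results=res,
        )


@dataclass
class EgfrReductionResults:
    """Fitted coefficients, standardized betas, p-values and fit diagnostics."""

    model: EgfrReductionModel
    params: pd.Series  # raw coefficients, 'const' + covariates
    bse: pd.Series  # standard errors, same index
    pvalues: pd.Series  # two-sided t-test p-values, same index
    std_betas: pd.Series  # standardized betas, covariates only
    rsquared: float
    nobs: int
    n_dropped: int
    _sm_results: object = field(repr=False, default=None)

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    def predict(self, covariate_values: Mapping[str, float]) -> float:
        """intercept + Σ coefficient·value; every model covariate must be supplied."""
        missing = [c for c in self.model.spec.covariates if c not in covariate_values]
        if missing:
            raise StatisticsError(f"missing covariate value(s): {', '.join(missing)}")
        return self.intercept + sum(
            float(self.params[c]) * float(covariate_values[c])
            for c in self.model.spec.covariates
        )

    def summary(self) -> str:
        """Plain-text coefficient table in the style of a clinical regression report."""
        rows = []
        for c in self.model.spec.covariates:
            rows.append(
                {
                    "covariate": c,
                    "coef": self.params[c],
                    "se": self.bse[c],
                    "std_beta": self.std_betas[c],
                    "p_value": self.pvalues[c],
                }
            )
        table = pd.DataFrame(rows).to_string(index=False, float_format=lambda v: f"{v:.4f}")
        head = (
            f"OLS: {self.model.spec.outcome} ~ "
            + " + ".join(self.model.spec.covariates)
            + f"\nn = {self.nobs} (dropped {self.n_dropped} incomplete), "
            f"R2 = {self.rsquared:.4f}, intercept = {self.intercept:.4f}\n"
        )
        return head + table


def fit_univariate(
    cohort: pd.DataFrame, outcome: str, covariate: str
) -> EgfrReductionResults:
    """Simple regression of ``outcome`` on one covariate."""
    return EgfrReductionModel(cohort, outcome, [covariate]).fit()


def fit_multivariate(cohort: pd.DataFrame, spec: ModelSpec) -> EgfrReductionResults:
    """One OLS model containing every covariate of ``spec`` simultaneously."""
    return EgfrReductionModel(cohort, spec.outcome, spec.covariates).fit()


@dataclass(frozen=True)
class PublishedUnivariateModel:
    """A literature-derived simple-regression line y = intercept + slope·x.

    Coefficients are carried verbatim from the published report (synthetic
    refits never overwrite them); ``r_squared`` is the published coefficient
    of determination used to calibrate simulation noise.
    """

    name: str
    covariate: str
    intercept: float
    slope: float
    r_squared: float

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * float(x)


#: Published univariate model of percent eGFR reduction on PRAIV (%).
PUBLISHED_PRAIV_MODEL = PublishedUnivariateModel(
    name="praiv", covariate="praiv", intercept=1.512, slope=2.752, r_squared=0.194
)

#: Published univariate model of percent eGFR reduction on age (years).
PUBLISHED_AGE_MODEL = PublishedUnivariateModel(
    name="age", covariate="age", intercept=-4.958, slope=0.324, r_squared=0.073
)
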