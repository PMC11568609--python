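"""Predictive layer: OLS regression, fixed published models, calibrations.

Two kinds of model live here.  Freshly *fitted* models: ordinary
least-squares multiple regression (via statsmodels, with t-based coefficient
p-values and R²) and polynomial biomass–area calibration curves.  And the
*fixed* published models from :mod:`halophen.published` — the general
projected-area equation and the two per-population substrate-salinity
equations — evaluated exactly as printed, never re-fitted in place.

Units: PA cm², Sd cm, Ht cm, Sal.s. mM NaCl, ΔE1 dimensionless.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .published import PA_MODEL, SALINITY_MODEL_HIGHER, SALINITY_MODEL_LOWER

__all__ = [
    "LinearModel",
    "BiomassCurve",
    "fit_ols",
    "predict_pa",
    "predict_salinity",
    "salinity_prediction_valid",
    "fit_biomass_curve",
    "r_squared",
]


@dataclasses.dataclass
class LinearModel:
    """A fitted linear model: named coefficients, p-values, diagnostics."""

    intercept: float
    coefficients: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    residual_se: float
    n: int

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table.loc[:, list(self.coefficients)].to_numpy(dtype=float)
        beta = np.array(list(self.coefficients.values()))
        return self.intercept + X @ beta

    def to_text(self) -> str:
        """Serialize to a plain-text key-value format."""
        lines = [
            f"n = {self.n}",
            f"r_squared = {self.r_squared!r}",
            f"residual_se = {self.residual_se!r}",
            f"coef const = {self.intercept!r}",
        ]
        for name, value in self.coefficients.items():
            lines.append(f"coef {name} = {value!r}")
        for name, value in self.p_values.items():
            lines.append(f"pvalue {name} = {value!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LinearModel":
        n = 0
        r2 = rse = intercept = 0.0
        coefficients: dict[str, float] = {}
        p_values: dict[str, float] = {}
        for line in text.splitlines():
            if not line.strip():
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key == "n":
                n = int(value)
            elif key == "r_squared":
                r2 = float(value)
            elif key == "residual_se":
                rse = float(value)
            elif key == "coef const":
                intercept = float(value)
            elif key.startswith("coef "):
                coefficients[key[5:]] = float(value)
            elif key.startswith("pvalue "):
                p_values[key[7:]] = float(value)
        return cls(intercept, coefficients, p_values, r2, rse, n)


def fit_ols(
    table: pd.DataFrame, response: str, predictors: Sequence[str]
) -> LinearModel:
    """Ordinary least squares of ``response`` on named ``predictors``.

    Coefficient p-values are two-sided t tests; rank deficiency is rejected
    with the offending (collinear) columns named.
    """
    predictors = list(predictors)
    cols = [response] + predictors
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    y = table[response].to_numpy(dtype=float)
    X = table.loc[:, predictors].to_numpy(dtype=float)
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in model columns")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > number of predictors + 1")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name columns involved: those whose removal restores full rank
        collinear = []
        for j, name in enumerate(predictors):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
                collinear.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    res = sm.OLS(y, design).fit()
    return LinearModel(
        intercept=float(res.params[0]),
        coefficients={name: float(b) for name, b in zip(predictors, res.params[1:])},
        p_values={name: float(q) for name, q in zip(predictors, res.pvalues[1:])},
        r_squared=float(res.rsquared),
        residual_se=float(np.sqrt(res.mse_resid)),
        n=n,
    )


def predict_pa(sal_s, sd, ht, delta_e1):
    """Projected area (cm²) from the general published model.

    PA = 83.34 − 0.23·Sal.s. + 1629.97·Sd + 25.71·Ht − 6.38·ΔE1
    """
    m = PA_MODEL
    return (
        m["const"]
        + m["Sal.s."] * np.asarray(sal_s, dtype=float)
        + m["Sd"] * np.asarray(sd, dtype=float)
        + m["Ht"] * np.asarray(ht, dtype=float)
        + m["dE1"] * np.asarray(delta_e1, dtype=float)
    )


def predict_salinity(pa, sd, ht, delta_e1, population: str):
    """Substrate salinity (mM) from the published per-population model."""
    if population == "lower":
        m = SALINITY_MODEL_LOWER
    elif population == "higher":
        m = SALINITY_MODEL_HIGHER
    else:
        raise ValueError(f"unknown population {population!r}; use 'lower' or 'higher'")
    return (
        m["const"]
        + m["PA"] * np.asarray(pa, dtype=float)
        + m["Sd"] * np.asarray(sd, dtype=float)
        + m["Ht"] * np.asarray(ht, dtype=float)
        + m["dE1"] * np.asarray(delta_e1, dtype=float)
    )


def salinity_prediction_valid(sal_s) -> np.ndarray:
    """Flag predictions inside the physically grown range [0, 1000] mM.

    Predictions are never clipped; this flag marks extrapolations.
    """
    arr = np.asarray(sal_s, dtype=float)
    return (arr >= 0.0) & (arr <= 1000.0)


class BiomassCurve:
    """Polynomial biomass-vs-projected-area calibration (degree 1 or 2).

    sklearn-style estimator: ``fit(pa, biomass)`` stores ``coef_`` (highest
    power first, np.polyval order) and ``r_squared_``.
    """

    def __init__(self, degree: int = 1, response: str = "FW", population: str = "lower"):
        self.degree = degree
        self.response = response
        self.population = population

    def get_params(self, deep: bool = True) -> dict:
        return {
            "degree": self.degree,
            "response": self.response,
            "population": self.population,
        }

    def set_params(self, **params) -> "BiomassCurve":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, pa, biomass) -> "BiomassCurve":
        if self.degree not in (1, 2):
            raise ValueError("calibration degree must be 1 or 2")
        x = np.asarray(pa, dtype=float)
        y = np.asarray(biomass, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("pa and biomass must be 1-D arrays of equal length")
        if x.size <= self.degree + 1:
            raise ValueError("need more points than degree + 1")
        self.coef_ = np.polyfit(x, y, self.degree)
        self.r_squared_ = r_squared(y, np.polyval(self.coef_, x))
        return self

    def predict(self, pa) -> np.ndarray:
        return np.polyval(self.coef_, np.asarray(pa, dtype=float))


def fit_biomass_curve(
    pa_values, biomass_values, degree: int, response: str = "FW",
    population: str = "lower",
) -> BiomassCurve:
    """Fit a biomass–area calibration curve (thin wrapper)."""
    return BiomassCurve(degree=degree, response=response, population=population).fit(
        pa_values, biomass_values
    )


def r_squared(actual, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("actual and predicted must be equal-length 1-D, n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined for constant actual values")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot
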