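"""Linear vs quadratic (Wundt) regression of enjoyment on complexity.

Two nested OLS models are fitted per complexity covariate x (average
information content, or average Cloud Momentum):

    linear:     z(y) ~ z(x)
    quadratic:  z(y) ~ z(x) + z(x²)

with every variable z-scored to unit variance so the coefficients are
standardized βs (a raw-scale switch is provided). A significant *negative*
squared-term β with a higher quadratic R² is the inverted-U (Wundt)
signature; a significant linear β without it supports a monotone
relationship.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import statsmodels.api as sm

__all__ = ["RegressionReport", "ModelComparison", "fit_linear", "fit_quadratic", "compare_models"]

_COND_LIMIT = 1e8


@dataclass(frozen=True)
class RegressionReport:
    """Standardized OLS fit summary for one covariate.

    ``beta``, ``t`` and ``p`` are keyed by term name ("x", and "x2" for the
    quadratic model); the intercept is fitted but not reported (it is 0 by
    construction under z-scoring).
    """

    model: Literal["linear", "quadratic"]
    covariate: str
    beta: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    r_squared: float
    f_statistic: float
    f_pvalue: float
    n: int
    standardized: bool = True


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector cannot be z-scored")
    return (v - v.mean()) / sd


def _fit(y: np.ndarray, terms: dict[str, np.ndarray], standardize: bool):
    if standardize:
        y = _zscore(y)
        terms = {k: _zscore(v) for k, v in terms.items()}
    X = sm.add_constant(np.column_stack(list(terms.values())))
    if np.linalg.cond(X) > _COND_LIMIT:
        raise ValueError("regressors are collinear beyond tolerance")
    res = sm.OLS(y, X).fit()
    names = list(terms)
    return res, names


def fit_linear(
    x: np.ndarray, y: np.ndarray, covariate: str = "x", standardize: bool = True
) -> RegressionReport:
    """OLS of enjoyment on one complexity covariate (df = n − 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    res, names = _fit(y, {"x": x}, standardize)
    return _report("linear", covariate, res, names, len(x), standardize)


def fit_quadratic(
    x: np.ndarray, y: np.ndarray, covariate: str = "x", standardize: bool = True
) -> RegressionReport:
    """OLS of enjoyment on the covariate and its square (df = n − 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct covariate values")
    res, names = _fit(y, {"x": x, "x2": x**2}, standardize)
    return _report("quadratic", covariate, res, names, len(x), standardize)


def _report(model, covariate, res, names, n, standardized) -> RegressionReport:
    return RegressionReport(
        model=model,
        covariate=covariate,
        beta={nm: float(res.params[i + 1]) for i, nm in enumerate(names)},
        t={nm: float(res.tvalues[i + 1]) for i, nm in enumerate(names)},
        p={nm: float(res.pvalues[i + 1]) for i, nm in enumerate(names)},
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        n=n,
        standardized=standardized,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Verdict of the linear-vs-quadratic comparison on the same data."""

    verdict: Literal["wundt", "linear", "neither"]
    linear: RegressionReport
    quadratic: RegressionReport
    alpha: float


def compare_models(
    lin: RegressionReport, quad: RegressionReport, alpha: float = 0.05
) -> ModelComparison:
    """"wundt" iff the quadratic model explains more variance and its squared
    term is significantly negative; else "linear" iff the linear slope is
    significant; else "neither"."""
    if lin.n != quad.n or lin.covariate != quad.covariate:
        raise ValueError("reports must describe the same data and covariate")
    wundt = (
        quad.r_squared > lin.r_squared
        and quad.p["x2"] < alpha
        and quad.beta["x2"] < 0
    )
    if wundt:
        verdict = "wundt"
    elif lin.p["x"] < alpha:
        verdict = "linear"
    else:
        verdict = "neither"
    return ModelComparison(verdict=verdict, linear=lin, quadratic=quad, alpha=alpha)
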