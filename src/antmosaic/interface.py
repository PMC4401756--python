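"""Cross-species phenotype-function regressions with jackknife inference.

The phenotypic interface of the mutualism is the regression, across ant
species, of the mean EFN abundance of the plants each species visits on a
functional ant trait (body size or recruitment).  Slopes are tested with
delete-one jackknife pseudo-values (robust to extreme species), one-tailed in
the hypothesized direction: EFN increases with ant size (bigger ants need
more nectar) and decreases with recruitment, which itself trades off against
size.  The fitted line plus its mean-response confidence band is later used
to classify populations as phenotypically matched or mismatched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import _TINY_P, _direction_ok, _tail_p

__all__ = [
    "RegressionFit",
    "InterfaceModel",
    "jackknife_regression",
    "fit_interface",
    "predict_band",
    "DEFAULT_TAILS",
]

#: Hypothesized test directions per (predictor, response) pair.
DEFAULT_TAILS = {
    ("body_length_mm", "mean_efn_visited"): "greater",
    ("recruitment", "mean_efn_visited"): "less",
    ("recruitment", "body_length_mm"): "less",
    ("recruitment", "mean_herbivory_visited"): "less",
    ("body_length_mm", "mean_herbivory_visited"): "two-sided",
}


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit plus jackknife inference for the slope.

    ``s`` is the residual standard deviation (df = n - 2); ``x_mean`` and
    ``sxx`` feed the closed-form mean-response confidence band.
    """

    slope: float
    intercept: float
    jk_slope: float
    jk_se: float
    t: float
    p: float
    tail: str
    n: int
    s: float
    x_mean: float
    sxx: float


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm = x.mean()
    ym = y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    return slope, ym - slope * xm


def jackknife_regression(x, y, tail: str = "two-sided") -> RegressionFit:
    """Simple linear regression with delete-one jackknife slope inference.

    The slope/intercept are ordinary least squares on the full data; the
    slope's pseudo-values b_i* = n b - (n-1) b_(-i) give the jackknife
    estimate and SE, tested as t = estimate/SE with n-1 df under ``tail``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"jackknife regression needs n >= 4, got {n}")
    if y.size != n or not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be equal-length finite arrays")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")

    slope, intercept = _ols(x, y)
    idx = np.arange(n)
    loo = np.array([_ols(x[idx != i], y[idx != i])[0] for i in range(n)])
    pseudo = n * slope - (n - 1) * loo
    jk_slope = float(pseudo.mean())
    jk_se = float(pseudo.std(ddof=1) / np.sqrt(n))
    if jk_se == 0.0:
        if jk_slope == 0.0:  # exactly flat, exactly certain: no effect
            t, p = 0.0, _tail_p(0.0, n - 1, tail)
        else:
            t = float(np.inf if jk_slope > 0 else -np.inf)
            p = _TINY_P if _direction_ok(jk_slope, tail) else 1.0
    else:
        t = jk_slope / jk_se
        p = _tail_p(t, n - 1, tail)

    resid = y - (intercept + slope * x)
    s = float(np.sqrt((resid @ resid) / (n - 2)))
    xm = float(x.mean())
    sxx = float(((x - xm) ** 2).sum())
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        jk_slope=jk_slope,
        jk_se=jk_se,
        t=float(t),
        p=p,
        tail=tail,
        n=n,
        s=s,
        x_mean=xm,
        sxx=sxx,
    )


@dataclass(frozen=True)
class InterfaceModel:
    """A fitted phenotype-function relationship across ant species."""

    predictor: str  # "body_length_mm" or "recruitment"
    response: str
    transform: str  # "identity" or "log10" (applied to the predictor)
    fit: RegressionFit
    alpha: float
    species: tuple[str, ...]

    def transform_x(self, x):
        if self.transform == "log10":
            x = np.asarray(x, dtype=float)
            if np.any(x <= 0):
                raise ValueError("log10 transform requires positive predictor values")
            return np.log10(x)
        return np.asarray(x, dtype=float)


def fit_interface(
    profiles: pd.DataFrame,
    predictor: str = "body_length_mm",
    response: str = "mean_efn_visited",
    tail: str | None = None,
    log_recruitment: bool = True,
    alpha: float = 0.05,
) -> InterfaceModel:
    """Fit the cross-species regression of ``response`` on ``predictor``.

    Only species profiles passing the >= 6 distinct-plants filter (column
    ``eligible``) enter the fit.  Recruitment is log10-transformed by default
    (its max-statistic construction makes it strongly right-skewed); pass
    ``log_recruitment=False`` for the raw scale.  The default tail follows
    the hypothesized direction for the pair, two-sided for unlisted pairs.
    """
    eligible = profiles[profiles["eligible"]] if "eligible" in profiles else profiles
    eligible = eligible.dropna(subset=[predictor, response])
    if len(eligible) < 4:
        raise ValueError(
            f"need >= 4 eligible species profiles, got {len(eligible)}"
        )
    if tail is None:
        tail = DEFAULT_TAILS.get((predictor, response), "two-sided")
    transform = "log10" if (predictor == "recruitment" and log_recruitment) else "identity"
    x = eligible[predictor].to_numpy(dtype=float)
    if transform == "log10":
        x = np.log10(x)
    y = eligible[response].to_numpy(dtype=float)
    fit = jackknife_regression(x, y, tail=tail)
    return InterfaceModel(
        predictor=predictor,
        response=response,
        transform=transform,
        fit=fit,
        alpha=alpha,
        species=tuple(eligible["species"]),
    )


def predict_band(
    model: InterfaceModel | RegressionFit,
    x0: float,
    alpha: float | None = None,
    kind: str = "mean",
) -> tuple[float, float, float]:
    """Predicted response and confidence band at ``x0`` (already on the
    fitted predictor scale).

    ``kind='mean'`` (default) is the confidence band for the mean response,

        yhat +- t_{1-alpha/2, n-2} * s * sqrt(1/n + (x0 - xbar)^2 / Sxx),

    narrowest at x0 = xbar and zero-width when the fit is noiseless.
    ``kind='prediction'`` adds the +1 term for a single new observation;
    ``kind='jackknife'`` uses yhat +- t_{1-alpha/2, n-1} * jk_se * |x0 - xbar|
    propagated from the jackknife slope SE.
    """
    fit = model.fit if isinstance(model, InterfaceModel) else model
    if alpha is None:
        alpha = model.alpha if isinstance(model, InterfaceModel) else 0.05
    if not math.isfinite(x0):
        raise ValueError("x0 must be finite")
    yhat = fit.intercept + fit.slope * x0
    if kind == "mean":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, fit.n - 2)
        half = tcrit * fit.s * math.sqrt(1.0 / fit.n + (x0 - fit.x_mean) ** 2 / fit.sxx)
    elif kind == "prediction":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, fit.n - 2)
        half = tcrit * fit.s * math.sqrt(1.0 + 1.0 / fit.n + (x0 - fit.x_mean) ** 2 / fit.sxx)
    elif kind == "jackknife":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, fit.n - 1)
        half = tcrit * fit.jk_se * abs(x0 - fit.x_mean)
    else:
        raise ValueError(f"unknown band kind {kind!r}")
    return float(yhat), float(yhat - half), float(yhat + half)
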