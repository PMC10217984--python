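"""Nonlinear least-squares estimation of growth-curve parameters.

The centrepiece is :class:`GrowthCurveRegressor`, a scikit-learn style
estimator: ``fit(X, y)`` takes ages in weeks and trait values, estimates
``(A, B, k)`` for one growth law by Levenberg–Marquardt least squares,
and exposes the fitted parameters, goodness of fit and inflection
analytics as trailing-underscore attributes.  Positivity of the
parameters is enforced by optimising over ``log(A, B, k)``; the
Jacobian is analytic (chain rule over :func:`goosegrowth.models.gradient`).

Module-level helpers (:func:`initial_guess`, :func:`fit_model`,
:func:`fit_all_models`, :func:`select_best`) are thin wrappers around
the estimator for pipeline use on :class:`TraitSeries` objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .models import (
    MODEL_NAMES,
    InflectionSummary,
    ModelParams,
    evaluate,
    gradient,
    inflection_summary,
    resolve_model_name,
)

__all__ = [
    "TraitSeries",
    "FitResult",
    "GrowthCurveRegressor",
    "InitializationError",
    "SelectionError",
    "initial_guess",
    "fit_model",
    "fit_all_models",
    "select_best",
]


class InitializationError(RuntimeError):
    """Raised when a linearised initial guess cannot be computed."""


class SelectionError(RuntimeError):
    """Raised when no candidate fit is eligible for model selection."""


@dataclass(frozen=True)
class TraitSeries:
    """One breed × trait longitudinal series of weekly (age, value) pairs.

    Ages must be strictly increasing and values strictly positive.
    Rate tables need at least 2 observations; a 3-parameter fit needs
    at least 5.
    """

    breed: str
    trait: str
    unit: str
    weeks: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        weeks = np.asarray(self.weeks, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "weeks", weeks)
        object.__setattr__(self, "values", values)
        if weeks.ndim != 1 or values.ndim != 1 or weeks.size != values.size:
            raise ValueError("weeks and values must be 1-d arrays of equal length")
        if not np.all(np.isfinite(weeks)) or not np.all(np.isfinite(values)):
            raise ValueError("weeks and values must be finite")
        if np.any(np.diff(weeks) <= 0):
            raise ValueError("weeks must be strictly increasing")
        if np.any(weeks < 0):
            raise ValueError("weeks must be non-negative")
        if np.any(values <= 0):
            raise ValueError("trait values must be strictly positive")

    def __len__(self) -> int:
        return self.weeks.size

    @property
    def key(self) -> tuple[str, str]:
        return (self.breed, self.trait)


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one growth law to one trait series."""

    model: str
    params: ModelParams
    r_squared: float
    sse: float
    n_iter: int
    converged: bool
    inflection: InflectionSummary
    message: str = ""
    series: TraitSeries | None = field(default=None, repr=False, compare=False)

    def predict(self, t):
        return evaluate(self.model, self.params, t)


def _linearized_guess(name: str, A: float, weeks: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """(B, k) from ordinary regression on the model's linearisation.

    Each law becomes linear in ``t`` after a transform of ``y`` given a
    provisional asymptote ``A``: the transformed value is
    ``ln(B) - k t``, so an OLS line yields both parameters.  Points
    where the transform is undefined (``y >= A``) are skipped.
    """
    y = values
    with np.errstate(divide="ignore", invalid="ignore"):
        if name == "logistic":
            z = np.log(A / y - 1.0)
        elif name == "gompertz":
            z = np.log(-np.log(y / A))
        else:  # von_bertalanffy
            z = np.log(1.0 - (y / A) ** (1.0 / 3.0))
    usable = np.isfinite(z)
    if usable.sum() < 2 or np.unique(weeks[usable]).size < 2:
        raise InitializationError(
            f"fewer than 2 usable points for the {name} linearisation"
        )
    slope, intercept = np.polyfit(weeks[usable], z[usable], 1)
    B, k = float(np.exp(intercept)), float(-slope)
    if not (B > 0 and k > 0) or not np.isfinite(B) or not np.isfinite(k):
        raise InitializationError(
            f"degenerate {name} linearisation (B={B:.3g}, k={k:.3g})"
        )
    return B, k


def initial_guess(model, series: TraitSeries) -> ModelParams:
    """Starting values for the nonlinear fit.

    ``A`` is guessed as 1.05 × the largest observed value; ``(B, k)``
    come from OLS on the model's linearisation.  Raises
    :class:`InitializationError` when the transform is degenerate
    (e.g. a constant series); callers may then fall back to fixed
    defaults.
    """
    name = resolve_model_name(model)
    A = 1.05 * float(np.max(series.values))
    B, k = _linearized_guess(name, A, series.weeks, series.values)
    return ModelParams(A=A, B=B, k=k)


class GrowthCurveRegressor(RegressorMixin, BaseEstimator):
    """Fit one sigmoidal growth law to (age, trait value) data.

    Parameters
    ----------
    model : str, default="logistic"
        ``"logistic"``, ``"gompertz"`` or ``"von_bertalanffy"``.
    max_iter : int, default=500
        Maximum number of residual evaluations for the optimiser.
    tol_sse : float, default=1e-12
        Relative decrease of the sum of squared errors below which the
        fit is declared converged.
    tol_step : float, default=1e-10
        Relative parameter-step size below which the fit is declared
        converged.
    fallback_B, fallback_k : float, defaults 10.0 and 0.5
        Starting values used when the linearised initial guess is
        degenerate.

    Attributes
    ----------
    A_, B_, k_ : float
        Estimated asymptote, adjustment parameter and growth rate.
    params_ : ModelParams
    r_squared_ : float
        ``1 - SSE/SST`` with SST about the observed mean; may be
        negative for a fit worse than the mean.
    sse_ : float
    n_iter_ : int
    converged_ : bool
    inflection_ : InflectionSummary

    Examples
    --------
    >>> import numpy as np
    >>> from goosegrowth.fitting import GrowthCurveRegressor
    >>> t = np.arange(13.0)
    >>> y = 5000 / (1 + 30 * np.exp(-0.6 * t))
    >>> reg = GrowthCurveRegressor(model="logistic").fit(t, y)
    >>> round(reg.A_), round(reg.B_), round(reg.k_, 3)
    (5000, 30, 0.6)
    """

    def __init__(
        self,
        model: str = "logistic",
        max_iter: int = 500,
        tol_sse: float = 1e-12,
        tol_step: float = 1e-10,
        fallback_B: float = 10.0,
        fallback_k: float = 0.5,
    ):
        self.model = model
        self.max_iter = max_iter
        self.tol_sse = tol_sse
        self.tol_step = tol_step
        self.fallback_B = fallback_B
        self.fallback_k = fallback_k

    @staticmethod
    def _as_time(X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must be 1-d ages or a single-column 2-d array")
            t = t[:, 0]
        elif t.ndim != 1:
            raise ValueError("X must be 1-d ages or a single-column 2-d array")
        return t

    def fit(self, X, y):
        """Estimate ``(A, B, k)`` from ages ``X`` (weeks) and values ``y``."""
        name = resolve_model_name(self.model)
        t = self._as_time(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("X and y have inconsistent lengths")
        if t.size < 5:
            raise ValueError(
                f"at least 5 observations are required for a 3-parameter fit, got {t.size}"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite")
        if np.any(y <= 0):
            raise ValueError("trait values must be strictly positive")
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0.0:
            raise ValueError("series has zero variance; growth-curve fit is undefined")

        A0 = 1.05 * float(y.max())
        try:
            B0, k0 = _linearized_guess(name, A0, t, y)
        except InitializationError:
            B0, k0 = float(self.fallback_B), float(self.fallback_k)
        theta0 = np.log([A0, B0, k0])

        def residuals(theta):
            return evaluate(name, np.exp(theta), t) - y

        def jac(theta):
            p = np.exp(theta)
            dA, dB, dk = gradient(name, p, t)
            # chain rule for the log-reparameterisation
            return np.column_stack([dA * p[0], dB * p[1], dk * p[2]])

        res = least_squares(
            residuals,
            theta0,
            jac=jac,
            method="lm",
            ftol=self.tol_sse,
            xtol=self.tol_step,
            gtol=1e-14,
            max_nfev=self.max_iter,
        )
        A, B, k = np.exp(res.x)
        self.model_ = name
        self.params_ = ModelParams(A=float(A), B=float(B), k=float(k))
        self.A_, self.B_, self.k_ = self.params_.A, self.params_.B, self.params_.k
        self.sse_ = float(2.0 * res.cost)
        self.r_squared_ = 1.0 - self.sse_ / sst
        self.n_iter_ = int(res.nfev)
        self.converged_ = bool(res.status > 0)
        self.message_ = str(res.message)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            self.inflection_ = inflection_summary(name, self.params_)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Trait values on the fitted curve at ages ``X``."""
        check_is_fitted(self, "params_")
        t = self._as_time(X)
        return np.asarray(evaluate(self.model_, self.params_, t), dtype=float)

    def result(self, series: TraitSeries | None = None) -> FitResult:
        """Package the fitted state as an immutable :class:`FitResult`."""
        check_is_fitted(self, "params_")
        return FitResult(
            model=self.model_,
            params=self.params_,
            r_squared=self.r_squared_,
            sse=self.sse_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            inflection=self.inflection_,
            message=self.message_,
            series=series,
        )


def fit_model(model, series: TraitSeries, **settings) -> FitResult:
    """Fit one growth law to a trait series; see :class:`GrowthCurveRegressor`."""
    reg = GrowthCurveRegressor(model=resolve_model_name(model), **settings)
    reg.fit(series.weeks, series.values)
    return reg.result(series)


def fit_all_models(series: TraitSeries, models=MODEL_NAMES, **settings) -> list[FitResult]:
    """Fit every requested growth law to the same series."""
    return [fit_model(m, series, **settings) for m in models]


def select_best(results: list[FitResult]) -> FitResult:
    """Pick the best fit by R²; ties by lower SSE, then fixed model order.

    Non-converged candidates are excluded with a warning; if every
    candidate failed, a :class:`SelectionError` is raised.
    """
    if not results:
        raise ValueError("select_best requires a non-empty list of fits")
    eligible = []
    for r in results:
        if r.converged:
            eligible.append(r)
        else:
            warnings.warn(
                f"excluding non-converged {r.model} fit from model selection",
                UserWarning,
                stacklevel=2,
            )
    if not eligible:
        raise SelectionError("no converged fit to select from")
    order = {name: i for i, name in enumerate(MODEL_NAMES)}
    return min(eligible, key=lambda r: (-r.r_squared, r.sse, order[r.model]))
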