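"""Three-parameter sigmoidal growth laws and their inflection analytics.

The logistic, Gompertz and von Bertalanffy models are the standard
fixed-shape growth laws used for poultry body weight and body-size
traits.  All three map age ``t`` (weeks) to a trait value ``Y`` through
an upper asymptote ``A`` (the mature trait value), an adjustment
parameter ``B`` (locating the curve relative to the time origin) and an
instantaneous growth-rate constant ``k`` (per week):

========================  =======================  ===============
model                     curve                    inflection value
========================  =======================  ===============
logistic                  ``A / (1 + B e^{-kt})``  ``A / 2``
von Bertalanffy           ``A (1 - B e^{-kt})^3``  ``8A / 27``
Gompertz                  ``A exp(-B e^{-kt})``    ``A / e``
========================  =======================  ===============

The inflection point is where the growth rate ``dY/dt`` is maximal;
its age (weeks at the growth inflection, often abbreviated WGI) and
value (trait value at the inflection, BGI) have closed forms, as does
the maximal weekly increment.  Everything in this module is a pure
function of ``(model, A, B, k)``; the fitting machinery lives in
:mod:`goosegrowth.fitting`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MODEL_NAMES",
    "GrowthModelSpec",
    "ModelParams",
    "InflectionSummary",
    "ParameterDomainError",
    "evaluate",
    "gradient",
    "inflection_summary",
]

#: Canonical model order; also the tie-break order in model selection.
MODEL_NAMES: tuple[str, ...] = ("logistic", "gompertz", "von_bertalanffy")

_ALIASES = {
    "logistic": "logistic",
    "gompertz": "gompertz",
    "von_bertalanffy": "von_bertalanffy",
    "bertalanffy": "von_bertalanffy",
    "von bertalanffy": "von_bertalanffy",
}


class ParameterDomainError(ValueError):
    """Raised when a growth-law parameter lies outside its domain."""


def resolve_model_name(model: "str | GrowthModelSpec") -> str:
    """Normalise a model identifier (spec object or name/alias) to a canonical name."""
    name = model.name if isinstance(model, GrowthModelSpec) else str(model)
    key = name.strip().lower().replace("-", "_")
    try:
        return _ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown growth model {name!r}; expected one of {MODEL_NAMES}"
        ) from None


@dataclass(frozen=True)
class GrowthModelSpec:
    """One of the three growth laws.

    Parameters
    ----------
    name:
        ``"logistic"``, ``"gompertz"`` or ``"von_bertalanffy"``
        (the alias ``"bertalanffy"`` is accepted and normalised).
    """

    name: str
    n_params: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", resolve_model_name(self.name))
        if self.n_params != 3:
            raise ValueError("all supported growth laws have exactly 3 parameters")


@dataclass(frozen=True)
class ModelParams:
    """Parameters ``(A, B, k)`` of a growth law.

    ``A`` is the upper asymptote in trait units, ``B`` the dimensionless
    adjustment parameter and ``k`` the instantaneous growth rate per
    week.  All three must be strictly positive — each law degenerates
    otherwise.
    """

    A: float
    B: float
    k: float

    def __post_init__(self) -> None:
        for name, value in (("A", self.A), ("B", self.B), ("k", self.k)):
            if not math.isfinite(value) or value <= 0:
                raise ParameterDomainError(
                    f"parameter {name} must be finite and > 0, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.k], dtype=float)


@dataclass(frozen=True)
class InflectionSummary:
    """Closed-form inflection analytics of a fitted growth curve.

    Attributes
    ----------
    age:
        Age in weeks at the inflection point (WGI), ``ln(B)/k`` for the
        logistic and Gompertz laws and ``ln(3B)/k`` for von Bertalanffy.
        May be negative when the inflection precedes the time origin.
    value:
        Trait value at the inflection (BGI): ``A/2``, ``A/e`` or
        ``8A/27`` respectively.
    max_increment:
        The curve's maximal slope (trait units per week): ``k·value/2``
        (logistic), ``k·value`` (Gompertz), ``3k·value/2``
        (von Bertalanffy).
    before_origin:
        True when ``age < 0``, i.e. the inflection falls before hatch.
    """

    age: float
    value: float
    max_increment: float
    before_origin: bool = False


def _coerce_params(params: "ModelParams | tuple[float, float, float]") -> ModelParams:
    if isinstance(params, ModelParams):
        return params
    return ModelParams(*params)


def evaluate(model, params, t):
    """Evaluate the growth law ``Y(t)``.

    Parameters
    ----------
    model:
        Model name or :class:`GrowthModelSpec`.
    params:
        :class:`ModelParams` or an ``(A, B, k)`` tuple.
    t:
        Age in weeks; scalar or array, negative values permitted for
        extrapolation before the time origin.

    Returns
    -------
    float or ndarray with the shape of ``t``.
    """
    p = _coerce_params(params)
    name = resolve_model_name(model)
    t = np.asarray(t, dtype=float)
    e = np.exp(-p.k * t)
    if name == "logistic":
        y = p.A / (1.0 + p.B * e)
    elif name == "gompertz":
        y = p.A * np.exp(-p.B * e)
    else:  # von_bertalanffy
        y = p.A * (1.0 - p.B * e) ** 3
    return y if y.ndim else float(y)


def gradient(model, params, t):
    """Analytic partial derivatives ``(∂Y/∂A, ∂Y/∂B, ∂Y/∂k)`` at ``t``.

    Used as the Jacobian of the least-squares fit; each component has
    the shape of ``t``.
    """
    p = _coerce_params(params)
    name = resolve_model_name(model)
    t = np.asarray(t, dtype=float)
    e = np.exp(-p.k * t)
    if name == "logistic":
        denom = (1.0 + p.B * e) ** 2
        dA = 1.0 / (1.0 + p.B * e)
        dB = -p.A * e / denom
        dk = p.A * p.B * t * e / denom
    elif name == "gompertz":
        y = p.A * np.exp(-p.B * e)
        dA = y / p.A
        dB = -y * e
        dk = y * p.B * t * e
    else:  # von_bertalanffy
        u = 1.0 - p.B * e
        dA = u**3
        dB = -3.0 * p.A * e * u**2
        dk = 3.0 * p.A * p.B * t * e * u**2
    if t.ndim:
        return dA, dB, dk
    return float(dA), float(dB), float(dk)


def inflection_summary(model, params) -> InflectionSummary:
    """Closed-form inflection age, value and maximal weekly increment.

    A negative inflection age (logistic/Gompertz with ``B < 1``,
    von Bertalanffy with ``3B < 1``) means the curve inflects before the
    time origin; it is returned as-is with ``before_origin=True`` and a
    :class:`UserWarning`, not raised as an error.
    """
    p = _coerce_params(params)
    name = resolve_model_name(model)
    if name == "logistic":
        value = p.A / 2.0
        age = math.log(p.B) / p.k
        max_increment = p.k * value / 2.0
    elif name == "gompertz":
        value = p.A / math.e
        age = math.log(p.B) / p.k
        max_increment = p.k * value
    else:  # von_bertalanffy
        value = 8.0 * p.A / 27.0
        age = math.log(3.0 * p.B) / p.k
        max_increment = 3.0 * p.k * value / 2.0
    before = age < 0
    if before:
        warnings.warn(
            f"{name} inflection age {age:.3f} weeks precedes the time origin",
            UserWarning,
            stacklevel=2,
        )
    return InflectionSummary(age=age, value=value, max_increment=max_increment, before_origin=before)
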