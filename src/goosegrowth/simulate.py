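"""Synthetic longitudinal cohorts and packaged reference data.

:func:`simulate_cohort` emulates the design behind weekly mean trait
trajectories: a cohort of birds measured at fixed ages, each bird's
value scattered around a shared growth curve by multiplicative
lognormal noise (so values stay positive and the spread scales with
size).  The weekly means across birds form the series the fitting
modules consume, which makes parameter-recovery experiments
self-contained: simulate → fit → compare with the generating truth.

The module also ships two small reference tables measured on Shitou and
Wuzong geese over weeks 0–12: weekly mean body weights
(:func:`load_body_weight`) and the published best-fit growth-law
parameters for ten body traits (:func:`load_reference_parameters`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .fitting import TraitSeries
from .models import ModelParams, evaluate, resolve_model_name

__all__ = [
    "SimConfig",
    "CohortSim",
    "simulate_cohort",
    "load_body_weight",
    "load_reference_parameters",
    "write_cohort_csv",
]

BREEDS = ("shitou", "wuzong")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated cohort.

    Attributes
    ----------
    model : str
        Growth law generating the mean trajectory.
    params : ModelParams
        Generating ``(A, B, k)``.
    weeks : sequence of float
        Sampling ages; default weeks 0–12, the usual early-growth grid.
    n_birds : int
        Cohort size; default 40 birds per breed.
    noise_cv : float
        Between-bird coefficient of variation of the multiplicative
        lognormal noise (0 = deterministic means).
    seed : int
        Seed; identical configs produce bit-identical cohorts.
    """

    model: str
    params: ModelParams
    weeks: tuple[float, ...] = tuple(float(w) for w in range(13))
    n_birds: int = 40
    noise_cv: float = 0.0
    seed: int = 0
    breed: str = "simulated"
    trait: str = "body weight"
    unit: str = "g"

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", resolve_model_name(self.model))
        if not isinstance(self.params, ModelParams):
            object.__setattr__(self, "params", ModelParams(*self.params))
        object.__setattr__(self, "weeks", tuple(float(w) for w in self.weeks))
        if self.n_birds < 1:
            raise ValueError("n_birds must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = ModelParams(**raw.pop("params"))
        if "weeks" in raw:
            raw["weeks"] = tuple(raw["weeks"])
        return cls(params=params, **raw)


@dataclass(frozen=True)
class CohortSim:
    """Simulated cohort: per-bird trajectories plus the weekly-mean series."""

    config: SimConfig
    birds: pd.DataFrame = field(repr=False)  # columns bird, week, value
    means: TraitSeries


def simulate_cohort(config: SimConfig) -> CohortSim:
    """Draw one cohort of birds following the configured growth law.

    Bird *b* at age *t* takes the value ``Y(t) · exp(ε)`` with
    ``ε ~ N(0, σ)`` and ``σ = sqrt(ln(1 + cv²))``, so each bird's value
    has coefficient of variation ``cv`` around the curve.  Weekly means
    are averaged across birds.  Deterministic under a fixed seed.
    """
    weeks = np.asarray(config.weeks, dtype=float)
    curve = np.asarray(evaluate(config.model, config.params, weeks), dtype=float)
    if config.noise_cv == 0.0:
        # exact: averaging identical birds must not introduce rounding
        values = np.tile(curve, (config.n_birds, 1))
        means_values = curve.copy()
    else:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        rng = np.random.default_rng(config.seed)
        eps = rng.normal(0.0, sigma, size=(config.n_birds, weeks.size))
        values = curve[None, :] * np.exp(eps)
        means_values = values.mean(axis=0)
    birds = pd.DataFrame(
        {
            "bird": np.repeat(np.arange(config.n_birds), weeks.size),
            "week": np.tile(weeks, config.n_birds),
            "value": values.ravel(),
        }
    )
    means = TraitSeries(
        breed=config.breed,
        trait=config.trait,
        unit=config.unit,
        weeks=weeks,
        values=means_values,
    )
    return CohortSim(config=config, birds=birds, means=means)


def write_cohort_csv(sim: CohortSim, path) -> None:
    """Write weekly means in the long format the trait-CSV reader accepts."""
    cfg = sim.config
    pd.DataFrame(
        {
            "breed": cfg.breed,
            "trait": cfg.trait,
            "unit": cfg.unit,
            "week": sim.means.weeks,
            "value": sim.means.values,
        }
    ).to_csv(path, index=False)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("goosegrowth.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_body_weight(breed: str) -> TraitSeries:
    """Weekly mean body weight (g) of one goose breed, weeks 0–12.

    ``breed`` is ``"shitou"`` or ``"wuzong"`` (case-insensitive).
    """
    key = breed.strip().lower()
    if key not in BREEDS:
        raise ValueError(f"unknown breed {breed!r}; expected one of {BREEDS}")
    df = _read_packaged("body_weight_means.csv")
    sub = df[df["breed"] == key].sort_values("week")
    return TraitSeries(
        breed=key,
        trait="body weight",
        unit="g",
        weeks=sub["week"].to_numpy(dtype=float),
        values=sub["value"].to_numpy(dtype=float),
    )


def load_reference_parameters() -> pd.DataFrame:
    """Published best-fit growth-law parameters for ten body traits.

    Columns: trait, unit, breed, model, A, B, k, r_squared,
    inflexion_age, inflection_value — one row per breed × trait, as
    reported for Shitou and Wuzong geese.  Useful for analytics-only
    workflows (inflection summaries without refitting).
    """
    return _read_packaged("best_fit_parameters.csv")
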