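"""Trait-table I/O and the end-to-end analysis pipeline.

`read_trait_csv` loads long-format trait tables
(``breed,trait,unit,week,value``) into :class:`TraitSeries` objects.
`run_pipeline` fits all three growth laws to each series, selects the
best by R², computes inflection analytics and the weekly-rate table,
and collects everything into an :class:`AnalysisReport` that serialises
to a fitted-parameter CSV (trait, breed, model, A, B, K, R², inflexion
age, inflection value) and a weekly-rates CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult, TraitSeries, fit_all_models, select_best
from .models import MODEL_NAMES, InflectionSummary, ModelParams
from .rates import rate_table

__all__ = [
    "TraitCSVError",
    "SeriesOutcome",
    "AnalysisReport",
    "read_trait_csv",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger("goosegrowth")

_REQUIRED = ["breed", "trait", "unit", "week", "value"]


class TraitCSVError(ValueError):
    """Raised when a trait CSV violates the expected schema."""


def read_trait_csv(path) -> list[TraitSeries]:
    """Parse a long-format trait CSV into one series per (breed, trait).

    The file must be UTF-8 with header ``breed,trait,unit,week,value``;
    weeks are sorted within each series.  Missing columns, non-numeric
    weeks or values, and duplicated (breed, trait, week) rows raise
    :class:`TraitCSVError` naming the offending line (1-based, header
    included).
    """
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise TraitCSVError(f"{path}: file is empty (expected header {_REQUIRED})")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TraitCSVError(f"{path}: missing columns {missing}")
    for col in ("week", "value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            line = int(bad[0]) + 2  # header is line 1
            raise TraitCSVError(
                f"{path}: non-numeric {col} {df.loc[bad[0], col]!r} at line {line}"
            )
        if df[col].isna().any():
            line = int(df.index[df[col].isna()][0]) + 2
            raise TraitCSVError(f"{path}: missing {col} at line {line}")
        df[col] = numeric
    dup = df.duplicated(subset=["breed", "trait", "week"], keep="first")
    if dup.any():
        line = int(df.index[dup][0]) + 2
        row = df.loc[df.index[dup][0]]
        raise TraitCSVError(
            f"{path}: duplicate (breed, trait, week) = "
            f"({row['breed']}, {row['trait']}, {row['week']}) at line {line}"
        )
    series = []
    for (breed, trait), grp in df.groupby(["breed", "trait"], sort=True):
        grp = grp.sort_values("week")
        units = grp["unit"].unique()
        if len(units) != 1:
            raise TraitCSVError(
                f"{path}: inconsistent units {list(units)} for ({breed}, {trait})"
            )
        try:
            series.append(
                TraitSeries(
                    breed=str(breed),
                    trait=str(trait),
                    unit=str(units[0]),
                    weeks=grp["week"].to_numpy(dtype=float),
                    values=grp["value"].to_numpy(dtype=float),
                )
            )
        except ValueError as exc:
            raise TraitCSVError(f"{path}: invalid series ({breed}, {trait}): {exc}")
    return series


@dataclass
class SeriesOutcome:
    """Per-series pipeline result: three fits, the selection, and rates."""

    series: TraitSeries
    fits: list[FitResult] = field(default_factory=list)
    best: FitResult | None = None
    rates: pd.DataFrame | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class AnalysisReport:
    """Full pipeline output with provenance metadata."""

    outcomes: list[SeriesOutcome]
    metadata: dict

    def fit_frame(self) -> pd.DataFrame:
        """Fitted-parameter table, one row per series × model, best flagged."""
        rows = []
        for oc in self.outcomes:
            if not oc.ok:
                continue
            for fit in oc.fits:
                rows.append(
                    {
                        "trait": oc.series.trait,
                        "unit": oc.series.unit,
                        "breed": oc.series.breed,
                        "model": fit.model,
                        "A": fit.params.A,
                        "B": fit.params.B,
                        "k": fit.params.k,
                        "r_squared": fit.r_squared,
                        "inflexion_age": fit.inflection.age,
                        "inflection_value": fit.inflection.value,
                        "max_increment": fit.inflection.max_increment,
                        "converged": fit.converged,
                        "best": oc.best is fit,
                    }
                )
        return pd.DataFrame(rows)

    def rates_frame(self) -> pd.DataFrame:
        rows = []
        for oc in self.outcomes:
            if not oc.ok or oc.rates is None:
                continue
            tbl = oc.rates.copy()
            tbl.insert(0, "breed", oc.series.breed)
            tbl.insert(1, "trait", oc.series.trait)
            tbl.insert(2, "unit", oc.series.unit)
            rows.append(tbl)
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    def to_dict(self) -> dict:
        """JSON-serialisable form; round-trips through :meth:`from_dict`."""
        out = {"metadata": self.metadata, "series": []}
        for oc in self.outcomes:
            entry = {
                "breed": oc.series.breed,
                "trait": oc.series.trait,
                "unit": oc.series.unit,
                "weeks": oc.series.weeks.tolist(),
                "values": oc.series.values.tolist(),
                "error": oc.error,
                "fits": [],
                "best_model": oc.best.model if oc.best else None,
            }
            for fit in oc.fits:
                entry["fits"].append(
                    {
                        "model": fit.model,
                        "A": fit.params.A,
                        "B": fit.params.B,
                        "k": fit.params.k,
                        "r_squared": fit.r_squared,
                        "sse": fit.sse,
                        "n_iter": fit.n_iter,
                        "converged": fit.converged,
                        "inflexion_age": fit.inflection.age,
                        "inflection_value": fit.inflection.value,
                        "max_increment": fit.inflection.max_increment,
                        "before_origin": fit.inflection.before_origin,
                        "message": fit.message,
                    }
                )
            out["series"].append(entry)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisReport":
        outcomes = []
        for entry in data["series"]:
            series = TraitSeries(
                breed=entry["breed"],
                trait=entry["trait"],
                unit=entry["unit"],
                weeks=np.asarray(entry["weeks"], dtype=float),
                values=np.asarray(entry["values"], dtype=float),
            )
            fits = [
                FitResult(
                    model=f["model"],
                    params=ModelParams(A=f["A"], B=f["B"], k=f["k"]),
                    r_squared=f["r_squared"],
                    sse=f["sse"],
                    n_iter=f["n_iter"],
                    converged=f["converged"],
                    inflection=InflectionSummary(
                        age=f["inflexion_age"],
                        value=f["inflection_value"],
                        max_increment=f["max_increment"],
                        before_origin=f["before_origin"],
                    ),
                    message=f["message"],
                    series=series,
                )
                for f in entry["fits"]
            ]
            best = next((f for f in fits if f.model == entry["best_model"]), None)
            oc = SeriesOutcome(series=series, fits=fits, best=best, error=entry["error"])
            if oc.ok and len(series) >= 2:
                oc.rates = rate_table(series)
            outcomes.append(oc)
        return cls(outcomes=outcomes, metadata=data["metadata"])


def run_pipeline(input_csv, models=MODEL_NAMES, **fit_settings) -> AnalysisReport:
    """Fit, select and tabulate every series in a trait CSV.

    Per-series failures (degenerate data, non-convergence of every
    model) are logged and recorded in the report without aborting the
    remaining series.
    """
    series_list = read_trait_csv(input_csv)
    outcomes = []
    for series in series_list:
        oc = SeriesOutcome(series=series)
        try:
            oc.fits = fit_all_models(series, models=models, **fit_settings)
            oc.best = select_best(oc.fits)
            oc.rates = rate_table(series)
        except Exception as exc:  # error isolation across series
            oc.error = f"{type(exc).__name__}: {exc}"
            logger.warning("series (%s, %s) failed: %s", series.breed, series.trait, oc.error)
        outcomes.append(oc)
    try:
        pkg_version = _pkg_version("goosegrowth")
    except Exception:
        pkg_version = "unknown"
    metadata = {
        "input": str(input_csv),
        "models": list(models),
        "fit_settings": dict(fit_settings),
        "package_version": pkg_version,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return AnalysisReport(outcomes=outcomes, metadata=metadata)


def write_report(report: AnalysisReport, out_dir) -> dict[str, Path]:
    """Write the fitted-parameter CSV, rates CSV and JSON report.

    Display rounding follows the conventions of published growth-curve
    tables: 3 decimals for parameters and ages, 2 for percentages.
    Data files carry no timestamps, so identical inputs give
    byte-identical CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fits": out_dir / "growth_fits.csv",
        "rates": out_dir / "weekly_rates.csv",
        "report": out_dir / "report.json",
    }
    fits = report.fit_frame()
    if not fits.empty:
        for col in ("A", "B", "k", "inflexion_age", "inflection_value", "max_increment"):
            fits[col] = fits[col].round(3)
        fits["r_squared"] = fits["r_squared"].round(3)
    fits.to_csv(paths["fits"], index=False)
    rates = report.rates_frame()
    if not rates.empty:
        rates["gain"] = rates["gain"].round(2)
        rates["relative_rate_pct"] = rates["relative_rate_pct"].round(2)
    rates.to_csv(paths["rates"], index=False)
    with open(paths["report"], "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return paths
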