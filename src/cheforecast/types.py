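"""Domain containers: country panels, covariate forecasts, GDP projections.

Tabular data is held in pandas DataFrames with a fixed schema, wrapped in
light dataclasses that validate invariants on construction.  World Bank
income groups are a closed four-class enum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)


class IncomeGroup(str, Enum):
    """World Bank income classification."""

    LIC = "LIC"  # low income
    LMIC = "LMIC"  # lower middle income
    UMIC = "UMIC"  # upper middle income
    HIC = "HIC"  # high income

    @classmethod
    def coerce(cls, value) -> "IncomeGroup":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            raise ValidationError(
                f"unknown income group {value!r}; expected one of "
                f"{[g.value for g in cls]}"
            ) from None


#: Column order of the long-format country-year panel.
PANEL_COLUMNS = ["country_id", "income_group", "year", "che", "oop_exp", "hex_gdp", "gdp_c"]

#: Column order of the per-country 2040 forecast table.
FORECAST_COLUMNS = [
    "country_id",
    "income_group",
    "oop_exp_mean",
    "oop_exp_lo",
    "oop_exp_hi",
    "hex_gdp_mean",
    "hex_gdp_lo",
    "hex_gdp_hi",
    "gdp_c_base",
    "base_year",
    "horizon_year",
]

_PROPORTION_PANEL_COLS = ["che", "oop_exp", "hex_gdp"]


def clip_proportions(
    frame: pd.DataFrame,
    columns: Sequence[str],
    clip_epsilon: float,
    *,
    context: str = "",
) -> pd.DataFrame:
    """Clip boundary proportions into (clip_epsilon, 1 - clip_epsilon).

    Values already strictly inside the clipped interval are left untouched;
    each clipped cell is logged.  Values outside [0, 1] raise.
    """
    frame = frame.copy()
    for col in columns:
        vals = frame[col].to_numpy(dtype=float)
        finite = ~np.isnan(vals)
        if np.any((vals[finite] < 0.0) | (vals[finite] > 1.0)):
            raise ValidationError(f"{context}{col} has values outside [0, 1]")
        mask = finite & ((vals <= clip_epsilon) | (vals >= 1.0 - clip_epsilon))
        if mask.any():
            logger.warning(
                "%s%s: clipped %d boundary value(s) into (%g, %g)",
                context, col, int(mask.sum()), clip_epsilon, 1.0 - clip_epsilon,
            )
            frame[col] = np.clip(vals, clip_epsilon, 1.0 - clip_epsilon)
    return frame


@dataclass
class CountryPanel:
    """Long-format country-year observations used for model fitting.

    ``data`` columns: country_id, income_group, year, che, oop_exp, hex_gdp,
    gdp_c.  CHE may be missing (NaN) — covariates are still used for
    projection; rows with missing CHE are excluded from fitting.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"panel is missing columns: {missing}")
        df = self.data[PANEL_COLUMNS].copy()
        df["income_group"] = df["income_group"].map(IncomeGroup.coerce)
        df["year"] = df["year"].astype(int)
        for col in ["che", "oop_exp", "hex_gdp", "gdp_c"]:
            df[col] = df[col].astype(float)
        dup = df.duplicated(subset=["country_id", "year"], keep=False)
        if dup.any():
            offenders = (
                df.loc[dup, ["country_id", "year"]]
                .drop_duplicates()
                .apply(lambda r: f"{r.country_id}, {r.year}", axis=1)
                .tolist()
            )
            raise ValidationError(f"duplicate (country, year) pairs: {offenders}")
        if (df["gdp_c"] <= 0).any():
            bad = df.loc[df["gdp_c"] <= 0, "country_id"].unique().tolist()
            raise ValidationError(f"non-positive gdp_c for countries: {bad}")
        for col in ["oop_exp", "hex_gdp"]:
            if df[col].isna().any():
                raise ValidationError(f"panel column {col} must not be missing")
        self.data = df.reset_index(drop=True)

    @property
    def n_countries(self) -> int:
        return int(self.data["country_id"].nunique())

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["country_id"].unique().tolist())

    def observed(self) -> pd.DataFrame:
        """Rows with non-missing CHE (the fitting subset)."""
        return self.data[self.data["che"].notna()].reset_index(drop=True)

    def last_observations(self) -> pd.DataFrame:
        """Latest row per country, indexed by country_id (baseline covariates)."""
        idx = self.data.groupby("country_id")["year"].idxmax()
        return self.data.loc[idx].set_index("country_id").sort_index()

    def group_of(self) -> dict[str, IncomeGroup]:
        return {
            r.country_id: r.income_group
            for r in self.data.drop_duplicates("country_id").itertuples()
        }


@dataclass
class ForecastSet:
    """Per-country horizon-year covariate forecasts: mean plus 95 % UI bounds.

    ``data`` columns follow :data:`FORECAST_COLUMNS`; each covariate's
    (lo, mean, hi) triple must be ordered and strictly inside (0, 1).
    A zero-width interval is accepted and treated as a point forecast.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FORECAST_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"forecast table is missing columns: {missing}")
        df = self.data[FORECAST_COLUMNS].copy()
        df["income_group"] = df["income_group"].map(IncomeGroup.coerce)
        for col in FORECAST_COLUMNS[2:9]:
            df[col] = df[col].astype(float)
        df["base_year"] = df["base_year"].astype(int)
        df["horizon_year"] = df["horizon_year"].astype(int)
        for prefix in ("oop_exp", "hex_gdp"):
            lo, mean, hi = (df[f"{prefix}_{s}"] for s in ("lo", "mean", "hi"))
            bad = ~((lo <= mean) & (mean <= hi))
            if bad.any():
                offenders = df.loc[bad, "country_id"].tolist()
                raise ValidationError(
                    f"{prefix} triplets violate lo <= mean <= hi for {offenders}"
                )
            for s in ("lo", "mean", "hi"):
                col = df[f"{prefix}_{s}"]
                if ((col <= 0) | (col >= 1)).any():
                    raise ValidationError(f"{prefix}_{s} must lie strictly in (0, 1)")
        if (df["gdp_c_base"] <= 0).any():
            raise ValidationError("gdp_c_base must be positive")
        if (df["horizon_year"] <= df["base_year"]).any():
            raise ValidationError("horizon_year must exceed base_year")
        dup = df.duplicated("country_id", keep=False)
        if dup.any():
            raise ValidationError(
                f"duplicate forecast countries: {df.loc[dup, 'country_id'].unique().tolist()}"
            )
        self.data = df.reset_index(drop=True)

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["country_id"].tolist())

    def point_mass_countries(self) -> list[str]:
        """Countries whose forecast UI is degenerate (lo == hi) for a covariate."""
        df = self.data
        flagged = (df["oop_exp_lo"] == df["oop_exp_hi"]) | (
            df["hex_gdp_lo"] == df["hex_gdp_hi"]
        )
        return df.loc[flagged, "country_id"].tolist()


@dataclass
class GdpProjection:
    """A run of GDP-per-capita values for one country over consecutive years."""

    country_id: str
    income_group: IncomeGroup
    years: list[int]
    gdp_c_values: list[float]

    def __post_init__(self) -> None:
        self.income_group = IncomeGroup.coerce(self.income_group)
        self.years = [int(y) for y in self.years]
        self.gdp_c_values = [float(v) for v in self.gdp_c_values]
        if len(self.years) != len(self.gdp_c_values):
            raise ValidationError("years and gdp_c_values must have equal length")
        if len(self.years) < 2:
            raise ValidationError("a GDP projection needs at least 2 years")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValidationError("years must be strictly increasing")
        if any(v <= 0 for v in self.gdp_c_values):
            raise ValidationError("gdp_c values must be positive")


@dataclass
class TargetReport:
    """Attainment probabilities and uncertainty summaries per income group.

    ``probabilities``    maps (group, threshold) -> P(group CHE < threshold);
    ``group_point``      maps group -> point (mean-of-draws) 2040 CHE;
    ``group_ui``         maps group -> (2.5th, 97.5th percentile);
    ``gap_probabilities`` maps group -> P(decline rate > reference group's),
    paired within Monte Carlo trial.
    """

    thresholds: list[float]
    probabilities: dict[tuple[IncomeGroup, float], float]
    group_point: dict[IncomeGroup, float] = field(default_factory=dict)
    group_ui: dict[IncomeGroup, tuple[float, float]] = field(default_factory=dict)
    gap_probabilities: dict[IncomeGroup, float] = field(default_factory=dict)

    @property
    def groups(self) -> list[IncomeGroup]:
        present = {g for g, _ in self.probabilities}
        return [g for g in IncomeGroup if g in present]
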