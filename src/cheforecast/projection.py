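"""Deterministic point projection of CHE incidence to the horizon year.

Sequence: annualize each country's GDP-per-capita run, summarize growth per
income group (mean and sample SD across countries), compound each country's
base GDP at its group's mean rate to the horizon, predict horizon CHE from
the fitted model at the forecast covariate means, and aggregate per income
group by the unweighted arithmetic average of country predictions.  The
stage contains no randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ValidationError
from .model import CheMixedModel, predict_che
from .transforms import (
    annualized_decline,
    annualized_rate,
    annualized_rate_ols,
    compound,
)
from .types import ForecastSet, GdpProjection, IncomeGroup

logger = logging.getLogger(__name__)


@dataclass
class GroupGrowthSummary:
    """Mean and sample SD of annualised GDP growth across a group's countries."""

    income_group: IncomeGroup
    mean_rate: float
    sd_rate: float
    n_countries: int

    def __post_init__(self) -> None:
        if self.sd_rate < 0:
            raise ValidationError("sd_rate must be non-negative")


@dataclass
class GroupProjection:
    """Horizon-year point projection for one income group."""

    income_group: IncomeGroup
    che_point: float
    country_points: dict[str, float]
    decline_rate_point: float | None = None


def summarize_growth(
    projections: list[GdpProjection], *, annualization: str = "endpoint"
) -> dict[IncomeGroup, GroupGrowthSummary]:
    """Annualise each country's GDP run, then average within income groups.

    ``annualization`` selects the endpoint geometric rate (default) or a
    log-linear regression over all years (``"ols_log"``).  The SD uses the
    n-1 denominator; a single-country group gets SD 0.  Groups absent from
    the input are absent from the output.
    """
    if annualization == "endpoint":
        rate_fn = annualized_rate
    elif annualization == "ols_log":
        rate_fn = annualized_rate_ols
    else:
        raise ValidationError(f"unknown annualization {annualization!r}")

    rates: dict[IncomeGroup, list[float]] = {}
    for p in projections:
        rates.setdefault(p.income_group, []).append(rate_fn(p.gdp_c_values, p.years))

    out: dict[IncomeGroup, GroupGrowthSummary] = {}
    for g in IncomeGroup:
        if g not in rates:
            logger.warning("no GDP projections for group %s; omitted", g.value)
            continue
        r = rates[g]
        n = len(r)
        mean = sum(r) / n
        sd = (sum((x - mean) ** 2 for x in r) / (n - 1)) ** 0.5 if n > 1 else 0.0
        out[g] = GroupGrowthSummary(income_group=g, mean_rate=mean, sd_rate=sd,
                                    n_countries=n)
    return out


def project_gdp_2040(forecast_row, growth: GroupGrowthSummary) -> float:
    """Compound a country's base GDP per capita at its group's mean rate.

    ``forecast_row`` is one row of a :class:`ForecastSet` (attribute access:
    gdp_c_base, base_year, horizon_year).  The rate is the group's, not the
    country's: two same-group countries with equal base GDP get identical
    horizon GDP.
    """
    n_years = int(forecast_row.horizon_year) - int(forecast_row.base_year)
    return compound(float(forecast_row.gdp_c_base), growth.mean_rate, n_years)


def project_group_che(
    model: CheMixedModel,
    forecasts: ForecastSet,
    growth: dict[IncomeGroup, GroupGrowthSummary],
    *,
    use_blup: bool = False,
) -> dict[IncomeGroup, GroupProjection]:
    """Predict horizon CHE per country and average within income groups.

    Each country is evaluated at its forecast covariate means and its
    group-growth-projected GDP.  ``use_blup`` carries the fitted country
    intercept (BLUP) into the prediction; the default predicts at the
    population level (random effect 0).  Countries whose group lacks a
    growth summary are excluded with a warning.  The group value is the
    exact unweighted arithmetic mean of its countries' predictions.
    """
    points: dict[IncomeGroup, dict[str, float]] = {}
    for row in forecasts.data.itertuples():
        g = row.income_group
        if g not in growth:
            logger.warning("country %s: no growth summary for group %s; excluded",
                           row.country_id, g.value)
            continue
        gdp_2040 = project_gdp_2040(row, growth[g])
        effect = model.country_effects_.get(row.country_id, 0.0) if use_blup else 0.0
        che = predict_che(model, row.oop_exp_mean, row.hex_gdp_mean, gdp_2040,
                          country_effect=effect)
        points.setdefault(g, {})[row.country_id] = che

    out = {}
    for g, cps in points.items():
        ordered = [cps[c] for c in sorted(cps)]
        out[g] = GroupProjection(
            income_group=g,
            che_point=sum(ordered) / len(ordered),
            country_points={c: cps[c] for c in sorted(cps)},
        )
    return out


def compute_decline(group_2013: float, group_2040: float, n_years: int = 27) -> float:
    """Annualised rate of decline between the base and horizon group CHE."""
    return annualized_decline(group_2013, group_2040, n_years)


def baseline_group_che(
    model: CheMixedModel, panel, *, use_blup: bool = False, fitted: bool = True
) -> dict[IncomeGroup, float]:
    """Base-year group CHE from a panel's latest observations per country.

    ``fitted=True`` evaluates the model at each country's last observed
    covariates (optionally with its BLUP); ``fitted=False`` averages the
    observed CHE values themselves (countries with missing CHE excluded).
    Both are plain arithmetic means across countries.
    """
    last = panel.last_observations()
    sums: dict[IncomeGroup, list[float]] = {}
    for cid, row in last.iterrows():
        g = row["income_group"]
        if fitted:
            effect = model.country_effects_.get(cid, 0.0) if use_blup else 0.0
            val = predict_che(model, row["oop_exp"], row["hex_gdp"], row["gdp_c"],
                              country_effect=effect)
        else:
            if row.isna()["che"]:
                continue
            val = float(row["che"])
        sums.setdefault(g, []).append(val)
    return {g: sum(v) / len(v) for g, v in sums.items() if v}
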