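"""CSV readers and writers for panels, forecasts, GDP runs, and reports.

All tables are plain RFC-4180 CSV (UTF-8, "." decimal separator).  Floats are
written with ``repr`` precision so read–write round trips preserve at least
12 significant digits.  Proportions may arrive on the percent scale; that is
declared explicitly via ``percent_input`` — never guessed from magnitudes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError
from .types import (
    FORECAST_COLUMNS,
    PANEL_COLUMNS,
    CountryPanel,
    ForecastSet,
    GdpProjection,
    IncomeGroup,
    TargetReport,
    clip_proportions,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _read_csv(path, required: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file {path} is missing columns: {missing}")
    return df


def read_country_panel(
    path,
    clip_epsilon: float = 1e-6,
    *,
    percent_input: bool = False,
    provenance: str = "",
) -> CountryPanel:
    """Read a country-year panel CSV and validate it.

    Parameters
    ----------
    path
        CSV with header country_id, income_group, year, che, oop_exp,
        hex_gdp, gdp_c.  ``che`` may be empty (missing).
    clip_epsilon
        Boundary proportions (0 or 1, where the logit is undefined) are
        clipped into ``(clip_epsilon, 1 - clip_epsilon)`` with a logged
        warning; interior values are untouched.
    percent_input
        If True, che/oop_exp/hex_gdp are given in percent and divided by 100
        at this boundary.  This is a declared flag, never inferred.
    """
    df = _read_csv(path, PANEL_COLUMNS, "panel")
    if percent_input:
        df[["che", "oop_exp", "hex_gdp"]] = df[["che", "oop_exp", "hex_gdp"]] / 100.0
    df = clip_proportions(
        df, ["che", "oop_exp", "hex_gdp"], clip_epsilon, context=f"{path}: "
    )
    return CountryPanel(df, provenance=provenance or str(path))


def write_country_panel(panel: CountryPanel, path) -> None:
    panel.data.assign(income_group=panel.data["income_group"].map(lambda g: g.value)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_forecasts(path, *, percent_input: bool = False) -> ForecastSet:
    """Read per-country horizon forecasts (mean/lo/hi per covariate).

    Ordering lo <= mean <= hi is enforced; countries not present in a fitted
    panel are the caller's concern (a warning is emitted when projecting).
    Zero-width intervals are accepted as point forecasts and logged.
    """
    df = _read_csv(path, FORECAST_COLUMNS, "forecast")
    if percent_input:
        cols = [f"{p}_{s}" for p in ("oop_exp", "hex_gdp") for s in ("mean", "lo", "hi")]
        df[cols] = df[cols] / 100.0
    fs = ForecastSet(df)
    degenerate = fs.point_mass_countries()
    if degenerate:
        logger.info("point-mass (zero-width) forecast UIs for: %s", degenerate)
    return fs


def write_forecasts(forecasts: ForecastSet, path) -> None:
    forecasts.data.assign(
        income_group=forecasts.data["income_group"].map(lambda g: g.value)
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_gdp_projections(path) -> list[GdpProjection]:
    """Read long-format GDP runs (country_id, income_group, year, gdp_c)."""
    df = _read_csv(path, ["country_id", "income_group", "year", "gdp_c"], "GDP projection")
    out = []
    for cid, sub in df.groupby("country_id", sort=True):
        sub = sub.sort_values("year")
        groups = sub["income_group"].unique()
        if len(groups) != 1:
            raise ValidationError(f"country {cid} has inconsistent income groups: {groups}")
        out.append(
            GdpProjection(
                country_id=str(cid),
                income_group=IncomeGroup.coerce(groups[0]),
                years=sub["year"].tolist(),
                gdp_c_values=sub["gdp_c"].tolist(),
            )
        )
    return out


def write_gdp_projections(projections: list[GdpProjection], path) -> None:
    rows = [
        {"country_id": p.country_id, "income_group": p.income_group.value, "year": y, "gdp_c": v}
        for p in projections
        for y, v in zip(p.years, p.gdp_c_values)
    ]
    pd.DataFrame(rows, columns=["country_id", "income_group", "year", "gdp_c"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_target_report(report: TargetReport, path) -> None:
    """Write attainment probabilities, with a companion point/UI table.

    The main CSV has one row per (income_group, threshold).  A companion file
    ``<stem>_groups.csv`` holds each group's point estimate and 95 % UI.
    """
    path = Path(path)
    rows = [
        {
            "income_group": g.value,
            "threshold": thr,
            "probability": report.probabilities[(g, thr)],
        }
        for g in report.groups
        for thr in report.thresholds
        if (g, thr) in report.probabilities
    ]
    pd.DataFrame(rows, columns=["income_group", "threshold", "probability"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )

    grows = []
    for g, point in report.group_point.items():
        lo, hi = report.group_ui.get(g, (float("nan"), float("nan")))
        grows.append(
            {
                "income_group": g.value,
                "che_point": point,
                "che_lo": lo,
                "che_hi": hi,
                "gap_probability": report.gap_probabilities.get(g, float("nan")),
            }
        )
    companion = path.with_name(path.stem + "_groups.csv")
    pd.DataFrame(
        grows,
        columns=["income_group", "che_point", "che_lo", "che_hi", "gap_probability"],
    ).to_csv(companion, index=False, float_format=_FLOAT_FMT)


def read_target_report(path) -> TargetReport:
    """Read back a report written by :func:`write_target_report`."""
    path = Path(path)
    df = _read_csv(path, ["income_group", "threshold", "probability"], "target report")
    probabilities = {
        (IncomeGroup.coerce(r.income_group), float(r.threshold)): float(r.probability)
        for r in df.itertuples()
    }
    thresholds = sorted(df["threshold"].unique().tolist())
    report = TargetReport(thresholds=thresholds, probabilities=probabilities)
    companion = path.with_name(path.stem + "_groups.csv")
    if companion.exists():
        gdf = pd.read_csv(companion)
        for r in gdf.itertuples():
            g = IncomeGroup.coerce(r.income_group)
            report.group_point[g] = float(r.che_point)
            report.group_ui[g] = (float(r.che_lo), float(r.che_hi))
            if not pd.isna(r.gap_probability):
                report.gap_probabilities[g] = float(r.gap_probability)
    return report
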