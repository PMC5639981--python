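"""End-to-end pipeline: data -> fit -> project -> Monte Carlo -> reports.

Three steps mirror the analysis design: (1) fit the mixed model on the
panel; (2) project each country's horizon CHE from forecast covariates and
group-level GDP growth and average within income groups; (3) propagate
input and estimation uncertainty by Monte Carlo and evaluate the
financial-risk-protection targets.  Scenario runs repeat (2)-(3) on
cap-modified forecasts.

All artifacts are plain CSV/JSON under the configured output directory; the
run log records seeds, library versions and row counts so a run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as che_io
from .config import RunConfig
from .model import CheMixedModel, fit_che_model
from .projection import (
    baseline_group_che,
    compute_decline,
    project_group_che,
    summarize_growth,
)
from .scenarios import apply_oop_cap, compare_scenarios
from .types import CountryPanel, ForecastSet, IncomeGroup
from .synthetic import generate_forecasts, generate_gdp_projections, generate_panel
from .uncertainty import percentile_ui, run_monte_carlo, target_probabilities

logger = logging.getLogger(__name__)


def load_inputs(config: RunConfig):
    """Load (or generate) the panel, forecasts and GDP projections."""
    if config.synthetic is not None:
        panel, truth = generate_panel(config.synthetic)
        forecasts = generate_forecasts(
            truth, base_year=config.base_year, horizon_year=config.horizon_year
        )
        gdp = generate_gdp_projections(truth)
        return panel, forecasts, gdp, truth
    panel = che_io.read_country_panel(
        config.panel_path, config.clip_epsilon, percent_input=config.percent_input
    )
    forecasts = che_io.read_forecasts(
        config.forecasts_path, percent_input=config.percent_input
    )
    unknown = set(forecasts.countries) - set(panel.countries)
    if unknown:
        logger.warning("forecast countries absent from panel (retained): %s",
                       sorted(unknown))
    gdp = che_io.read_gdp_projections(config.gdp_path)
    return panel, forecasts, gdp, None


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the artifact set; returns result objects."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_run_log(out)
    logger.info("run seed=%d  numpy=%s pandas=%s", config.seed,
                np.__version__, pd.__version__)

    panel, forecasts, gdp, truth = load_inputs(config)
    logger.info("panel: %d rows, %d countries (%d with observed CHE)",
                len(panel.data), panel.n_countries,
                panel.observed()["country_id"].nunique())
    if config.synthetic is not None:
        che_io.write_country_panel(panel, out / "panel.csv")
        che_io.write_forecasts(forecasts, out / "forecasts.csv")
        che_io.write_gdp_projections(gdp, out / "gdp_projections.csv")

    # stage 1: fit
    model = fit_che_model(panel, method=config.method)
    model.to_json(out / "model.json")

    # stage 2: deterministic projection
    growth = summarize_growth(gdp, annualization=config.annualization)
    pd.DataFrame(
        [
            {"income_group": g.value, "mean_rate": s.mean_rate,
             "sd_rate": s.sd_rate, "n_countries": s.n_countries}
            for g, s in growth.items()
        ]
    ).to_csv(out / "growth_summary.csv", index=False)

    projections = project_group_che(model, forecasts, growth,
                                    use_blup=config.use_blup)
    baseline = baseline_group_che(model, panel, use_blup=config.use_blup)
    n_years = config.horizon_year - config.base_year
    country_rows, group_rows = [], []
    for g, proj in projections.items():
        decline = (compute_decline(baseline[g], proj.che_point, n_years)
                   if g in baseline else float("nan"))
        proj.decline_rate_point = decline
        group_rows.append({"income_group": g.value, "che_2013_fitted": baseline.get(g),
                           "che_2040": proj.che_point, "decline_rate": decline})
        for cid, che in proj.country_points.items():
            country_rows.append({"country_id": cid, "income_group": g.value,
                                 "che_2040": che})
    pd.DataFrame(country_rows).to_csv(out / "projection_countries.csv", index=False)
    pd.DataFrame(group_rows).to_csv(out / "projection_groups.csv", index=False)

    # stage 3: Monte Carlo + targets
    base_cov = panel.last_observations()
    samples = run_monte_carlo(
        model, forecasts, growth, n=config.mc_n, seed=config.seed,
        baseline_covariates=base_cov, use_blup=config.use_blup,
        include_residual=config.include_residual,
        decline_baseline=config.decline_baseline,
    )
    include = (list(samples.per_group) if config.include_hic_in_targets
               else [g for g in samples.per_group if g is not IncomeGroup.HIC])
    report = target_probabilities(samples, config.mc_thresholds,
                                  include_groups=include)
    che_io.write_target_report(report, out / "target_report.csv")
    _report_json(report, out / "target_report.json")
    _decline_histograms(samples, out / "decline_hist.csv")
    _gap_scatter(samples, out / "gap_scatter.csv")

    results = {"model": model, "growth": growth, "projections": projections,
               "baseline": baseline, "samples": samples, "report": report,
               "panel": panel, "forecasts": forecasts, "truth": truth}

    # scenarios: re-run projection + MC on capped forecasts
    for scenario in config.scenarios:
        capped = apply_oop_cap(forecasts, scenario)
        s_samples = run_monte_carlo(
            model, capped, growth, n=config.mc_n, seed=config.seed,
            baseline_covariates=base_cov, use_blup=config.use_blup,
            include_residual=config.include_residual,
            decline_baseline=config.decline_baseline,
        )
        s_report = target_probabilities(s_samples, config.mc_thresholds,
                                        include_groups=include)
        che_io.write_target_report(s_report, out / f"target_report_{scenario.name}.csv")
        compare_scenarios(report, s_report).to_csv(
            out / f"scenario_{scenario.name}_vs_base.csv", index=False
        )
        results[f"scenario:{scenario.name}"] = s_report
    return results


def _setup_run_log(out: Path) -> None:
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("cheforecast")
    root.addHandler(handler)
    root.setLevel(logging.INFO)


def _report_json(report, path) -> None:
    payload = {
        "thresholds": report.thresholds,
        "probabilities": {
            f"{g.value}:{t}": p for (g, t), p in report.probabilities.items()
        },
        "group_point": {g.value: v for g, v in report.group_point.items()},
        "group_ui": {g.value: list(v) for g, v in report.group_ui.items()},
        "gap_probabilities": {g.value: v for g, v in report.gap_probabilities.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def _decline_histograms(samples, path, bins: int = 60) -> None:
    """Histogram data for the per-group decline-rate distributions."""
    rows = []
    for g, arr in samples.decline_per_group.items():
        counts, edges = np.histogram(arr, bins=bins)
        for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
            rows.append({"income_group": g.value, "bin_lo": lo, "bin_hi": hi,
                         "count": int(c)})
    pd.DataFrame(rows, columns=["income_group", "bin_lo", "bin_hi", "count"]).to_csv(
        path, index=False
    )


def _gap_scatter(samples, path, n_points: int = 1000) -> None:
    """Thinned paired decline draws of LIC/LMIC against the UMIC reference."""
    ref = samples.decline_per_group.get(IncomeGroup.UMIC)
    rows = []
    if ref is not None:
        step = max(1, len(ref) // n_points)
        for g in (IncomeGroup.LIC, IncomeGroup.LMIC):
            arr = samples.decline_per_group.get(g)
            if arr is None:
                continue
            for k in range(0, len(ref), step):
                rows.append({"income_group": g.value, "trial": k,
                             "decline": arr[k], "decline_ref": ref[k]})
    pd.DataFrame(rows, columns=["income_group", "trial", "decline", "decline_ref"]).to_csv(
        path, index=False
    )


def make_report_tables(outputs_dir) -> str:
    """Render the target-probability and point/UI tables from artifacts.

    Returns a human-readable text block; raises if an artifact is missing,
    naming the file.
    """
    out = Path(outputs_dir)
    report_path = out / "target_report.csv"
    groups_path = out / "target_report_groups.csv"
    for p in (report_path, groups_path):
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline artifact: {p}")
    probs = pd.read_csv(report_path)
    table = probs.pivot(index="income_group", columns="threshold",
                        values="probability")
    table.columns = [f"CHE < {100 * t:g}%" for t in table.columns]
    groups = pd.read_csv(groups_path)
    lines = ["Probability of attaining financial-risk-protection targets by 2040",
             table.to_string(float_format=lambda v: f"{v:.2f}"), "",
             "Projected 2040 CHE incidence (point and 95% UI)"]
    for r in groups.itertuples():
        lines.append(
            f"  {r.income_group}: {100 * r.che_point:.2f}% "
            f"({100 * r.che_lo:.2f}-{100 * r.che_hi:.2f})"
        )
    return "\n".join(lines)
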