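"""Counterfactual financing-policy scenarios.

The policy lever studied here is the out-of-pocket share of total health
expenditure (OOP_EXP): capping it at, say, 20 % or 15 % by the horizon year
emulates a shift from direct payments to prepayment mechanisms.  A scenario
rewrites the forecast inputs (mean and both UI bounds clipped at the cap, so
the capped covariate can never be sampled above the cap) and the projection
and Monte Carlo stages are simply re-run on the modified forecasts.
Scenario application is pure: the input ForecastSet is never mutated, and
applying the same cap twice equals applying it once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError, ValidationError
from .types import ForecastSet, IncomeGroup, TargetReport


@dataclass
class Scenario:
    """A named counterfactual: cap OOP_EXP for selected income groups."""

    name: str
    oop_cap: float | None = None
    applies_to: frozenset = field(
        default_factory=lambda: frozenset(IncomeGroup)
    )

    def __post_init__(self) -> None:
        if self.oop_cap is not None and not (0.0 < self.oop_cap < 1.0):
            raise DomainError(f"oop_cap must lie in (0, 1); got {self.oop_cap}")
        self.applies_to = frozenset(IncomeGroup.coerce(g) for g in self.applies_to)


def apply_oop_cap(forecasts: ForecastSet, scenario: Scenario) -> ForecastSet:
    """Return a new ForecastSet with OOP_EXP clipped at the scenario cap.

    For each targeted country, mean, lo and hi are each replaced by
    ``min(value, cap)``; the lo <= mean <= hi ordering is preserved because
    min(., cap) is monotone.  Countries outside ``applies_to`` (or all of
    them, when the scenario has no cap) pass through unchanged.
    """
    df = forecasts.data.copy(deep=True)
    if scenario.oop_cap is None:
        return ForecastSet(df)
    cap = scenario.oop_cap
    mask = df["income_group"].isin(scenario.applies_to)
    for col in ("oop_exp_mean", "oop_exp_lo", "oop_exp_hi"):
        df.loc[mask, col] = df.loc[mask, col].clip(upper=cap)
    return ForecastSet(df)


def compare_scenarios(base: TargetReport, alt: TargetReport) -> pd.DataFrame:
    """Tabulate alt - base differences per (group, threshold) and per group.

    Returns a DataFrame with one row per (income_group, threshold) holding
    both attainment probabilities and their difference, plus the group
    point-estimate difference repeated per row for convenience.
    """
    if set(base.probabilities) != set(alt.probabilities):
        raise ValidationError("reports have mismatched (group, threshold) structure")
    rows = []
    for g in base.groups:
        for t in base.thresholds:
            key = (g, t)
            rows.append(
                {
                    "income_group": g.value,
                    "threshold": t,
                    "probability_base": base.probabilities[key],
                    "probability_alt": alt.probabilities[key],
                    "probability_diff": alt.probabilities[key] - base.probabilities[key],
                    "che_point_diff": (
                        alt.group_point.get(g, float("nan"))
                        - base.group_point.get(g, float("nan"))
                    ),
                }
            )
    return pd.DataFrame(rows)
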