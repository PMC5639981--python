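"""YAML run configuration for the end-to-end pipeline.

A run either points at three CSV files (panel, forecasts, GDP projections)
or carries a ``synthetic`` block with generator parameters — exactly one of
the two.  All randomness is controlled by integer seeds in the config.

Example
-------
.. code-block:: yaml

    seed: 42
    percent_input: false
    synthetic:
      n_countries_per_group: {LIC: 8, LMIC: 10, UMIC: 12, HIC: 12}
      years: [2000, 2013]
      che_missingness: 0.1
    model:
      method: reml
      use_blup: false
    projection:
      base_year: 2013
      horizon_year: 2040
      annualization: endpoint
    mc:
      n: 100000
      thresholds: [0.005, 0.01, 0.015, 0.02]
      include_residual: false
      decline_baseline: per_trial
    scenarios:
      - {name: cap20, oop_cap: 0.20}
    output_dir: out
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .scenarios import Scenario
from .synthetic import GeneratorConfig
from .types import IncomeGroup


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    percent_input: bool = False
    panel_path: str | None = None
    forecasts_path: str | None = None
    gdp_path: str | None = None
    synthetic: GeneratorConfig | None = None
    method: str = "reml"
    use_blup: bool = False
    r2_definition: str = "marginal"
    base_year: int = 2013
    horizon_year: int = 2040
    annualization: str = "endpoint"
    clip_epsilon: float = 1e-6
    mc_n: int = 100_000
    mc_thresholds: tuple = (0.005, 0.010, 0.015, 0.020)
    include_residual: bool = False
    decline_baseline: str = "per_trial"
    include_hic_in_targets: bool = False
    scenarios: list[Scenario] = field(default_factory=list)
    output_dir: str = "out"

    def __post_init__(self) -> None:
        has_paths = all(p is not None for p in
                        (self.panel_path, self.forecasts_path, self.gdp_path))
        if not has_paths and self.synthetic is None:
            raise ConfigError(
                "config needs either panel/forecasts/gdp paths or a synthetic block"
            )
        if self.horizon_year <= self.base_year:
            raise ConfigError("horizon_year must exceed base_year")


def load_config(path) -> RunConfig:
    """Parse a YAML file into a :class:`RunConfig`."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    paths = raw.get("paths", {}) or {}
    synth = None
    if "synthetic" in raw and raw["synthetic"] is not None:
        sblock = dict(raw["synthetic"])
        if "years" in sblock:
            sblock["years"] = tuple(sblock["years"])
        if "seed" not in sblock:
            sblock["seed"] = int(raw.get("seed", 0))
        try:
            synth = GeneratorConfig(**sblock)
        except TypeError as exc:
            raise ConfigError(f"bad synthetic block: {exc}") from None
    model = raw.get("model", {}) or {}
    proj = raw.get("projection", {}) or {}
    mc = raw.get("mc", {}) or {}
    scenarios = [
        Scenario(name=s["name"], oop_cap=s.get("oop_cap"),
                 applies_to=frozenset(s.get("applies_to", list(IncomeGroup))))
        for s in raw.get("scenarios", []) or []
    ]
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        percent_input=bool(raw.get("percent_input", False)),
        panel_path=paths.get("panel"),
        forecasts_path=paths.get("forecasts"),
        gdp_path=paths.get("gdp"),
        synthetic=synth,
        method=model.get("method", "reml"),
        use_blup=bool(model.get("use_blup", False)),
        r2_definition=model.get("r2_definition", "marginal"),
        base_year=int(proj.get("base_year", 2013)),
        horizon_year=int(proj.get("horizon_year", 2040)),
        annualization=proj.get("annualization", "endpoint"),
        clip_epsilon=float(raw.get("clip_epsilon", 1e-6)),
        mc_n=int(mc.get("n", 100_000)),
        mc_thresholds=tuple(mc.get("thresholds", (0.005, 0.010, 0.015, 0.020))),
        include_residual=bool(mc.get("include_residual", False)),
        decline_baseline=mc.get("decline_baseline", "per_trial"),
        include_hic_in_targets=bool(raw.get("include_hic_in_targets", False)),
        scenarios=scenarios,
        output_dir=str(raw.get("output_dir", "out")),
    )
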