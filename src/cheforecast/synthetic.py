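"""Synthetic country-panel generator with known ground truth.

The generator is the exact forward model of the regression stage: for each
country it draws a random intercept once, then for every retained
country-year draws covariates from per-income-group distributions and
computes

    logit(CHE) = b0 + b1*logit(OOP_EXP) + b2*logit(HEX_GDP) + b3*ln(GDP_C)
                 + u_country + e,

inverting the logit to obtain the incidence.  Because the data-generating
process matches the fitted model exactly, parameter-recovery and coverage
tests have an unambiguous truth to compare against.

Default parameter choices (documented constants, not claims about real data):

* Country counts per income group default to 32/45/51/51 (LIC/LMIC/UMIC/HIC),
  the World Bank class sizes of the 179-country study population this
  generator emulates; years default to 1995-2013.
* Slopes default to 0.67 (logit OOP_EXP), 0.67 (logit HEX_GDP), -0.38
  (ln GDP_C) and the random-intercept variance to 0.29 — the published
  coefficient set this pipeline is designed around.  The intercept (0.5) and
  residual SD (0.35) are not published anywhere; they are chosen so synthetic
  CHE incidence lands in the low single-digit percent range with a
  realistic signal-to-noise ratio.
* Covariate distributions follow the qualitative income gradient: poorer
  groups have a higher out-of-pocket share, a slightly lower health-spending
  share, and lower GDP per capita.  Annual GDP growth (mean, SD) per group
  defaults to 4.5(2.9)/4.5(2.7)/4.1(2.4)/3.4(2.0) percent.
* Covariates are drawn i.i.d. across years within a country by default
  (exogenous regressors); ``ar1_rho`` switches on an AR(1) option on the
  latent (logit / log) scale for robustness studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .transforms import inverse_logit, logit
from .types import CountryPanel, ForecastSet, GdpProjection, IncomeGroup

logger = logging.getLogger(__name__)

_GROUPS = list(IncomeGroup)

_DEFAULT_N = {IncomeGroup.LIC: 32, IncomeGroup.LMIC: 45,
              IncomeGroup.UMIC: 51, IncomeGroup.HIC: 51}

# Per-group beta shapes for OOP_EXP and HEX_GDP and log-normal (mu, sigma)
# for GDP_C.  Means: OOP 0.55/0.45/0.32/0.18; HEX 0.050/0.055/0.060/0.090;
# GDP_C ~ exp(mu) = 600/2000/7300/30000 USD per capita.
_DEFAULT_OOP_BETA = {
    IncomeGroup.LIC: (5.5, 4.5),
    IncomeGroup.LMIC: (4.5, 5.5),
    IncomeGroup.UMIC: (3.2, 6.8),
    IncomeGroup.HIC: (1.8, 8.2),
}
_DEFAULT_HEX_BETA = {
    IncomeGroup.LIC: (5.0, 95.0),
    IncomeGroup.LMIC: (5.5, 94.5),
    IncomeGroup.UMIC: (6.0, 94.0),
    IncomeGroup.HIC: (9.0, 91.0),
}
_DEFAULT_GDP_LOGNORM = {
    IncomeGroup.LIC: (6.4, 0.5),
    IncomeGroup.LMIC: (7.6, 0.5),
    IncomeGroup.UMIC: (8.9, 0.5),
    IncomeGroup.HIC: (10.3, 0.5),
}
_DEFAULT_GROWTH = {
    IncomeGroup.LIC: (0.045, 0.029),
    IncomeGroup.LMIC: (0.045, 0.027),
    IncomeGroup.UMIC: (0.041, 0.024),
    IncomeGroup.HIC: (0.034, 0.020),
}


@dataclass
class GeneratorConfig:
    """Ground-truth parameters for the synthetic panel generator."""

    n_countries_per_group: dict = field(default_factory=lambda: dict(_DEFAULT_N))
    years: tuple[int, int] = (1995, 2013)  # inclusive
    true_beta0: float = 0.5
    true_beta1: float = 0.67
    true_beta2: float = 0.67
    true_beta3: float = -0.38
    random_effect_sd: float = float(np.sqrt(0.29))
    residual_sd: float = 0.35
    oop_beta: dict = field(default_factory=lambda: dict(_DEFAULT_OOP_BETA))
    hex_beta: dict = field(default_factory=lambda: dict(_DEFAULT_HEX_BETA))
    gdp_lognorm: dict = field(default_factory=lambda: dict(_DEFAULT_GDP_LOGNORM))
    gdp_growth_mean_sd: dict = field(default_factory=lambda: dict(_DEFAULT_GROWTH))
    che_missingness: float = 0.0
    ar1_rho: float = 0.0  # 0 = i.i.d. covariates across years
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_countries_per_group = {
            IncomeGroup.coerce(k): int(v) for k, v in self.n_countries_per_group.items()
        }
        for name in ("oop_beta", "hex_beta", "gdp_lognorm", "gdp_growth_mean_sd"):
            setattr(
                self, name,
                {IncomeGroup.coerce(k): tuple(map(float, v))
                 for k, v in getattr(self, name).items()},
            )
        if self.random_effect_sd < 0 or self.residual_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        if not (0.0 <= self.che_missingness < 1.0):
            raise ConfigError("che_missingness must be in [0, 1)")
        if any(n < 0 for n in self.n_countries_per_group.values()):
            raise ConfigError("group country counts must be non-negative")
        for g, (a, b) in self.oop_beta.items():
            if a <= 0 or b <= 0:
                raise ConfigError(f"non-positive beta shape for OOP_EXP in {g}")
        for g, (a, b) in self.hex_beta.items():
            if a <= 0 or b <= 0:
                raise ConfigError(f"non-positive beta shape for HEX_GDP in {g}")
        if not (-1.0 < self.ar1_rho < 1.0):
            raise ConfigError("ar1_rho must lie in (-1, 1)")
        if self.years[1] < self.years[0]:
            raise ConfigError("years range is reversed")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.true_beta0, self.true_beta1, self.true_beta2,
                         self.true_beta3])


@dataclass
class GroundTruth:
    """What the generator actually realized, for downstream oracle checks."""

    config: GeneratorConfig
    random_effects: dict[str, float]
    group_of: dict[str, IncomeGroup]
    last_covariates: pd.DataFrame  # index country_id: oop_exp, hex_gdp, gdp_c, year
    growth_rates: dict[str, float]  # realized per-country annual GDP growth
    #: per-country true horizon-year values, filled by generate_forecasts
    true_2040: pd.DataFrame | None = None

    def true_group_che_2040(self) -> dict[IncomeGroup, float]:
        """Arithmetic group means of the noiseless true horizon CHE."""
        if self.true_2040 is None:
            raise ConfigError("call generate_forecasts first")
        df = self.true_2040
        return {
            g: float(df.loc[[c for c in df.index if self.group_of[c] == g], "che"].mean())
            for g in _GROUPS
            if any(self.group_of[c] == g for c in df.index)
        }


def _draw_latent_series(rng, n, rho, draw_iid):
    """AR(1) on a latent scale; rho=0 reduces to i.i.d. draws."""
    base = draw_iid(n)
    if rho == 0.0:
        return base
    out = np.empty(n)
    out[0] = base[0]
    for t in range(1, n):
        out[t] = rho * out[t - 1] + np.sqrt(1 - rho**2) * base[t]
    return out


def generate_panel(config: GeneratorConfig) -> tuple[CountryPanel, GroundTruth]:
    """Simulate a country-year panel from the forward model.

    Deterministic given ``config.seed``.  Returns the panel together with the
    realized ground truth (random effects, per-country growth rates, last
    observed covariates) needed by the forecast and GDP generators and by
    recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    rows = []
    random_effects: dict[str, float] = {}
    group_of: dict[str, IncomeGroup] = {}
    growth_rates: dict[str, float] = {}

    for g in _GROUPS:
        n = config.n_countries_per_group.get(g, 0)
        oa, ob = config.oop_beta[g]
        ha, hb = config.hex_beta[g]
        mu, sigma = config.gdp_lognorm[g]
        gmean, gsd = config.gdp_growth_mean_sd[g]
        for i in range(n):
            cid = f"{g.value}{i:03d}"
            group_of[cid] = g
            u = rng.normal(0.0, config.random_effect_sd)
            random_effects[cid] = float(u)
            # constant per-country growth, truncated so GDP stays positive
            growth = rng.normal(gmean, gsd)
            while growth <= -1.0:
                growth = rng.normal(gmean, gsd)
            growth_rates[cid] = float(growth)

            ny = len(years)
            if config.ar1_rho == 0.0:
                oop = rng.beta(oa, ob, ny)
                hex_ = rng.beta(ha, hb, ny)
                gdp = np.exp(rng.normal(mu, sigma, ny))
            else:
                rho = config.ar1_rho
                z_o = _draw_latent_series(rng, ny, rho, lambda k: rng.standard_normal(k))
                z_h = _draw_latent_series(rng, ny, rho, lambda k: rng.standard_normal(k))
                z_g = _draw_latent_series(rng, ny, rho, lambda k: rng.standard_normal(k))
                from scipy.stats import beta as beta_dist, norm
                oop = beta_dist.ppf(norm.cdf(z_o), oa, ob)
                hex_ = beta_dist.ppf(norm.cdf(z_h), ha, hb)
                gdp = np.exp(mu + sigma * z_g)
            oop = np.clip(oop, 1e-9, 1 - 1e-9)
            hex_ = np.clip(hex_, 1e-9, 1 - 1e-9)
            eps = (rng.normal(0.0, config.residual_sd, ny)
                   if config.residual_sd > 0 else np.zeros(ny))
            eta = (config.true_beta0
                   + config.true_beta1 * logit(oop)
                   + config.true_beta2 * logit(hex_)
                   + config.true_beta3 * np.log(gdp)
                   + u + eps)
            che = inverse_logit(eta)
            missing = (rng.random(ny) < config.che_missingness
                       if config.che_missingness > 0 else np.zeros(ny, dtype=bool))
            for t, yr in enumerate(years):
                rows.append(
                    {
                        "country_id": cid,
                        "income_group": g,
                        "year": int(yr),
                        "che": np.nan if missing[t] else float(che[t]),
                        "oop_exp": float(oop[t]),
                        "hex_gdp": float(hex_[t]),
                        "gdp_c": float(gdp[t]),
                    }
                )

    panel = CountryPanel(
        pd.DataFrame(rows), provenance=f"synthetic(seed={config.seed})"
    )
    truth = GroundTruth(
        config=config,
        random_effects=random_effects,
        group_of=group_of,
        last_covariates=panel.last_observations()[["oop_exp", "hex_gdp", "gdp_c", "year"]],
        growth_rates=growth_rates,
    )
    return panel, truth


def generate_forecasts(
    truth: GroundTruth,
    ui_width_factor: float = 0.5,
    *,
    forecast_noise_sd: float = 0.15,
    base_year: int = 2013,
    horizon_year: int = 2040,
    seed: int | None = None,
) -> ForecastSet:
    """Emulate horizon-year covariate forecasts with uncertainty intervals.

    Per country, a *true* horizon value for each covariate is drawn near the
    country's last observed value (a logit-scale Gaussian step of SD
    ``forecast_noise_sd``); the reported forecast mean is the true value
    perturbed by the same noise scale, and lo/hi are symmetric on the logit
    scale with half-width ``1.96 * forecast_noise_sd * ui_width_factor``.
    With ``ui_width_factor = 1`` the intervals therefore reflect the true
    sampling noise of the reported means; 0 gives point forecasts.

    Side effect: stores the per-country true horizon covariates and the true
    noiseless horizon CHE (including the country's realized random intercept)
    in ``truth.true_2040``.
    """
    if ui_width_factor < 0:
        raise ConfigError("ui_width_factor must be non-negative")
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    half = 1.96 * forecast_noise_sd * ui_width_factor

    rows, true_rows = [], []
    for cid in sorted(truth.group_of):
        last = truth.last_covariates.loc[cid]
        true_logit_oop = logit(float(last["oop_exp"])) + rng.normal(0, forecast_noise_sd)
        true_logit_hex = logit(float(last["hex_gdp"])) + rng.normal(0, forecast_noise_sd)
        obs_logit_oop = true_logit_oop + rng.normal(0, forecast_noise_sd)
        obs_logit_hex = true_logit_hex + rng.normal(0, forecast_noise_sd)
        gdp_true = float(last["gdp_c"]) * (1.0 + truth.growth_rates[cid]) ** (
            horizon_year - base_year
        )
        eta = (cfg.true_beta0
               + cfg.true_beta1 * true_logit_oop
               + cfg.true_beta2 * true_logit_hex
               + cfg.true_beta3 * np.log(gdp_true)
               + truth.random_effects[cid])
        true_rows.append(
            {
                "country_id": cid,
                "oop_exp": inverse_logit(true_logit_oop),
                "hex_gdp": inverse_logit(true_logit_hex),
                "gdp_c": gdp_true,
                "che": inverse_logit(eta),
            }
        )
        rows.append(
            {
                "country_id": cid,
                "income_group": truth.group_of[cid],
                "oop_exp_mean": inverse_logit(obs_logit_oop),
                "oop_exp_lo": inverse_logit(obs_logit_oop - half),
                "oop_exp_hi": inverse_logit(obs_logit_oop + half),
                "hex_gdp_mean": inverse_logit(obs_logit_hex),
                "hex_gdp_lo": inverse_logit(obs_logit_hex - half),
                "hex_gdp_hi": inverse_logit(obs_logit_hex + half),
                "gdp_c_base": float(last["gdp_c"]),
                "base_year": base_year,
                "horizon_year": horizon_year,
            }
        )
    truth.true_2040 = pd.DataFrame(true_rows).set_index("country_id")
    return ForecastSet(pd.DataFrame(rows))


def generate_gdp_projections(
    truth: GroundTruth, years: tuple[int, int] = (2015, 2021)
) -> list[GdpProjection]:
    """Emit per-country GDP runs at each country's realized constant growth.

    The run over ``years`` (inclusive) compounds the country's last observed
    GDP per capita at its ground-truth growth rate, so annualizing any
    generated series recovers that rate exactly.
    """
    y0, y1 = int(years[0]), int(years[1])
    if y1 <= y0:
        raise ConfigError("projection year range must span >= 2 years")
    out = []
    for cid in sorted(truth.group_of):
        base = float(truth.last_covariates.loc[cid, "gdp_c"])
        base_year = int(truth.last_covariates.loc[cid, "year"])
        g = truth.growth_rates[cid]
        yrs = list(range(y0, y1 + 1))
        vals = [base * (1.0 + g) ** (y - base_year) for y in yrs]
        out.append(
            GdpProjection(
                country_id=cid,
                income_group=truth.group_of[cid],
                years=yrs,
                gdp_c_values=vals,
            )
        )
    return out


def default_config(**overrides) -> GeneratorConfig:
    """A :class:`GeneratorConfig` with study-scale defaults, with overrides."""
    return replace(GeneratorConfig(), **overrides)
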