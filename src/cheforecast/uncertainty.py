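"""Probabilistic sensitivity analysis for the horizon-year CHE projection.

Two uncertainty sources are propagated jointly through the projection:

* parameter uncertainty in the inputs — horizon OOP_EXP and HEX_GDP get beta
  distributions fitted to each country's forecast mean and 95 % uncertainty
  interval, and the annual GDP-growth rate of each income group gets a gamma
  distribution moment-matched to the group's (mean, SD);
* estimation uncertainty in the regression — coefficient vectors are drawn
  from a multivariate Gaussian with the fitted mean and variance-covariance
  matrix.

Each trial draws one coefficient vector, per-country covariates, and one
growth rate per income group (shared by the group's countries within the
trial), projects GDP, predicts CHE per country, and averages countries
within income groups — yielding per-country and per-group sample arrays.
95 % uncertainty intervals are the 2.5th/97.5th percentiles; target
attainment is the fraction of trials with group CHE strictly below a
threshold; gap-closing probabilities compare per-trial annualised decline
rates between groups, paired within trial so coefficient-draw correlation
is preserved.

The random-intercept and residual terms are excluded by default (only input
and coefficient uncertainty are propagated); ``include_residual`` adds both
for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, FittingError, ValidationError
from .model import CheMixedModel
from .projection import GroupGrowthSummary
from .types import ForecastSet, IncomeGroup, TargetReport

logger = logging.getLogger(__name__)

#: Default financial-risk-protection thresholds, as proportions:
#: CHE incidence < 0.5 %, 1 %, 1.5 %, 2 %.
DEFAULT_THRESHOLDS = (0.005, 0.010, 0.015, 0.020)


# --------------------------------------------------------------------------
# input distributions
# --------------------------------------------------------------------------

@dataclass
class BetaParams:
    """Beta(alpha, beta) parameters, or a flagged point mass at ``mean``."""

    alpha: float
    beta: float
    point_mass: bool = False
    mean: float | None = None

    def __post_init__(self) -> None:
        if not self.point_mass and (self.alpha <= 0 or self.beta <= 0):
            raise ValidationError("beta shapes must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.point_mass:
            return np.full(n, self.mean)
        return rng.beta(self.alpha, self.beta, n)


@dataclass
class GammaParams:
    """Gamma(shape, scale); mean = shape*scale, sd = sqrt(shape)*scale."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValidationError("gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.shape) * self.scale)


def beta_from_mean_ui(mean: float, lo: float, hi: float,
                      tolerance: float = 1e-6) -> BetaParams:
    """Fit a beta distribution to a mean and 95 % uncertainty interval.

    The mean constraint is enforced exactly by parameterizing
    ``alpha = mean * k``, ``beta = (1 - mean) * k`` and optimizing the
    concentration ``k`` so that the (2.5th, 97.5th) quantiles match
    ``(lo, hi)`` in the least-squares sense.  The initial ``k`` comes from
    moment matching with ``sd0 = (hi - lo) / 3.92`` (the normal-approximation
    SD of a 95 % interval).  A triple actually generated by a beta
    distribution is recovered exactly; inconsistent triples get the best
    least-squares compromise.

    A zero-width interval returns a flagged point mass whose samples are all
    equal to the mean.
    """
    if not (0.0 < lo <= mean <= hi < 1.0):
        raise DomainError(
            f"need 0 < lo <= mean <= hi < 1; got ({mean}, {lo}, {hi})"
        )
    if hi - lo < 1e-14:
        return BetaParams(alpha=1.0, beta=1.0, point_mass=True, mean=mean)

    sd0 = (hi - lo) / 3.92
    k0 = max(mean * (1.0 - mean) / sd0**2 - 1.0, 1e-3)

    def residuals(log_k):
        k = np.exp(log_k[0])
        a, b = mean * k, (1.0 - mean) * k
        q = stats.beta.ppf([0.025, 0.975], a, b)
        return q - [lo, hi]

    sol = optimize.least_squares(residuals, [np.log(k0)], xtol=1e-14, ftol=1e-14,
                                 gtol=1e-14)
    k = float(np.exp(sol.x[0]))
    res = residuals(sol.x)
    if not sol.success or not np.all(np.isfinite(res)):
        raise FittingError(
            f"beta quantile fit failed for (mean={mean}, lo={lo}, hi={hi}); "
            f"residuals {res}"
        )
    return BetaParams(alpha=mean * k, beta=(1.0 - mean) * k)


def gamma_from_mean_sd(mean: float, sd: float) -> GammaParams:
    """Moment-matched gamma: shape = (mean/sd)^2, scale = sd^2/mean."""
    if mean <= 0 or sd <= 0:
        raise DomainError("gamma moment matching needs mean > 0 and sd > 0")
    return GammaParams(shape=(mean / sd) ** 2, scale=sd**2 / mean)


# --------------------------------------------------------------------------
# coefficient sampling
# --------------------------------------------------------------------------

def sample_coefficients(model: CheMixedModel, n: int,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` coefficient vectors from MVN(beta, beta_vcov).

    Sampling goes through a symmetric eigendecomposition; eigenvalues in
    [-1e-10, 0) are clipped to 0 (numerical PSD repair), anything more
    negative is an error.  A zero matrix reproduces the mean exactly.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    model._check_fitted()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    vcov = 0.5 * (model.beta_vcov_ + model.beta_vcov_.T)
    eigval, eigvec = np.linalg.eigh(vcov)
    if np.any(eigval < -1e-10):
        raise ValidationError(
            f"beta_vcov is not positive semi-definite (min eigenvalue {eigval.min():.3g})"
        )
    eigval = np.clip(eigval, 0.0, None)
    root = eigvec * np.sqrt(eigval)
    z = rng.standard_normal((n, len(model.beta_)))
    return model.beta_ + z @ root.T


# --------------------------------------------------------------------------
# the Monte Carlo engine
# --------------------------------------------------------------------------

@dataclass
class McSamples:
    """Per-country and per-group Monte Carlo draws of horizon CHE."""

    n: int
    seed: int
    per_country: dict[str, np.ndarray]
    per_group: dict[IncomeGroup, np.ndarray]
    decline_per_group: dict[IncomeGroup, np.ndarray] = field(default_factory=dict)
    baseline_per_group: dict[IncomeGroup, np.ndarray] = field(default_factory=dict)

    def group_members(self) -> dict[IncomeGroup, list[str]]:
        return self._members

    _members: dict[IncomeGroup, list[str]] = field(default_factory=dict, repr=False)


def run_monte_carlo(
    model: CheMixedModel,
    forecasts: ForecastSet,
    growth: dict[IncomeGroup, GroupGrowthSummary],
    n: int = 100_000,
    seed: int = 0,
    *,
    baseline_covariates=None,
    use_blup: bool = False,
    include_residual: bool = False,
    decline_baseline: str = "per_trial",
    growth_per_country: bool = False,
    n_years_decline: int | None = None,
) -> McSamples:
    """Propagate input and estimation uncertainty through the projection.

    Per trial k: one coefficient draw; per country, OOP_EXP and HEX_GDP
    draws from betas fitted to the forecast mean/UI; one growth-rate draw
    per income group from the gamma moment-matched to the group (mean, SD)
    — shared by every member country in that trial unless
    ``growth_per_country`` — then GDP compounding, CHE prediction and
    within-group arithmetic averaging (countries stacked in sorted-id order).

    ``baseline_covariates`` (DataFrame indexed by country_id with oop_exp,
    hex_gdp, gdp_c, e.g. ``panel.last_observations()``) enables per-trial
    annualised decline rates between the base-year group CHE and the horizon
    draws; with ``decline_baseline="fixed"`` the baseline uses the mean
    coefficients instead of the per-trial draw.

    Deterministic given ``seed``.  With every uncertainty source degenerate
    (zero-width UIs, zero vcov, zero growth SD) all trials coincide with the
    deterministic projection.
    """
    if n < 100:
        logger.warning("n=%d Monte Carlo trials; tail percentiles will be unstable", n)
    if decline_baseline not in ("per_trial", "fixed"):
        raise ValidationError(f"unknown decline_baseline {decline_baseline!r}")
    rng = np.random.default_rng(seed)
    coefs = sample_coefficients(model, n, rng)  # (n, 4)

    # one growth draw per group per trial, in fixed group order
    growth_draws: dict[IncomeGroup, np.ndarray] = {}
    if not growth_per_country:
        for g in IncomeGroup:
            if g not in growth:
                continue
            gs = growth[g]
            if gs.sd_rate == 0.0:
                growth_draws[g] = np.full(n, gs.mean_rate)
            else:
                gp = gamma_from_mean_sd(gs.mean_rate, gs.sd_rate)
                growth_draws[g] = rng.gamma(gp.shape, gp.scale, n)

    residual_sd = float(np.sqrt(model.residual_variance_)) if include_residual else 0.0
    re_sd = (float(np.sqrt(model.random_effect_variance_))
             if include_residual else 0.0)

    per_country: dict[str, np.ndarray] = {}
    members: dict[IncomeGroup, list[str]] = {}
    skipped = []
    for row in forecasts.data.sort_values("country_id").itertuples():
        g = row.income_group
        if g not in growth:
            skipped.append(row.country_id)
            continue
        try:
            oop_dist = beta_from_mean_ui(row.oop_exp_mean, row.oop_exp_lo, row.oop_exp_hi)
            hex_dist = beta_from_mean_ui(row.hex_gdp_mean, row.hex_gdp_lo, row.hex_gdp_hi)
        except (DomainError, FittingError) as exc:
            logger.warning("country %s excluded from Monte Carlo: %s", row.country_id, exc)
            skipped.append(row.country_id)
            continue
        oop = np.clip(oop_dist.sample(n, rng), 1e-12, 1 - 1e-12)
        hex_ = np.clip(hex_dist.sample(n, rng), 1e-12, 1 - 1e-12)
        if growth_per_country:
            gs = growth[g]
            if gs.sd_rate == 0.0:
                gdraw = np.full(n, gs.mean_rate)
            else:
                gp = gamma_from_mean_sd(gs.mean_rate, gs.sd_rate)
                gdraw = rng.gamma(gp.shape, gp.scale, n)
        else:
            gdraw = growth_draws[g]
        n_years = int(row.horizon_year) - int(row.base_year)
        gdp = row.gdp_c_base * (1.0 + gdraw) ** n_years

        eta = (coefs[:, 0]
               + coefs[:, 1] * np.log(oop / (1.0 - oop))
               + coefs[:, 2] * np.log(hex_ / (1.0 - hex_))
               + coefs[:, 3] * np.log(gdp))
        if use_blup:
            eta = eta + model.country_effects_.get(row.country_id, 0.0)
        if re_sd > 0:
            eta = eta + rng.normal(0.0, re_sd, n)
        if residual_sd > 0:
            eta = eta + rng.normal(0.0, residual_sd, n)
        per_country[row.country_id] = 1.0 / (1.0 + np.exp(-eta))
        members.setdefault(g, []).append(row.country_id)
    if skipped:
        logger.warning("countries excluded from Monte Carlo: %s", skipped)

    per_group = {
        g: np.vstack([per_country[c] for c in sorted(cids)]).mean(axis=0)
        for g, cids in members.items()
    }

    samples = McSamples(n=n, seed=seed, per_country=per_country,
                        per_group=per_group,
                        _members={g: sorted(c) for g, c in members.items()})

    if baseline_covariates is not None:
        _add_decline_rates(samples, model, coefs, forecasts, baseline_covariates,
                           members, use_blup=use_blup,
                           decline_baseline=decline_baseline,
                           n_years_decline=n_years_decline)
    return samples


def _add_decline_rates(samples, model, coefs, forecasts, baseline_covariates,
                       members, *, use_blup, decline_baseline, n_years_decline):
    """Per-trial group baselines and annualised 2013->2040 decline rates."""
    base = baseline_covariates
    horizon = forecasts.data.set_index("country_id")
    for g, cids in members.items():
        cids = sorted(c for c in cids if c in base.index)
        if not cids:
            continue
        n = samples.n
        acc = np.zeros(n)
        n_years = None
        for cid in cids:
            row = base.loc[cid]
            x = np.array([1.0,
                          np.log(row["oop_exp"] / (1.0 - row["oop_exp"])),
                          np.log(row["hex_gdp"] / (1.0 - row["hex_gdp"])),
                          np.log(row["gdp_c"])])
            effect = model.country_effects_.get(cid, 0.0) if use_blup else 0.0
            if decline_baseline == "per_trial":
                eta = coefs @ x + effect
            else:
                eta = np.full(n, float(model.beta_ @ x) + effect)
            acc += 1.0 / (1.0 + np.exp(-eta))
            hrow = horizon.loc[cid]
            n_years = int(hrow["horizon_year"]) - int(hrow["base_year"])
        baseline_group = acc / len(cids)
        if n_years_decline is not None:
            n_years = n_years_decline
        samples.baseline_per_group[g] = baseline_group
        samples.decline_per_group[g] = 1.0 - (
            samples.per_group[g] / baseline_group
        ) ** (1.0 / n_years)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def percentile_ui(values, lo_pct: float = 2.5, hi_pct: float = 97.5) -> tuple[float, float]:
    """Linear-interpolation percentile interval (default the 95 % UI)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("need >= 2 samples for a percentile interval")
    lo, hi = np.percentile(arr, [lo_pct, hi_pct], method="linear")
    return float(lo), float(hi)


def target_probabilities(
    samples: McSamples,
    thresholds=DEFAULT_THRESHOLDS,
    *,
    decline_reference: IncomeGroup | None = IncomeGroup.UMIC,
    include_groups=None,
) -> TargetReport:
    """Attainment probability per (group, threshold), plus points/UIs/gaps.

    The probability is the fraction of trials with group CHE strictly below
    the threshold.  ``group_point`` is the mean of the group's draws and
    ``group_ui`` its 2.5/97.5 percentile interval.  When decline-rate arrays
    are present, each non-reference group also gets the gap-closing
    probability against ``decline_reference`` (default the upper-middle
    income group), computed trial-paired with a strict ``>``.
    """
    thresholds = [float(t) for t in thresholds]
    if any(not (0.0 < t < 1.0) for t in thresholds):
        raise ValidationError("thresholds must be proportions in (0, 1)")
    groups = list(samples.per_group) if include_groups is None else list(include_groups)
    probabilities = {}
    group_point, group_ui = {}, {}
    for g in groups:
        arr = samples.per_group[g]
        for t in thresholds:
            probabilities[(g, t)] = float(np.mean(arr < t))
        group_point[g] = float(arr.mean())
        group_ui[g] = percentile_ui(arr)
    gap = {}
    if decline_reference is not None and decline_reference in samples.decline_per_group:
        ref = samples.decline_per_group[decline_reference]
        for g, arr in samples.decline_per_group.items():
            if g is decline_reference:
                continue
            gap[g] = gap_closing_probability(arr, ref)
    return TargetReport(
        thresholds=thresholds,
        probabilities=probabilities,
        group_point=group_point,
        group_ui=group_ui,
        gap_probabilities=gap,
    )


def gap_closing_probability(decline_a, decline_ref) -> float:
    """Fraction of paired trials where group A declines faster than reference.

    Strict inequality: identical arrays give 0.  Pairing within trial keeps
    the common coefficient draw, so this is the probability that A's
    annualised CHE decline exceeds the reference group's under the same
    parameter state.
    """
    a = np.asarray(decline_a, dtype=float)
    r = np.asarray(decline_ref, dtype=float)
    if a.shape != r.shape:
        raise ValidationError(f"mismatched trial arrays: {a.shape} vs {r.shape}")
    return float(np.mean(a > r))
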