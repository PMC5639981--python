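"""Mixed-effects regression of logit CHE incidence on health-financing covariates.

The core statistical model is a linear mixed model on the logit scale,

    logit(CHE_it) = b0 + b1 * logit(OOP_EXP_it) + b2 * logit(HEX_GDP_it)
                    + b3 * ln(GDP_C_it) + u_i + e_it,

with a random intercept u_i ~ N(0, s_u^2) per country capturing heterogeneity
between countries and data sources, and residual e_it ~ N(0, s_e^2).  CHE is
the incidence of catastrophic health expenditure (household out-of-pocket
medical spending above 40 % of capacity to pay), OOP_EXP the out-of-pocket
share of total health expenditure, HEX_GDP the health-expenditure share of
GDP, and GDP_C GDP per capita.

The estimator follows the scikit-learn protocol: construct with
hyper-parameters, call :meth:`fit`, read trailing-underscore attributes,
call :meth:`predict`.  Estimation is delegated to statsmodels ``MixedLM``
(REML by default); everything downstream needs only the fitted fixed effects,
their variance-covariance matrix, the variance components, and the per-country
random-intercept predictions (BLUPs), all of which are exposed as attributes
and serializable to JSON so the Monte Carlo engine can run without refitting.
"""

from __future__ import annotations

import json
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import DomainError, FittingError, ValidationError
from .transforms import inverse_logit, logit
from .types import CountryPanel

logger = logging.getLogger(__name__)

#: Order of the fixed-effect coefficient vector.
COEF_NAMES = ["intercept", "logit_oop_exp", "logit_hex_gdp", "ln_gdp_c"]

#: Random-effect variance below which the fit is flagged as effectively
#: fixed-effects only.
_SINGULAR_RE_VARIANCE = 1e-8


def design_matrix(oop_exp, hex_gdp, gdp_c) -> np.ndarray:
    """Stack [1, logit(OOP_EXP), logit(HEX_GDP), ln(GDP_C)] row-wise."""
    oop = np.atleast_1d(np.asarray(oop_exp, dtype=float))
    hex_ = np.atleast_1d(np.asarray(hex_gdp, dtype=float))
    gdp = np.atleast_1d(np.asarray(gdp_c, dtype=float))
    if np.any(gdp <= 0.0):
        raise DomainError("gdp_c must be strictly positive")
    return np.column_stack([np.ones(oop.shape[0]), logit(oop), logit(hex_), np.log(gdp)])


class CheMixedModel(BaseEstimator, RegressorMixin):
    """Linear mixed model for logit CHE with a country random intercept.

    Parameters
    ----------
    method : {"reml", "ml"}
        Variance-component estimator.  REML is the default (standard choice
        for variance components); ML is available for likelihood comparisons.
    r2_definition : {"marginal", "conditional"}
        Which pseudo-R² to store in ``r_squared_``.  Marginal credits only the
        fixed effects; conditional also credits the country intercepts.

    Attributes (after fit)
    ----------------------
    beta_ : ndarray, shape (4,)
        Fixed effects in :data:`COEF_NAMES` order.
    beta_se_ : ndarray, shape (4,)
        Standard errors (normal approximation).
    beta_vcov_ : ndarray, shape (4, 4)
        Variance-covariance of the fixed effects (symmetric PSD).
    pvalues_ : ndarray, shape (4,)
        Two-sided Wald p-values from the normal approximation.
    random_effect_variance_, residual_variance_ : float
        Estimated variance components.
    country_effects_ : dict[str, float]
        Predicted random intercepts (BLUPs) per country.
    r_squared_ : float
        Pseudo-R² under ``r2_definition``.
    n_obs_, n_countries_ : int
        Fitting-sample sizes (rows with missing CHE are dropped).
    converged_ : bool
    """

    def __init__(self, method: str = "reml", r2_definition: str = "marginal"):
        self.method = method
        self.r2_definition = r2_definition

    # ------------------------------------------------------------------ fit

    def fit(self, X, y=None, groups=None) -> "CheMixedModel":
        """Fit the mixed model.

        ``X`` is a :class:`CountryPanel` or a DataFrame with columns
        country_id, che, oop_exp, hex_gdp, gdp_c; ``y``/``groups`` override
        the che column / country ids when ``X`` is a bare covariate frame.
        """
        df = self._as_frame(X, y, groups)
        dropped = int(df["che"].isna().sum())
        if dropped:
            logger.info("dropping %d row(s) with missing CHE before fitting", dropped)
        df = df.dropna(subset=["che"]).reset_index(drop=True)
        n_countries = df["country_id"].nunique()
        if n_countries < 2:
            raise FittingError(
                f"mixed-model fitting needs >= 2 countries, got {n_countries}"
            )
        if self.method not in ("reml", "ml"):
            raise ValueError(f"method must be 'reml' or 'ml', got {self.method!r}")

        Xmat = design_matrix(df["oop_exp"], df["hex_gdp"], df["gdp_c"])
        yvec = logit(df["che"].to_numpy(dtype=float))
        model = MixedLM(yvec, Xmat, groups=df["country_id"].to_numpy())
        result = last = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence chatter on clean fits
            for optimizer in ("bfgs", "lbfgs", "cg", "powell"):
                try:
                    candidate = model.fit(reml=(self.method == "reml"), method=optimizer)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                last = candidate
                if candidate.converged:
                    result = candidate
                    break
        if result is None:
            # The optimizer stalls on the boundary when the random-effect
            # variance is (near) zero; the model then degrades to a plain
            # fixed-effects fit, as the variance component is not identifiable.
            if last is not None and float(np.asarray(last.cov_re)[0, 0]) < 1e-6:
                logger.warning(
                    "random-effect variance hit the zero boundary; "
                    "falling back to a fixed-effects (OLS) fit"
                )
                return self._fit_fixed_effects(df, Xmat, yvec)
            raise FittingError(
                "mixed-model optimizer did not converge "
                f"(tried bfgs/lbfgs/cg/powell; last cov_re="
                f"{None if last is None else np.asarray(last.cov_re)[0, 0]})"
            )

        self.beta_ = np.asarray(result.fe_params, dtype=float)
        cov = np.asarray(result.cov_params(), dtype=float)[:4, :4]
        self.beta_vcov_ = 0.5 * (cov + cov.T)  # symmetrize numerical noise
        self.beta_se_ = np.sqrt(np.diag(self.beta_vcov_))
        from scipy.stats import norm

        z = self.beta_ / self.beta_se_
        self.pvalues_ = 2.0 * norm.sf(np.abs(z))
        self.random_effect_variance_ = float(np.asarray(result.cov_re)[0, 0])
        self.residual_variance_ = float(result.scale)
        self.country_effects_ = {
            str(cid): float(np.asarray(eff)[0])
            for cid, eff in result.random_effects.items()
        }
        self.n_obs_ = int(len(df))
        self.n_countries_ = int(n_countries)
        self.converged_ = bool(result.converged)
        if self.random_effect_variance_ < _SINGULAR_RE_VARIANCE:
            logger.warning(
                "random-effect variance is effectively zero (%.3g); the model "
                "degrades to a fixed-effects fit",
                self.random_effect_variance_,
            )
        self.r_squared_ = compute_r_squared(self, df, self.r2_definition)
        return self

    def _fit_fixed_effects(self, df, Xmat, yvec) -> "CheMixedModel":
        """OLS fallback used when the random-effect variance is singular."""
        import statsmodels.api as sm
        from scipy.stats import norm

        ols = sm.OLS(yvec, Xmat).fit()
        self.beta_ = np.asarray(ols.params, dtype=float)
        cov = np.asarray(ols.cov_params(), dtype=float)
        self.beta_vcov_ = 0.5 * (cov + cov.T)
        self.beta_se_ = np.sqrt(np.diag(self.beta_vcov_))
        self.pvalues_ = 2.0 * norm.sf(np.abs(self.beta_ / self.beta_se_))
        self.random_effect_variance_ = 0.0
        self.residual_variance_ = float(ols.scale)
        self.country_effects_ = {str(c): 0.0 for c in df["country_id"].unique()}
        self.n_obs_ = int(len(df))
        self.n_countries_ = int(df["country_id"].nunique())
        self.converged_ = True
        self.r_squared_ = compute_r_squared(self, df, self.r2_definition)
        return self

    @staticmethod
    def _as_frame(X, y, groups) -> pd.DataFrame:
        if isinstance(X, CountryPanel):
            return X.data.copy()
        df = pd.DataFrame(X).copy()
        if y is not None:
            df["che"] = np.asarray(y, dtype=float)
        if groups is not None:
            df["country_id"] = np.asarray(groups)
        required = ["country_id", "che", "oop_exp", "hex_gdp", "gdp_c"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"fit input is missing columns: {missing}")
        return df

    # -------------------------------------------------------------- predict

    def predict(self, X=None, *, oop_exp=None, hex_gdp=None, gdp_c=None,
                country_effect=0.0):
        """Predict CHE incidence (a proportion) for given covariates.

        Either pass a DataFrame/panel with oop_exp, hex_gdp, gdp_c columns,
        or the three covariates as keyword scalars/arrays.  ``country_effect``
        is the random intercept to add on the logit scale (0 gives the
        population-level prediction; pass a BLUP from ``country_effects_``
        to predict for a specific fitted country).
        """
        self._check_fitted()
        if X is not None:
            df = X.data if isinstance(X, CountryPanel) else pd.DataFrame(X)
            oop_exp, hex_gdp, gdp_c = df["oop_exp"], df["hex_gdp"], df["gdp_c"]
        Xmat = design_matrix(oop_exp, hex_gdp, gdp_c)
        eta = Xmat @ self.beta_ + np.asarray(country_effect, dtype=float)
        out = inverse_logit(eta)
        return float(out[0]) if out.size == 1 else out

    def _check_fitted(self) -> None:
        if not hasattr(self, "beta_"):
            raise FittingError("model is not fitted; call fit() first")

    # ------------------------------------------------------- serialization

    def to_json(self, path=None) -> str:
        """Serialize fitted state (coefficients, vcov, variances, BLUPs)."""
        self._check_fitted()
        payload = {
            "coef_names": COEF_NAMES,
            "beta": self.beta_.tolist(),
            "beta_se": self.beta_se_.tolist(),
            "beta_vcov": self.beta_vcov_.tolist(),
            "pvalues": self.pvalues_.tolist(),
            "random_effect_variance": self.random_effect_variance_,
            "residual_variance": self.residual_variance_,
            "country_effects": self.country_effects_,
            "r_squared": self.r_squared_,
            "n_obs": self.n_obs_,
            "n_countries": self.n_countries_,
            "method": self.method,
            "r2_definition": self.r2_definition,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CheMixedModel":
        """Rebuild a fitted model from :meth:`to_json` output (path or str)."""
        if isinstance(source, (str,)) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                payload = json.load(fh)
        est = cls(method=payload.get("method", "reml"),
                  r2_definition=payload.get("r2_definition", "marginal"))
        est.beta_ = np.asarray(payload["beta"], dtype=float)
        est.beta_se_ = np.asarray(payload["beta_se"], dtype=float)
        est.beta_vcov_ = np.asarray(payload["beta_vcov"], dtype=float)
        est.pvalues_ = np.asarray(payload["pvalues"], dtype=float)
        est.random_effect_variance_ = float(payload["random_effect_variance"])
        est.residual_variance_ = float(payload["residual_variance"])
        est.country_effects_ = {k: float(v) for k, v in payload["country_effects"].items()}
        est.r_squared_ = float(payload["r_squared"])
        est.n_obs_ = int(payload["n_obs"])
        est.n_countries_ = int(payload["n_countries"])
        est.converged_ = True
        return est


def fit_che_model(panel: CountryPanel, method: str = "reml") -> CheMixedModel:
    """Fit the mixed model on a panel; thin wrapper over :class:`CheMixedModel`."""
    return CheMixedModel(method=method).fit(panel)


def predict_che(model: CheMixedModel, oop_exp, hex_gdp, gdp_c,
                country_effect: float = 0.0):
    """Population- or country-level CHE prediction from a fitted model.

    Inverse-logit of the linear predictor; ``country_effect`` shifts the
    logit by the given random intercept (default 0).
    """
    model._check_fitted()
    Xmat = design_matrix(oop_exp, hex_gdp, gdp_c)
    eta = Xmat @ model.beta_ + np.asarray(country_effect, dtype=float)
    out = inverse_logit(eta)
    return float(out[0]) if out.size == 1 else out


def compute_r_squared(model: CheMixedModel, panel: CountryPanel,
                      definition: str = "marginal") -> float:
    """Pseudo-R² on the logit scale for a mixed model.

    marginal:    var(fixed-effect predictions) /
                 (var(fixed) + random-effect variance + residual variance)
    conditional: (var(fixed) + random-effect variance) / same denominator,
    i.e. the share of total latent variance explained without / with the
    country intercepts.  Both lie in [0, 1] and conditional >= marginal.
    """
    if definition not in ("marginal", "conditional"):
        raise ValueError(f"unknown R^2 definition {definition!r}")
    model._check_fitted()
    df = panel.data if isinstance(panel, CountryPanel) else pd.DataFrame(panel)
    df = df.dropna(subset=["che"])
    if df.empty:
        raise ValidationError("panel has no observed CHE rows")
    Xmat = design_matrix(df["oop_exp"], df["hex_gdp"], df["gdp_c"])
    eta = Xmat @ model.beta_
    var_fixed = float(np.var(eta, ddof=1)) if len(eta) > 1 else 0.0
    denom = var_fixed + model.random_effect_variance_ + model.residual_variance_
    if denom <= 0.0:
        return 1.0
    num = var_fixed
    if definition == "conditional":
        num += model.random_effect_variance_
    return float(num / denom)
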