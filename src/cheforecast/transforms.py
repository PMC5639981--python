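"""Pure numeric primitives shared by every pipeline stage.

The projection model lives on the logit scale, GDP growth is annualised
geometrically, and headline results are phrased as annualised rates of decline
in catastrophic-health-expenditure (CHE) incidence.  These helpers implement
those conversions once, with explicit domain checks, so the statistical
modules never re-derive them.

Scale conventions
-----------------
* Proportions (CHE, OOP_EXP, HEX_GDP) live strictly inside (0, 1).
* Rates of change are per-year fractions (0.045 means 4.5 %/year); whether a
  positive rate means growth or decline is documented per function.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit
from scipy.special import logit as _logit

from .errors import DomainError

__all__ = [
    "logit",
    "inverse_logit",
    "odds_effect",
    "annualized_rate",
    "compound",
    "annualized_decline",
    "cumulative_decline",
]


def logit(p):
    """Log-odds ln(p / (1 - p)) of a proportion in the open interval (0, 1).

    Accepts scalars or arrays; raises :class:`DomainError` if any value lies
    on or outside the boundary, where the log-odds are undefined.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DomainError(f"logit requires values strictly in (0, 1); got {p!r}")
    out = _logit(arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def inverse_logit(x):
    """Inverse of :func:`logit`: 1 / (1 + exp(-x)), always in (0, 1)."""
    arr = np.asarray(x, dtype=float)
    out = _expit(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def odds_effect(beta: float, relative_change: float) -> float:
    """Relative change in outcome odds implied by a logit-logit coefficient.

    For a model ``logit(y) = ... + beta * logit(x) + ...``, multiplying the
    odds of ``x`` by ``(1 + relative_change)`` multiplies the odds of ``y`` by
    ``(1 + relative_change) ** beta``.  The return value is that factor minus
    one, i.e. the fractional change in the odds of the outcome.

    This is an odds-scale statement, not a risk-ratio approximation: for a
    rare outcome odds and risk nearly coincide, but the function makes no such
    assumption.

    Parameters
    ----------
    beta
        Coefficient on the logit of the predictor (for a log-predictor such as
        ln(GDP per capita), the same formula applies with ``relative_change``
        read as the relative change in the predictor itself).
    relative_change
        Fractional change in the predictor's odds; must exceed -1.
    """
    if relative_change <= -1.0:
        raise DomainError(
            f"relative change must be > -1 (a change of {relative_change} "
            "would make the odds non-positive)"
        )
    return float((1.0 + relative_change) ** beta - 1.0)


def annualized_rate(values, years) -> float:
    """Geometric annualised rate of change between the endpoints of a series.

    Returns ``(values[-1] / values[0]) ** (1 / (years[-1] - years[0])) - 1``:
    the constant per-year growth rate that carries the first value to the last
    over the elapsed years.  Interior points do not influence the endpoint
    definition (see :func:`annualized_rate_ols` for the regression variant).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(years, dtype=float)
    if v.size < 2 or v.size != y.size:
        raise DomainError("need >= 2 values with matching years")
    if np.any(v <= 0.0):
        raise DomainError("values must be strictly positive")
    if np.any(np.diff(y) <= 0):
        raise DomainError("years must be strictly increasing")
    span = y[-1] - y[0]
    return float((v[-1] / v[0]) ** (1.0 / span) - 1.0)


def annualized_rate_ols(values, years) -> float:
    """Annualised growth rate from a log-linear least-squares fit.

    Regresses ln(value) on year and returns ``exp(slope) - 1``.  Uses every
    observation, so it is less sensitive to endpoint noise than
    :func:`annualized_rate`; the two coincide for exactly geometric series.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(years, dtype=float)
    if v.size < 2 or v.size != y.size:
        raise DomainError("need >= 2 values with matching years")
    if np.any(v <= 0.0):
        raise DomainError("values must be strictly positive")
    slope = np.polyfit(y, np.log(v), 1)[0]
    return float(np.exp(slope) - 1.0)


def compound(base: float, rate: float, n_years: int) -> float:
    """Project ``base`` forward ``n_years`` at a constant annual ``rate``.

    Inverse of :func:`annualized_rate` in the sense that compounding a value
    at the annualised rate of a series reproduces the series' endpoint.
    """
    if rate <= -1.0:
        raise DomainError("rate must be > -1")
    if n_years < 0:
        raise DomainError("n_years must be non-negative")
    return float(base * (1.0 + rate) ** n_years)


def annualized_decline(start: float, end: float, n_years: int) -> float:
    """Annualised rate of decline r such that ``start * (1 - r)^n = end``.

    Positive when the level falls; negative when it rises.  Both levels must
    be proportions in (0, 1) — this is used for CHE incidence endpoints.
    """
    if not (0.0 < start < 1.0 and 0.0 < end < 1.0):
        raise DomainError("start and end must be proportions in (0, 1)")
    if n_years < 1:
        raise DomainError("n_years must be >= 1")
    return float(1.0 - (end / start) ** (1.0 / n_years))


def cumulative_decline(rate: float, n_years: int) -> float:
    """Total fraction of the starting level removed after ``n_years``.

    ``1 - (1 - rate)^n``: a 1.7 %/year decline sustained for 27 years removes
    about 37 % of the starting incidence.  Exact inverse of
    :func:`annualized_decline` applied to the implied endpoints.
    """
    if rate >= 1.0:
        raise DomainError("rate must be < 1 (100 %/year would hit zero)")
    if n_years < 1:
        raise DomainError("n_years must be >= 1")
    return float(1.0 - (1.0 - rate) ** n_years)
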