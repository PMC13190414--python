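"""Parametric survival curves, right-censored maximum likelihood, and
rate/probability conversions.

Seven candidate families are supported, matching the standard extrapolation
toolbox used in oncology cost-effectiveness work: exponential, Weibull in
proportional-hazards form, Gompertz, log-logistic, log-normal, gamma and the
three-parameter generalized gamma.  Parameters follow the shape/scale
conventions in which fitted model coefficients are usually reported:

====================  =================================  =====================
family                parameters                         survival function
====================  =================================  =====================
exponential           (rate,)                            exp(-rate*t)
weibull_ph            (shape, rate)                      exp(-rate*t**shape)
gompertz              (shape, rate)                      exp(-(rate/shape)*(exp(shape*t)-1))
loglogistic           (shape, scale)                     1/(1+(t/scale)**shape)
lognormal             (meanlog, sdlog)                   1-Phi((ln t - meanlog)/sdlog)
gamma                 (shape, rate)                      regularized upper gamma
gengamma              (mu, sigma, Q)                     Prentice parameterization
====================  =================================  =====================

Times are in months throughout (1 month = 365.25/12 days).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: month length in days used for all month <-> day arithmetic
DAYS_PER_MONTH = 365.25 / 12.0
#: year length in days used for the annual-probability -> cycle-probability
#: conversion (the "28-day probability" convention)
DAYS_PER_YEAR = 365.0

FAMILIES = (
    "exponential",
    "weibull_ph",
    "gompertz",
    "loglogistic",
    "lognormal",
    "gamma",
    "gengamma",
)

_N_PARAMS = {
    "exponential": 1,
    "weibull_ph": 2,
    "gompertz": 2,
    "loglogistic": 2,
    "lognormal": 2,
    "gamma": 2,
    "gengamma": 3,
}


class ConfigError(ValueError):
    """Invalid family name or parameter vector."""


@dataclass(frozen=True)
class ParametricSurvival:
    """One parametric survival curve (a fitted or assumed distribution).

    ``params`` holds the family-specific parameter vector documented in the
    module docstring.  Positivity constraints are enforced at construction.
    """

    family: str
    params: tuple

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown survival family {self.family!r}")
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if len(params) != _N_PARAMS[self.family]:
            raise ConfigError(
                f"{self.family} takes {_N_PARAMS[self.family]} parameters, "
                f"got {len(params)}"
            )
        if not all(math.isfinite(p) for p in params):
            raise ConfigError(f"non-finite parameters {params}")
        self._check_positivity(params)

    def _check_positivity(self, params):
        fam = self.family
        if fam == "lognormal":
            if params[1] <= 0:
                raise ConfigError("lognormal sdlog must be > 0")
        elif fam == "gengamma":
            if params[1] <= 0:
                raise ConfigError("gengamma sigma must be > 0")
        else:
            if any(p <= 0 for p in params):
                raise ConfigError(f"{fam} parameters must be > 0, got {params}")

    # -- distribution machinery -------------------------------------------

    def _frozen(self):
        """The scipy.stats frozen distribution implementing this curve."""
        fam, p = self.family, self.params
        if fam == "exponential":
            return stats.expon(scale=1.0 / p[0])
        if fam == "weibull_ph":
            shape, rate = p
            return stats.weibull_min(shape, scale=rate ** (-1.0 / shape))
        if fam == "gompertz":
            shape, rate = p
            return stats.gompertz(rate / shape, scale=1.0 / shape)
        if fam == "loglogistic":
            shape, scale = p
            return stats.fisk(shape, scale=scale)
        if fam == "lognormal":
            mu, sigma = p
            return stats.lognorm(sigma, scale=math.exp(mu))
        if fam == "gamma":
            shape, rate = p
            return stats.gamma(shape, scale=1.0 / rate)
        # Prentice (mu, sigma, Q); Q -> 0 degenerates to log-normal
        mu, sigma, q = p
        if abs(q) < 1e-8:
            return stats.lognorm(sigma, scale=math.exp(mu))
        a = q ** -2.0
        c = q / sigma
        scale = math.exp(mu) * (q * q) ** (sigma / q)
        return stats.gengamma(a, c, scale=scale)

    def sf(self, t):
        """Survival probability S(t); t in months, scalar or array, t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival time must be non-negative")
        with np.errstate(divide="ignore"):
            out = self._frozen().sf(t)
        return out if out.ndim else float(out)

    def logpdf(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            out = self._frozen().logpdf(t)
        return out if out.ndim else float(out)

    def logsf(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            out = self._frozen().logsf(t)
        return out if out.ndim else float(out)

    def isf(self, p):
        """Inverse survival: the time t with S(t) = p."""
        p = np.asarray(p, dtype=float)
        out = self._frozen().isf(p)
        return out if out.ndim else float(out)

    def median(self):
        return float(self._frozen().median())


def survival_probability(spec: ParametricSurvival, t) -> float:
    """S(t) for a single time point (months)."""
    return spec.sf(t)


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class FittedModel:
    """A maximum-likelihood fit of one family to right-censored data."""

    spec: ParametricSurvival
    loglik: float
    aic: float = field(default=None)
    bic: float = field(default=None)
    n: int = 0
    converged: bool = True
    message: str = ""

    def __post_init__(self):
        k = len(self.spec.params)
        if self.aic is None:
            object.__setattr__(self, "aic", -2.0 * self.loglik + 2.0 * k)
        if self.bic is None:
            object.__setattr__(
                self, "bic", -2.0 * self.loglik + k * math.log(self.n)
            )


class FittingError(RuntimeError):
    pass


def _validate_ipd(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.shape != event.shape:
        raise ValueError("time and event must have the same length")
    if np.any(time < 0):
        raise ValueError("event/censoring times must be >= 0")
    if not np.all(np.isin(event, (0.0, 1.0))):
        raise ValueError("event indicator must be 0 or 1")
    return time, event


def _neg_loglik(spec: ParametricSurvival, time, event):
    lp = spec.logpdf(np.maximum(time, 1e-12))
    ls = spec.logsf(time)
    ll = np.where(event == 1, lp, ls)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(np.sum(ll))


def _initial_guess(family, time, event):
    d = float(event.sum())
    exposure = float(time.sum())
    rate0 = d / max(exposure, 1e-12)
    tev = time[event == 1]
    tev = tev[tev > 0]
    if tev.size == 0:
        tev = np.array([max(np.median(time), 1e-6)])
    mu0 = float(np.mean(np.log(tev)))
    sd0 = float(np.std(np.log(tev))) or 0.5
    med0 = float(np.median(tev))
    if family == "exponential":
        return [rate0]
    if family == "weibull_ph":
        return [1.0, rate0]
    if family == "gompertz":
        return [0.05, rate0]
    if family == "loglogistic":
        return [1.5, med0]
    if family == "lognormal":
        return [mu0, sd0]
    if family == "gamma":
        return [1.0, rate0]
    return [mu0, sd0, 0.5]  # gengamma


def _pack(family, params):
    """Optimize positive parameters on the log scale; location-like free."""
    free = {"lognormal": {0}, "gengamma": {0, 2}}.get(family, set())
    return [p if i in free else math.log(p) for i, p in enumerate(params)], free


def _unpack(family, x, free):
    return tuple(
        xi if i in free else math.exp(min(xi, 50.0)) for i, xi in enumerate(x)
    )


def fit_parametric(time, event, family: str) -> FittedModel:
    """Fit one parametric family to right-censored data by MLE.

    Maximizes sum(event*log f(t) + (1-event)*log S(t)).  Raises
    :class:`FittingError` on all-censored data; non-convergence is reported
    on the returned object rather than silently discarded.
    """
    time, event = _validate_ipd(time, event)
    if family not in FAMILIES:
        raise ConfigError(f"unknown survival family {family!r}")
    n_events = int(event.sum())
    if n_events < 1:
        raise FittingError("cannot fit a survival model to all-censored data")

    if family == "exponential":
        # closed-form MLE: rate = events / total exposure
        rate = n_events / float(time.sum())
        spec = ParametricSurvival("exponential", (rate,))
        return FittedModel(
            spec, loglik=-_neg_loglik(spec, time, event), n=time.size
        )

    x0, free = _pack(family, _initial_guess(family, time, event))

    def objective(x):
        try:
            spec = ParametricSurvival(family, _unpack(family, x, free))
        except (ConfigError, OverflowError):
            return np.inf
        return _neg_loglik(spec, time, event)

    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    params = _unpack(family, res.x, free)
    spec = ParametricSurvival(family, params)
    nll = _neg_loglik(spec, time, event)
    if not np.isfinite(nll):
        raise FittingError(f"{family} fit diverged: {res.message}")
    if not res.success:
        logger.warning("%s fit did not fully converge: %s", family, res.message)
    return FittedModel(
        spec,
        loglik=-nll,
        n=time.size,
        converged=bool(res.success),
        message=str(res.message),
    )


def select_best_model(fits) -> FittedModel:
    """Pick the fit with the lowest AIC; ties broken by lower BIC.

    When the AIC and BIC rankings disagree on the winner the disagreement is
    logged (AIC governs).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("select_best_model requires at least one fit")
    best_aic = min(fits, key=lambda f: (f.aic, f.bic))
    best_bic = min(fits, key=lambda f: (f.bic, f.aic))
    if best_bic.spec.family != best_aic.spec.family:
        logger.info(
            "AIC selects %s but BIC selects %s; AIC governs",
            best_aic.spec.family,
            best_bic.spec.family,
        )
    return best_aic


def fit_report(fits_by_label: dict) -> pd.DataFrame:
    """AIC/BIC table (family x endpoint/arm label), mirroring the usual
    supplementary layout of survival-model selection tables."""
    rows = []
    for label, fits in fits_by_label.items():
        for f in fits:
            rows.append(
                {
                    "label": label,
                    "family": f.spec.family,
                    "params": list(f.spec.params),
                    "loglik": f.loglik,
                    "aic": f.aic,
                    "bic": f.bic,
                    "n": f.n,
                    "converged": f.converged,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rate / probability conversions


def annual_prob_to_cycle_prob(annual_prob: float, cycle_days: int) -> float:
    """Convert an annual probability to a per-cycle probability through the
    constant-rate identity p_cycle = 1 - exp(-r * cycle_days/365) with
    r = -ln(1 - p_annual)."""
    if not 0.0 <= annual_prob < 1.0:
        raise ValueError("annual probability must be in [0, 1)")
    if cycle_days < 1:
        raise ValueError("cycle length must be >= 1 day")
    rate = -math.log1p(-annual_prob)
    return -math.expm1(-rate * cycle_days / DAYS_PER_YEAR)


def interval_transition_prob(
    spec: ParametricSurvival, t: float, delta: float
) -> float:
    """Probability of leaving the curve's state during (t, t+delta] given
    survival to t: 1 - S(t+delta)/S(t)."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    s_t = spec.sf(t)
    if s_t <= 0.0:
        warnings.warn(
            "S(t) = 0: interval transition probability set to 1 (absorbing tail)"
        )
        return 1.0
    p = 1.0 - spec.sf(t + delta) / s_t
    return float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# IPD CSV round trip


def read_ipd(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate_ipd(df["time"].to_numpy(), df["event"].to_numpy())
    return df[["time", "event"]]


def write_ipd(df: pd.DataFrame, path) -> None:
    _validate_ipd(df["time"].to_numpy(), df["event"].to_numpy())
    df[["time", "event"]].to_csv(path, index=False)
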