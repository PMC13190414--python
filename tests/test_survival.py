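"""Parametric survival curves, MLE fitting, model selection and
rate/probability conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from sactmt_cea import (
    ParametricSurvival,
    annual_prob_to_cycle_prob,
    fit_parametric,
    interval_transition_prob,
    select_best_model,
    survival_probability,
)
from sactmt_cea.survival import ConfigError, FittedModel, FittingError

SAMPLE_PARAMS = {
    "exponential": (0.1,),
    "weibull_ph": (1.599, 0.007),
    "gompertz": (0.08, 0.02),
    "loglogistic": (1.538, 27.354),
    "lognormal": (2.20, 0.999),
    "gamma": (1.5, 0.12),
    "gengamma": (2.0, 0.8, 0.5),
}


@pytest.mark.parametrize("family,params", SAMPLE_PARAMS.items())
def test_survival_function_shape(family, params):
    """S(0)=1, S non-increasing on [0, 600] months, bounded in [0,1], and
    decaying towards 0 in the far tail."""
    spec = ParametricSurvival(family, params)
    t = np.linspace(0.0, 600.0, 1201)
    s = np.asarray(spec.sf(t))
    assert s[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.diff(s) <= 1e-12)
    assert np.all((s >= 0.0) & (s <= 1.0))
    assert s[-1] < 0.05


@pytest.mark.parametrize(
    "family,params",
    [
        ("weibull_ph", (-1.0, 0.007)),
        ("weibull_ph", (1.6, 0.0)),
        ("lognormal", (2.2, 0.0)),
        ("loglogistic", (0.0, 27.0)),
        ("gengamma", (2.0, -0.1, 0.5)),
        ("gamma", (1.0, -2.0)),
    ],
)
def test_invalid_parameters_rejected(family, params):
    with pytest.raises(ConfigError):
        ParametricSurvival(family, params)


def test_unknown_family_rejected():
    with pytest.raises(ConfigError):
        ParametricSurvival("spline", (1.0,))


def test_negative_time_rejected():
    spec = ParametricSurvival("exponential", (0.1,))
    with pytest.raises(ValueError):
        spec.sf(-1.0)


def test_loglogistic_median_equals_scale():
    spec = ParametricSurvival("loglogistic", (1.538, 27.354))
    assert survival_probability(spec, 27.354) == pytest.approx(0.5, abs=1e-12)


def test_weibull_median_closed_form():
    """Median = (ln 2 / rate)^(1/shape), cross-checked against the numeric
    root of S(t) = 1/2."""
    spec = ParametricSurvival("weibull_ph", (1.599, 0.007))
    t_med = (math.log(2.0) / 0.007) ** (1.0 / 1.599)
    assert spec.sf(t_med) == pytest.approx(0.5, abs=1e-12)
    root = optimize.brentq(lambda t: spec.sf(t) - 0.5, 1.0, 100.0)
    assert root == pytest.approx(t_med, rel=1e-9)
    assert spec.median() == pytest.approx(t_med, rel=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    shape=st.floats(0.3, 4.0),
    scale=st.floats(0.5, 60.0),
    t=st.floats(0.0, 400.0),
    delta=st.floats(0.01, 24.0),
)
def test_interval_prob_is_probability(shape, scale, t, delta):
    spec = ParametricSurvival("loglogistic", (shape, scale))
    p = interval_transition_prob(spec, t, delta)
    assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# fitting


def test_exponential_mle_closed_form(rng):
    t = rng.exponential(scale=10.0, size=500)
    fit = fit_parametric(t, np.ones(500), "exponential")
    assert fit.spec.params[0] == pytest.approx(0.1, rel=0.10)
    # closed form: rate = events / total exposure
    assert fit.spec.params[0] == pytest.approx(500 / t.sum(), rel=1e-12)


def test_single_event_exponential_rate_one():
    fit = fit_parametric([1.0], [1.0], "exponential")
    assert fit.spec.params[0] == pytest.approx(1.0, abs=1e-12)


def test_all_censored_rejected():
    with pytest.raises(FittingError):
        fit_parametric([1.0, 2.0], [0.0, 0.0], "exponential")


def test_weibull_recovery_under_censoring(rng):
    """Data from Weibull-PH(1.6, 0.007) with ~20% uniform censoring at
    n=2000 recovers the shape within [1.4, 1.8]."""
    gen = ParametricSurvival("weibull_ph", (1.6, 0.007))
    t = np.asarray(gen.isf(rng.uniform(size=2000)))
    cens = rng.uniform(0, t.max(), size=2000)
    censored = (rng.uniform(size=2000) < 0.2) & (cens < t)
    obs = np.where(censored, cens, t)
    event = (~censored).astype(float)
    fit = fit_parametric(obs, event, "weibull_ph")
    assert 1.4 <= fit.spec.params[0] <= 1.8


def test_aic_bic_hand_computed():
    """Exponential fit on 5 points, 3 events: rate = 3/15 = 0.2,
    loglik = 3 ln 0.2 - 0.2*15, AIC = -2 ll + 2, BIC = -2 ll + ln 5."""
    fit = fit_parametric([1, 2, 3, 4, 5], [1, 1, 0, 1, 0], "exponential")
    ll = 3 * math.log(0.2) - 0.2 * 15
    assert fit.loglik == pytest.approx(ll, abs=1e-12)
    assert fit.aic == pytest.approx(-2 * ll + 2, abs=1e-12)
    assert fit.bic == pytest.approx(-2 * ll + math.log(5), abs=1e-12)


def test_loglik_matches_lifelines_oracle(rng):
    """Independent cross-check: our MLE agrees with lifelines' fitters on
    the families both implement."""
    lifelines = pytest.importorskip("lifelines")
    gen = ParametricSurvival("lognormal", (2.2, 0.999))
    t = np.asarray(gen.isf(rng.uniform(size=800)))
    cens = np.full(800, 30.0)
    event = (t <= cens).astype(float)
    obs = np.minimum(t, cens)

    ours = fit_parametric(obs, event, "lognormal")
    lf = lifelines.LogNormalFitter().fit(obs, event)
    assert ours.spec.params[0] == pytest.approx(lf.mu_, rel=1e-3)
    assert ours.spec.params[1] == pytest.approx(lf.sigma_, rel=1e-3)
    assert ours.aic == pytest.approx(lf.AIC_, rel=1e-6)

    ours_w = fit_parametric(obs, event, "weibull_ph")
    lfw = lifelines.WeibullFitter().fit(obs, event)
    # lifelines uses S = exp(-(t/lambda)^rho): rate = lambda^-rho
    assert ours_w.spec.params[0] == pytest.approx(lfw.rho_, rel=1e-3)
    assert ours_w.spec.params[1] == pytest.approx(
        lfw.lambda_ ** -lfw.rho_, rel=5e-3
    )

    ours_ll = fit_parametric(obs, event, "loglogistic")
    lfll = lifelines.LogLogisticFitter().fit(obs, event)
    assert ours_ll.spec.params[0] == pytest.approx(lfll.beta_, rel=1e-3)
    assert ours_ll.spec.params[1] == pytest.approx(lfll.alpha_, rel=1e-3)


# ---------------------------------------------------------------------------
# selection


def _dummy_fit(family, params, loglik, n=100):
    return FittedModel(ParametricSurvival(family, params), loglik=loglik, n=n)


def test_select_best_is_argmin_aic():
    fits = [
        _dummy_fit("exponential", (0.1,), -49.0),  # aic 100
        _dummy_fit("weibull_ph", (1.0, 0.1), -45.5),  # aic 95
        _dummy_fit("lognormal", (1.0, 1.0), -49.0),  # aic 102
    ]
    assert select_best_model(fits).spec.family == "weibull_ph"


def test_select_best_tie_broken_by_bic():
    # equal AIC; the 1-parameter exponential has the lower BIC
    fits = [
        _dummy_fit("lognormal", (1.0, 1.0), -48.0),  # aic 100, k=2
        _dummy_fit("exponential", (0.1,), -49.0),  # aic 100, k=1
    ]
    assert select_best_model(fits).spec.family == "exponential"


def test_select_best_empty_rejected():
    with pytest.raises(ValueError):
        select_best_model([])


def test_aic_selection_consistency(rng):
    """At n=5000 from a clearly non-exponential log-normal, AIC picks the
    log-normal over the exponential."""
    gen = ParametricSurvival("lognormal", (2.2, 0.5))
    t = np.asarray(gen.isf(rng.uniform(size=5000)))
    event = np.ones(5000)
    fits = [
        fit_parametric(t, event, "exponential"),
        fit_parametric(t, event, "lognormal"),
    ]
    assert select_best_model(fits).spec.family == "lognormal"


# ---------------------------------------------------------------------------
# conversions


def test_annual_to_cycle_probability_routes_agree():
    """Rate route and direct power route agree to 1e-12 for the national
    crude mortality 8.04 per mille over a 28-day cycle."""
    p = annual_prob_to_cycle_prob(0.00804, 28)
    power_route = 1.0 - (1.0 - 0.00804) ** (28.0 / 365.0)
    assert p == pytest.approx(power_route, abs=1e-12)
    assert p == pytest.approx(6.19e-4, abs=1e-5)


def test_annual_to_cycle_probability_edge_cases():
    assert annual_prob_to_cycle_prob(0.0, 28) == 0.0
    assert annual_prob_to_cycle_prob(0.3, 365) == pytest.approx(0.3, abs=1e-12)
    with pytest.raises(ValueError):
        annual_prob_to_cycle_prob(1.0, 28)
    with pytest.raises(ValueError):
        annual_prob_to_cycle_prob(-0.1, 28)


def test_interval_transition_memoryless():
    spec = ParametricSurvival("exponential", (0.2,))
    expected = 1.0 - math.exp(-0.2 * 0.92)
    for t in (0.0, 7.0, 123.4):
        assert interval_transition_prob(spec, t, 0.92) == pytest.approx(
            expected, abs=1e-12
        )


def test_interval_transition_chains_to_survival():
    """Chained cycle probabilities reproduce S(k*delta) as a product of
    complements, to 1e-10."""
    spec = ParametricSurvival("loglogistic", (1.538, 27.354))
    delta = 28.0 / (365.25 / 12.0)
    prod = 1.0
    for k in range(60):
        prod *= 1.0 - interval_transition_prob(spec, k * delta, delta)
    assert prod == pytest.approx(spec.sf(60 * delta), abs=1e-10)


def test_interval_transition_absorbing_tail():
    spec = ParametricSurvival("weibull_ph", (1.599, 0.007))
    with pytest.warns(UserWarning):
        assert interval_transition_prob(spec, 1e6, 1.0) == 1.0


def test_interval_transition_small_delta_vanishes():
    spec = ParametricSurvival("lognormal", (2.2, 0.999))
    assert interval_transition_prob(spec, 10.0, 1e-9) < 1e-6
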