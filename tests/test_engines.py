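"""Partitioned survival and Markov cohort engines: occupancy, conservation,
half-cycle accrual, and the equivalence/tracking properties connecting the
two engines."""

import math

import numpy as np
import pytest

from sactmt_cea import (
    CycleSchedule,
    ModelSettings,
    ParametricSurvival,
    accrue,
    build_transition_schedule,
    compute_occupancy_markov,
    compute_occupancy_psm,
    run_cohort_markov,
    trace_totals,
)

SETTINGS = ModelSettings()


def _unit_schedule(settings, u_pfs=1.0, u_pd=1.0):
    n = settings.n_cycles
    return CycleSchedule(np.zeros(n), np.zeros(n), u_pfs, u_pd)


def test_base_case_cycle_grid():
    assert SETTINGS.n_cycles == 130
    assert SETTINGS.cycle_months == pytest.approx(28.0 / (365.25 / 12.0))


def test_psm_starts_all_in_pfs(table1_curves):
    occ = compute_occupancy_psm(
        table1_curves[("sac_tmt", "pfs")], table1_curves[("sac_tmt", "os")], SETTINGS
    )
    assert (occ.pfs[0], occ.pd[0], occ.dead[0]) == (1.0, 0.0, 0.0)


def test_psm_identical_curves_no_pd():
    c = ParametricSurvival("exponential", (0.15,))
    occ = compute_occupancy_psm(c, c, SETTINGS)
    assert np.allclose(occ.pd, 0.0, atol=1e-12)


def test_psm_exponential_closed_form():
    pfs = ParametricSurvival("exponential", (0.2,))
    os_ = ParametricSurvival("exponential", (0.1,))
    occ = compute_occupancy_psm(pfs, os_, SETTINGS)
    t = occ.times_months
    assert np.allclose(occ.pfs, np.exp(-0.2 * t), atol=1e-12)
    assert np.allclose(occ.pd, np.exp(-0.1 * t) - np.exp(-0.2 * t), atol=1e-12)
    assert np.allclose(occ.dead, 1.0 - np.exp(-0.1 * t), atol=1e-12)


def test_psm_crossing_curves_capped(table1_curves):
    """The chemo arm's log-logistic PFS exceeds its Weibull OS in the far
    tail; the PFS share must be capped at OS."""
    occ = compute_occupancy_psm(
        table1_curves[("chemotherapy", "pfs")],
        table1_curves[("chemotherapy", "os")],
        SETTINGS,
    )
    assert np.all(occ.pfs <= 1.0 - occ.dead + 1e-12)
    assert np.all(occ.pd >= -1e-12)


def test_conservation_and_monotone_death(model, spec):
    for engine in ("psm", "markov"):
        for arm in spec.strategies:
            occ = model.occupancy(engine, arm)
            assert np.allclose(occ.pfs + occ.pd + occ.dead, 1.0, atol=1e-9)
            assert np.all(np.diff(occ.dead) >= -1e-9)


def test_qaly_conservation_nobody_dies():
    """No deaths, utility 1 everywhere, 0% discount: QALYs equal the
    horizon covered by the cycles (~10 years)."""
    settings = ModelSettings(discount_annual=0.0)
    near_immortal = ParametricSurvival("exponential", (1e-12,))
    occ = compute_occupancy_psm(near_immortal, near_immortal, settings)
    _, qalys, lys = trace_totals(accrue(occ, _unit_schedule(settings), settings))
    horizon = settings.n_cycles * settings.cycle_years
    assert qalys == pytest.approx(horizon, abs=1e-6)
    assert abs(qalys - 10.0) < 0.1  # cycle-grid rounding only
    assert lys == pytest.approx(qalys, abs=1e-9)


def test_qaly_linearity_in_utilities(table1_curves):
    occ = compute_occupancy_psm(
        table1_curves[("sac_tmt", "pfs")], table1_curves[("sac_tmt", "os")], SETTINGS
    )
    full = accrue(occ, _unit_schedule(SETTINGS, 0.8, 0.4), SETTINGS)
    half = accrue(occ, _unit_schedule(SETTINGS, 0.4, 0.2), SETTINGS)
    assert trace_totals(half)[1] == pytest.approx(trace_totals(full)[1] / 2, rel=1e-12)


def test_cycle_halving_stability(table1_curves):
    """Halving the cycle length moves total QALYs by < 0.5%."""
    pfs, os_ = table1_curves[("sac_tmt", "pfs")], table1_curves[("sac_tmt", "os")]
    totals = {}
    for cd in (28.0, 14.0):
        settings = ModelSettings(cycle_days=cd)
        occ = compute_occupancy_psm(pfs, os_, settings)
        totals[cd] = trace_totals(
            accrue(occ, _unit_schedule(settings, 0.804, 0.321), settings)
        )[1]
    assert abs(totals[14.0] / totals[28.0] - 1.0) < 0.005


def test_undiscounted_lys_match_os_area(table1_curves):
    """With no discounting, life-years equal the trapezoidal area under
    S_OS within 1%."""
    settings = ModelSettings(discount_annual=0.0)
    pfs, os_ = table1_curves[("chemotherapy", "pfs")], table1_curves[("chemotherapy", "os")]
    occ = compute_occupancy_psm(pfs, os_, settings)
    lys = trace_totals(accrue(occ, _unit_schedule(settings), settings))[2]
    t = np.linspace(0, settings.n_cycles * settings.cycle_months, 5000)
    area_years = np.trapezoid(np.asarray(os_.sf(t)), t) / 12.0
    assert lys == pytest.approx(area_years, rel=0.01)


# ---------------------------------------------------------------------------
# Markov engine


def test_transition_rows_are_probability_rows(model, spec):
    for arm in spec.strategies:
        curves = spec.strategies[arm].curves
        sched = build_transition_schedule(
            curves.pfs.to_spec(), curves.os.to_spec(), model.p_bg_cycle, SETTINGS
        )
        pfs_out = sched[["p_pfs_to_pfs", "p_pfs_to_pd", "p_pfs_to_dead"]].sum(axis=1)
        pd_out = sched[["p_pd_to_pd", "p_pd_to_dead"]].sum(axis=1)
        assert np.allclose(pfs_out, 1.0, atol=1e-12)
        assert np.allclose(pd_out, 1.0, atol=1e-12)
        assert (sched.drop(columns="cycle") >= -1e-15).all().all()
        assert (sched.drop(columns="cycle") <= 1.0 + 1e-15).all().all()


def test_identity_schedule_freezes_cohort():
    import pandas as pd

    n = SETTINGS.n_cycles
    sched = pd.DataFrame(
        {
            "cycle": np.arange(n),
            "p_pfs_to_pfs": 1.0,
            "p_pfs_to_pd": 0.0,
            "p_pfs_to_dead": 0.0,
            "p_pd_to_pd": 1.0,
            "p_pd_to_dead": 0.0,
        }
    )
    occ = run_cohort_markov(sched, SETTINGS)
    assert np.all(occ.pfs == 1.0)
    settings0 = ModelSettings(discount_annual=0.0)
    qalys = trace_totals(accrue(occ, _unit_schedule(settings0, 0.7, 0.0), settings0))[1]
    assert qalys == pytest.approx(0.7 * SETTINGS.n_cycles * SETTINGS.cycle_years, rel=1e-12)


def test_markov_death_tracks_os_curve(model, spec):
    """The PD->death closure reproduces 1 - S_OS within 0.005 from the
    second cycle boundary on.  At the first boundary PD is still empty and
    PFS->death is capped at background mortality, so the realizable deaths
    are exactly p_bg: the deficit equals the OS curve's first-cycle deaths
    minus background mortality (structural, asserted exactly)."""
    for arm in spec.strategies:
        occ = model.occupancy("markov", arm)
        s_os = np.asarray(spec.strategies[arm].curves.os.to_spec().sf(occ.times_months))
        drift = np.abs(occ.dead - (1.0 - s_os))
        assert drift[2:].max() <= 0.005
        structural = (1.0 - s_os[1]) - model.p_bg_cycle
        assert drift[1] == pytest.approx(structural, abs=1e-12)


def test_markov_matches_psm_on_exponential_curves():
    """With exponential curves the OS closure reproduces the partitioned
    survival occupancy to 1e-6 per cycle from the second boundary on (the
    first boundary carries the structural empty-PD deficit, repaid in the
    next cycle)."""
    pfs = ParametricSurvival("exponential", (0.2,))
    os_ = ParametricSurvival("exponential", (0.1,))
    occ_m = compute_occupancy_markov(pfs, os_, 0.0, SETTINGS)
    occ_p = compute_occupancy_psm(pfs, os_, SETTINGS)
    for a, b in ((occ_m.pfs, occ_p.pfs), (occ_m.pd, occ_p.pd), (occ_m.dead, occ_p.dead)):
        assert np.max(np.abs(a[2:] - b[2:])) <= 1e-6
    # first boundary: deaths can only come from background mortality (= 0)
    assert occ_m.dead[1] == 0.0
    assert occ_p.dead[1] == pytest.approx(1.0 - math.exp(-0.1 * SETTINGS.cycle_months))


def test_markov_psm_qaly_gap_small(base_results):
    """Base-case QALY difference between the engines stays below 0.1."""
    for arm in ("sac_tmt", "chemotherapy"):
        gap = abs(
            base_results["markov"][arm].total_qalys
            - base_results["psm"][arm].total_qalys
        )
        assert gap < 0.1


def test_chemo_cohort_nearly_extinct_at_horizon(model):
    """The 10-year horizon captures >99% of chemo-arm mortality (and the
    sac-TMT arm's terminal share is reported via its occupancy)."""
    occ = model.occupancy("psm", "chemotherapy")
    assert occ.dead[-1] > 0.99
    occ_sac = model.occupancy("psm", "sac_tmt")
    assert 0.0 < occ_sac.dead[-1] <= 1.0


def test_schedule_must_cover_horizon():
    import pandas as pd

    short = pd.DataFrame(
        {
            "cycle": [0],
            "p_pfs_to_pfs": [1.0],
            "p_pfs_to_pd": [0.0],
            "p_pfs_to_dead": [0.0],
            "p_pd_to_pd": [1.0],
            "p_pd_to_dead": [0.0],
        }
    )
    with pytest.raises(ValueError):
        run_cohort_markov(short, SETTINGS)
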