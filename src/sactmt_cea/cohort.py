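"""Shared cohort-model machinery: cycle grid, state occupancy, discounting
and half-cycle-corrected accrual of costs, QALYs and life-years.

Both engines (partitioned survival and Markov) produce the same
:class:`Occupancy` object — per-cycle-boundary shares of the three health
states PFS / progressed disease (PD) / death — which is then combined with
an economic :class:`CycleSchedule` into a :class:`CohortTrace`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import DAYS_PER_MONTH

_CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class ModelSettings:
    """Time/discount conventions shared by both engines."""

    cycle_days: float = 28.0
    horizon_years: float = 10.0
    discount_annual: float = 0.05
    half_cycle_correction: bool = True

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25

    @property
    def n_cycles(self) -> int:
        """Number of full cycles fitting inside the horizon (130 for the
        28-day cycle / 10-year base case)."""
        return int(math.floor(self.horizon_years * 365.25 / self.cycle_days))

    def boundary_times_months(self) -> np.ndarray:
        return np.arange(self.n_cycles + 1) * self.cycle_months

    def discount_factors(self) -> np.ndarray:
        years = np.arange(self.n_cycles + 1) * self.cycle_years
        return (1.0 + self.discount_annual) ** (-years)


@dataclass
class Occupancy:
    """State shares at each cycle boundary (arrays of length n_cycles+1)."""

    times_months: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray

    def __post_init__(self):
        total = self.pfs + self.pd + self.dead
        if np.max(np.abs(total - 1.0)) > _CONSERVATION_TOL:
            raise AssertionError("state shares must sum to 1 at every cycle")
        for arr in (self.pfs, self.pd, self.dead):
            if np.any(arr < -_CONSERVATION_TOL) or np.any(arr > 1 + _CONSERVATION_TOL):
                raise AssertionError("state shares must lie in [0, 1]")
        if np.any(np.diff(self.dead) < -_CONSERVATION_TOL):
            raise AssertionError("death share must be non-decreasing")

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.dead


@dataclass
class CycleSchedule:
    """Per-cycle economic inputs for one strategy.

    Costs are per model cycle while occupying the state; the entry terms are
    one-off expectations applied at model start (grade >=3 adverse events).
    """

    cost_pfs: np.ndarray  # length n_cycles
    cost_pd: np.ndarray
    u_pfs: float
    u_pd: float
    entry_cost: float = 0.0
    entry_qaly_loss: float = 0.0


@dataclass
class CohortTrace:
    """Occupancy plus discounted per-cycle accruals for one strategy."""

    settings: ModelSettings
    occupancy: Occupancy
    disc_cost: np.ndarray
    disc_qaly: np.ndarray
    disc_ly: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        occ = self.occupancy
        n = self.settings.n_cycles
        return pd.DataFrame(
            {
                "cycle": np.arange(n),
                "time_months": occ.times_months[:-1],
                "share_pfs": occ.pfs[:-1],
                "share_pd": occ.pd[:-1],
                "share_dead": occ.dead[:-1],
                "disc_cost": self.disc_cost,
                "disc_qaly": self.disc_qaly,
                "disc_ly": self.disc_ly,
            }
        )


def _cycle_average(values: np.ndarray, settings: ModelSettings) -> np.ndarray:
    """Trapezoidal (half-cycle-corrected) per-cycle average of a quantity
    known at cycle boundaries; start-of-cycle accrual when the correction is
    disabled."""
    if settings.half_cycle_correction:
        return 0.5 * (values[:-1] + values[1:])
    return values[:-1]


def accrue(occ: Occupancy, sched: CycleSchedule, settings: ModelSettings) -> CohortTrace:
    """Attach discounted per-cycle cost/QALY/LY accruals to an occupancy.

    State costs and utilities are weighted by discounted state membership
    with half-cycle correction; the one-off entry cost and entry QALY
    decrement land undiscounted in cycle 0.
    """
    d = settings.discount_factors()
    pfs_d, pd_d, alive_d = occ.pfs * d, occ.pd * d, occ.alive * d

    cost = sched.cost_pfs * _cycle_average(pfs_d, settings) + sched.cost_pd * _cycle_average(pd_d, settings)
    util = sched.u_pfs * pfs_d + sched.u_pd * pd_d
    qaly = _cycle_average(util, settings) * settings.cycle_years
    ly = _cycle_average(alive_d, settings) * settings.cycle_years

    cost = cost.astype(float).copy()
    qaly = qaly.astype(float).copy()
    cost[0] += sched.entry_cost
    qaly[0] -= sched.entry_qaly_loss
    return CohortTrace(settings, occ, cost, qaly, ly)


def trace_totals(trace: CohortTrace) -> tuple[float, float, float]:
    """(total discounted cost, total QALYs, total life-years)."""
    return (
        float(trace.disc_cost.sum()),
        float(trace.disc_qaly.sum()),
        float(trace.disc_ly.sum()),
    )
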