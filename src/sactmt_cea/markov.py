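"""Markov cohort engine with time-dependent transition probabilities derived
from the fitted PFS/OS curves.

Construction of the per-cycle transition rows:

* PFS exit probability comes from the PFS curve's interval probability
  ``1 - S_PFS(t+d)/S_PFS(t)``.
* PFS -> death is the background (natural) mortality per cycle, floored at
  the total exit probability so PFS -> PD is never negative.
* PD -> death closes the OS curve: the deaths still owed by the OS curve at
  the end of the cycle (cumulative target 1 - S_OS(t+d), net of deaths
  already realized and of background deaths out of PFS this cycle) are
  assigned to PD, as a probability against the running cohort's PD
  occupancy (clamped to [0, 1]; zero when PD is empty).  Targeting the
  cumulative rather than the per-cycle death increment repays the entry
  transient: at model start PD is empty, so the first cycle's OS deaths
  can only be realized up to background mortality, and the deficit is
  recovered as soon as PD has mass.

Death is absorbing.  The resulting cohort death share tracks 1 - S_OS up
to clamping and the entry transient, both measurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ModelSettings, Occupancy
from .survival import ParametricSurvival

logger = logging.getLogger(__name__)

_COLUMNS = [
    "cycle",
    "p_pfs_to_pfs",
    "p_pfs_to_pd",
    "p_pfs_to_dead",
    "p_pd_to_pd",
    "p_pd_to_dead",
]


def build_transition_schedule(
    pfs: ParametricSurvival,
    os: ParametricSurvival,
    p_bg_cycle: float,
    settings: ModelSettings,
) -> pd.DataFrame:
    """Per-cycle transition rows (one per model cycle), computed alongside
    the cohort recursion so the PD -> death closure sees actual occupancy."""
    if not 0.0 <= p_bg_cycle < 1.0:
        raise ValueError("background cycle mortality must be in [0, 1)")
    t = settings.boundary_times_months()
    # same curve-crossing guard as the partitioned survival engine: the
    # progression-free share can never exceed overall survival
    s_pfs = np.minimum(np.asarray(pfs.sf(t), dtype=float), np.asarray(os.sf(t), dtype=float))
    s_os = np.asarray(os.sf(t), dtype=float)
    n = settings.n_cycles

    rows = np.zeros((n, 5))
    occ_pfs, occ_pd, occ_dead = 1.0, 0.0, 0.0
    n_clamped = 0
    for k in range(n):
        if s_pfs[k] > 0.0:
            p_exit = 1.0 - s_pfs[k + 1] / s_pfs[k]
        else:
            p_exit = 1.0  # absorbing handoff out of an empty PFS curve
        p_exit = min(max(p_exit, 0.0), 1.0)
        p_fd = min(p_bg_cycle, p_exit)
        p_fp = p_exit - p_fd
        deaths_owed = (1.0 - s_os[k + 1]) - occ_dead  # cumulative OS target
        if occ_pd > 0.0:
            q = (deaths_owed - occ_pfs * p_fd) / occ_pd
            if q < 0.0 or q > 1.0:
                n_clamped += 1
            q = min(max(q, 0.0), 1.0)
        else:
            q = 0.0
        rows[k] = (p_exit, p_fp, p_fd, 1.0 - q, q)
        occ_pfs, occ_pd, occ_dead = (
            occ_pfs * (1.0 - p_exit),
            occ_pd * (1.0 - q) + occ_pfs * p_fp,
            occ_dead + occ_pd * q + occ_pfs * p_fd,
        )
    if n_clamped:
        logger.info("PD->death probability clamped in %d cycles", n_clamped)
    df = pd.DataFrame(
        {
            "cycle": np.arange(n),
            "p_pfs_to_pfs": 1.0 - rows[:, 0],
            "p_pfs_to_pd": rows[:, 1],
            "p_pfs_to_dead": rows[:, 2],
            "p_pd_to_pd": rows[:, 3],
            "p_pd_to_dead": rows[:, 4],
        }
    )
    return df


def run_cohort_markov(schedule: pd.DataFrame, settings: ModelSettings) -> Occupancy:
    """Standard cohort recursion from (1, 0, 0) under a transition schedule."""
    n = settings.n_cycles
    if len(schedule) < n:
        raise ValueError("transition schedule does not cover the horizon")
    pfs = np.zeros(n + 1)
    pd_ = np.zeros(n + 1)
    dead = np.zeros(n + 1)
    pfs[0] = 1.0
    p_stay = schedule["p_pfs_to_pfs"].to_numpy()
    p_fp = schedule["p_pfs_to_pd"].to_numpy()
    p_fd = schedule["p_pfs_to_dead"].to_numpy()
    p_pp = schedule["p_pd_to_pd"].to_numpy()
    p_pd_d = schedule["p_pd_to_dead"].to_numpy()
    for k in range(n):
        pfs[k + 1] = pfs[k] * p_stay[k]
        pd_[k + 1] = pd_[k] * p_pp[k] + pfs[k] * p_fp[k]
        dead[k + 1] = dead[k] + pd_[k] * p_pd_d[k] + pfs[k] * p_fd[k]
    return Occupancy(settings.boundary_times_months(), pfs, pd_, dead)


def compute_occupancy_markov(
    pfs: ParametricSurvival,
    os: ParametricSurvival,
    p_bg_cycle: float,
    settings: ModelSettings,
) -> Occupancy:
    """Convenience: build the schedule and run the cohort through it."""
    schedule = build_transition_schedule(pfs, os, p_bg_cycle, settings)
    return run_cohort_markov(schedule, settings)
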