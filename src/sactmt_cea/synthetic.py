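"""Synthetic trial-data generation.

No individual patient data from the underlying trial are deposited, so the
pipeline's inputs — right-censored PFS/OS records, published-style step
curves and numbers-at-risk tables — are emulated here.  Defaults mirror the
base case's four fitted curves and the trial's 1:1 randomization of 376
patients (188 per arm), without claiming to reproduce trial data.

PFS and OS times are comonotone (one shared uniform rank per subject), which
guarantees PFS <= OS for every subject whenever the PFS curve lies below the
OS curve, as the partitioned-survival structure assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .km import DigitizedCurve, RiskTable, km_estimate
from .survival import ParametricSurvival


@dataclass(frozen=True)
class SimSpec:
    """Generating model for one simulated arm."""

    pfs: ParametricSurvival
    os: ParametricSurvival
    n: int = 188
    admin_censor_months: float = 24.0
    dropout_prob: float = 0.05  # probability of random early dropout
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 subjects")
        if self.admin_censor_months <= 0:
            raise ValueError("administrative cutoff must be > 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout probability must be in [0, 1]")


DEFAULT_ARMS = {
    "sac_tmt": {
        "pfs": ParametricSurvival("lognormal", (2.20, 0.999)),
        "os": ParametricSurvival("loglogistic", (1.538, 27.354)),
    },
    "chemotherapy": {
        "pfs": ParametricSurvival("loglogistic", (2.420, 4.590)),
        "os": ParametricSurvival("weibull_ph", (1.599, 0.007)),
    },
}


def simulate_ipd(spec: SimSpec) -> dict[str, pd.DataFrame]:
    """Simulate one arm's PFS and OS records.

    Event times come from the generating curves by inverse survival at a
    shared rank; censoring is min(administrative cutoff, random dropout
    uniform on (0, cutoff) with probability ``dropout_prob``), applied to
    both endpoints consistently.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    t_os = np.asarray(spec.os.isf(u), dtype=float)
    t_pfs = np.minimum(np.asarray(spec.pfs.isf(u), dtype=float), t_os)

    cens = np.full(spec.n, spec.admin_censor_months)
    drop = rng.uniform(size=spec.n) < spec.dropout_prob
    cens[drop] = rng.uniform(0.0, spec.admin_censor_months, size=int(drop.sum()))

    out = {}
    for endpoint, t in (("pfs", t_pfs), ("os", t_os)):
        event = (t <= cens).astype(float)
        time = np.minimum(t, cens)
        out[endpoint] = pd.DataFrame({"time": time, "event": event})
    return out


def simulate_trial(
    arms: dict | None = None,
    n_per_arm: int = 188,
    admin_censor_months: float = 24.0,
    dropout_prob: float = 0.05,
    seed: int = 0,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Simulate all arms/endpoints; keys are (arm, endpoint)."""
    arms = arms or DEFAULT_ARMS
    out = {}
    for i, (arm, curves) in enumerate(arms.items()):
        spec = SimSpec(
            curves["pfs"],
            curves["os"],
            n=n_per_arm,
            admin_censor_months=admin_censor_months,
            dropout_prob=dropout_prob,
            seed=seed + i,
        )
        records = simulate_ipd(spec)
        for endpoint, df in records.items():
            out[(arm, endpoint)] = df
    return out


def make_digitized_fixture(
    data: pd.DataFrame,
    grid_step_months: float = 0.5,
    risk_times=None,
    jitter: float = 0.0,
    seed: int = 0,
    arm: str = "",
    endpoint: str = "",
) -> tuple[DigitizedCurve, RiskTable]:
    """Emulate manual digitization of a published KM plot.

    The true KM step function is sampled on a regular grid (plus t=0), an
    optional bounded uniform jitter is added and clamped back to a
    non-increasing step, and the numbers-at-risk table is counted exactly
    from the data.
    """
    if len(data) == 0:
        raise ValueError("no records to digitize")
    time = data["time"].to_numpy(dtype=float)
    event = data["event"].to_numpy(dtype=float)
    km = km_estimate(time, event, arm, endpoint)

    t_max = float(time.max())
    if grid_step_months <= 0:
        grid = km.times
    else:
        grid = np.unique(
            np.concatenate(
                [[0.0], np.arange(grid_step_months, t_max + grid_step_months, grid_step_months)]
            )
        )
    surv = km.at(grid)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noisy = surv + rng.uniform(-jitter, jitter, size=surv.size)
        noisy[0] = 1.0
        surv = np.minimum.accumulate(np.clip(noisy, 0.0, 1.0))
    curve = DigitizedCurve(grid, surv, arm, endpoint)

    if risk_times is None:
        step = max(math.ceil(t_max / 4.0), 1)
        risk_times = np.arange(0.0, t_max + step, step)
    risk_times = np.asarray(risk_times, dtype=float)
    n_risk = np.array([(time >= t).sum() for t in risk_times], dtype=int)
    keep = n_risk >= 0
    return curve, RiskTable(risk_times[keep], n_risk[keep])
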