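"""Kaplan-Meier estimation and pseudo-IPD reconstruction from digitized
survival curves plus numbers-at-risk (Guyot-style inversion of the
product-limit construction)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ReconstructionInputError(ValueError):
    """Inconsistent digitized curve / risk table inputs."""


@dataclass
class DigitizedCurve:
    """An ordered (time, survival) step function starting at (0, 1)."""

    times: np.ndarray
    surv: np.ndarray
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        if self.times.size != self.surv.size or self.times.size == 0:
            raise ReconstructionInputError("times and surv must match and be non-empty")
        if self.times[0] != 0.0 or not np.isclose(self.surv[0], 1.0):
            raise ReconstructionInputError("curve must start at (0, 1)")
        if np.any(np.diff(self.times) <= 0):
            raise ReconstructionInputError("curve times must be strictly increasing")
        if np.any(self.surv < -1e-9) or np.any(self.surv > 1.0 + 1e-9):
            raise ReconstructionInputError("survival values must lie in [0, 1]")
        self.surv = np.clip(self.surv, 0.0, 1.0)

    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.surv) <= 1e-12))

    def clamped_monotone(self) -> "DigitizedCurve":
        """Running-minimum pass removing digitization jitter; logged when it
        actually changes anything."""
        clamped = np.minimum.accumulate(self.surv)
        if not np.allclose(clamped, self.surv):
            logger.info(
                "digitized survival clamped to non-increasing at %d points",
                int(np.sum(clamped != self.surv)),
            )
        return DigitizedCurve(self.times.copy(), clamped, self.arm, self.endpoint)

    def at(self, t) -> np.ndarray:
        """Step-function value at arbitrary times (right-continuous)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.surv[np.clip(idx, 0, self.surv.size - 1)]


@dataclass
class RiskTable:
    """Numbers at risk at selected times; first entry is the cohort size."""

    times: np.ndarray
    n_risk: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=int)
        if self.times.size != self.n_risk.size or self.times.size < 2:
            raise ReconstructionInputError("risk table needs >= 2 matching rows")
        if np.any(np.diff(self.times) <= 0):
            raise ReconstructionInputError("risk-table times must be strictly increasing")
        if np.any(self.n_risk < 0):
            raise ReconstructionInputError("numbers at risk must be non-negative")
        bad = np.where(np.diff(self.n_risk) > 0)[0]
        if bad.size:
            raise ReconstructionInputError(
                f"numbers at risk increase at rows {list(bad + 1)}"
            )


def km_estimate(time, event, arm: str = "", endpoint: str = "") -> DigitizedCurve:
    """Product-limit estimator as a right-continuous step function.

    Returns the curve evaluated at 0 and at every distinct event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.size == 0:
        raise ValueError("km_estimate requires at least one record")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    s = 1.0
    ts, ss = [0.0], [1.0]
    n_at_risk = time.size
    i = 0
    while i < time.size:
        t = time[i]
        d = 0
        c = 0
        while i < time.size and time[i] == t:
            if event[i] == 1:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / n_at_risk
            ts.append(t)
            ss.append(s)
        n_at_risk -= d + c
    return DigitizedCurve(np.array(ts), np.array(ss), arm, endpoint)


def _interval_records(t_steps, s_steps, s_enter, n_enter, n_target, t_end):
    """Reconstruct one risk-table interval for a candidate censoring count.

    Searches over the number censored in the interval so that the at-risk
    count carried to the interval end best matches the published value, with
    censoring times spread evenly and events placed at the digitized drops.
    Returns (event_times, censor_times, n_exit, s_exit).
    """
    t_start = t_steps[0] if len(t_steps) else t_end
    best = None
    max_cens = n_enter
    for n_cens in range(max_cens + 1):
        if n_cens:
            cens_times = t_start + (np.arange(n_cens) + 0.5) * (
                (t_end - t_start) / n_cens
            )
        else:
            cens_times = np.empty(0)
        n = n_enter
        s_model = s_enter
        ev_times = []
        ct_used = []
        ci = 0
        for tj, sj in zip(t_steps, s_steps):
            while ci < n_cens and cens_times[ci] < tj and n > 0:
                ct_used.append(cens_times[ci])
                n -= 1
                ci += 1
            if n <= 0:
                break
            d = int(round(n * (1.0 - sj / s_model))) if s_model > 0 else 0
            d = min(max(d, 0), n)
            if d > 0:
                s_model *= 1.0 - d / n
                ev_times.extend([tj] * d)
                n -= d
        while ci < n_cens and n > 0:
            ct_used.append(cens_times[ci])
            n -= 1
            ci += 1
        err = abs(n - n_target)
        key = (err, n_cens)
        if best is None or key < best[0]:
            best = (key, ev_times, ct_used, n, s_model)
        if err == 0:
            break
    _, ev_times, ct_used, n_exit, s_exit = best
    return ev_times, ct_used, n_exit, s_exit


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk: RiskTable,
    total_events: int | None = None,
) -> pd.DataFrame:
    """Reconstruct pseudo individual patient data from a digitized KM curve
    and its numbers-at-risk table.

    Within each risk-table interval the number censored is chosen so the
    implied at-risk count at the interval end matches the published one,
    and event counts at each digitized drop follow the product-limit
    relation d_j = n_j * (1 - S_j / S_prev).  The returned record count
    equals the initial number at risk exactly.  With ``total_events`` the
    reconstructed event count is rescaled by flipping the latest events to
    censorings (or vice versa).
    """
    curve = curve.clamped_monotone()
    n0 = int(risk.n_risk[0])
    events: list[float] = []
    censors: list[float] = []
    n_cur = n0
    s_cur = 1.0
    bounds = list(risk.times) + [max(curve.times[-1], risk.times[-1])]
    for i in range(len(risk.times)):
        lo, hi = bounds[i], bounds[i + 1]
        last = i == len(risk.times) - 1
        mask = (curve.times > lo) & (
            (curve.times <= hi) if not last else np.ones_like(curve.times, bool)
        )
        t_steps = curve.times[mask]
        s_steps = curve.surv[mask]
        n_target = int(risk.n_risk[i + 1]) if not last else 0
        if last:
            # final interval: censorings only after the last drop
            n = n_cur
            s_model = s_cur
            for tj, sj in zip(t_steps, s_steps):
                if n <= 0:
                    break
                d = int(round(n * (1.0 - sj / s_model))) if s_model > 0 else 0
                d = min(max(d, 0), n)
                if d > 0:
                    s_model *= 1.0 - d / n
                    events.extend([tj] * d)
                    n -= d
            censors.extend([hi] * n)  # administratively censored at curve end
            n_cur, s_cur = 0, s_model
        else:
            ev, ce, n_cur, s_cur = _interval_records(
                t_steps, s_steps, s_cur, n_cur, n_target, hi
            )
            events.extend(ev)
            censors.extend(ce)

    df = pd.DataFrame(
        {
            "time": np.concatenate([np.asarray(events), np.asarray(censors)])
            if events or censors
            else np.empty(0),
            "event": np.concatenate(
                [np.ones(len(events)), np.zeros(len(censors))]
            )
            if events or censors
            else np.empty(0),
        }
    ).sort_values(["time", "event"], ignore_index=True)

    if total_events is not None and len(df):
        diff = int(total_events) - int(df["event"].sum())
        if diff < 0:  # too many events: censor the latest ones
            idx = df.index[df["event"] == 1][diff:]
            df.loc[idx, "event"] = 0
        elif diff > 0:  # too few: convert the latest censorings
            idx = df.index[df["event"] == 0][-diff:]
            df.loc[idx, "event"] = 1
    if len(df) != n0:
        raise AssertionError("reconstruction lost records")  # pragma: no cover
    return df
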