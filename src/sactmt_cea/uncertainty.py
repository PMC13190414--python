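"""Sensitivity analysis: one-way (tornado), probabilistic (second-order
Monte Carlo), and the cost-effectiveness acceptability curve.

PSA distribution assignment follows standard practice: Gamma for costs and
Beta for utilities, disutilities (on the absolute value) and probabilities,
each moment-matched to (mean = base value, sd = (high - low)/3.92), i.e.
the deterministic ranges read as 95% intervals.  Survival-curve parameters
are model structure and are held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import KIND_PSA, CEModel, ParamRange

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# one-way sensitivity analysis


def owsa(model: CEModel, engine: str, ranges=None) -> pd.DataFrame:
    """Tornado table: the ICER when each parameter is set to its low/high
    bound with everything else at base, sorted by spread (descending).

    Variations that produce a non-positive QALY gain are flagged in the
    ``status`` columns rather than dropped.
    """
    ranges = list(ranges) if ranges is not None else model.registry
    base_cmp = model.evaluate(engines=(engine,))[engine]
    rows = []
    for p in ranges:
        entry = {"parameter": p.name, "base": p.base, "low": p.low, "high": p.high}
        for bound, value in (("low", p.low), ("high", p.high)):
            cmp_ = model.evaluate({p.name: value}, engines=(engine,))[engine]
            entry[f"icer_at_{bound}"] = cmp_.icer
            entry[f"status_{bound}"] = cmp_.status
        lo, hi = entry["icer_at_low"], entry["icer_at_high"]
        entry["spread"] = (
            abs(hi - lo) if lo is not None and hi is not None else np.nan
        )
        rows.append(entry)
    df = pd.DataFrame(rows).sort_values("spread", ascending=False, ignore_index=True)
    df.attrs["base_icer"] = base_cmp.icer
    return df


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class _Draw:
    name: str
    dist: str  # gamma | beta | beta_neg | uniform | degenerate
    a: float = 0.0
    b: float = 0.0


def _moment_matched(p: ParamRange) -> _Draw:
    sd = (p.high - p.low) / 3.92
    dist = KIND_PSA[p.kind]
    if dist is None or sd <= 0:
        return _Draw(p.name, "degenerate", p.base)
    if dist == "gamma":
        mean = p.base
        if mean <= 0:
            logger.warning("gamma infeasible for %s (base <= 0); uniform fallback", p.name)
            return _Draw(p.name, "uniform", p.low, p.high)
        shape = (mean / sd) ** 2
        scale = sd * sd / mean
        return _Draw(p.name, "gamma", shape, scale)
    # beta on the mean (absolute value for disutilities)
    mean = abs(p.base)
    neg = p.kind == "disutility"
    if not 0.0 < mean < 1.0 or sd * sd >= mean * (1.0 - mean):
        logger.warning("beta moments infeasible for %s; uniform fallback", p.name)
        lo, hi = (abs(p.high), abs(p.low)) if neg else (p.low, p.high)
        return _Draw(p.name, "uniform_neg" if neg else "uniform", min(lo, hi), max(lo, hi))
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return _Draw(p.name, "beta_neg" if neg else "beta", mean * nu, (1.0 - mean) * nu)


def draw_psa_samples(
    model: CEModel, n_iterations: int, seed: int, overrides: dict | None = None
) -> pd.DataFrame:
    """Parameter draws only (one row per iteration, one column per varied
    parameter).  A single seeded generator draws parameters in registry
    order, so any iteration is reproducible from (seed, registry).

    ``overrides`` shift a parameter's base; its range is rescaled
    proportionally so relative uncertainty is preserved.
    """
    rng = np.random.default_rng(seed)
    params = model.resolve_params(overrides)
    cols = {}
    for p in model.registry:
        if KIND_PSA[p.kind] is None:
            continue
        base = params[p.name]
        if overrides and p.name in overrides and p.base != 0:
            ratio = base / p.base
            p = ParamRange(p.name, base, p.low * ratio, p.high * ratio, p.kind)
        d = _moment_matched(p)
        if d.dist == "degenerate":
            cols[p.name] = np.full(n_iterations, d.a)
        elif d.dist == "gamma":
            cols[p.name] = rng.gamma(d.a, d.b, size=n_iterations)
        elif d.dist == "beta":
            cols[p.name] = rng.beta(d.a, d.b, size=n_iterations)
        elif d.dist == "beta_neg":
            cols[p.name] = -rng.beta(d.a, d.b, size=n_iterations)
        elif d.dist == "uniform":
            cols[p.name] = rng.uniform(d.a, d.b, size=n_iterations)
        else:  # uniform_neg
            cols[p.name] = -rng.uniform(d.a, d.b, size=n_iterations)
    df = pd.DataFrame(cols)
    df.insert(0, "iteration", np.arange(n_iterations))
    return df


def run_psa(
    model: CEModel,
    n_iterations: int | None = None,
    seed: int | None = None,
    overrides: dict | None = None,
    engines=None,
) -> pd.DataFrame:
    """Second-order Monte Carlo: per iteration, draw one parameter set and
    re-evaluate both engines from common draws.  Returns the draws plus
    ``delta_cost_<engine>`` / ``delta_qaly_<engine>`` columns."""
    n_iterations = n_iterations or model.spec.psa.iterations
    seed = model.spec.psa.seed if seed is None else seed
    engines = engines or model._engines()
    draws = draw_psa_samples(model, n_iterations, seed, overrides)
    drawn_names = [c for c in draws.columns if c != "iteration"]
    fixed = model.resolve_params(overrides)

    out = {f"delta_{q}_{e}": np.empty(n_iterations) for e in engines for q in ("cost", "qaly")}
    for i in range(n_iterations):
        it_params = dict(fixed)
        for name in drawn_names:
            it_params[name] = float(draws.at[i, name])
        for engine in engines:
            a = model.strategy_result(engine, model.spec.intervention, it_params)
            b = model.strategy_result(engine, model.spec.comparator, it_params)
            out[f"delta_cost_{engine}"][i] = a.total_cost - b.total_cost
            out[f"delta_qaly_{engine}"][i] = a.total_qalys - b.total_qalys
    for k, v in out.items():
        draws[k] = v
    return draws


def probability_cost_effective(
    samples: pd.DataFrame, wtp: float, engine: str
) -> float:
    """Fraction of PSA draws with positive incremental net monetary benefit
    at the given willingness-to-pay threshold."""
    nmb = wtp * samples[f"delta_qaly_{engine}"] - samples[f"delta_cost_{engine}"]
    return float((nmb > 0).mean())


def ceac(samples: pd.DataFrame, wtp_grid, engine: str) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("ceac requires a non-empty WTP grid")
    probs = [probability_cost_effective(samples, w, engine) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability_cost_effective": probs})
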