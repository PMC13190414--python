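"""Scenario machinery: parameter overrides (e.g. a negotiated reimbursement
price) and alternative willingness-to-pay thresholds, each re-running the
deterministic engines and the PSA."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import ScenarioCfg
from .model import CEModel
from .uncertainty import probability_cost_effective, run_psa


@dataclass
class ScenarioResult:
    name: str
    comparisons: dict  # engine -> CEComparison
    strategy_results: dict  # engine -> {strategy: StrategyResult}
    ceac: pd.DataFrame | None  # columns: engine, wtp, probability_cost_effective


def run_scenario(
    model: CEModel,
    scenario: ScenarioCfg,
    psa_iterations: int | None = None,
    seed: int | None = None,
    with_psa: bool = True,
) -> ScenarioResult:
    """Apply the scenario's overrides, rerun both engines deterministically,
    and (optionally) evaluate the probability of cost-effectiveness at each
    of the scenario's WTP thresholds from a fresh PSA under the overrides.

    Unknown override keys raise (config error) before anything runs.
    """
    overrides = dict(scenario.overrides)
    model.resolve_params(overrides)  # validates keys
    comparisons = model.evaluate(overrides)
    strategy_results = model.strategy_results(overrides)

    ceac_df = None
    if with_psa and scenario.wtp_thresholds:
        samples = run_psa(
            model, n_iterations=psa_iterations, seed=seed, overrides=overrides
        )
        rows = [
            {
                "engine": engine,
                "wtp": wtp,
                "probability_cost_effective": probability_cost_effective(
                    samples, wtp, engine
                ),
            }
            for engine in comparisons
            for wtp in scenario.wtp_thresholds
        ]
        ceac_df = pd.DataFrame(rows)
    return ScenarioResult(scenario.name, comparisons, strategy_results, ceac_df)
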