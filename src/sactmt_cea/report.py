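"""Result rendering: the standard seven-column base-case table (model,
treatment, total cost, incremental cost, QALYs, incremental QALYs, ICER)
plus a lossless machine-readable form."""

from __future__ import annotations

import json

import pandas as pd

COLUMNS = [
    "Model",
    "Treatment",
    "Total cost",
    "Δ Cost",
    "QALYs",
    "Δ QALYs",
    "ICER ($/QALY)",
]

_ENGINE_LABEL = {"psm": "PSM", "markov": "Markov"}


def render_results(strategy_results: dict, comparisons: dict, labels: dict) -> pd.DataFrame:
    """Human table: one block per engine, comparator row first with empty
    incremental columns.  Values rounded to 2 decimals here only; use
    :func:`results_payload` for full precision."""
    rows = []
    for engine, cmp_ in comparisons.items():
        res = strategy_results[engine]
        comp = res[cmp_.comparator]
        inter = res[cmp_.strategy]
        rows.append(
            {
                "Model": _ENGINE_LABEL.get(engine, engine),
                "Treatment": labels.get(cmp_.comparator, cmp_.comparator),
                "Total cost": round(comp.total_cost, 2),
                "Δ Cost": "—",
                "QALYs": round(comp.total_qalys, 2),
                "Δ QALYs": "—",
                "ICER ($/QALY)": "—",
            }
        )
        rows.append(
            {
                "Model": _ENGINE_LABEL.get(engine, engine),
                "Treatment": labels.get(cmp_.strategy, cmp_.strategy),
                "Total cost": round(inter.total_cost, 2),
                "Δ Cost": round(cmp_.delta_cost, 2),
                "QALYs": round(inter.total_qalys, 2),
                "Δ QALYs": round(cmp_.delta_qalys, 2),
                "ICER ($/QALY)": round(cmp_.icer, 2) if cmp_.icer is not None else cmp_.status,
            }
        )
    return pd.DataFrame(rows, columns=COLUMNS)


def results_payload(strategy_results: dict, comparisons: dict) -> dict:
    """Full-precision JSON-serializable mirror of the rendered table."""
    payload = {}
    for engine, cmp_ in comparisons.items():
        payload[engine] = {
            "strategies": {
                name: {
                    "total_cost": r.total_cost,
                    "total_qalys": r.total_qalys,
                    "total_lys": r.total_lys,
                }
                for name, r in strategy_results[engine].items()
            },
            "delta_cost": cmp_.delta_cost,
            "delta_qalys": cmp_.delta_qalys,
            "delta_lys": cmp_.delta_lys,
            "icer": cmp_.icer,
            "status": cmp_.status,
        }
    return payload


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
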