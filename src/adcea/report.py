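"""Human-readable and machine-readable renderings of analysis results."""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd

from .cea import CEAResult, OneTimeResult, SuiteResult
from .errors import ConfigurationError

__all__ = [
    "format_icer",
    "render_scenario_table",
    "render_onetime_table",
    "results_to_frame",
    "render_report",
    "suite_to_json",
]

THIN_SPACE = " "


def format_icer(result: CEAResult) -> str:
    """ICER rounded to the nearest $1,000 with thin-space grouping, or a dominance label."""
    if result.status == "dominant":
        return "dominant"
    if result.status == "dominated":
        return "dominated"
    if result.status == "undefined" or result.icer is None:
        return "undefined"
    rounded = round(result.icer / 1000.0) * 1000
    return f"{rounded:,.0f}".replace(",", THIN_SPACE)


def render_scenario_table(results: list[CEAResult]) -> str:
    """One-row ICER table with one column per scenario."""
    if not results:
        raise ConfigurationError("render_scenario_table requires at least one result")
    ids = [r.scenario_id for r in results]
    cells = [format_icer(r) for r in results]
    width = max(max(len(c) for c in cells + ids), 9)
    header = "ICER, $/QALY by scenario"
    row_ids = "  ".join(i.rjust(width) for i in ids)
    row = "  ".join(c.rjust(width) for c in cells)
    return f"{header}\n{'Scenario'.ljust(8)}  {row_ids}\n{'ICER'.ljust(8)}  {row}\n"


def render_onetime_table(results: list[OneTimeResult]) -> str:
    if not results:
        raise ConfigurationError("render_onetime_table requires at least one result")
    lines = ["ICER, $/QALY by drug administration and price"]
    for r in results:
        lines.append(f"  {r.label:<40} {format_icer(r.result):>12}")
    return "\n".join(lines) + "\n"


def _result_row(result: CEAResult) -> dict:
    row = {
        "scenario": result.scenario_id,
        "n": result.n,
        "seed": result.seed,
        "status": result.status,
        "icer": result.icer,
        "icer_rounded": round(result.icer / 1000.0) * 1000 if result.icer is not None else None,
        "incremental_cost": result.incremental_cost,
        "incremental_qalys": result.incremental_qalys,
        "incremental_life_years": result.incremental_life_years,
        "se_incremental_cost": result.se_incremental_cost,
        "se_incremental_qalys": result.se_incremental_qalys,
    }
    for arm_name, arm in (("treated", result.treated), ("untreated", result.untreated)):
        row[f"{arm_name}_qalys_patient"] = arm.qalys_patient
        row[f"{arm_name}_qalys_caregiver"] = arm.qalys_caregiver
        row[f"{arm_name}_qalys_total"] = arm.qalys_total
        row[f"{arm_name}_life_years"] = arm.life_years
        row[f"{arm_name}_cost_total"] = arm.cost_total
        for comp, value in arm.costs.as_dict().items():
            row[f"{arm_name}_cost_{comp}"] = value
    return row


def results_to_frame(results: list[CEAResult]) -> pd.DataFrame:
    if not results:
        raise ConfigurationError("results_to_frame requires at least one result")
    return pd.DataFrame([_result_row(r) for r in results])


def render_report(suite: SuiteResult) -> dict[str, str]:
    """Render a suite as text tables and CSV; both carry identical values."""
    text = (
        f"seed={suite.seed} n={suite.n} config_hash={suite.config_hash}\n\n"
        + render_scenario_table(suite.scenario_results)
        + "\n"
        + render_onetime_table(suite.onetime_results)
    )
    csv = results_to_frame(
        suite.scenario_results + [r.result for r in suite.onetime_results]
    ).to_csv(index=False)
    return {"text": text, "csv": csv}


def suite_to_json(suite: SuiteResult) -> str:
    """Full machine-readable dump (seed, config hash, per-scenario detail)."""
    payload = {
        "seed": suite.seed,
        "n": suite.n,
        "config_hash": suite.config_hash,
        "scenarios": [asdict(r) for r in suite.scenario_results],
        "one_time": [
            {
                "label": r.label,
                "mode": r.mode,
                "effect_scale": r.effect_scale,
                "price": r.price,
                "result": asdict(r.result),
            }
            for r in suite.onetime_results
        ],
    }
    return json.dumps(payload, indent=2, default=str)
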