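"""Rendering scenario results as publication-style tables and JSON.

Rounding happens only here, at the reporting boundary: totals in GBP
million at 0 dp, populations in millions at 2 dp, per-person values in
GBP at 0 dp.  Values that round to zero at the display precision render
as a dash, mirroring the published tables' footnote convention.
Rendering is a pure function of (result, spec): re-rendering the same
result is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .scenarios import ECONOMIC_COMPONENTS, ScenarioResult
from .stages import STAGES, StageVector

DASH = "-"


@dataclass(frozen=True)
class ReportSpec:
    """Reporting-boundary rounding rules."""

    totals_unit: float = 1e6          # GBP million
    totals_decimals: int = 0
    population_unit: float = 1e6      # millions of persons
    population_decimals: int = 2
    per_person_decimals: int = 0
    dash: str = DASH

    def fmt(self, value: float, unit: float, decimals: int) -> str:
        scaled = value / unit
        # sub-half-display-unit values render as a dash
        if abs(scaled) < 0.5 * 10 ** (-decimals):
            return self.dash
        return f"{scaled:,.{decimals}f}"

    def fmt_total(self, value: float) -> str:
        return self.fmt(value, self.totals_unit, self.totals_decimals)

    def fmt_population(self, value: float) -> str:
        return self.fmt(value, self.population_unit, self.population_decimals)

    def fmt_per_person(self, value: float) -> str:
        return self.fmt(value, 1.0, self.per_person_decimals)


def _stage_row(values: StageVector, fmt) -> dict[str, str]:
    row = {s: fmt(values[s]) for s in STAGES}
    row["Total"] = fmt(values.sum())
    return row


def population_table(result: ScenarioResult, spec: ReportSpec) -> pd.DataFrame:
    """Diagnosed population by stage: share of prevalence and headcount."""
    prevalent = result.population.prevalent.stage_totals()
    diagnosed = result.population.diagnosed.stage_totals()
    share = {}
    for s in STAGES:
        share[s] = (f"{diagnosed[s] / prevalent[s] * 100:.2f}"
                    if prevalent[s] > 0 else spec.dash)
    share["Total"] = f"{diagnosed.sum() / prevalent.sum() * 100:.2f}"
    counts = _stage_row(diagnosed, spec.fmt_population)
    return pd.DataFrame(
        [share, counts],
        index=["Diagnosed (% of prevalence)", "Diagnosed (millions)"],
    )


def economic_total_table(result: ScenarioResult, spec: ReportSpec) -> pd.DataFrame:
    """Economic costs by component and stage, GBP million."""
    comp = result.economic_by_component_stage()
    rows = {}
    for name in ECONOMIC_COMPONENTS:
        rows[name] = _stage_row(StageVector(comp.loc[name].to_numpy()),
                                spec.fmt_total)
    rows["total"] = _stage_row(result.economic_by_stage(), spec.fmt_total)
    return pd.DataFrame(rows).T


def economic_per_person_table(result: ScenarioResult,
                              spec: ReportSpec) -> pd.DataFrame:
    """Economic costs per diagnosed person by component and stage, GBP."""
    comp = result.economic_by_component_stage()
    counts = result.population.diagnosed.stage_totals()
    rows = {}
    for name in list(ECONOMIC_COMPONENTS) + ["total"]:
        values = (comp.loc[name] if name != "total" else comp.sum(axis=0))
        row = {}
        for s in STAGES:
            row[s] = (spec.fmt_per_person(values[s] / counts[s])
                      if counts[s] > 0 else spec.dash)
        total_pp = (values.sum() / counts.sum()) if counts.sum() > 0 else 0.0
        row["Total"] = spec.fmt_per_person(total_pp)
        rows[name] = row
    return pd.DataFrame(rows).T


def wellbeing_total_table(result: ScenarioResult, spec: ReportSpec) -> pd.DataFrame:
    """Wellbeing (monetised DALY) costs by stage, GBP million."""
    return pd.DataFrame(
        [_stage_row(result.burden.wellbeing_by_stage(), spec.fmt_total)],
        index=["Total wellbeing costs"],
    )


def wellbeing_per_person_table(result: ScenarioResult,
                               spec: ReportSpec) -> pd.DataFrame:
    """Per-person wellbeing costs by stage, GBP."""
    per_person = result.burden.wellbeing_per_person_by_stage()
    counts = result.population.diagnosed.stage_totals()
    row = {}
    for s in STAGES:
        row[s] = (spec.fmt_per_person(per_person[s])
                  if counts[s] > 0 else spec.dash)
    row["Total"] = spec.fmt_per_person(result.per_person_wellbeing)
    return pd.DataFrame([row], index=["Total wellbeing costs"])


def tidy_costs(result: ScenarioResult) -> pd.DataFrame:
    """Long-format economic costs (full precision, no rounding)."""
    comp = result.economic_by_component_stage()
    long = comp.stack().rename("value").reset_index()
    long.columns = ["component", "stage", "value"]
    long.insert(0, "prevalence", result.prevalence_label)
    long.insert(1, "diagnosis", result.diagnosis_label)
    return long


def summarise(result: ScenarioResult) -> dict:
    """Key headline figures, full precision."""
    return {
        "prevalence_scenario": result.prevalence_label,
        "diagnosis_scenario": result.diagnosis_label,
        "prevalent_total": result.population.prevalent.total(),
        "diagnosed_total": result.diagnosed_total,
        "undiagnosed_share": result.undiagnosed_share,
        "economic_total": result.economic_total,
        "wellbeing_total": result.wellbeing_total,
        "dalys": result.dalys_total,
        "per_person_economic": result.per_person_economic,
        "per_person_wellbeing": result.per_person_wellbeing,
        "provenance": dict(result.metadata),
    }


TABLES = {
    "population": population_table,
    "economic_total": economic_total_table,
    "economic_per_person": economic_per_person_table,
    "wellbeing_total": wellbeing_total_table,
    "wellbeing_per_person": wellbeing_per_person_table,
}


def render_tables(result: ScenarioResult, spec: ReportSpec | None = None,
                  out_dir=None) -> dict[str, pd.DataFrame]:
    """Render the five publication-style tables (plus tidy CSV / JSON).

    Returns the formatted tables; when ``out_dir`` is given, also writes
    ``table_<name>.csv`` for each, ``costs_tidy.csv`` (full precision)
    and ``summary.json``.
    """
    spec = spec or ReportSpec()
    tables = {name: fn(result, spec) for name, fn in TABLES.items()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"table_{name}.csv")
        tidy_costs(result).to_csv(out / "costs_tidy.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summarise(result), fh, indent=2)
    return tables
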