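"""Health-system costs by stage, category and payer.

Only diagnosed patients incur costs.  Each stage/status cell of the unit
cost schedule is applied to the matching population; liver-transplant
care is costed as an initial-year amount for in-year transplants plus a
subsequent-year amount for the monitored post-transplant stock.  The
pooled medical-research spend is a fixed total spread uniformly per
diagnosed person, so totals are scenario-invariant while per-person
values fall as the diagnosed population grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .params import COST_CATEGORIES, CostSchedule, PayerSplit
from .stages import COSTED_STAGES, STAGES, StageVector

#: Category label for the pooled research spend.
RESEARCH_CATEGORY = "medical_research"


@dataclass(frozen=True)
class HealthCostResult:
    """Health-system cost totals (GBP) with stage/category resolution."""

    total_by_stage_category: pd.DataFrame = field(repr=False)
    diagnosed_by_stage: StageVector
    payer_totals: Optional[dict[str, float]] = None

    @property
    def grand_total(self) -> float:
        return float(self.total_by_stage_category.to_numpy().sum())

    def total_by_stage(self) -> StageVector:
        return StageVector(self.total_by_stage_category.sum(axis=1).to_numpy())

    def total_by_category(self) -> pd.Series:
        return self.total_by_stage_category.sum(axis=0)

    def per_person_by_stage(self) -> StageVector:
        totals = self.total_by_stage().values
        counts = self.diagnosed_by_stage.values
        with np.errstate(divide="ignore", invalid="ignore"):
            pp = np.where(counts > 0, totals / np.where(counts > 0, counts, 1.0), 0.0)
        return StageVector(pp)

    @property
    def per_person_overall(self) -> float:
        n = self.diagnosed_by_stage.sum()
        return self.grand_total / n if n else 0.0


def stage_health_costs(
    schedule: CostSchedule,
    newly_diagnosed: CohortTable,
    in_monitoring: CohortTable,
    transplants: Optional[CohortTable] = None,
) -> HealthCostResult:
    """Pre-research health costs: unit cost times population, cell-wise.

    ``transplants`` carries this-year transplant counts (initial-year LT
    cost); if omitted, the newly-diagnosed LT population stands in.  The
    monitored LT stock incurs the subsequent-year cost.  LT amounts are
    booked under secondary care.
    """
    n_new = newly_diagnosed.stage_totals()
    n_mon = in_monitoring.stage_totals()
    for stage in COSTED_STAGES:
        if stage not in schedule.unit_costs.index:
            raise ValueError(f"unit-cost schedule missing stage {stage}")

    table = pd.DataFrame(0.0, index=list(STAGES), columns=list(COST_CATEGORIES))
    for cat in COST_CATEGORIES:
        for stage in COSTED_STAGES:
            table.loc[stage, cat] = (
                schedule.unit_costs.loc[stage, ("newly_diagnosed", cat)] * n_new[stage]
                + schedule.unit_costs.loc[stage, ("in_monitoring", cat)] * n_mon[stage]
            )
    tx_total = transplants.total() if transplants is not None else n_new["LT"]
    table.loc["LT", "secondary_care"] = (
        schedule.lt_initial_year * tx_total
        + schedule.lt_subsequent_year * n_mon["LT"]
    )
    return HealthCostResult(
        total_by_stage_category=table,
        diagnosed_by_stage=n_new + n_mon,
    )


def add_medical_research(
    result: HealthCostResult, research_pool: float, diagnosed_total: float
) -> HealthCostResult:
    """Fold the pooled research spend into the result.

    The grand total rises by exactly the pool; per-person values rise by
    ``pool / diagnosed_total`` uniformly, so the pool's stage allocation
    is proportional to the diagnosed population.
    """
    if research_pool < 0:
        raise ValueError("research pool must be >= 0")
    table = result.total_by_stage_category.copy()
    if research_pool == 0:
        table[RESEARCH_CATEGORY] = 0.0
        return replace(result, total_by_stage_category=table)
    if diagnosed_total <= 0:
        raise ValueError(
            "cannot spread a positive research pool over zero diagnosed patients"
        )
    shares = result.diagnosed_by_stage.values / diagnosed_total
    table[RESEARCH_CATEGORY] = research_pool * shares
    return replace(result, total_by_stage_category=table)


def allocate_payers(result: HealthCostResult, split: PayerSplit) -> HealthCostResult:
    """Attach payer totals: split fractions applied to the grand total."""
    grand = result.grand_total
    payers = {payer: frac * grand for payer, frac in split.fractions.items()}
    return replace(result, payer_totals=payers)
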