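"""Care costs, welfare transfers, deadweight loss and funeral costs.

Formal and informal care accrue to the end-stage liver disease (ESLD)
population only, varying by stage but applied evenly across age and sex;
informal care is valued by the opportunity-cost method (carer hours at
carer earnings).  Welfare transfers (PIP, ESA, Carer's Allowance) are
redistributions, not resource costs: their face value is excluded from
economic-cost totals, but the deadweight loss of raising them -- together
with forgone tax revenue and, optionally, government health spending --
is a real cost borne by society.  Premature deaths bring funeral costs
forward; only the discounting differential is a cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, cell_index
from .discounting import bring_forward_factor
from .params import OtherCostParams, WelfareParams
from .stages import ESLD_STAGES, STAGES, StageVector

WELFARE_BENEFITS: tuple[str, ...] = ("PIP", "ESA", "CA")


@dataclass(frozen=True)
class OtherCostResult:
    """Other-cost totals (GBP).

    ``welfare_transfers`` are carried for the DWL base and reporting but
    are *not* part of the economic-cost total.
    """

    formal_care_by_stage: pd.Series = field(repr=False)
    informal_care_by_stage: pd.Series = field(repr=False)
    welfare_transfers: dict[str, float]
    dwl: float
    funeral: float
    diagnosed_by_stage: StageVector

    @property
    def carer_total(self) -> float:
        return float(self.formal_care_by_stage.sum()
                     + self.informal_care_by_stage.sum())

    @property
    def transfers_total(self) -> float:
        return float(sum(self.welfare_transfers.values()))

    @property
    def economic_total(self) -> float:
        """Care + DWL + funeral; transfer face values excluded."""
        return self.carer_total + self.dwl + self.funeral

    def carer_by_stage(self) -> StageVector:
        s = self.formal_care_by_stage.add(self.informal_care_by_stage,
                                          fill_value=0.0)
        return StageVector({k: float(v) for k, v in s.items()})


def formal_care_cost(esld_pop: CohortTable, unit_cost: float,
                     share_receiving: StageVector) -> pd.Series:
    """Formal care: population x share receiving x annual unit cost."""
    if unit_cost < 0:
        raise ValueError("unit cost must be >= 0")
    totals = esld_pop.stage_totals()
    return pd.Series(
        {s: totals[s] * share_receiving[s] * unit_cost for s in ESLD_STAGES}
    )


def informal_care_cost(esld_pop: CohortTable, share_receiving: StageVector,
                       hours_per_week: float, carer_wage: float) -> pd.Series:
    """Informal care by the opportunity-cost method.

    Carer hours are valued at carer earnings: population x share cared
    for x hours/week x 52 x hourly wage, by ESLD stage.  ``hours_per_week``
    may be a scalar or a per-stage :class:`StageVector`.
    """
    totals = esld_pop.stage_totals()

    def _hours(stage: str) -> float:
        if isinstance(hours_per_week, StageVector):
            return hours_per_week[stage]
        return float(hours_per_week)

    return pd.Series(
        {s: totals[s] * share_receiving[s] * _hours(s) * 52.0 * carer_wage
         for s in ESLD_STAGES}
    )


def welfare_transfers(params: WelfareParams,
                      diagnosed_esld: float,
                      care_receiving: float) -> dict[str, float]:
    """Annual transfer totals by benefit.

    PIP and ESA claims scale with the diagnosed ESLD population via
    attribution shares; Carer's Allowance claims equal the care-receiving
    population times the probability that the carer receives the benefit.
    """
    if diagnosed_esld < 0 or care_receiving < 0:
        raise ValueError("populations must be >= 0")
    return {
        "PIP": params.pip_claim_share * diagnosed_esld * params.pip_annual_value,
        "ESA": params.esa_claim_share * diagnosed_esld * params.esa_annual_value,
        "CA": params.ca_receipt_prob * care_receiving * params.ca_annual_value,
    }


def deadweight_loss(tax_forgone: float, transfers: float,
                    govt_health_spend: float, dwl_rate: float) -> float:
    """Efficiency loss of the taxation needed to cover the distortion base."""
    if not 0.0 <= dwl_rate < 1.0:
        raise ValueError("dwl_rate must lie in [0, 1)")
    base = tax_forgone + transfers + govt_health_spend
    return dwl_rate * base


def funeral_costs_brought_forward(deaths: CohortTable, unit_cost: float,
                                  life_table: pd.Series,
                                  discount_rate: float) -> float:
    """Cost of funerals brought forward by premature death.

    Each death brings a funeral forward by the decedent's remaining life
    expectancy; the cost is the bring-forward differential
    ``unit_cost x (1 - (1+r)^-L)``, zero at r = 0 or L = 0.
    """
    if unit_cost < 0:
        raise ValueError("unit cost must be >= 0")
    lt = life_table.reindex(cell_index())
    counts = deaths.data["DEATH"]
    if (counts[lt.isna()] > 0).any():
        raise ValueError("life table missing band(s) with deaths")
    factor = bring_forward_factor(discount_rate, lt.fillna(0.0).to_numpy())
    return float((counts.to_numpy() * factor).sum() * unit_cost)


def assemble_other_costs(
    params: OtherCostParams,
    diagnosed: CohortTable,
    deaths: CohortTable,
    life_table: pd.Series,
    discount_rate: float,
    tax_forgone: float,
    govt_health_spend: float,
) -> OtherCostResult:
    """Compute every other-cost component for one scenario.

    ``tax_forgone`` is the government's lost tax on productivity losses;
    ``govt_health_spend`` enters the DWL base when the corresponding flag
    is on.
    """
    formal = formal_care_cost(diagnosed, params.formal_care_annual_cost,
                              params.formal_care_share)
    informal = informal_care_cost(diagnosed, params.informal_care_share,
                                  params.informal_care_hours_per_week,
                                  params.carer_hourly_earnings)
    stage_totals = diagnosed.stage_totals()
    diagnosed_esld = float(sum(stage_totals[s] for s in ESLD_STAGES))
    care_receiving = float(
        sum(stage_totals[s] * params.informal_care_share[s]
            for s in ESLD_STAGES)
    )
    transfers = welfare_transfers(params.welfare, diagnosed_esld,
                                  care_receiving)
    health_base = govt_health_spend if params.include_government_health_in_dwl else 0.0
    dwl = deadweight_loss(tax_forgone, sum(transfers.values()), health_base,
                          params.dwl_rate)
    funeral = funeral_costs_brought_forward(deaths, params.funeral_cost,
                                            life_table, discount_rate)
    return OtherCostResult(
        formal_care_by_stage=formal,
        informal_care_by_stage=informal,
        welfare_transfers=transfers,
        dwl=dwl,
        funeral=funeral,
        diagnosed_by_stage=stage_totals,
    )
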