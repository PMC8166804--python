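"""Disease burden (YLD, YLL, DALYs) and VSLY-monetised wellbeing costs.

Burden follows standard burden-of-disease accounting: years lived with
disability (YLD) weight each diagnosed person-year in the base year by a
stage disability weight; years of life lost (YLL) value each attributable
death by the discounted stream of its remaining life expectancy.  YLL are
discounted at an annual rate (default 3%) with a discrete annuity and no
age-weighting.  DALYs = YLD + YLL, monetised at the value of a
statistical life year (VSLY).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, cell_index
from .discounting import annuity_factor
from .params import BurdenParams
from .stages import LIVING_STAGES, STAGES, StageVector


@dataclass(frozen=True)
class BurdenResult:
    """DALY components and their monetised value for one scenario."""

    yld_by_stage: StageVector
    yll_total: float
    diagnosed_by_stage: StageVector
    deaths_total: float
    vsly: float
    disability_weight: StageVector = field(repr=False)

    @property
    def yld_total(self) -> float:
        return self.yld_by_stage.sum()

    @property
    def dalys_total(self) -> float:
        return self.yld_total + self.yll_total

    def dalys_by_stage(self) -> StageVector:
        return self.yld_by_stage.replace(DEATH=self.yll_total)

    def wellbeing_by_stage(self) -> StageVector:
        """Total wellbeing cost (GBP) by stage: DALYs x VSLY."""
        return StageVector(self.dalys_by_stage().values * self.vsly)

    @property
    def wellbeing_total(self) -> float:
        return self.dalys_total * self.vsly

    def wellbeing_per_person_by_stage(self) -> StageVector:
        """Per-person wellbeing cost by stage.

        For living stages this is exactly disability weight x VSLY
        (scenario-invariant); for the death column it is the discounted
        life-years lost per decedent times the VSLY.
        """
        out = {}
        for s in LIVING_STAGES:
            out[s] = self.disability_weight[s] * self.vsly
        out["DEATH"] = (
            self.yll_total / self.deaths_total * self.vsly
            if self.deaths_total > 0 else 0.0
        )
        return StageVector(out)


def yld(diagnosed: CohortTable, weights: StageVector) -> StageVector:
    """Years lived with disability by stage over the base year.

    One base year means person-years equal persons; the DEATH column is
    handled by YLL, not a disability weight.
    """
    weights.require_probability("disability weights")
    totals = diagnosed.stage_totals()
    vals = totals.values * weights.values
    return StageVector(vals).replace(DEATH=0.0)


def yll_per_death(remaining_life_expectancy, discount_rate: float):
    """Discounted years of life lost per death (annuity closed form)."""
    return annuity_factor(discount_rate, remaining_life_expectancy)


def yll(deaths: CohortTable, life_table: pd.Series,
        discount_rate: float) -> float:
    """Total discounted years of life lost across all attributable deaths."""
    lt = life_table.reindex(cell_index())
    counts = deaths.data["DEATH"]
    if (counts[lt.isna()] > 0).any():
        missing = lt[lt.isna()].index.tolist()
        raise ValueError(f"life table missing band(s): {missing[:4]}")
    per_death = yll_per_death(lt.fillna(0.0).to_numpy(), discount_rate)
    return float((counts.to_numpy() * per_death).sum())


def monetise(dalys, vsly: float):
    """Convert DALYs to GBP at the VSLY; linear at every aggregation level."""
    if vsly <= 0:
        raise ValueError("vsly must be > 0")
    if isinstance(dalys, StageVector):
        return StageVector(dalys.values * vsly)
    return np.asarray(dalys, dtype=float) * vsly if np.ndim(dalys) else float(dalys) * vsly


def assemble_burden(
    diagnosed: CohortTable,
    deaths: CohortTable,
    params: BurdenParams,
) -> BurdenResult:
    """YLD, YLL and monetised wellbeing for one scenario's populations."""
    yld_stage = yld(diagnosed, params.disability_weight)
    yll_total = yll(deaths, params.life_table, params.discount_rate)
    return BurdenResult(
        yld_by_stage=yld_stage,
        yll_total=yll_total,
        diagnosed_by_stage=diagnosed.stage_totals(),
        deaths_total=float(deaths.data["DEATH"].sum()),
        vsly=params.vsly,
        disability_weight=params.disability_weight,
    )
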