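"""Human-capital productivity costs.

Five components, all valued at expected market earnings (average weekly
earnings adjusted for age, sex and general-population employment rates):

* **participation** -- the percentage-point drop in workforce
  participation attributable to end-stage liver disease, valued at a full
  working year of earnings per exit.
* **absenteeism / presenteeism** -- weeks of productive time lost per
  employed patient-year, by stage; the survey behind the week-loss inputs
  covered F0..F4CC, so F4CC values are extrapolated to DCC, HCC and LT
  where none are supplied.
* **forgone income** -- the discounted stream of expected earnings a
  decedent would have received up to retirement.
* **search, hiring and training** -- a fixed friction cost per workforce
  exit (employed decedents plus participation exits).

Bearer attribution follows the standard human-capital convention: the
government loses the effective-tax share of all lost earnings, employers
bear presenteeism and paid sick leave plus replacement frictions, and
individuals bear the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CohortTable, band_lower, band_midpoint, cell_index
from .discounting import annuity_factor
from .params import LabourParams
from .stages import STAGES, StageVector

PRODUCTIVITY_COMPONENTS: tuple[str, ...] = (
    "participation",
    "absenteeism",
    "presenteeism",
    "forgone_income",
    "search_hire_train",
)


@dataclass(frozen=True)
class ProductivityResult:
    """Productivity cost totals (GBP), component x stage."""

    component_by_stage: pd.DataFrame = field(repr=False)
    diagnosed_by_stage: StageVector
    bearer_totals: Optional[dict[str, float]] = None

    @property
    def grand_total(self) -> float:
        return float(self.component_by_stage.to_numpy().sum())

    def total_by_component(self) -> pd.Series:
        return self.component_by_stage.sum(axis=0)

    def total_by_stage(self) -> StageVector:
        return StageVector(self.component_by_stage.sum(axis=1).to_numpy())

    def per_person_by_stage(self) -> StageVector:
        totals = self.total_by_stage().values
        counts = self.diagnosed_by_stage.values
        pp = np.where(counts > 0, totals / np.where(counts > 0, counts, 1.0), 0.0)
        return StageVector(pp)


def working_age_mask(retirement_age: int) -> pd.Series:
    """True for cells whose band lower bound is below retirement age."""
    idx = cell_index()
    return pd.Series([band_lower(b) < retirement_age for b, _ in idx], index=idx)


def earnings_lookup(labour: LabourParams,
                    cohort: Optional[CohortTable] = None) -> pd.Series:
    """Expected weekly earnings per cell: AWE x employment rate.

    If a cohort is given, every cell it populates must be covered by the
    labour tables.
    """
    if cohort is not None:
        populated = cohort.by_age_sex()
        covered = labour.weekly_earnings.index.intersection(populated.index)
        missing = populated[populated > 0].index.difference(covered)
        if len(missing):
            raise ValueError(f"labour tables missing band(s): {list(missing)[:4]}")
    return labour.weekly_earnings * labour.employment_rate


def resolve_weeks(weeks: StageVector, fallback_stage: str = "F4CC") -> StageVector:
    """Fill unset (NaN) week-loss entries with the F4CC estimate."""
    fallback = weeks[fallback_stage]
    if np.isnan(fallback):
        raise ValueError(f"weeks for {fallback_stage} must be set")
    vals = np.where(np.isnan(weeks.values), fallback, weeks.values)
    return StageVector(vals)


def participation_cost(labour: LabourParams, diagnosed: CohortTable) -> pd.Series:
    """Reduced-participation cost by stage.

    ``reduced_participation[s]`` is the percentage-point fall in the
    employment rate among stage-s patients; each induced exit is valued
    at a full year (52 weeks) of average earnings.  Working-age cells only.
    """
    mask = working_age_mask(labour.retirement_age).astype(float)
    weighted = diagnosed.mul_cells(labour.weekly_earnings * mask)
    per_stage = weighted.stage_totals().values * labour.reduced_participation.values * 52.0
    return pd.Series(per_stage, index=list(STAGES))


def absenteeism_presenteeism_cost(
    labour: LabourParams, diagnosed: CohortTable
) -> pd.DataFrame:
    """Absenteeism and presenteeism cost by stage.

    Weeks lost apply to employed, working-age patients, valued at average
    weekly earnings; hence the employment-rate weighting per cell.
    """
    mask = working_age_mask(labour.retirement_age).astype(float)
    weights = labour.weekly_earnings * labour.employment_rate * mask
    weighted = diagnosed.mul_cells(weights).stage_totals().values
    out = pd.DataFrame(index=list(STAGES))
    out["absenteeism"] = weighted * resolve_weeks(labour.absenteeism_weeks).values
    out["presenteeism"] = weighted * resolve_weeks(labour.presenteeism_weeks).values
    # decedents lose no further in-year productive time under these heads
    out.loc["DEATH"] = 0.0
    return out


def forgone_income_per_person(annual_earnings: float, years_to_retirement: float,
                              discount_rate: float) -> float:
    """Discounted future earnings stream for one decedent (annuity form)."""
    return annual_earnings * annuity_factor(discount_rate, years_to_retirement)


def forgone_income(deaths: CohortTable, labour: LabourParams,
                   discount_rate: float) -> pd.Series:
    """Forgone future income of decedents, by (age band, sex).

    Expected annual earnings (AWE x 52 x employment rate) are projected
    from the band midpoint to retirement and discounted as an annuity;
    bands at or above retirement age contribute nothing.
    """
    idx = cell_index()
    years = np.array(
        [max(labour.retirement_age - band_midpoint(b), 0.0) for b, _ in idx]
    )
    mask = working_age_mask(labour.retirement_age).to_numpy().astype(float)
    annual = (labour.weekly_earnings * 52.0 * labour.employment_rate).to_numpy()
    per_person = annual * annuity_factor(discount_rate, years) * mask
    death_counts = deaths.data["DEATH"].to_numpy()
    return pd.Series(death_counts * per_person, index=idx)


def search_hire_train_cost(exits: float, unit_cost: float) -> float:
    """Replacement friction cost: exits times the per-exit unit cost."""
    if exits < 0:
        raise ValueError("exits must be >= 0")
    return exits * unit_cost


def workforce_exits_by_stage(labour: LabourParams, diagnosed: CohortTable,
                             deaths: CohortTable) -> pd.Series:
    """Workforce exits by stage: participation exits plus employed decedents."""
    mask = working_age_mask(labour.retirement_age).astype(float)
    working = diagnosed.mul_cells(mask).stage_totals().values
    exits = working * labour.reduced_participation.values
    out = pd.Series(exits, index=list(STAGES))
    employed_deaths = float(
        (deaths.data["DEATH"] * labour.employment_rate * mask).sum()
    )
    out["DEATH"] += employed_deaths
    return out


def assemble_productivity(
    labour: LabourParams,
    diagnosed: CohortTable,
    deaths: CohortTable,
    discount_rate: float,
) -> ProductivityResult:
    """Compute all five components for one scenario's populations."""
    table = pd.DataFrame(
        0.0, index=list(STAGES), columns=list(PRODUCTIVITY_COMPONENTS)
    )
    table["participation"] = participation_cost(labour, diagnosed)
    ap = absenteeism_presenteeism_cost(labour, diagnosed)
    table["absenteeism"] = ap["absenteeism"]
    table["presenteeism"] = ap["presenteeism"]
    table.loc["DEATH", "forgone_income"] = float(
        forgone_income(deaths, labour, discount_rate).sum()
    )
    exits = workforce_exits_by_stage(labour, diagnosed, deaths)
    table["search_hire_train"] = exits * labour.search_hire_train_cost
    return ProductivityResult(
        component_by_stage=table,
        diagnosed_by_stage=diagnosed.stage_totals(),
    )


def allocate_bearers(result: ProductivityResult,
                     effective_tax_rate: float) -> ProductivityResult:
    """Split the total over government, employers and individuals.

    Government recoups the effective-tax share of all lost earnings;
    employers bear the after-tax value of on-the-job losses (absenteeism
    under sick pay, presenteeism) plus replacement frictions; individuals
    bear the after-tax value of participation losses and forgone income.
    """
    if not 0.0 <= effective_tax_rate < 1.0:
        raise ValueError("effective tax rate must lie in [0, 1)")
    comp = result.total_by_component()
    earnings_like = (
        comp["participation"] + comp["absenteeism"]
        + comp["presenteeism"] + comp["forgone_income"]
    )
    tax = effective_tax_rate
    bearers = {
        "government": tax * earnings_like,
        "employers": (1 - tax) * (comp["absenteeism"] + comp["presenteeism"])
        + comp["search_hire_train"],
        "individuals": (1 - tax) * (comp["participation"] + comp["forgone_income"]),
    }
    return replace(result, bearer_totals={k: float(v) for k, v in bearers.items()})
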