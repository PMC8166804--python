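"""Prevalent, diagnosed and event populations for the base year.

The prevalence approach takes a single base-year snapshot: prevalence
rates are applied to the adult population pyramid, the per-stage
probability of diagnosis yields the diagnosed population (only diagnosed
patients incur costs), and incidence fractions split the diagnosed stock
into newly-diagnosed and in-monitoring patients.  Attributable deaths and
transplants are in-year events carried alongside.

Decedents are carried as a tenth population column (stage DEATH) with a
diagnosis probability of one, so the published population-table layout is
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AGE_BANDS, SEXES, CohortTable, DemographicTable, band_lower, cell_index
from .params import DiagnosisProfile, MortalityParams, PrevalenceScenario, TransplantParams
from .stages import LIVING_STAGES, StageVector


@dataclass(frozen=True)
class PopulationState:
    """All base-year population tables for one scenario combination."""

    prevalent: CohortTable
    diagnosed: CohortTable
    newly_diagnosed: CohortTable
    in_monitoring: CohortTable
    deaths_liver: CohortTable
    deaths_cvd: CohortTable
    transplants: CohortTable

    @property
    def deaths(self) -> CohortTable:
        return self.deaths_liver + self.deaths_cvd

    def validate(self, tol: float = 1e-9) -> None:
        if ((self.diagnosed.data - self.prevalent.data) > tol).any().any():
            raise ValueError("diagnosed exceeds prevalent")
        recombined = self.newly_diagnosed + self.in_monitoring
        if not recombined.allclose(self.diagnosed, rtol=tol, atol=tol):
            raise ValueError("newly_diagnosed + in_monitoring != diagnosed")


def prevalent_population(
    scenario: PrevalenceScenario, demographics: DemographicTable
) -> CohortTable:
    """Spread ``rate x adult population`` over stage, age band and sex.

    The joint cell count is the product of the overall total with the
    stage share, the stage-conditional age share and the sex share, so
    every marginal reproduces its input distribution exactly.
    """
    total = scenario.overall_rate * demographics.total
    sex_shares = np.array([scenario.sex_distribution[s] for s in SEXES])
    table = CohortTable.zeros()
    df = table.data
    for stage in LIVING_STAGES:
        stage_mass = total * scenario.stage_distribution[stage]
        age_shares = scenario.age_distribution.loc[stage].to_numpy()
        # cell order is the product (age_band, sex)
        df[stage] = stage_mass * np.repeat(age_shares, len(SEXES)) * np.tile(
            sex_shares, len(AGE_BANDS)
        )
    return CohortTable(df)


def diagnosed_population(
    prevalent: CohortTable, profile: DiagnosisProfile
) -> CohortTable:
    """Apply the per-stage probability of diagnosis cell-wise."""
    return prevalent.mul_stage(profile.probability)


def overall_diagnosed_share(
    prevalent: CohortTable, diagnosed: CohortTable
) -> float:
    """Diagnosed cases as a fraction of all prevalent cases."""
    denom = prevalent.total()
    return diagnosed.total() / denom if denom else 0.0


def split_new_vs_monitoring(
    diagnosed: CohortTable, incidence: StageVector
) -> tuple[CohortTable, CohortTable]:
    """Split the diagnosed stock proportionally to per-stage incidence.

    ``incidence[s]`` is the fraction of stage-``s`` prevalence that entered
    the stage in the base year; under a proportionate diagnosis rate the
    same fraction of the diagnosed stock is newly diagnosed.
    """
    incidence.require_probability("incidence")
    newly = diagnosed.mul_stage(incidence)
    monitoring = diagnosed - newly
    return newly, monitoring


def attributable_mortality(
    rate: float,
    demographics: DemographicTable,
    cvd_share: float,
    age_sex_distribution: pd.Series,
) -> tuple[CohortTable, CohortTable]:
    """Excess deaths in the base year, split into liver and CVD causes.

    ``rate`` is expressed as a fraction of the adult population; total
    deaths are distributed over (age band, sex) by the supplied
    distribution and split by the CVD share (excess cardiovascular deaths
    among NASH patients, the remainder liver-related).

    Returns ``(liver, cvd)`` death tables, each with all mass in the
    DEATH column.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"mortality rate must lie in [0, 1), got {rate}")
    if not 0.0 <= cvd_share <= 1.0:
        raise ValueError("cvd_share must lie in [0, 1]")
    total = rate * demographics.total
    dist = age_sex_distribution.reindex(cell_index()).fillna(0.0)
    liver = CohortTable.zeros()
    cvd = CohortTable.zeros()
    liver.data["DEATH"] = total * (1.0 - cvd_share) * dist
    cvd.data["DEATH"] = total * cvd_share * dist
    return CohortTable(liver.data), CohortTable(cvd.data)


def mortality_for_scenario(
    scenario: PrevalenceScenario,
    demographics: DemographicTable,
    mortality: MortalityParams,
) -> tuple[CohortTable, CohortTable]:
    """Deaths under a prevalence scenario.

    The per-prevalent-case death rate times the scenario prevalence rate
    gives the adult-population mortality rate, so attributable deaths
    scale with the prevalence scenario.
    """
    rate = mortality.rate_per_prevalent * scenario.overall_rate
    return attributable_mortality(
        rate, demographics, mortality.cvd_share, mortality.age_sex_distribution
    )


def liver_transplants(
    total_elective: float,
    nash_indication_share: float,
    prevalence_age_sex_distribution: pd.Series,
    age_cap: int = 70,
) -> CohortTable:
    """In-year transplants, excluded above the age cap.

    Attributable transplants (elective total x indication share) are
    spread over (age band, sex) proportionally to the prevalence
    distribution renormalised below the cap; bands whose lower bound
    reaches the cap receive none.
    """
    total = total_elective * nash_indication_share
    dist = prevalence_age_sex_distribution.reindex(cell_index()).fillna(0.0)
    eligible = pd.Series(
        [band_lower(b) < age_cap for b, _ in cell_index()], index=cell_index()
    )
    mass = dist.where(eligible, 0.0)
    if total > 0 and mass.sum() <= 0:
        raise ValueError(
            f"no prevalence mass below the transplant age cap ({age_cap})"
        )
    table = CohortTable.zeros()
    if total > 0:
        table.data["LT"] = total * mass / mass.sum()
    return CohortTable(table.data)


def build_population_state(
    scenario: PrevalenceScenario,
    profile: DiagnosisProfile,
    demographics: DemographicTable,
    incidence: StageVector,
    mortality: MortalityParams,
    transplants: TransplantParams,
) -> PopulationState:
    """Assemble every base-year population table for one scenario pair."""
    prevalent = prevalent_population(scenario, demographics)
    deaths_liver, deaths_cvd = mortality_for_scenario(
        scenario, demographics, mortality
    )
    deaths = deaths_liver + deaths_cvd
    # decedents join the prevalence table as the tenth column
    prevalent = prevalent + deaths
    diagnosed = diagnosed_population(prevalent, profile)

    age_sex = prevalent.by_age_sex()
    total_prev = age_sex.sum()
    prev_dist = age_sex / total_prev if total_prev else age_sex
    tx = liver_transplants(
        transplants.total_elective,
        transplants.nash_indication_share,
        prev_dist,
        transplants.age_cap,
    )

    newly, monitoring = split_new_vs_monitoring(diagnosed, incidence)
    state = PopulationState(
        prevalent=prevalent,
        diagnosed=diagnosed,
        newly_diagnosed=newly,
        in_monitoring=monitoring,
        deaths_liver=deaths_liver,
        deaths_cvd=deaths_cvd,
        transplants=tx,
    )
    state.validate()
    return state
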