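"""Shared fixtures: synthetic bundles at several scales plus small helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coiburden.cohort import AGE_BANDS, SEXES, CohortTable, DemographicTable, cell_index
from coiburden.params import (
    COST_CATEGORIES,
    PATIENT_STATUSES,
    CostSchedule,
)
from coiburden.stages import COSTED_STAGES, STAGES, StageVector
from coiburden.synthetic import SyntheticSpec, calibrate_uk_like, generate_bundle


@pytest.fixture(scope="session")
def uk_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=42)


@pytest.fixture(scope="session")
def uk_bundle(uk_spec):
    """Full-scale synthetic UK-like bundle (uncalibrated)."""
    return generate_bundle(uk_spec)


@pytest.fixture(scope="session")
def calibrated_spec(uk_spec):
    return calibrate_uk_like(uk_spec)


@pytest.fixture(scope="session")
def calibrated_bundle(calibrated_spec):
    """Bundle with scale knobs calibrated to the published anchors."""
    return generate_bundle(calibrated_spec)


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic population (~120k adults, ~1.2k diagnosed cases)."""
    return generate_bundle(SyntheticSpec(seed=7, adult_population=120_000.0))


def make_cohort(stage_values: dict[str, float],
                band: str = "40-44", sex: str = "male") -> CohortTable:
    """A cohort table with all mass in one (age band, sex) cell."""
    t = CohortTable.zeros()
    for stage, v in stage_values.items():
        t.data.loc[(band, sex), stage] = float(v)
    return CohortTable(t.data)


def uniform_cohort(value: float) -> CohortTable:
    """Same count in every stage, all in one working-age cell."""
    return make_cohort({s: value for s in STAGES})


def flat_series(value: float) -> pd.Series:
    """A per-cell series with one constant value."""
    return pd.Series(value, index=cell_index())


def flat_schedule(new: dict[str, float] | float,
                  mon: dict[str, float] | float | None = None,
                  lt_initial: float = 0.0, lt_subsequent: float = 0.0,
                  research_pool: float = 0.0) -> CostSchedule:
    """Unit-cost schedule with one per-person total per stage and status,
    spread evenly over the four categories."""
    def as_dict(x):
        if x is None:
            return None
        if not isinstance(x, dict):
            return {s: float(x) for s in COSTED_STAGES}
        return x

    new, mon = as_dict(new), as_dict(mon)
    if mon is None:
        mon = new
    cols = pd.MultiIndex.from_product([PATIENT_STATUSES, COST_CATEGORIES],
                                      names=["status", "category"])
    uc = pd.DataFrame(0.0, index=list(COSTED_STAGES), columns=cols)
    share = 1.0 / len(COST_CATEGORIES)
    for stage in COSTED_STAGES:
        for status, totals in (("newly_diagnosed", new), ("in_monitoring", mon)):
            for cat in COST_CATEGORIES:
                uc.loc[stage, (status, cat)] = totals.get(stage, 0.0) * share
    return CostSchedule(unit_costs=uc, lt_initial_year=lt_initial,
                        lt_subsequent_year=lt_subsequent,
                        medical_research_pool=research_pool)
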