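"""Human-capital productivity components and bearer attribution."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import flat_series, make_cohort

from coiburden import StageVector
from coiburden.cohort import CohortTable, cell_index
from coiburden.params import LabourParams
from coiburden.productivity import (
    absenteeism_presenteeism_cost,
    allocate_bearers,
    assemble_productivity,
    earnings_lookup,
    forgone_income,
    forgone_income_per_person,
    participation_cost,
    resolve_weeks,
    search_hire_train_cost,
    workforce_exits_by_stage,
)
from coiburden.stages import STAGES


def make_labour(awe=500.0, emp=1.0, tax=0.2, reduction=None, abs_weeks=None,
                pres_weeks=None, sht=0.0, retirement=66) -> LabourParams:
    nan = float("nan")
    return LabourParams(
        employment_rate=flat_series(emp),
        weekly_earnings=flat_series(awe),
        reduced_participation=reduction or StageVector({}),
        absenteeism_weeks=abs_weeks or StageVector({"F4CC": 0.0}, fill=nan),
        presenteeism_weeks=pres_weeks or StageVector({"F4CC": 0.0}, fill=nan),
        effective_tax_rate=tax,
        retirement_age=retirement,
        search_hire_train_cost=sht,
    )


class TestEarningsLookup:
    def test_expected_weekly_value(self):
        labour = make_labour(awe=600.0, emp=0.75)
        assert (earnings_lookup(labour) == 450.0).all()

    def test_zero_employment_zero_value(self):
        labour = make_labour(awe=600.0, emp=0.0)
        assert (earnings_lookup(labour) == 0.0).all()

    def test_cellwise_product(self, uk_bundle):
        labour = uk_bundle.labour
        got = earnings_lookup(labour)
        for cell in [("20-24", "male"), ("45-49", "female"), ("90+", "male")]:
            assert got[cell] == pytest.approx(
                labour.weekly_earnings[cell] * labour.employment_rate[cell])


class TestParticipation:
    def test_exit_valued_at_full_year_of_earnings(self):
        labour = make_labour(awe=500.0,
                             reduction=StageVector({"DCC": 0.1}))
        diagnosed = make_cohort({"DCC": 100.0})
        cost = participation_cost(labour, diagnosed)
        assert cost["DCC"] == pytest.approx(260_000.0)

    def test_no_reduction_no_cost(self):
        labour = make_labour(awe=500.0)
        diagnosed = make_cohort({"DCC": 100.0})
        assert participation_cost(labour, diagnosed).sum() == 0.0

    def test_retired_cells_excluded(self):
        labour = make_labour(awe=500.0, reduction=StageVector({"DCC": 0.1}))
        diagnosed = make_cohort({"DCC": 100.0}, band="70-74")
        assert participation_cost(labour, diagnosed).sum() == 0.0


class TestAbsenteeismPresenteeism:
    def test_weeks_times_expected_earnings(self):
        labour = make_labour(
            awe=400.0, emp=1.0,
            abs_weeks=StageVector({"F2": 2.0, "F4CC": 1.0}, fill=float("nan")),
            pres_weeks=StageVector({"F4CC": 0.0}, fill=float("nan")))
        diagnosed = make_cohort({"F2": 10.0})
        out = absenteeism_presenteeism_cost(labour, diagnosed)
        assert out.loc["F2", "absenteeism"] == pytest.approx(8_000.0)

    def test_zero_weeks_zero_cost(self):
        labour = make_labour(awe=400.0)
        diagnosed = make_cohort({s: 10.0 for s in STAGES})
        assert absenteeism_presenteeism_cost(labour, diagnosed).to_numpy().sum() == 0.0

    def test_f4cc_weeks_extrapolate_to_esld(self):
        nan = float("nan")
        labour = make_labour(
            awe=400.0, emp=0.8,
            abs_weeks=StageVector({"F0": 1.0, "F4CC": 4.0}, fill=nan),
            pres_weeks=StageVector({"F0": 2.0, "F4CC": 9.0}, fill=nan))
        dcc = make_cohort({"DCC": 10.0})
        f4 = make_cohort({"F4CC": 10.0})
        out_dcc = absenteeism_presenteeism_cost(labour, dcc)
        out_f4 = absenteeism_presenteeism_cost(labour, f4)
        assert out_dcc.loc["DCC", "absenteeism"] == pytest.approx(
            out_f4.loc["F4CC", "absenteeism"])
        assert out_dcc.loc["DCC", "presenteeism"] == pytest.approx(
            out_f4.loc["F4CC", "presenteeism"])
        weeks = resolve_weeks(labour.absenteeism_weeks)
        assert weeks["HCC"] == 4.0 and weeks["LT"] == 4.0


class TestForgoneIncome:
    def test_decedent_at_retirement_contributes_nothing(self):
        assert forgone_income_per_person(20_000.0, 0.0, 0.03) == 0.0

    def test_undiscounted_sum(self):
        assert forgone_income_per_person(20_000.0, 10.0, 0.0) == \
            pytest.approx(200_000.0)

    def test_closed_form_annuity(self):
        expected = 20_000.0 * (1 - 1.03 ** -10) / 0.03
        assert forgone_income_per_person(20_000.0, 10.0, 0.03) == \
            pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(170_604, abs=1.0)

    def test_zero_above_retirement_and_nonincreasing_in_age(self):
        labour = make_labour(awe=500.0, emp=0.8)
        values = []
        for band in ("25-29", "40-44", "55-59", "60-64", "70-74"):
            deaths = make_cohort({"DEATH": 1.0}, band=band)
            values.append(forgone_income(deaths, labour, 0.03).sum())
        assert values == sorted(values, reverse=True)
        assert values[-1] == 0.0

    def test_decreasing_in_discount_rate(self):
        deaths = make_cohort({"DEATH": 5.0}, band="30-34")
        labour = make_labour(awe=500.0, emp=0.8)
        low = forgone_income(deaths, labour, 0.01).sum()
        high = forgone_income(deaths, labour, 0.05).sum()
        assert high < low


class TestSearchHireTrain:
    def test_product(self):
        assert search_hire_train_cost(100.0, 2_000.0) == 200_000.0
        assert search_hire_train_cost(0.0, 2_000.0) == 0.0

    def test_exits_count_employed_decedents(self):
        labour = make_labour(awe=500.0, emp=0.6,
                             reduction=StageVector({"DCC": 0.1}))
        diagnosed = make_cohort({"DCC": 50.0})
        deaths = make_cohort({"DEATH": 10.0}, band="40-44")
        exits = workforce_exits_by_stage(labour, diagnosed, deaths)
        assert exits["DCC"] == pytest.approx(5.0)     # 50 x 0.1
        assert exits["DEATH"] == pytest.approx(6.0)   # 10 x 0.6


class TestBearers:
    def test_zero_tax_means_no_government_share(self):
        labour = make_labour(awe=500.0, tax=0.0,
                             reduction=StageVector({"DCC": 0.1}))
        diagnosed = make_cohort({"DCC": 100.0})
        deaths = make_cohort({"DEATH": 3.0})
        res = assemble_productivity(labour, diagnosed, deaths, 0.03)
        res = allocate_bearers(res, 0.0)
        assert res.bearer_totals["government"] == 0.0

    def test_bearers_conserve_total(self, uk_bundle):
        from coiburden.scenarios import run_scenario
        res = run_scenario(uk_bundle, "higher", "base").productivity
        assert sum(res.bearer_totals.values()) == pytest.approx(
            res.grand_total, rel=1e-9)

    def test_calibrated_shares_near_published_split(self, calibrated_bundle):
        # published bearer split is 22% government / 46% employers /
        # 32% individuals; the synthetic calibration should sit within
        # ten percentage points of each
        from coiburden.scenarios import run_scenario
        res = run_scenario(calibrated_bundle, "higher", "base").productivity
        total = res.grand_total
        shares = {k: v / total for k, v in res.bearer_totals.items()}
        assert shares["government"] == pytest.approx(0.22, abs=0.10)
        assert shares["employers"] == pytest.approx(0.46, abs=0.10)
        assert shares["individuals"] == pytest.approx(0.32, abs=0.10)


class TestDegenerateEconomy:
    def test_zero_earnings_zero_productivity(self):
        # no market earnings and no replacement friction: every component
        # must vanish
        labour = make_labour(awe=0.0, emp=0.8, sht=0.0,
                             reduction=StageVector({"DCC": 0.2}),
                             abs_weeks=StageVector({"F4CC": 3.0},
                                                   fill=float("nan")),
                             pres_weeks=StageVector({"F4CC": 8.0},
                                                    fill=float("nan")))
        diagnosed = make_cohort({s: 25.0 for s in STAGES})
        deaths = make_cohort({"DEATH": 10.0})
        res = assemble_productivity(labour, diagnosed, deaths, 0.03)
        assert res.grand_total == 0.0
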