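"""Health-system costing: unit-cost application, research pool, payers."""

import numpy as np
import pytest

from conftest import flat_schedule, make_cohort

from coiburden.health_costs import (
    add_medical_research,
    allocate_payers,
    stage_health_costs,
)
from coiburden.params import PayerSplit
from coiburden.stages import COSTED_STAGES


class TestStageHealthCosts:
    def test_new_and_monitoring_unit_costs_apply(self):
        schedule = flat_schedule(new=500.0, mon=200.0)
        newly = make_cohort({"F2": 10.0})
        mon = make_cohort({"F2": 40.0})
        res = stage_health_costs(schedule, newly, mon)
        assert res.total_by_stage()["F2"] == pytest.approx(13_000.0)
        assert res.grand_total == pytest.approx(13_000.0)

    def test_zero_population_zero_cost(self):
        schedule = flat_schedule(new=500.0, mon=200.0, lt_initial=70e3,
                                 lt_subsequent=15e3)
        from coiburden.cohort import CohortTable
        res = stage_health_costs(schedule, CohortTable.zeros(),
                                 CohortTable.zeros())
        assert res.grand_total == 0.0

    def test_matches_per_stage_hand_sum(self):
        new_costs = {s: 100.0 + 10.0 * i for i, s in enumerate(COSTED_STAGES)}
        mon_costs = {s: 50.0 + 5.0 * i for i, s in enumerate(COSTED_STAGES)}
        schedule = flat_schedule(new=new_costs, mon=mon_costs,
                                 lt_initial=70e3, lt_subsequent=15e3)
        n_new = {s: 3.0 + i for i, s in enumerate(COSTED_STAGES)}
        n_mon = {s: 7.0 + 2 * i for i, s in enumerate(COSTED_STAGES)}
        newly = make_cohort(dict(n_new))
        mon = make_cohort({**n_mon, "LT": 4.0})
        res = stage_health_costs(schedule, newly, mon)
        hand = sum(new_costs[s] * n_new[s] + mon_costs[s] * n_mon[s]
                   for s in COSTED_STAGES)
        hand += 70e3 * 0.0 + 15e3 * 4.0  # LT: no in-year transplants
        assert res.grand_total == pytest.approx(hand, rel=1e-12)

    def test_transplant_year_uses_initial_cost(self):
        schedule = flat_schedule(new=0.0, mon=0.0, lt_initial=70e3,
                                 lt_subsequent=15e3)
        from coiburden.cohort import CohortTable
        tx = make_cohort({"LT": 2.0})
        mon = make_cohort({"LT": 5.0})
        res = stage_health_costs(schedule, CohortTable.zeros(), mon,
                                 transplants=tx)
        assert res.total_by_stage()["LT"] == pytest.approx(
            2 * 70e3 + 5 * 15e3)


class TestMedicalResearchPool:
    def test_per_person_uplift_depends_on_population(self):
        schedule = flat_schedule(new=100.0)
        base_small = stage_health_costs(schedule, make_cohort({"F2": 0.0}),
                                        make_cohort({"F2": 250_000.0}))
        base_large = stage_health_costs(schedule, make_cohort({"F2": 0.0}),
                                        make_cohort({"F2": 500_000.0}))
        small = add_medical_research(base_small, 10e6, 250_000.0)
        large = add_medical_research(base_large, 10e6, 500_000.0)
        uplift_small = small.per_person_by_stage()["F2"] - 100.0
        uplift_large = large.per_person_by_stage()["F2"] - 100.0
        assert uplift_small == pytest.approx(40.0)
        assert uplift_large == pytest.approx(20.0)
        # total uplift is scenario-invariant
        assert small.grand_total - base_small.grand_total == pytest.approx(10e6)
        assert large.grand_total - base_large.grand_total == pytest.approx(10e6)

    def test_zero_pool_is_identity(self):
        schedule = flat_schedule(new=100.0)
        base = stage_health_costs(schedule, make_cohort({"F0": 5.0}),
                                  make_cohort({"F0": 5.0}))
        out = add_medical_research(base, 0.0, 10.0)
        assert out.grand_total == base.grand_total

    def test_pool_with_no_diagnosed_rejected(self):
        schedule = flat_schedule(new=100.0)
        from coiburden.cohort import CohortTable
        base = stage_health_costs(schedule, CohortTable.zeros(),
                                  CohortTable.zeros())
        with pytest.raises(ValueError, match="zero diagnosed"):
            add_medical_research(base, 1e6, 0.0)

    def test_pool_total_conserved_exactly(self, uk_bundle):
        from coiburden.scenarios import run_scenario
        res = run_scenario(uk_bundle, "higher", "base")
        pool = uk_bundle.cost_schedule.medical_research_pool
        from coiburden.health_costs import RESEARCH_CATEGORY
        assert res.health.total_by_category()[RESEARCH_CATEGORY] == \
            pytest.approx(pool, rel=1e-12)


class TestPayerAllocation:
    def test_published_split(self):
        schedule = flat_schedule(new=1.0)
        base = stage_health_costs(schedule, make_cohort({"F0": 100e6}),
                                  make_cohort({}))
        split = PayerSplit(fractions={"government": 0.79,
                                      "individuals_families": 0.15,
                                      "other": 0.06})
        out = allocate_payers(base, split)
        assert out.payer_totals["government"] == pytest.approx(79e6)
        assert out.payer_totals["individuals_families"] == pytest.approx(15e6)
        assert out.payer_totals["other"] == pytest.approx(6e6)

    def test_degenerate_split_all_government(self):
        schedule = flat_schedule(new=10.0)
        base = stage_health_costs(schedule, make_cohort({"F1": 3.0}),
                                  make_cohort({}))
        out = allocate_payers(base, PayerSplit(fractions={
            "government": 1.0, "individuals_families": 0.0, "other": 0.0}))
        assert out.payer_totals["government"] == pytest.approx(base.grand_total)

    def test_payers_conserve_grand_total(self, uk_bundle):
        from coiburden.scenarios import run_scenario
        res = run_scenario(uk_bundle, "higher", "base")
        assert sum(res.health.payer_totals.values()) == pytest.approx(
            res.health.grand_total, rel=1e-9)


class TestLinearity:
    def test_doubling_population_doubles_pre_pool_costs(self):
        schedule = flat_schedule(new={s: 100.0 + 7 * i for i, s in
                                      enumerate(COSTED_STAGES)},
                                 mon=80.0, lt_initial=70e3, lt_subsequent=15e3)
        newly = make_cohort({"F2": 11.0, "F4CC": 5.0})
        mon = make_cohort({"F2": 29.0, "LT": 2.0})
        single = stage_health_costs(schedule, newly, mon)
        double = stage_health_costs(schedule, newly.scale(2), mon.scale(2))
        assert double.grand_total == pytest.approx(2 * single.grand_total,
                                                   rel=1e-12)
        # with the fixed pool added, totals increase by the doubled
        # pre-pool amount only
        with_pool_1 = add_medical_research(single, 5e4, single.diagnosed_by_stage.sum())
        with_pool_2 = add_medical_research(double, 5e4, double.diagnosed_by_stage.sum())
        assert with_pool_2.grand_total - with_pool_1.grand_total == \
            pytest.approx(single.grand_total, rel=1e-9)

    def test_secondary_care_and_diagnostics_dominate(self, calibrated_bundle):
        from coiburden.scenarios import run_scenario
        res = run_scenario(calibrated_bundle, "higher", "base")
        cats = res.health.total_by_category().drop("medical_research")
        top_two = set(cats.sort_values(ascending=False).index[:2])
        assert top_two == {"secondary_care", "diagnostics"}
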