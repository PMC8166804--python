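"""Population construction: prevalence, diagnosis, splits, deaths, transplants."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import make_cohort

from coiburden import StageVector
from coiburden.cohort import AGE_BANDS, DemographicTable, cell_index
from coiburden.epidemiology import (
    attributable_mortality,
    build_population_state,
    diagnosed_population,
    liver_transplants,
    overall_diagnosed_share,
    prevalent_population,
    split_new_vs_monitoring,
)
from coiburden.params import published_fixture
from coiburden.stages import LIVING_STAGES, STAGES


class TestPrevalentPopulation:
    def test_total_is_rate_times_adult_population(self, uk_bundle):
        demo = uk_bundle.demographics.scale(
            50_000_000 / uk_bundle.demographics.total)
        sc = dataclasses.replace(uk_bundle.prevalence["higher"],
                                 overall_rate=0.041)
        table = prevalent_population(sc, demo)
        assert table.total() == pytest.approx(2_050_000, rel=1e-6)

    def test_vanishing_rate_gives_vanishing_table(self, uk_bundle):
        sc = dataclasses.replace(uk_bundle.prevalence["higher"],
                                 overall_rate=1e-15)
        table = prevalent_population(sc, uk_bundle.demographics)
        assert table.total() < 1.0

    def test_marginals_reproduce_input_distributions(self, uk_bundle):
        sc = uk_bundle.prevalence["higher"]
        table = prevalent_population(sc, uk_bundle.demographics)
        total = table.total()
        # stage marginal
        stage_marginal = table.stage_totals()
        for s in LIVING_STAGES:
            assert stage_marginal[s] == pytest.approx(
                total * sc.stage_distribution[s], rel=1e-9)
        # sex marginal
        by_sex = table.data.groupby(level="sex").sum().sum(axis=1)
        for sex, share in sc.sex_distribution.items():
            assert by_sex[sex] == pytest.approx(total * share, rel=1e-9)
        # age marginal within each stage
        for s in ("F0", "DCC"):
            by_age = table.data[s].groupby(level="age_band").sum()
            for band in AGE_BANDS:
                expected = (total * sc.stage_distribution[s]
                            * sc.age_distribution.loc[s, band])
                assert by_age[band] == pytest.approx(expected, abs=1e-9 * total)


class TestDiagnosedPopulation:
    def test_f2_sixteen_point_five_percent(self, uk_bundle):
        prevalent = make_cohort({"F2": 1000.0})
        diag = diagnosed_population(prevalent, uk_bundle.diagnosis["base"])
        assert diag.stage_totals()["F2"] == pytest.approx(165.0)

    def test_certain_diagnosis_is_identity(self, uk_bundle):
        prevalent = make_cohort({s: 37.0 for s in STAGES})
        profile = dataclasses.replace(
            uk_bundle.diagnosis["base"],
            probability=StageVector([1.0] * len(STAGES)))
        assert diagnosed_population(prevalent, profile).allclose(prevalent)

    def test_uniform_prevalence_gives_mean_probability_share(self, uk_bundle):
        # 100 persons in each of the nine states; overall diagnosed share is
        # the plain mean of the base probabilities, computed by hand
        p = published_fixture().diagnosis_base
        hand_mean = sum(p[s] for s in STAGES) / len(STAGES)
        prevalent = make_cohort({s: 100.0 for s in STAGES})
        diag = diagnosed_population(prevalent, uk_bundle.diagnosis["base"])
        assert overall_diagnosed_share(prevalent, diag) == pytest.approx(
            hand_mean, rel=1e-12)
        assert hand_mean == pytest.approx((0.02 + 0.02 + 0.165 + 0.5825 + 5.0) / 9)


class TestNewVersusMonitoring:
    def test_proportional_split(self):
        diagnosed = make_cohort({"F2": 200.0})
        newly, mon = split_new_vs_monitoring(
            diagnosed, StageVector({"F2": 0.25}))
        assert newly.stage_totals()["F2"] == pytest.approx(50.0)
        assert mon.stage_totals()["F2"] == pytest.approx(150.0)

    def test_full_incidence_means_all_newly_diagnosed(self):
        diagnosed = make_cohort({"F0": 80.0})
        newly, mon = split_new_vs_monitoring(
            diagnosed, StageVector([1.0] * len(STAGES)))
        assert newly.allclose(diagnosed)
        assert mon.total() == 0.0

    def test_split_conserves_diagnosed(self, small_bundle):
        from coiburden.scenarios import run_scenario
        res = run_scenario(small_bundle, "higher", "base")
        recombined = res.population.newly_diagnosed + res.population.in_monitoring
        assert recombined.allclose(res.population.diagnosed, rtol=1e-12)

    def test_incidence_outside_unit_interval_rejected(self):
        diagnosed = make_cohort({"F0": 10.0})
        with pytest.raises(ValueError):
            split_new_vs_monitoring(diagnosed, StageVector({"F0": 1.2}))


class TestAttributableMortality:
    def test_headline_death_count(self, uk_bundle):
        # 0.023% of ~52.65m adults is the printed 12,110 deaths
        demo = uk_bundle.demographics.scale(
            52_652_174 / uk_bundle.demographics.total)
        liver, cvd = attributable_mortality(
            0.00023, demo, 0.60, uk_bundle.mortality.age_sex_distribution)
        assert (liver + cvd).total() == pytest.approx(12_110, abs=0.5)

    def test_cvd_share_partitions_deaths(self, uk_bundle):
        demo = uk_bundle.demographics.scale(
            1000 / (0.001 * uk_bundle.demographics.total))
        liver, cvd = attributable_mortality(
            0.001, demo, 0.60, uk_bundle.mortality.age_sex_distribution)
        assert cvd.total() == pytest.approx(600.0)
        assert liver.total() == pytest.approx(400.0)

    def test_zero_cvd_share_is_all_liver(self, uk_bundle):
        liver, cvd = attributable_mortality(
            0.0001, uk_bundle.demographics, 0.0,
            uk_bundle.mortality.age_sex_distribution)
        assert cvd.total() == 0.0
        assert liver.total() > 0.0


class TestLiverTransplants:
    def test_mass_at_or_above_cap_is_renormalised_away(self):
        idx = cell_index()
        dist = pd.Series(0.0, index=idx)
        for band in ("40-44", "55-59", "65-69", "70-74"):
            dist[(band, "male")] = 0.25
        table = liver_transplants(100.0, 1.0, dist, age_cap=70)
        by_band = table.data["LT"].groupby(level="age_band").sum()
        for band in ("40-44", "55-59", "65-69"):
            assert by_band[band] == pytest.approx(100.0 / 3)
        assert by_band["70-74"] == 0.0

    def test_zero_share_zero_table(self, uk_bundle):
        dist = uk_bundle.demographics.age_sex_distribution()
        assert liver_transplants(900.0, 0.0, dist).total() == 0.0

    def test_total_is_conserved(self, uk_bundle):
        dist = uk_bundle.demographics.age_sex_distribution()
        table = liver_transplants(900.0, 0.1, dist, age_cap=70)
        assert table.total() == pytest.approx(90.0, rel=1e-9)

    def test_no_eligible_mass_raises(self):
        dist = pd.Series(0.0, index=cell_index())
        dist[("90+", "female")] = 1.0
        with pytest.raises(ValueError, match="age cap"):
            liver_transplants(10.0, 1.0, dist, age_cap=70)


class TestPopulationStateProperties:
    def test_diagnosed_never_exceeds_prevalent(self, small_bundle):
        from coiburden.scenarios import run_scenario
        res = run_scenario(small_bundle, "higher", "base")
        gap = res.population.prevalent.data - res.population.diagnosed.data
        assert (gap.to_numpy() >= -1e-9).all()

    def test_transplants_zero_from_age_seventy(self, small_bundle):
        from coiburden.scenarios import run_scenario
        res = run_scenario(small_bundle, "higher", "base")
        tx = res.population.transplants.data["LT"]
        for (band, sex), v in tx.items():
            if int(band.rstrip("+").split("-")[0]) >= 70:
                assert v == 0.0

    def test_monotone_in_diagnosis_probability(self, small_bundle):
        base = build_population_state(
            small_bundle.prevalence["higher"], small_bundle.diagnosis["base"],
            small_bundle.demographics, small_bundle.incidence,
            small_bundle.mortality, small_bundle.transplants)
        bumped_profile = dataclasses.replace(
            small_bundle.diagnosis["base"],
            probability=StageVector(np.minimum(
                small_bundle.diagnosis["base"].probability.values * 1.5, 1.0)))
        bumped = build_population_state(
            small_bundle.prevalence["higher"], bumped_profile,
            small_bundle.demographics, small_bundle.incidence,
            small_bundle.mortality, small_bundle.transplants)
        diff = bumped.diagnosed.data - base.diagnosed.data
        assert (diff.to_numpy() >= -1e-12).all()
        assert bumped.diagnosed.total() > base.diagnosed.total()

    def test_homogeneous_in_population_scale(self, small_bundle):
        k = 3.0
        base = build_population_state(
            small_bundle.prevalence["higher"], small_bundle.diagnosis["base"],
            small_bundle.demographics, small_bundle.incidence,
            small_bundle.mortality, small_bundle.transplants)
        scaled = build_population_state(
            small_bundle.prevalence["higher"], small_bundle.diagnosis["base"],
            small_bundle.demographics.scale(k), small_bundle.incidence,
            small_bundle.mortality, small_bundle.transplants)
        # transplants are an external count, so compare the modelled tables
        for name in ("prevalent", "diagnosed", "newly_diagnosed",
                     "in_monitoring", "deaths_liver", "deaths_cvd"):
            a = getattr(base, name).data.to_numpy()
            b = getattr(scaled, name).data.to_numpy()
            assert np.allclose(b, k * a, rtol=1e-12)
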