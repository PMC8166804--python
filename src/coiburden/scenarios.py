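"""Scenario runs, the full-diagnosis counterfactual and one-way sensitivity.

A scenario is a (prevalence, diagnosis) label pair.  ``run_scenario``
threads one pair through the whole pipeline -- populations, health costs,
productivity, other costs, burden -- and assembles a
:class:`ScenarioResult` whose grand economic total is

    health + productivity + carer + deadweight loss + funeral,

with welfare transfer face values excluded (only their deadweight loss is
a resource cost).  Runs are deterministic: identical bundles yield
bit-identical results, and each result carries the bundle hash for
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import health_costs as hc
from . import other_costs as oc
from . import productivity as prod_mod
from .burden import BurdenResult
from .epidemiology import PopulationState, build_population_state
from .health_costs import HealthCostResult
from .other_costs import OtherCostResult
from .params import (
    DiagnosisProfile,
    ParameterBundle,
    bundle_to_mapping,
)
from .productivity import ProductivityResult
from .stages import ESLD_STAGES, STAGES, StageVector

#: Economic cost components, in reporting order.
ECONOMIC_COMPONENTS: tuple[str, ...] = (
    "health_system",
    "productivity",
    "carer",
    "other",  # funeral costs brought forward
    "deadweight_loss",
)


def bundle_hash(bundle: ParameterBundle) -> str:
    """SHA-256 of the serialised bundle (provenance for scenario outputs)."""
    payload = yaml.safe_dump(bundle_to_mapping(bundle), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class ScenarioResult:
    """Full nested results for one (prevalence, diagnosis) combination."""

    prevalence_label: str
    diagnosis_label: str
    population: PopulationState
    health: HealthCostResult
    productivity: ProductivityResult
    other: OtherCostResult
    burden: BurdenResult
    dwl_by_stage: pd.Series = field(repr=False)
    metadata: dict = field(default_factory=dict)

    # -- headline totals ---------------------------------------------------
    @property
    def diagnosed_total(self) -> float:
        return self.population.diagnosed.total()

    @property
    def undiagnosed_share(self) -> float:
        prev = self.population.prevalent.total()
        return 1.0 - self.diagnosed_total / prev if prev else 0.0

    @property
    def economic_total(self) -> float:
        return (
            self.health.grand_total
            + self.productivity.grand_total
            + self.other.economic_total
        )

    @property
    def wellbeing_total(self) -> float:
        return self.burden.wellbeing_total

    @property
    def dalys_total(self) -> float:
        return self.burden.dalys_total

    @property
    def per_person_economic(self) -> float:
        n = self.diagnosed_total
        return self.economic_total / n if n else 0.0

    @property
    def per_person_wellbeing(self) -> float:
        n = self.diagnosed_total
        return self.wellbeing_total / n if n else 0.0

    # -- stage breakdowns --------------------------------------------------
    def economic_by_component_stage(self) -> pd.DataFrame:
        """Component x stage economic totals (GBP)."""
        out = pd.DataFrame(0.0, index=list(ECONOMIC_COMPONENTS),
                           columns=list(STAGES))
        out.loc["health_system"] = self.health.total_by_stage().values
        out.loc["productivity"] = self.productivity.total_by_stage().values
        out.loc["carer"] = self.other.carer_by_stage().values
        out.loc["other", "DEATH"] = self.other.funeral
        out.loc["deadweight_loss"] = self.dwl_by_stage.reindex(
            list(STAGES)).fillna(0.0).values
        return out

    def economic_by_stage(self) -> StageVector:
        return StageVector(self.economic_by_component_stage().sum(axis=0).to_numpy())

    def per_person_economic_by_stage(self) -> StageVector:
        totals = self.economic_by_stage().values
        counts = self.population.diagnosed.stage_totals().values
        pp = np.where(counts > 0, totals / np.where(counts > 0, counts, 1.0), 0.0)
        return StageVector(pp)

    def validate(self, rtol: float = 1e-6) -> None:
        """Cross-check the nested totals for conservation."""
        comp = self.economic_by_component_stage()
        assert np.isclose(comp.to_numpy().sum(), self.economic_total,
                          rtol=rtol), "component breakdown != economic total"
        if self.health.payer_totals is not None:
            assert np.isclose(sum(self.health.payer_totals.values()),
                              self.health.grand_total, rtol=rtol)
        if self.productivity.bearer_totals is not None:
            assert np.isclose(sum(self.productivity.bearer_totals.values()),
                              self.productivity.grand_total, rtol=rtol)
        self.population.validate(tol=max(rtol, 1e-9) * max(1.0, self.diagnosed_total))


def run_scenario(
    bundle: ParameterBundle,
    prevalence_label: str = "higher",
    diagnosis_label: str = "base",
) -> ScenarioResult:
    """Run the full pipeline for one scenario combination."""
    if prevalence_label not in bundle.prevalence:
        raise KeyError(
            f"prevalence scenario {prevalence_label!r} not in bundle "
            f"(have {sorted(bundle.prevalence)})"
        )
    if diagnosis_label not in bundle.diagnosis:
        raise KeyError(
            f"diagnosis scenario {diagnosis_label!r} not in bundle "
            f"(have {sorted(bundle.diagnosis)})"
        )
    scenario = bundle.prevalence[prevalence_label]
    profile = bundle.diagnosis[diagnosis_label]

    state = build_population_state(
        scenario, profile, bundle.demographics, bundle.incidence,
        bundle.mortality, bundle.transplants,
    )

    health = hc.stage_health_costs(
        bundle.cost_schedule, state.newly_diagnosed, state.in_monitoring,
        transplants=state.transplants,
    )
    health = hc.add_medical_research(
        health, bundle.cost_schedule.medical_research_pool,
        state.diagnosed.total(),
    )
    health = hc.allocate_payers(health, bundle.payer_split)

    productivity = prod_mod.assemble_productivity(
        bundle.labour, state.diagnosed, state.deaths,
        bundle.burden.discount_rate,
    )
    productivity = prod_mod.allocate_bearers(
        productivity, bundle.labour.effective_tax_rate)

    tax_forgone = productivity.bearer_totals["government"]
    govt_health = health.payer_totals["government"]
    other = oc.assemble_other_costs(
        bundle.other_costs, state.diagnosed, state.deaths,
        bundle.burden.life_table, bundle.burden.discount_rate,
        tax_forgone=tax_forgone, govt_health_spend=govt_health,
    )

    dwl_stage = _dwl_by_stage(bundle, state, health, productivity, other)

    burden = burden_mod.assemble_burden(state.diagnosed, state.deaths,
                                        bundle.burden)

    result = ScenarioResult(
        prevalence_label=prevalence_label,
        diagnosis_label=diagnosis_label,
        population=state,
        health=health,
        productivity=productivity,
        other=other,
        burden=burden,
        dwl_by_stage=dwl_stage,
        metadata={
            "bundle_hash": bundle_hash(bundle),
            "prevalence": prevalence_label,
            "diagnosis": diagnosis_label,
        },
    )
    result.validate()
    return result


def _dwl_by_stage(bundle, state, health, productivity, other) -> pd.Series:
    """Allocate total DWL over stages proportionally to the distortion base.

    The base per stage combines forgone tax on that stage's productivity
    losses, transfers to its ESLD patients, and the government share of
    its health costs.  Purely a reporting allocation; the total is fixed.
    """
    tax = bundle.labour.effective_tax_rate
    earnings_like = (
        productivity.component_by_stage[
            ["participation", "absenteeism", "presenteeism", "forgone_income"]
        ].sum(axis=1)
    )
    base = tax * earnings_like
    gov_share = bundle.payer_split.fractions["government"]
    if bundle.other_costs.include_government_health_in_dwl:
        base = base + gov_share * pd.Series(
            health.total_by_stage().values, index=list(STAGES))
    esld_counts = pd.Series(
        {s: state.diagnosed.stage_totals()[s] for s in ESLD_STAGES})
    if esld_counts.sum() > 0:
        transfer_alloc = other.transfers_total * esld_counts / esld_counts.sum()
        base = base.add(transfer_alloc, fill_value=0.0)
    total_base = base.sum()
    if total_base <= 0:
        return pd.Series(0.0, index=list(STAGES))
    return other.dwl * base.reindex(list(STAGES)).fillna(0.0) / total_base


def full_diagnosis_counterfactual(
    bundle: ParameterBundle, prevalence_label: str = "higher"
) -> ScenarioResult:
    """Re-run a prevalence scenario with every diagnosis probability at 1."""
    label = "full_diagnosis"
    profile = DiagnosisProfile(label=label,
                               probability=StageVector([1.0] * len(STAGES)))
    cf = bundle.replace(diagnosis={**bundle.diagnosis, label: profile})
    return run_scenario(cf, prevalence_label, label)


# ---------------------------------------------------------------------------
# one-way sensitivity
# ---------------------------------------------------------------------------

def _clip01(v: StageVector) -> StageVector:
    return StageVector(np.clip(v.values, 0.0, 1.0))


def _scale_sv(v: StageVector, f: float, clip_hi: Optional[float] = None) -> StageVector:
    vals = v.values * f
    if clip_hi is not None:
        vals = np.clip(vals, 0.0, clip_hi)
    return StageVector(vals)


def _perturb_prevalence(bundle: ParameterBundle, f: float) -> ParameterBundle:
    new = {
        label: dataclasses.replace(
            sc, overall_rate=min(sc.overall_rate * f, 1.0 - 1e-12))
        for label, sc in bundle.prevalence.items()
    }
    return bundle.replace(prevalence=new)


def _perturb_diagnosis(bundle: ParameterBundle, f: float) -> ParameterBundle:
    new = {
        label: dataclasses.replace(
            pr, probability=_scale_sv(pr.probability, f, clip_hi=1.0))
        for label, pr in bundle.diagnosis.items()
    }
    return bundle.replace(diagnosis=new)


def _perturb_schedule(bundle: ParameterBundle, f: float) -> ParameterBundle:
    cs = bundle.cost_schedule
    new = dataclasses.replace(
        cs,
        unit_costs=cs.unit_costs * f,
        lt_initial_year=cs.lt_initial_year * f,
        lt_subsequent_year=cs.lt_subsequent_year * f,
    )
    return bundle.replace(cost_schedule=new)


#: Perturbable scalar parameters: name -> bundle transform at factor f.
#: Fractions are clipped to their domain (a probability of 1 stays 1).
PERTURBATIONS: dict[str, Callable[[ParameterBundle, float], ParameterBundle]] = {
    "prevalence_rate": _perturb_prevalence,
    "diagnosis_probability": _perturb_diagnosis,
    "health_unit_costs": _perturb_schedule,
    "medical_research_pool": lambda b, f: b.replace(
        cost_schedule=dataclasses.replace(
            b.cost_schedule,
            medical_research_pool=b.cost_schedule.medical_research_pool * f)),
    "weekly_earnings": lambda b, f: b.replace(
        labour=dataclasses.replace(b.labour,
                                   weekly_earnings=b.labour.weekly_earnings * f)),
    "employment_rate": lambda b, f: b.replace(
        labour=dataclasses.replace(
            b.labour,
            employment_rate=(b.labour.employment_rate * f).clip(upper=1.0))),
    "reduced_participation": lambda b, f: b.replace(
        labour=dataclasses.replace(
            b.labour,
            reduced_participation=_scale_sv(b.labour.reduced_participation, f,
                                            clip_hi=1.0))),
    "absenteeism_weeks": lambda b, f: b.replace(
        labour=dataclasses.replace(
            b.labour,
            absenteeism_weeks=_scale_sv(b.labour.absenteeism_weeks, f,
                                        clip_hi=52.0))),
    "presenteeism_weeks": lambda b, f: b.replace(
        labour=dataclasses.replace(
            b.labour,
            presenteeism_weeks=_scale_sv(b.labour.presenteeism_weeks, f,
                                         clip_hi=52.0))),
    "search_hire_train_cost": lambda b, f: b.replace(
        labour=dataclasses.replace(
            b.labour,
            search_hire_train_cost=b.labour.search_hire_train_cost * f)),
    "mortality_rate": lambda b, f: b.replace(
        mortality=dataclasses.replace(
            b.mortality,
            rate_per_prevalent=min(b.mortality.rate_per_prevalent * f,
                                   1.0 - 1e-12))),
    "transplants": lambda b, f: b.replace(
        transplants=dataclasses.replace(
            b.transplants, total_elective=b.transplants.total_elective * f)),
    "formal_care_cost": lambda b, f: b.replace(
        other_costs=dataclasses.replace(
            b.other_costs,
            formal_care_annual_cost=b.other_costs.formal_care_annual_cost * f)),
    "informal_care_hours": lambda b, f: b.replace(
        other_costs=dataclasses.replace(
            b.other_costs,
            informal_care_hours_per_week=(
                b.other_costs.informal_care_hours_per_week * f))),
    "carer_hourly_earnings": lambda b, f: b.replace(
        other_costs=dataclasses.replace(
            b.other_costs,
            carer_hourly_earnings=b.other_costs.carer_hourly_earnings * f)),
    "dwl_rate": lambda b, f: b.replace(
        other_costs=dataclasses.replace(
            b.other_costs,
            dwl_rate=min(b.other_costs.dwl_rate * f, 1.0 - 1e-12))),
    "funeral_cost": lambda b, f: b.replace(
        other_costs=dataclasses.replace(
            b.other_costs, funeral_cost=b.other_costs.funeral_cost * f)),
    "disability_weights": lambda b, f: b.replace(
        burden=dataclasses.replace(
            b.burden,
            disability_weight=_scale_sv(b.burden.disability_weight, f,
                                        clip_hi=1.0))),
    "discount_rate": lambda b, f: b.replace(
        burden=dataclasses.replace(
            b.burden, discount_rate=min(b.burden.discount_rate * f,
                                        1.0 - 1e-12))),
    "vsly": lambda b, f: b.replace(
        burden=dataclasses.replace(b.burden, vsly=b.burden.vsly * f)),
}

#: Result metrics one-way sensitivity can target.
METRICS: dict[str, Callable[[ScenarioResult], float]] = {
    "economic_total": lambda r: r.economic_total,
    "wellbeing_total": lambda r: r.wellbeing_total,
    "dalys_total": lambda r: r.dalys_total,
    "combined_total": lambda r: r.economic_total + r.wellbeing_total,
}


def perturb(bundle: ParameterBundle, parameter: str, factor: float) -> ParameterBundle:
    """Return a copy of the bundle with one parameter scaled by ``factor``."""
    try:
        fn = PERTURBATIONS[parameter]
    except KeyError:
        raise KeyError(
            f"unknown perturbable parameter {parameter!r}; "
            f"choose from {sorted(PERTURBATIONS)}"
        ) from None
    return fn(bundle, factor)


def one_way_sensitivity(
    bundle: ParameterBundle,
    parameter_list: Optional[Sequence[str]] = None,
    delta: float = 0.10,
    prevalence_label: str = "higher",
    diagnosis_label: str = "base",
    metric: str = "economic_total",
) -> pd.DataFrame:
    """One-way (tornado) sensitivity: re-run at (1 +/- delta) per parameter.

    Returns a DataFrame with columns parameter/base/low/high/swing sorted
    by descending swing (ties broken by parameter name, so ordering is
    deterministic and reproducible).
    """
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    metric_fn = METRICS[metric]
    params = list(parameter_list) if parameter_list is not None else sorted(PERTURBATIONS)
    base_value = metric_fn(run_scenario(bundle, prevalence_label, diagnosis_label))
    rows = []
    for name in params:
        low = metric_fn(run_scenario(perturb(bundle, name, 1.0 - delta),
                                     prevalence_label, diagnosis_label))
        high = metric_fn(run_scenario(perturb(bundle, name, 1.0 + delta),
                                      prevalence_label, diagnosis_label))
        rows.append({"parameter": name, "base": base_value,
                     "low": low, "high": high, "swing": abs(high - low)})
    out = pd.DataFrame(rows)
    return out.sort_values(["swing", "parameter"],
                           ascending=[False, True]).reset_index(drop=True)


def run_scenario_grid(bundle: ParameterBundle) -> dict[tuple[str, str], ScenarioResult]:
    """Run every (prevalence, diagnosis) combination in the bundle."""
    return {
        (p, d): run_scenario(bundle, p, d)
        for p in sorted(bundle.prevalence)
        for d in sorted(bundle.diagnosis)
    }
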