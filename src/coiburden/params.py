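"""Parameter types, published scalar fixtures and configuration I/O.

All rates are carried internally as fractions (never percent) and all
money as 2018 GBP.  Percentages appear only at the reporting boundary.

The model needs two kinds of inputs:

* **published scalars** -- the handful of headline parameters available in
  print for the UK 2018 analysis (prevalence rates, per-stage diagnosis
  probabilities, the CVD mortality share, disability weights, the discount
  rate, the VSLY, the health payer split).  These ship as
  :func:`published_fixture`.
* **tables** -- demographics, life table, earnings/employment schedules,
  per-stage unit costs and the like, which are not available in print.
  They must be supplied by the user or generated by
  :mod:`coiburden.synthetic`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import AGE_BANDS, SEXES, DemographicTable, cell_index
from .stages import (
    COSTED_STAGES,
    ESLD_STAGES,
    LIVING_STAGES,
    STAGES,
    StageVector,
)

_SUM_TOL = 1e-9

#: Health-system cost categories.
COST_CATEGORIES: tuple[str, ...] = (
    "primary_care",
    "secondary_care",
    "diagnostics",
    "pharmaceuticals",
)

#: Patient statuses carrying distinct unit-cost schedules.
PATIENT_STATUSES: tuple[str, ...] = ("newly_diagnosed", "in_monitoring")

HEALTH_PAYERS: tuple[str, ...] = ("government", "individuals_families", "other")
PRODUCTIVITY_BEARERS: tuple[str, ...] = ("government", "employers", "individuals")


class ParameterError(ValueError):
    """A named parameter violated its constraint."""

    def __init__(self, fieldname: str, message: str) -> None:
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


def _check_fraction(name: str, value: float, lo: float = 0.0, hi: float = 1.0,
                    open_lo: bool = False, open_hi: bool = False) -> float:
    v = float(value)
    if np.isnan(v):
        raise ParameterError(name, "must not be NaN")
    if (v < lo) or (v > hi) or (open_lo and v == lo) or (open_hi and v == hi):
        lob, hib = ("(" if open_lo else "["), (")" if open_hi else "]")
        raise ParameterError(name, f"must lie in {lob}{lo}, {hi}{hib}, got {v}")
    return v


def _check_split(name: str, split: Mapping[str, float], keys: tuple[str, ...]) -> dict:
    d = {k: float(split[k]) for k in keys}
    if abs(sum(d.values()) - 1.0) > _SUM_TOL:
        raise ParameterError(name, f"shares must sum to 1, got {sum(d.values())!r}")
    for k, v in d.items():
        _check_fraction(f"{name}.{k}", v)
    return d


# ---------------------------------------------------------------------------
# scenario / profile types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrevalenceScenario:
    """One prevalence scenario: overall rate plus stage/age/sex structure.

    ``stage_distribution`` covers the eight living states (F0..LT) and
    sums to one; the base-year decedent column is populated separately
    from attributable mortality.  ``age_distribution`` holds, per living
    stage, the conditional distribution over age bands (rows = stages,
    columns = age bands, each row sums to one).
    """

    label: str
    overall_rate: float
    stage_distribution: StageVector
    age_distribution: pd.DataFrame = field(repr=False)
    sex_distribution: dict[str, float]

    def __post_init__(self) -> None:
        _check_fraction(f"prevalence[{self.label}].overall_rate",
                        self.overall_rate, open_lo=True, open_hi=True)
        sd = self.stage_distribution
        if abs(sum(sd[s] for s in LIVING_STAGES) - 1.0) > _SUM_TOL:
            raise ParameterError(
                f"prevalence[{self.label}].stage_distribution",
                "living-stage shares must sum to 1",
            )
        if sd["DEATH"] != 0.0:
            raise ParameterError(
                f"prevalence[{self.label}].stage_distribution",
                "DEATH mass is derived from attributable mortality, set 0",
            )
        sd.require_probability(f"prevalence[{self.label}].stage_distribution")
        ad = self.age_distribution.reindex(
            index=list(LIVING_STAGES), columns=list(AGE_BANDS)
        )
        if ad.isna().any().any():
            raise ParameterError(
                f"prevalence[{self.label}].age_distribution",
                "must cover every living stage and age band",
            )
        if not np.allclose(ad.sum(axis=1).to_numpy(), 1.0, atol=_SUM_TOL):
            raise ParameterError(
                f"prevalence[{self.label}].age_distribution",
                "each stage row must sum to 1",
            )
        object.__setattr__(self, "age_distribution", ad.astype(float))
        _check_split(f"prevalence[{self.label}].sex_distribution",
                     self.sex_distribution, SEXES)


@dataclass(frozen=True)
class DiagnosisProfile:
    """Per-stage probability that a prevalent case is diagnosed."""

    label: str
    probability: StageVector

    def __post_init__(self) -> None:
        p = self.probability
        p.require_probability(f"diagnosis[{self.label}].probability")
        vals = [p[s] for s in ("F0", "F1", "F2", "F3", "F4CC")]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise ParameterError(
                f"diagnosis[{self.label}].probability",
                "must be non-decreasing across F0..F4CC",
            )


@dataclass(frozen=True)
class MortalityParams:
    """Attributable mortality, expressed per prevalent case.

    The headline figure (0.023% of UK adults in the higher-prevalence
    scenario) is a joint product of the prevalence rate and the
    per-prevalent-case excess death rate; carrying the latter makes
    attributable deaths scale with the prevalence scenario, as the
    published scenario results do.
    """

    rate_per_prevalent: float
    cvd_share: float
    age_sex_distribution: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        _check_fraction("mortality.rate_per_prevalent", self.rate_per_prevalent,
                        hi=1.0, open_hi=True)
        _check_fraction("mortality.cvd_share", self.cvd_share)
        dist = self.age_sex_distribution.reindex(cell_index())
        if dist.isna().any():
            raise ParameterError("mortality.age_sex_distribution",
                                 "must cover every (age_band, sex) cell")
        if abs(dist.sum() - 1.0) > _SUM_TOL:
            raise ParameterError("mortality.age_sex_distribution",
                                 "must sum to 1")
        object.__setattr__(self, "age_sex_distribution", dist.astype(float))


@dataclass(frozen=True)
class TransplantParams:
    """Elective liver transplants attributable to NASH in the base year."""

    total_elective: float
    nash_indication_share: float
    age_cap: int = 70

    def __post_init__(self) -> None:
        if self.total_elective < 0:
            raise ParameterError("transplants.total_elective", "must be >= 0")
        _check_fraction("transplants.nash_indication_share",
                        self.nash_indication_share)


# ---------------------------------------------------------------------------
# cost schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostSchedule:
    """Per-person annual health-system unit costs (2018 GBP).

    ``unit_costs`` is indexed by stage (F0..HCC) with MultiIndex columns
    (patient status, cost category).  Liver-transplant costs are carried
    separately as initial-year and subsequent-year amounts; the pooled
    medical-research spend is a fixed total, not a per-person cost.
    """

    unit_costs: pd.DataFrame = field(repr=False)
    lt_initial_year: float
    lt_subsequent_year: float
    medical_research_pool: float

    def __post_init__(self) -> None:
        cols = pd.MultiIndex.from_product(
            [PATIENT_STATUSES, COST_CATEGORIES], names=["status", "category"]
        )
        uc = self.unit_costs.reindex(index=list(COSTED_STAGES), columns=cols)
        if uc.isna().any().any():
            missing = uc.columns[uc.isna().any(axis=0)].tolist()
            raise ParameterError(
                "health_costs.unit_costs",
                f"must cover stages {COSTED_STAGES} for all status/category "
                f"pairs; missing e.g. {missing[:3]}",
            )
        if (uc.to_numpy() < 0).any():
            raise ParameterError("health_costs.unit_costs", "costs must be >= 0")
        object.__setattr__(self, "unit_costs", uc.astype(float))
        for nm in ("lt_initial_year", "lt_subsequent_year",
                   "medical_research_pool"):
            if getattr(self, nm) < 0:
                raise ParameterError(f"health_costs.{nm}", "must be >= 0")

    def per_person_total(self, status: str) -> StageVector:
        """Summed categories per stage for one patient status (F0..HCC)."""
        sums = self.unit_costs[status].sum(axis=1)
        return StageVector({s: float(sums[s]) for s in COSTED_STAGES})


@dataclass(frozen=True)
class PayerSplit:
    """Fractional split of health-system costs over payers."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fractions",
            _check_split("payer_split", self.fractions, HEALTH_PAYERS),
        )


@dataclass(frozen=True)
class BurdenParams:
    """Disability weights, discounting, VSLY and the life table."""

    disability_weight: StageVector
    discount_rate: float
    vsly: float
    life_table: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.disability_weight.require_probability("burden.disability_weight")
        _check_fraction("burden.discount_rate", self.discount_rate, hi=1.0,
                        open_hi=True)
        if self.vsly <= 0:
            raise ParameterError("burden.vsly", "must be > 0")
        lt = self.life_table.reindex(cell_index())
        if lt.isna().any():
            raise ParameterError("burden.life_table",
                                 "must cover every (age_band, sex) cell")
        if (lt < 0).any():
            raise ParameterError("burden.life_table",
                                 "life expectancy must be >= 0")
        object.__setattr__(self, "life_table", lt.astype(float))


@dataclass(frozen=True)
class LabourParams:
    """Earnings, employment and productive-time-loss parameters.

    ``absenteeism_weeks`` / ``presenteeism_weeks`` may carry NaN for
    DCC/HCC/LT, in which case the F4CC estimate is extrapolated to those
    stages (the survey informing the week-loss inputs covered F0..F4CC
    only).
    """

    employment_rate: pd.Series = field(repr=False)
    weekly_earnings: pd.Series = field(repr=False)
    reduced_participation: StageVector
    absenteeism_weeks: StageVector
    presenteeism_weeks: StageVector
    effective_tax_rate: float
    retirement_age: int = 66
    search_hire_train_cost: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("employment_rate", "weekly_earnings"):
            s = getattr(self, nm).reindex(cell_index())
            if s.isna().any():
                raise ParameterError(f"labour.{nm}",
                                     "must cover every (age_band, sex) cell")
            if (s < 0).any():
                raise ParameterError(f"labour.{nm}", "must be >= 0")
            object.__setattr__(self, nm, s.astype(float))
        if (self.employment_rate > 1).any():
            raise ParameterError("labour.employment_rate", "must be <= 1")
        self.reduced_participation.require_probability(
            "labour.reduced_participation")
        for nm in ("absenteeism_weeks", "presenteeism_weeks"):
            v = getattr(self, nm).values
            finite = v[~np.isnan(v)]
            if (finite < 0).any() or (finite > 52).any():
                raise ParameterError(f"labour.{nm}",
                                     "weeks must lie in [0, 52]")
        _check_fraction("labour.effective_tax_rate", self.effective_tax_rate,
                        open_hi=True)
        if self.search_hire_train_cost < 0:
            raise ParameterError("labour.search_hire_train_cost",
                                 "must be >= 0")


@dataclass(frozen=True)
class WelfareParams:
    """Welfare transfer parameters (PIP, ESA, Carer's Allowance).

    PIP/ESA claimants are expressed as a share of the diagnosed ESLD
    population so claim totals scale with the scenario; CA claimants are
    derived from the care-receiving population and the probability that a
    carer receives the allowance.
    """

    pip_claim_share: float
    pip_annual_value: float
    esa_claim_share: float
    esa_annual_value: float
    ca_receipt_prob: float
    ca_annual_value: float

    def __post_init__(self) -> None:
        for nm in ("pip_claim_share", "esa_claim_share", "ca_receipt_prob"):
            _check_fraction(f"welfare.{nm}", getattr(self, nm))
        for nm in ("pip_annual_value", "esa_annual_value", "ca_annual_value"):
            if getattr(self, nm) < 0:
                raise ParameterError(f"welfare.{nm}", "must be >= 0")


@dataclass(frozen=True)
class OtherCostParams:
    """Care, welfare, deadweight-loss and funeral-cost parameters."""

    formal_care_annual_cost: float
    formal_care_share: StageVector
    informal_care_share: StageVector
    informal_care_hours_per_week: float
    carer_hourly_earnings: float
    welfare: WelfareParams
    dwl_rate: float
    include_government_health_in_dwl: bool = True
    funeral_cost: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("formal_care_annual_cost", "informal_care_hours_per_week",
                   "carer_hourly_earnings", "funeral_cost"):
            if getattr(self, nm) < 0:
                raise ParameterError(f"other_costs.{nm}", "must be >= 0")
        for nm in ("formal_care_share", "informal_care_share"):
            sv: StageVector = getattr(self, nm)
            sv.require_probability(f"other_costs.{nm}")
            outside = [s for s in STAGES
                       if s not in ESLD_STAGES and sv[s] != 0.0]
            if outside:
                raise ParameterError(
                    f"other_costs.{nm}",
                    f"care applies to ESLD stages only; nonzero at {outside}",
                )
        _check_fraction("other_costs.dwl_rate", self.dwl_rate, open_hi=True)


# ---------------------------------------------------------------------------
# the full bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterBundle:
    """Everything one scenario run needs."""

    demographics: DemographicTable
    prevalence: dict[str, PrevalenceScenario]
    diagnosis: dict[str, DiagnosisProfile]
    incidence: StageVector
    mortality: MortalityParams
    transplants: TransplantParams
    cost_schedule: CostSchedule
    payer_split: PayerSplit
    labour: LabourParams
    other_costs: OtherCostParams
    burden: BurdenParams
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.incidence.require_probability("incidence")
        for label, sc in self.prevalence.items():
            if sc.label != label:
                raise ParameterError(f"prevalence[{label}]", "label mismatch")
        for label, pr in self.diagnosis.items():
            if pr.label != label:
                raise ParameterError(f"diagnosis[{label}]", "label mismatch")

    def replace(self, **changes) -> "ParameterBundle":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# published scalar fixture
# ---------------------------------------------------------------------------

#: Input tables required to run the model but unavailable in print; they
#: must come from user data or :mod:`coiburden.synthetic`.
UNPUBLISHED_TABLES: tuple[str, ...] = (
    "demographics",
    "prevalence stage/age/sex distributions",
    "incidence fractions",
    "health unit-cost schedule",
    "labour (earnings, employment, weeks lost)",
    "life table",
    "care and welfare parameters",
)


@dataclass(frozen=True)
class PublishedScalars:
    """The scalar parameters available in print for the UK 2018 analysis.

    Attributes are fractions/GBP as stored internally.  ``requires_data``
    names the tables a complete :class:`ParameterBundle` additionally needs.
    """

    prevalence_rate_lower: float = 0.022
    prevalence_rate_higher: float = 0.041
    # base diagnosis probabilities; F3 is stored at the 4-dp precision of
    # the population table (58.25%), of which the headline 58.3% is the
    # 1-dp rounding
    diagnosis_base: StageVector = StageVector(
        {"F0": 0.02, "F1": 0.02, "F2": 0.165, "F3": 0.5825,
         "F4CC": 1.0, "DCC": 1.0, "HCC": 1.0, "LT": 1.0, "DEATH": 1.0}
    )
    cvd_mortality_share: float = 0.60
    adult_mortality_rate_higher: float = 0.00023  # 12,110 deaths / UK adults
    attributable_deaths_higher: float = 12110.0
    disability_weight_dcc: float = 0.178
    disability_weight_hcc: float = 0.296
    disability_weight_f4cc: float = 0.0
    discount_rate: float = 0.03
    vsly: float = 60000.0
    payer_split_health: tuple[tuple[str, float], ...] = (
        ("government", 0.79), ("individuals_families", 0.15), ("other", 0.06),
    )
    requires_data: tuple[str, ...] = UNPUBLISHED_TABLES

    @property
    def mortality_rate_per_prevalent(self) -> float:
        """Excess deaths per prevalent case, backed out of the headline
        0.023%-of-adults figure under the higher (4.1%) prevalence rate."""
        return self.adult_mortality_rate_higher / self.prevalence_rate_higher


def published_fixture() -> PublishedScalars:
    """Return the bundle of published scalar parameters.

    Tables listed in :attr:`PublishedScalars.requires_data` are not in
    print and must be supplied separately (user data or the synthetic
    generator).
    """
    return PublishedScalars()


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _sv_to_obj(v: StageVector) -> dict:
    return {s: (None if np.isnan(x) else float(x))
            for s, x in zip(STAGES, v.values)}


def _sv_from_obj(obj: Mapping[str, Optional[float]],
                 fill: float = 0.0) -> StageVector:
    vals = {k: (np.nan if v is None else float(v)) for k, v in obj.items()}
    return StageVector(vals, fill=fill)


def _cells_to_records(s: pd.Series, value_name: str) -> list[dict]:
    out = []
    for (band, sex), v in s.items():
        out.append({"age_band": band, "sex": sex, value_name: float(v)})
    return out


def _cells_from_records(records: list[dict], value_name: str) -> pd.Series:
    df = pd.DataFrame(records)
    return df.set_index(["age_band", "sex"])[value_name].astype(float)


def bundle_to_mapping(bundle: ParameterBundle) -> dict:
    """Serialise a bundle to a plain nested mapping (YAML/JSON-safe)."""
    uc = bundle.cost_schedule.unit_costs
    uc_records = [
        {"stage": stage, "status": status, "category": cat,
         "value": float(uc.loc[stage, (status, cat)])}
        for stage in COSTED_STAGES
        for status in PATIENT_STATUSES
        for cat in COST_CATEGORIES
    ]
    ad_records = {
        label: [
            {"stage": stage, "age_band": band,
             "share": float(sc.age_distribution.loc[stage, band])}
            for stage in LIVING_STAGES for band in AGE_BANDS
        ]
        for label, sc in bundle.prevalence.items()
    }
    lab = bundle.labour
    labour_records = [
        {"age_band": band, "sex": sex,
         "employment_rate": float(lab.employment_rate[(band, sex)]),
         "weekly_earnings": float(lab.weekly_earnings[(band, sex)])}
        for band in AGE_BANDS for sex in SEXES
    ]
    oc = bundle.other_costs
    return {
        "metadata": dict(bundle.metadata),
        "demographics": _cells_to_records(bundle.demographics.counts, "count"),
        "prevalence": {
            label: {
                "overall_rate": float(sc.overall_rate),
                "stage_distribution": _sv_to_obj(sc.stage_distribution),
                "age_distribution": ad_records[label],
                "sex_distribution": {k: float(v)
                                     for k, v in sc.sex_distribution.items()},
            }
            for label, sc in bundle.prevalence.items()
        },
        "diagnosis": {
            label: {"probability": _sv_to_obj(pr.probability)}
            for label, pr in bundle.diagnosis.items()
        },
        "incidence": _sv_to_obj(bundle.incidence),
        "mortality": {
            "rate_per_prevalent": float(bundle.mortality.rate_per_prevalent),
            "cvd_share": float(bundle.mortality.cvd_share),
            "age_sex_distribution": _cells_to_records(
                bundle.mortality.age_sex_distribution, "share"),
        },
        "transplants": {
            "total_elective": float(bundle.transplants.total_elective),
            "nash_indication_share": float(
                bundle.transplants.nash_indication_share),
            "age_cap": int(bundle.transplants.age_cap),
        },
        "health_costs": {
            "unit_costs": uc_records,
            "lt_initial_year": float(bundle.cost_schedule.lt_initial_year),
            "lt_subsequent_year": float(
                bundle.cost_schedule.lt_subsequent_year),
            "medical_research_pool": float(
                bundle.cost_schedule.medical_research_pool),
            "payer_split": dict(bundle.payer_split.fractions),
        },
        "labour": {
            "table": labour_records,
            "reduced_participation": _sv_to_obj(lab.reduced_participation),
            "absenteeism_weeks": _sv_to_obj(lab.absenteeism_weeks),
            "presenteeism_weeks": _sv_to_obj(lab.presenteeism_weeks),
            "effective_tax_rate": float(lab.effective_tax_rate),
            "retirement_age": int(lab.retirement_age),
            "search_hire_train_cost": float(lab.search_hire_train_cost),
        },
        "other_costs": {
            "formal_care_annual_cost": float(oc.formal_care_annual_cost),
            "formal_care_share": _sv_to_obj(oc.formal_care_share),
            "informal_care_share": _sv_to_obj(oc.informal_care_share),
            "informal_care_hours_per_week": float(
                oc.informal_care_hours_per_week),
            "carer_hourly_earnings": float(oc.carer_hourly_earnings),
            "welfare": {
                nm: float(getattr(oc.welfare, nm))
                for nm in ("pip_claim_share", "pip_annual_value",
                           "esa_claim_share", "esa_annual_value",
                           "ca_receipt_prob", "ca_annual_value")
            },
            "dwl_rate": float(oc.dwl_rate),
            "include_government_health_in_dwl": bool(
                oc.include_government_health_in_dwl),
            "funeral_cost": float(oc.funeral_cost),
        },
        "burden": {
            "disability_weights": _sv_to_obj(bundle.burden.disability_weight),
            "discount_rate": float(bundle.burden.discount_rate),
            "vsly": float(bundle.burden.vsly),
            "life_table": _cells_to_records(bundle.burden.life_table,
                                            "life_expectancy"),
        },
    }


def bundle_from_mapping(obj: Mapping) -> ParameterBundle:
    """Deserialise a bundle, validating every type invariant.

    Omitted published scalars are filled from :func:`published_fixture`;
    tables have no published values and must be present.
    """
    fx = published_fixture()

    def _req(section: Mapping, key: str, where: str):
        if key not in section:
            raise ParameterError(f"{where}.{key}", "required field missing")
        return section[key]

    demo = DemographicTable(
        _cells_from_records(_req(obj, "demographics", "config"), "count"))

    prevalence = {}
    for label, sec in _req(obj, "prevalence", "config").items():
        ad = pd.DataFrame(_req(sec, "age_distribution", f"prevalence.{label}"))
        ad = ad.pivot(index="stage", columns="age_band", values="share")
        default_rate = {"lower": fx.prevalence_rate_lower,
                        "higher": fx.prevalence_rate_higher}.get(label)
        rate = sec.get("overall_rate", default_rate)
        if rate is None:
            raise ParameterError(f"prevalence.{label}.overall_rate",
                                 "required field missing")
        prevalence[label] = PrevalenceScenario(
            label=label,
            overall_rate=float(rate),
            stage_distribution=_sv_from_obj(
                _req(sec, "stage_distribution", f"prevalence.{label}")),
            age_distribution=ad,
            sex_distribution=_req(sec, "sex_distribution",
                                  f"prevalence.{label}"),
        )

    diag_section = dict(obj.get("diagnosis", {}))
    if "base" not in diag_section:
        diag_section["base"] = {"probability": _sv_to_obj(fx.diagnosis_base)}
    diagnosis = {
        label: DiagnosisProfile(
            label=label,
            probability=_sv_from_obj(
                _req(sec, "probability", f"diagnosis.{label}")),
        )
        for label, sec in diag_section.items()
    }

    mort = _req(obj, "mortality", "config")
    mortality = MortalityParams(
        rate_per_prevalent=float(
            mort.get("rate_per_prevalent", fx.mortality_rate_per_prevalent)),
        cvd_share=float(mort.get("cvd_share", fx.cvd_mortality_share)),
        age_sex_distribution=_cells_from_records(
            _req(mort, "age_sex_distribution", "mortality"), "share"),
    )

    tr = _req(obj, "transplants", "config")
    transplants = TransplantParams(
        total_elective=float(_req(tr, "total_elective", "transplants")),
        nash_indication_share=float(
            _req(tr, "nash_indication_share", "transplants")),
        age_cap=int(tr.get("age_cap", 70)),
    )

    hc = _req(obj, "health_costs", "config")
    uc_long = pd.DataFrame(_req(hc, "unit_costs", "health_costs"))
    uc = uc_long.pivot_table(index="stage", columns=["status", "category"],
                             values="value")
    cost_schedule = CostSchedule(
        unit_costs=uc,
        lt_initial_year=float(_req(hc, "lt_initial_year", "health_costs")),
        lt_subsequent_year=float(
            _req(hc, "lt_subsequent_year", "health_costs")),
        medical_research_pool=float(
            hc.get("medical_research_pool", 0.0)),
    )
    payer_split = PayerSplit(fractions=dict(
        hc.get("payer_split", dict(fx.payer_split_health))))

    lab = _req(obj, "labour", "config")
    lab_df = pd.DataFrame(_req(lab, "table", "labour")).set_index(
        ["age_band", "sex"])
    labour = LabourParams(
        employment_rate=lab_df["employment_rate"].astype(float),
        weekly_earnings=lab_df["weekly_earnings"].astype(float),
        reduced_participation=_sv_from_obj(
            _req(lab, "reduced_participation", "labour")),
        absenteeism_weeks=_sv_from_obj(
            _req(lab, "absenteeism_weeks", "labour")),
        presenteeism_weeks=_sv_from_obj(
            _req(lab, "presenteeism_weeks", "labour")),
        effective_tax_rate=float(_req(lab, "effective_tax_rate", "labour")),
        retirement_age=int(lab.get("retirement_age", 66)),
        search_hire_train_cost=float(
            lab.get("search_hire_train_cost", 0.0)),
    )

    oc = _req(obj, "other_costs", "config")
    wf = _req(oc, "welfare", "other_costs")
    other_costs = OtherCostParams(
        formal_care_annual_cost=float(
            _req(oc, "formal_care_annual_cost", "other_costs")),
        formal_care_share=_sv_from_obj(
            _req(oc, "formal_care_share", "other_costs")),
        informal_care_share=_sv_from_obj(
            _req(oc, "informal_care_share", "other_costs")),
        informal_care_hours_per_week=float(
            _req(oc, "informal_care_hours_per_week", "other_costs")),
        carer_hourly_earnings=float(
            _req(oc, "carer_hourly_earnings", "other_costs")),
        welfare=WelfareParams(**{k: float(v) for k, v in wf.items()}),
        dwl_rate=float(oc.get("dwl_rate", 0.20)),
        include_government_health_in_dwl=bool(
            oc.get("include_government_health_in_dwl", True)),
        funeral_cost=float(oc.get("funeral_cost", 0.0)),
    )

    bu = _req(obj, "burden", "config")
    default_weights = _sv_to_obj(StageVector(
        {"DCC": fx.disability_weight_dcc, "HCC": fx.disability_weight_hcc}))
    burden = BurdenParams(
        disability_weight=_sv_from_obj(
            bu.get("disability_weights", default_weights)),
        discount_rate=float(bu.get("discount_rate", fx.discount_rate)),
        vsly=float(bu.get("vsly", fx.vsly)),
        life_table=_cells_from_records(
            _req(bu, "life_table", "burden"), "life_expectancy"),
    )

    return ParameterBundle(
        demographics=demo,
        prevalence=prevalence,
        diagnosis=diagnosis,
        incidence=_sv_from_obj(_req(obj, "incidence", "config")),
        mortality=mortality,
        transplants=transplants,
        cost_schedule=cost_schedule,
        payer_split=payer_split,
        labour=labour,
        other_costs=other_costs,
        burden=burden,
        metadata=dict(obj.get("metadata", {})),
    )


# CSV side-files a directory-style config may reference instead of
# inlining the table under the YAML key.
_CSV_SECTIONS = {
    ("demographics",),
    ("mortality", "age_sex_distribution"),
    ("health_costs", "unit_costs"),
    ("labour", "table"),
    ("burden", "life_table"),
}


def load_config(path) -> ParameterBundle:
    """Read and validate a YAML configuration file.

    Any table-valued key may be given either inline (list of records) or
    as ``{csv: relative/path.csv}`` pointing at a headed CSV next to the
    config file.  Omitted published scalars are filled from
    :func:`published_fixture`.
    """
    path = Path(path)
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    if not isinstance(obj, Mapping):
        raise ParameterError("config", "top level must be a mapping")
    obj = _resolve_csv_refs(obj, path.parent)
    return bundle_from_mapping(obj)


def _resolve_csv_refs(node, base: Path):
    if isinstance(node, Mapping):
        if set(node.keys()) == {"csv"}:
            # round_trip parsing keeps the write/read cycle bit-exact
            df = pd.read_csv(base / node["csv"], float_precision="round_trip")
            return df.to_dict(orient="records")
        return {k: _resolve_csv_refs(v, base) for k, v in node.items()}
    return node


def save_config(bundle: ParameterBundle, path) -> None:
    """Write a bundle to a single self-contained YAML file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(bundle_to_mapping(bundle), fh, sort_keys=False)


def save_bundle_dir(bundle: ParameterBundle, directory) -> Path:
    """Write a bundle as config.yaml plus CSV side-files.

    Large tables go to headed CSVs referenced from the YAML; scalars stay
    in the YAML.  Returns the config path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    obj = bundle_to_mapping(bundle)

    def _extract(keys: tuple[str, ...], filename: str) -> None:
        node = obj
        for k in keys[:-1]:
            node = node[k]
        pd.DataFrame(node[keys[-1]]).to_csv(directory / filename, index=False)
        node[keys[-1]] = {"csv": filename}

    _extract(("demographics",), "demographics.csv")
    _extract(("mortality", "age_sex_distribution"), "mortality_distribution.csv")
    _extract(("health_costs", "unit_costs"), "unit_costs.csv")
    _extract(("labour", "table"), "labour.csv")
    _extract(("burden", "life_table"), "life_table.csv")
    for label in obj["prevalence"]:
        fn = f"age_distribution_{label}.csv"
        _extract(("prevalence", label, "age_distribution"), fn)

    cfg = directory / "config.yaml"
    with open(cfg, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return cfg


def bundles_equal(a: ParameterBundle, b: ParameterBundle) -> bool:
    """Bit-exact equality on the serialised representation."""
    return yaml.safe_dump(bundle_to_mapping(a)) == yaml.safe_dump(
        bundle_to_mapping(b))
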