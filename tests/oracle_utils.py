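"""Independent brute-force oracle for the whole pipeline.

Re-derives every cost and burden component by enumerating the synthetic
population cell by cell with plain scalar arithmetic (per-person Bernoulli
assignment replaced by expected values), entirely outside the package's
vectorised code paths.  Used to check the model aggregates to full
floating precision on small populations.
"""

from __future__ import annotations

import math

from coiburden.cohort import AGE_BANDS, SEXES, band_lower, band_midpoint
from coiburden.stages import COSTED_STAGES, ESLD_STAGES, LIVING_STAGES, STAGES

CATEGORIES = ("primary_care", "secondary_care", "diagnostics",
              "pharmaceuticals")


def _annuity(rate: float, years: float) -> float:
    years = max(years, 0.0)
    if rate == 0.0:
        return years
    return (1.0 - (1.0 + rate) ** (-years)) / rate


def enumerate_components(bundle, prevalence_label: str,
                         diagnosis_label: str) -> dict:
    """Compute every aggregate by explicit loops over cells and stages."""
    sc = bundle.prevalence[prevalence_label]
    prob = bundle.diagnosis[diagnosis_label].probability
    demo_total = sum(
        bundle.demographics.counts[(b, x)] for b in AGE_BANDS for x in SEXES)
    prev_total = sc.overall_rate * demo_total
    r = bundle.burden.discount_rate
    lab = bundle.labour
    retire = lab.retirement_age

    # populations per (band, sex, stage), deaths per (band, sex) ----------
    prevalent = {}
    for b in AGE_BANDS:
        for x in SEXES:
            for s in LIVING_STAGES:
                prevalent[(b, x, s)] = (
                    prev_total * sc.stage_distribution[s]
                    * float(sc.age_distribution.loc[s, b])
                    * sc.sex_distribution[x])
    death_rate = bundle.mortality.rate_per_prevalent * sc.overall_rate
    deaths_total = death_rate * demo_total
    deaths = {}
    for b in AGE_BANDS:
        for x in SEXES:
            deaths[(b, x)] = deaths_total * float(
                bundle.mortality.age_sex_distribution[(b, x)])
            prevalent[(b, x, "DEATH")] = deaths[(b, x)]

    diagnosed, newly, monitoring = {}, {}, {}
    for key, n in prevalent.items():
        s = key[2]
        d = n * prob[s]
        diagnosed[key] = d
        newly[key] = d * bundle.incidence[s]
        monitoring[key] = d - newly[key]
    diagnosed_total = sum(diagnosed.values())

    # transplants: prevalence-proportional below the age cap --------------
    cell_prev = {
        (b, x): sum(prevalent[(b, x, s)] for s in STAGES)
        for b in AGE_BANDS for x in SEXES}
    cap = bundle.transplants.age_cap
    eligible_mass = sum(v for (b, x), v in cell_prev.items()
                        if band_lower(b) < cap)
    tx_total = (bundle.transplants.total_elective
                * bundle.transplants.nash_indication_share)
    tx = {
        (b, x): (tx_total * v / eligible_mass if band_lower(b) < cap else 0.0)
        for (b, x), v in cell_prev.items()}

    # health system costs --------------------------------------------------
    uc = bundle.cost_schedule.unit_costs
    health = 0.0
    for b in AGE_BANDS:
        for x in SEXES:
            for s in COSTED_STAGES:
                for c in CATEGORIES:
                    health += (float(uc.loc[s, ("newly_diagnosed", c)])
                               * newly[(b, x, s)])
                    health += (float(uc.loc[s, ("in_monitoring", c)])
                               * monitoring[(b, x, s)])
            health += bundle.cost_schedule.lt_initial_year * tx[(b, x)]
            health += (bundle.cost_schedule.lt_subsequent_year
                       * monitoring[(b, x, "LT")])
    health += bundle.cost_schedule.medical_research_pool

    # productivity ---------------------------------------------------------
    def weeks(vec, s):
        v = vec[s]
        return vec["F4CC"] if math.isnan(v) else v

    participation = absenteeism = presenteeism = 0.0
    forgone = sht_exits = 0.0
    for b in AGE_BANDS:
        for x in SEXES:
            working = band_lower(b) < retire
            awe = float(lab.weekly_earnings[(b, x)])
            emp = float(lab.employment_rate[(b, x)])
            for s in STAGES:
                d = diagnosed[(b, x, s)]
                if working:
                    participation += d * lab.reduced_participation[s] * awe * 52.0
                    absenteeism += (d * weeks(lab.absenteeism_weeks, s)
                                    * awe * emp) if s != "DEATH" else 0.0
                    presenteeism += (d * weeks(lab.presenteeism_weeks, s)
                                     * awe * emp) if s != "DEATH" else 0.0
                    sht_exits += d * lab.reduced_participation[s]
            if working:
                years = max(retire - band_midpoint(b), 0.0)
                forgone += deaths[(b, x)] * awe * 52.0 * emp * _annuity(r, years)
                sht_exits += deaths[(b, x)] * emp
    sht = sht_exits * lab.search_hire_train_cost
    productivity = participation + absenteeism + presenteeism + forgone + sht

    # other costs ----------------------------------------------------------
    oc = bundle.other_costs
    formal = informal = 0.0
    esld_diag = cared = 0.0
    for s in ESLD_STAGES:
        n = sum(diagnosed[(b, x, s)] for b in AGE_BANDS for x in SEXES)
        esld_diag += n
        cared += n * oc.informal_care_share[s]
        formal += n * oc.formal_care_share[s] * oc.formal_care_annual_cost
        informal += (n * oc.informal_care_share[s]
                     * oc.informal_care_hours_per_week * 52.0
                     * oc.carer_hourly_earnings)
    wf = oc.welfare
    transfers = (wf.pip_claim_share * esld_diag * wf.pip_annual_value
                 + wf.esa_claim_share * esld_diag * wf.esa_annual_value
                 + wf.ca_receipt_prob * cared * wf.ca_annual_value)
    tax_forgone = lab.effective_tax_rate * (
        participation + absenteeism + presenteeism + forgone)
    gov_health = bundle.payer_split.fractions["government"] * health
    dwl_base = tax_forgone + transfers
    if oc.include_government_health_in_dwl:
        dwl_base += gov_health
    dwl = oc.dwl_rate * dwl_base
    funeral = 0.0
    for b in AGE_BANDS:
        for x in SEXES:
            L = float(bundle.burden.life_table[(b, x)])
            funeral += deaths[(b, x)] * oc.funeral_cost * (
                1.0 - (1.0 + r) ** (-L))

    # burden ---------------------------------------------------------------
    yld = 0.0
    for s in LIVING_STAGES:
        n = sum(diagnosed[(b, x, s)] for b in AGE_BANDS for x in SEXES)
        yld += n * bundle.burden.disability_weight[s]
    yll = 0.0
    for b in AGE_BANDS:
        for x in SEXES:
            L = float(bundle.burden.life_table[(b, x)])
            yll += deaths[(b, x)] * _annuity(r, L)

    economic = health + productivity + formal + informal + dwl + funeral
    return {
        "prevalent_total": sum(prevalent.values()),
        "diagnosed_total": diagnosed_total,
        "health": health,
        "participation": participation,
        "absenteeism": absenteeism,
        "presenteeism": presenteeism,
        "forgone_income": forgone,
        "search_hire_train": sht,
        "productivity": productivity,
        "formal_care": formal,
        "informal_care": informal,
        "transfers": transfers,
        "dwl": dwl,
        "funeral": funeral,
        "yld": yld,
        "yll": yll,
        "dalys": yld + yll,
        "wellbeing": (yld + yll) * bundle.burden.vsly,
        "economic_total": economic,
    }
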