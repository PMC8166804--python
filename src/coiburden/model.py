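"""Model / results front-end.

:class:`CostOfIllnessModel` is built from a :class:`ParameterBundle`
(from a config file, or the synthetic generator) and ``fit()`` evaluates
one scenario combination, returning :class:`ScenarioResults` -- the
results object carrying the population state, every cost component,
burden, headline totals and a ``summary()`` table.  Scenario ranges and
one-way sensitivity, rather than sampling error, are the model's
uncertainty statements: the counterfactual and tornado analyses hang off
the same two objects.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .params import ParameterBundle, load_config
from .scenarios import (
    ScenarioResult,
    full_diagnosis_counterfactual,
    one_way_sensitivity,
    run_scenario,
    run_scenario_grid,
)
from .stages import STAGES


class CostOfIllnessModel:
    """Prevalence-approach cost-of-illness model for diagnosed NASH.

    Parameters
    ----------
    bundle :
        A validated parameter bundle (see :mod:`coiburden.params`).

    Examples
    --------
    >>> from coiburden import CostOfIllnessModel
    >>> model = CostOfIllnessModel.from_synthetic(seed=42, calibrate=False)
    >>> res = model.fit(prevalence="higher", diagnosis="base")
    >>> res.economic_total > 0
    True
    """

    def __init__(self, bundle: ParameterBundle) -> None:
        self.bundle = bundle

    @classmethod
    def from_config(cls, path) -> "CostOfIllnessModel":
        """Build from a YAML configuration file."""
        return cls(load_config(path))

    @classmethod
    def from_synthetic(cls, spec=None, seed: Optional[int] = None,
                       calibrate: bool = True) -> "CostOfIllnessModel":
        """Build from the synthetic UK-like generator.

        ``calibrate`` runs the published-anchor calibration of the
        scale knobs before generating the bundle.
        """
        from .synthetic import SyntheticSpec, calibrate_uk_like, generate_bundle

        if spec is None:
            spec = SyntheticSpec() if seed is None else SyntheticSpec(seed=seed)
        elif seed is not None:
            spec = spec.replace(seed=seed)
        if calibrate:
            spec = calibrate_uk_like(spec)
        return cls(generate_bundle(spec))

    # -- runs -------------------------------------------------------------
    def fit(self, prevalence: str = "higher",
            diagnosis: str = "base") -> "ScenarioResults":
        """Evaluate one (prevalence, diagnosis) scenario combination."""
        return ScenarioResults(self, run_scenario(self.bundle, prevalence,
                                                  diagnosis))

    def fit_grid(self) -> dict[tuple[str, str], "ScenarioResults"]:
        """Evaluate every scenario combination in the bundle."""
        return {key: ScenarioResults(self, res)
                for key, res in run_scenario_grid(self.bundle).items()}

    def counterfactual(self, prevalence: str = "higher") -> "ScenarioResults":
        """Re-run with all diagnosis probabilities set to one."""
        return ScenarioResults(
            self, full_diagnosis_counterfactual(self.bundle, prevalence))

    def sensitivity(self, parameters: Optional[Sequence[str]] = None,
                    delta: float = 0.10, prevalence: str = "higher",
                    diagnosis: str = "base",
                    metric: str = "economic_total") -> pd.DataFrame:
        """One-way (tornado) sensitivity table, sorted by swing."""
        return one_way_sensitivity(self.bundle, parameters, delta,
                                   prevalence, diagnosis, metric)


class ScenarioResults:
    """Results object for one fitted scenario.

    Thin wrapper over :class:`ScenarioResult` adding ``summary()`` and
    convenience access; all underlying attributes are delegated.
    """

    def __init__(self, model: CostOfIllnessModel, result: ScenarioResult) -> None:
        self.model = model
        self._result = result

    def __getattr__(self, name):
        return getattr(self._result, name)

    @property
    def result(self) -> ScenarioResult:
        return self._result

    def component_table(self) -> pd.DataFrame:
        """Economic component x stage totals in GBP."""
        return self._result.economic_by_component_stage()

    def summary(self) -> str:
        """Human-readable summary of the scenario's headline results."""
        r = self._result
        lines = [
            "Cost of illness: diagnosed NASH (prevalence approach)",
            "=" * 60,
            f"Scenario:            prevalence={r.prevalence_label}, "
            f"diagnosis={r.diagnosis_label}",
            f"Prevalent cases:     {r.population.prevalent.total():,.0f}",
            f"Diagnosed cases:     {r.diagnosed_total:,.0f} "
            f"({(1 - r.undiagnosed_share) * 100:.1f}% of prevalent)",
            f"Attributable deaths: {r.population.deaths.total():,.0f}",
            "-" * 60,
            "Economic costs (GBP million)",
        ]
        comp = r.economic_by_component_stage().sum(axis=1) / 1e6
        for name, value in comp.items():
            lines.append(f"  {name:<20s} {value:>12,.1f}")
        lines += [
            f"  {'total':<20s} {r.economic_total / 1e6:>12,.1f}",
            "-" * 60,
            f"DALYs total:         {r.dalys_total:,.0f} "
            f"(YLD {r.burden.yld_total:,.0f} + YLL {r.burden.yll_total:,.0f})",
            f"Wellbeing total:     GBP {r.wellbeing_total / 1e6:,.1f} million",
            f"Per diagnosed person: economic GBP {r.per_person_economic:,.0f}, "
            f"wellbeing GBP {r.per_person_wellbeing:,.0f}",
            "=" * 60,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        r = self._result
        return (
            f"<ScenarioResults {r.prevalence_label}/{r.diagnosis_label}: "
            f"economic GBP {r.economic_total / 1e9:.2f}bn, "
            f"DALYs {r.dalys_total:,.0f}>"
        )
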