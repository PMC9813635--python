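"""Deterministic end-to-end run of one scenario at point estimates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import RiskGradient, SbpEffectModel, apply_chain
from .events import DEFAULT_PREMATURE_FRAC_65_74, ScenarioResult, yearly_events
from .population import DISEASES, KEY_COLUMNS, PopulationTable
from .scenarios import SaltTrajectory, Scenario, build_trajectory


@dataclass(frozen=True)
class DeterministicRun:
    """One scenario run at point estimates: trajectory, chain and events.

    The scenario-level aggregates mirror what the uncertainty module
    reports per Monte Carlo draw:

    - ``salt_reduction``: population-weighted salt fall (g/day) at the
      year the scenario is achieved (the sustained level);
    - ``sbp_reduction``: population-weighted SBP fall (mm Hg) at the same
      year;
    - ``risk_reduction_pct``: percentage fall in population event risk at
      the achieve year, weighted by baseline events (population x
      incidence), per disease.
    """

    scenario: Scenario
    trajectory: SaltTrajectory
    chain: pd.DataFrame
    result: ScenarioResult
    pop: PopulationTable

    def _at_achieve(self, disease: str | None = None) -> pd.DataFrame:
        sub = self.chain[self.chain["year"] == self.scenario.achieve_year]
        if disease is not None:
            sub = sub[sub["disease"] == disease]
        return sub.merge(self.pop.frame, on=KEY_COLUMNS, validate="many_to_one")

    @property
    def salt_reduction(self) -> float:
        sub = self._at_achieve(DISEASES[0])
        return float(np.average(sub["delta_salt"], weights=sub["population"]))

    @property
    def sbp_reduction(self) -> float:
        sub = self._at_achieve(DISEASES[0])
        return float(np.average(sub["delta_sbp"], weights=sub["population"]))

    def risk_reduction_pct(self, disease: str) -> float:
        sub = self._at_achieve(disease)
        w = sub["population"] * sub[f"{disease}_incidence"]
        return 100.0 * float(1.0 - np.average(sub["rr"], weights=w))

    def summary_outputs(self, horizons: tuple[int, ...]) -> dict[str, float]:
        """Flat dict of every reported output, keyed like the Monte Carlo
        summary, for zero-spread cross-checks and the deterministic CLI."""
        out = {
            "salt_reduction": self.salt_reduction,
            "sbp_reduction": self.sbp_reduction,
            "ihd_risk_pct": self.risk_reduction_pct("ihd"),
            "stroke_risk_pct": self.risk_reduction_pct("stroke"),
        }
        for horizon in horizons:
            cum = self.result.cumulate(horizon)
            for disease in list(DISEASES) + ["cvd"]:
                out[f"events_prevented_{disease}_{horizon}"] = float(
                    cum.loc[disease, "events_prevented"]
                )
                out[f"deaths_prevented_{disease}_{horizon}"] = float(
                    cum.loc[disease, "deaths_prevented"]
                )
                out[f"premature_prevented_{disease}_{horizon}"] = float(
                    cum.loc[disease, "premature_prevented"]
                )
        return out


def run_scenario(
    pop: PopulationTable,
    scenario: Scenario,
    model: SbpEffectModel | str,
    gradient: RiskGradient | None = None,
    premature_frac_65_74: float = DEFAULT_PREMATURE_FRAC_65_74,
) -> DeterministicRun:
    """Build the trajectory, run the chain and tabulate prevented events."""
    if isinstance(model, str):
        model = SbpEffectModel.default(model)
    gradient = gradient or RiskGradient.default()
    trajectory = build_trajectory(pop, scenario)
    chain = apply_chain(trajectory, pop, model, gradient)
    result = yearly_events(pop, chain, premature_frac_65_74)
    return DeterministicRun(scenario, trajectory, chain, result, pop)
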