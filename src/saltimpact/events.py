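"""First-ever CVD events, deaths and premature deaths prevented.

Events are expectations: counterfactual events in a stratum-year are
population x incidence; intervention events are scaled by the relative
risk; the difference is what the salt reduction prevents.  Deaths apply
the stratum's fatal fraction, and premature deaths (before age 70) take
the age bands below 65 in full, a configurable share (default half) of
the 65-74 band, and none of 75-84.

Population counts and incidence rates are held constant over the
horizon, and the susceptible pool is not depleted — the standard
comparative-risk-assessment reading of per-person-year first-event
rates.  Stochastic uncertainty lives in :mod:`saltimpact.uncertainty`,
not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, StratumMismatchError
from .population import AGE_BANDS, DISEASES, KEY_COLUMNS, PopulationTable
from .scenarios import check_same_strata

#: Share of each age band's deaths counted as premature (< 70 years),
#: before the configurable 65-74 apportionment is applied.
PREMATURE_BANDS_FULL = ("35-44", "45-54", "55-64")
PREMATURE_BAND_PARTIAL = "65-74"
DEFAULT_PREMATURE_FRAC_65_74 = 0.5


def premature_weights(frac_65_74: float = DEFAULT_PREMATURE_FRAC_65_74) -> dict[str, float]:
    if not 0.0 <= frac_65_74 <= 1.0:
        raise DomainError(f"frac_65_74 must be in [0, 1], got {frac_65_74}")
    weights = {band: 0.0 for band in AGE_BANDS}
    for band in PREMATURE_BANDS_FULL:
        weights[band] = 1.0
    weights[PREMATURE_BAND_PARTIAL] = frac_65_74
    return weights


def premature_split(
    deaths_by_band: Mapping[str, float] | pd.Series,
    frac_65_74: float = DEFAULT_PREMATURE_FRAC_65_74,
) -> float:
    """Premature (< 70 years) share of deaths tabulated by age band."""
    weights = premature_weights(frac_65_74)
    total = 0.0
    for band, deaths in dict(deaths_by_band).items():
        if band not in weights:
            raise DomainError(f"unknown age band {band!r}")
        total += weights[band] * float(deaths)
    return total


@dataclass(frozen=True)
class ScenarioResult:
    """Per (stratum, year, disease) expected events under both arms.

    ``frame`` columns: KEY_COLUMNS + year, disease, events_counterfactual,
    events_intervention, events_prevented, deaths_prevented,
    premature_prevented.
    """

    frame: pd.DataFrame
    baseline_year: int
    end_year: int

    def cumulate(self, horizon_year: int) -> pd.DataFrame:
        """Cumulative prevented totals over baseline_year+1 .. horizon.

        Returns a frame indexed by disease ('ihd', 'stroke', 'cvd') with
        columns events_prevented, deaths_prevented, premature_prevented.
        """
        if horizon_year > self.end_year:
            raise DomainError(
                f"horizon {horizon_year} is beyond the simulated end year "
                f"{self.end_year}"
            )
        if horizon_year < self.baseline_year:
            raise DomainError(
                f"horizon {horizon_year} precedes the baseline year "
                f"{self.baseline_year}"
            )
        window = self.frame[
            (self.frame["year"] > self.baseline_year)
            & (self.frame["year"] <= horizon_year)
        ]
        cols = ["events_prevented", "deaths_prevented", "premature_prevented"]
        by_disease = window.groupby("disease")[cols].sum()
        by_disease = by_disease.reindex(list(DISEASES)).fillna(0.0)
        by_disease.loc["cvd"] = by_disease.sum(axis=0)
        return by_disease

    def per_year_totals(self) -> pd.DataFrame:
        """Prevented totals per year summed over strata, per disease + cvd."""
        cols = ["events_prevented", "deaths_prevented", "premature_prevented"]
        per = self.frame.groupby(["year", "disease"])[cols].sum().reset_index()
        cvd = per.groupby("year")[cols].sum().reset_index()
        cvd["disease"] = "cvd"
        return pd.concat([per, cvd], ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(Path(path), index=False)


def cumulate(result: ScenarioResult, horizon_year: int) -> pd.DataFrame:
    """Cumulative prevented totals up to a horizon (see
    :meth:`ScenarioResult.cumulate`)."""
    return result.cumulate(horizon_year)


def yearly_events(
    pop: PopulationTable,
    rr_table: pd.DataFrame,
    premature_frac_65_74: float = DEFAULT_PREMATURE_FRAC_65_74,
) -> ScenarioResult:
    """Apply relative risks to baseline disease rates, per stratum-year.

    ``rr_table`` is the output of :func:`saltimpact.dose_response.apply_chain`
    (KEY_COLUMNS + year, disease, rr).  The counterfactual arm always runs
    at baseline incidence (rr = 1 implicitly).
    """
    required = set(KEY_COLUMNS + ["year", "disease", "rr"])
    if not required <= set(rr_table.columns):
        raise DomainError(f"rr_table needs columns {sorted(required)}")
    check_same_strata(
        sorted(set(rr_table[KEY_COLUMNS].itertuples(index=False, name=None))),
        pop.keys(),
        what="rr table and population",
    )
    merged = rr_table.merge(
        pop.frame[
            KEY_COLUMNS
            + ["population", "ihd_incidence", "stroke_incidence",
               "ihd_fatal_frac", "stroke_fatal_frac"]
        ],
        on=KEY_COLUMNS,
        how="left",
        validate="many_to_one",
    )
    incidence = np.where(
        merged["disease"] == "ihd",
        merged["ihd_incidence"],
        merged["stroke_incidence"],
    )
    fatal = np.where(
        merged["disease"] == "ihd",
        merged["ihd_fatal_frac"],
        merged["stroke_fatal_frac"],
    )
    counterfactual = merged["population"].to_numpy() * incidence
    intervention = counterfactual * merged["rr"].to_numpy()
    prevented = counterfactual - intervention
    deaths = prevented * fatal
    weights = premature_weights(premature_frac_65_74)
    premature = deaths * merged["age_band"].map(weights).to_numpy()

    out = merged[KEY_COLUMNS + ["year", "disease"]].copy()
    out["events_counterfactual"] = counterfactual
    out["events_intervention"] = intervention
    out["events_prevented"] = prevented
    out["deaths_prevented"] = deaths
    out["premature_prevented"] = premature
    years = out["year"].to_numpy()
    return ScenarioResult(out, int(years.min()), int(years.max()))
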