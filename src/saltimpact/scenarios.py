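"""Salt-reduction scenarios and per-stratum, per-year intake trajectories.

A scenario is one of:

``fixed_gram``
    an absolute reduction (g/day) ramped linearly and completed by
    ``achieve_year``;
``percent_total``
    a total fractional reduction achieved by compounding the same
    per-year percentage cut in every stratum (e.g. the WHO interim
    target: 30% by 2025, ~7%/year over five annual steps);
``target_level``
    a common absolute end point (g/day, e.g. 5 g/day by 2030) which each
    stratum approaches by compounding its own per-year percentage cut.

After ``achieve_year`` the reduced level is sustained unchanged until
``end_year``.  The counterfactual holds baseline salt flat throughout.
The time grid is integer calendar years; the first reduction step falls
in the year after the baseline year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, StratumMismatchError
from .population import KEY_COLUMNS, PopulationTable

SCENARIO_KINDS = ("fixed_gram", "percent_total", "target_level")


def annual_rate_from_total(total_fraction: float, n_years: int) -> float:
    """Per-year compounding rate a with (1-a)^n_years = 1 - total_fraction.

    E.g. a 30% total reduction over 5 annual steps requires ~6.9%/year
    (reported as 7%/year).
    """
    if not 0 < total_fraction < 1:
        raise DomainError(
            f"total_fraction must be in (0, 1), got {total_fraction}"
        )
    if n_years < 1:
        raise DomainError(f"n_years must be >= 1, got {n_years}")
    return 1.0 - (1.0 - total_fraction) ** (1.0 / n_years)


def annual_rate_from_target(
    baseline_salt: float, target_salt: float, n_years: int
) -> float:
    """Per-year rate a with baseline_salt * (1-a)^n_years = target_salt."""
    if baseline_salt <= 0:
        raise DomainError(f"baseline_salt must be > 0, got {baseline_salt}")
    if not 0 < target_salt < baseline_salt:
        raise DomainError(
            f"target_salt must be in (0, baseline_salt={baseline_salt}), "
            f"got {target_salt}"
        )
    if n_years < 1:
        raise DomainError(f"n_years must be >= 1, got {n_years}")
    return 1.0 - (target_salt / baseline_salt) ** (1.0 / n_years)


@dataclass(frozen=True)
class Scenario:
    """A salt-reduction policy: what to cut, by when, simulated to when."""

    kind: str
    magnitude: float  # g/day (fixed_gram, target_level) or fraction (percent_total)
    achieve_year: int
    end_year: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigError(
                f"kind must be one of {SCENARIO_KINDS}, got {self.kind!r}"
            )
        if not self.magnitude > 0:
            raise ConfigError(f"magnitude must be > 0, got {self.magnitude}")
        if self.kind == "percent_total" and not self.magnitude < 1:
            raise ConfigError(
                f"percent_total magnitude is a fraction in (0, 1), "
                f"got {self.magnitude}"
            )
        if self.end_year < self.achieve_year:
            raise ConfigError(
                f"end_year ({self.end_year}) must be >= achieve_year "
                f"({self.achieve_year})"
            )
        if not self.name:
            object.__setattr__(self, "name", _default_name(self))

    def validate_against(self, baseline_year: int) -> None:
        if self.achieve_year <= baseline_year:
            raise ConfigError(
                f"achieve_year ({self.achieve_year}) must be after the "
                f"baseline year ({baseline_year})"
            )


def _default_name(s: Scenario) -> str:
    if s.kind == "fixed_gram":
        return f"minus_{s.magnitude:g}g_by_{s.achieve_year}"
    if s.kind == "percent_total":
        return f"minus_{100 * s.magnitude:g}pct_by_{s.achieve_year}"
    return f"to_{s.magnitude:g}g_by_{s.achieve_year}"


def paper_scenarios(
    baseline_year: int = 2020, end_year: int = 2040
) -> list[Scenario]:
    """The three policy scenarios modelled throughout: 1 g/day in one
    year, the WHO interim target (-30% by 2025) and the Healthy China
    2030 target (<=5 g/day by 2030)."""
    return [
        Scenario("fixed_gram", 1.0, baseline_year + 1, end_year, name="one_gram"),
        Scenario("percent_total", 0.30, 2025, end_year, name="who_30pct"),
        Scenario("target_level", 5.0, 2030, end_year, name="china_5g"),
    ]


@dataclass(frozen=True)
class SaltTrajectory:
    """Per-stratum, per-year salt path (g/day) and its flat counterfactual."""

    frame: pd.DataFrame  # KEY_COLUMNS + year, salt_intervention, salt_counterfactual
    baseline_year: int
    achieve_year: int
    end_year: int

    def __post_init__(self) -> None:
        f = self.frame
        if (f["salt_intervention"] > f["salt_counterfactual"] + 1e-12).any():
            raise DomainError("intervention salt exceeds the counterfactual")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.baseline_year, self.end_year + 1)

    def salt_at(self, year: int) -> pd.DataFrame:
        return self.frame[self.frame["year"] == year].reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(Path(path), index=False)


def reduction_path(
    baseline_salt: np.ndarray, scenario: Scenario, baseline_year: int, years: np.ndarray
) -> np.ndarray:
    """Salt intake (g/day) per stratum per year under the scenario.

    ``baseline_salt`` has shape (..., S); the result has shape (..., S, Y).
    Shared by the deterministic trajectory builder and the vectorised
    Monte Carlo engine, so both arms use identical arithmetic.
    """
    n = scenario.achieve_year - baseline_year
    steps = np.clip(years - baseline_year, 0, n).astype(float)  # (Y,)
    base = np.asarray(baseline_salt, dtype=float)[..., None]    # (..., S, 1)
    if scenario.kind == "fixed_gram":
        salt = base - scenario.magnitude * steps / n
    elif scenario.kind == "percent_total":
        a = annual_rate_from_total(scenario.magnitude, n)
        salt = base * (1.0 - a) ** steps
    else:  # target_level: per-stratum rate; strata already at/below target stay put
        ratio = np.minimum(scenario.magnitude / base, 1.0)
        salt = base * ratio ** (steps / n)
    return salt


def build_trajectory(pop: PopulationTable, scenario: Scenario) -> SaltTrajectory:
    """Realise a scenario as a per-stratum, per-year salt trajectory."""
    scenario.validate_against(pop.baseline_year)
    frame = pop.frame
    base = frame["salt_mean"].to_numpy()
    years = np.arange(pop.baseline_year, scenario.end_year + 1)

    if scenario.kind == "fixed_gram":
        too_low = base <= scenario.magnitude
        if too_low.any():
            key = tuple(frame.loc[too_low, KEY_COLUMNS].iloc[0])
            raise DomainError(
                f"fixed_gram reduction {scenario.magnitude} g/day exceeds the "
                f"baseline salt of stratum {key}"
            )
    if scenario.kind == "target_level":
        too_low = base <= scenario.magnitude
        if too_low.any():
            key = tuple(frame.loc[too_low, KEY_COLUMNS].iloc[0])
            raise DomainError(
                f"target_level {scenario.magnitude} g/day is not below the "
                f"baseline salt of stratum {key}"
            )

    salt = reduction_path(base, scenario, pop.baseline_year, years)  # (S, Y)
    long = frame[KEY_COLUMNS].loc[frame.index.repeat(len(years))].reset_index(drop=True)
    long["year"] = np.tile(years, len(frame))
    long["salt_intervention"] = salt.ravel()
    long["salt_counterfactual"] = np.repeat(base, len(years))
    return SaltTrajectory(
        long, pop.baseline_year, scenario.achieve_year, scenario.end_year
    )


def check_same_strata(
    a_keys: list[tuple], b_keys: list[tuple], what: str = "tables"
) -> None:
    only_a = sorted(set(a_keys) - set(b_keys))
    only_b = sorted(set(b_keys) - set(a_keys))
    if only_a or only_b:
        raise StratumMismatchError(
            f"{what} cover different strata; unmatched: {only_a + only_b}"
        )
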