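"""Stratified baseline population: data model, CSV I/O and synthetic generator.

The model's world state is a table of demographic strata (region x sex x
age band), each carrying population size, habitual salt intake (mean/SD in
g/day, as measured by 24 h urinary sodium), systolic blood pressure
(mean/SD in mm Hg), hypertension prevalence, and first-ever IHD and stroke
incidence with their fatal fractions.

Because the real stratified baseline tables for China are not publicly
deposited, :func:`generate_population` builds a synthetic stand-in
calibrated to the published national aggregates (salt 11.1 g/day, SBP
128.1 mm Hg) with a north-south salt gradient, age-increasing incidence
and hypertension, and configurable fatality.  Every downstream stage is
exercised against these synthetic tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DuplicateKeyError, RangeError, SchemaError

#: The five age bands for which SBP->risk gradients are available.
AGE_BANDS: tuple[str, ...] = ("35-44", "45-54", "55-64", "65-74", "75-84")
REGIONS: tuple[str, ...] = ("north", "south")
SEXES: tuple[str, ...] = ("male", "female")
DISEASES: tuple[str, ...] = ("ihd", "stroke")

KEY_COLUMNS = ["region", "sex", "age_band"]
NUMERIC_COLUMNS = [
    "population",
    "salt_mean",
    "salt_sd",
    "sbp_mean",
    "sbp_sd",
    "htn_prev",
    "ihd_incidence",
    "stroke_incidence",
    "ihd_fatal_frac",
    "stroke_fatal_frac",
]
POPULATION_COLUMNS = KEY_COLUMNS + NUMERIC_COLUMNS

# Columns constrained to [0, 1].
_FRACTION_COLUMNS = [
    "htn_prev",
    "ihd_incidence",
    "stroke_incidence",
    "ihd_fatal_frac",
    "stroke_fatal_frac",
]


@dataclass(frozen=True)
class Stratum:
    """One demographic cell of the baseline population."""

    region: str
    sex: str
    age_band: str
    population: float
    salt_mean: float
    salt_sd: float
    sbp_mean: float
    sbp_sd: float
    htn_prev: float
    ihd_incidence: float
    stroke_incidence: float
    ihd_fatal_frac: float
    stroke_fatal_frac: float

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise RangeError(
                f"age_band {self.age_band!r} is not one of {AGE_BANDS}"
            )
        if not self.population > 0:
            raise RangeError(f"population must be > 0, got {self.population}")
        for name in ("salt_mean", "sbp_mean"):
            if not getattr(self, name) > 0:
                raise RangeError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("salt_sd", "sbp_sd"):
            if getattr(self, name) < 0:
                raise RangeError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in _FRACTION_COLUMNS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise RangeError(f"{name} must be in [0, 1], got {value}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.region, self.sex, self.age_band)


class PopulationTable:
    """A validated collection of strata plus the baseline calendar year.

    Wraps a :class:`pandas.DataFrame` with one row per stratum and the
    columns in :data:`POPULATION_COLUMNS`.  Construction validates the
    schema, numeric ranges and key uniqueness; instances are treated as
    immutable (``frame`` returns a copy).
    """

    def __init__(
        self,
        strata: pd.DataFrame | Iterable[Stratum],
        baseline_year: int = 2020,
    ) -> None:
        if isinstance(strata, pd.DataFrame):
            frame = strata.copy()
        else:
            rows = list(strata)
            frame = pd.DataFrame([vars(s) for s in rows])
        self._frame = _validate_frame(frame)
        self.baseline_year = int(baseline_year)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def strata(self) -> list[Stratum]:
        return [
            Stratum(**row)  # type: ignore[arg-type]
            for row in self._frame.to_dict(orient="records")
        ]

    @property
    def n_strata(self) -> int:
        return len(self._frame)

    @property
    def total_population(self) -> float:
        return float(self._frame["population"].sum())

    def weighted_mean(self, column: str) -> float:
        """Population-weighted mean of a numeric column."""
        if column not in NUMERIC_COLUMNS:
            raise SchemaError(f"unknown numeric column {column!r}")
        w = self._frame["population"].to_numpy(dtype=float)
        x = self._frame[column].to_numpy(dtype=float)
        return float(np.average(x, weights=w))

    @property
    def salt_mean(self) -> float:
        return self.weighted_mean("salt_mean")

    @property
    def sbp_mean(self) -> float:
        return self.weighted_mean("sbp_mean")

    @property
    def htn_prev(self) -> float:
        return self.weighted_mean("htn_prev")

    def keys(self) -> list[tuple[str, str, str]]:
        return list(
            self._frame[KEY_COLUMNS].itertuples(index=False, name=None)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PopulationTable):
            return NotImplemented
        if self.baseline_year != other.baseline_year:
            return False
        a = self._frame.sort_values(KEY_COLUMNS).reset_index(drop=True)
        b = other._frame.sort_values(KEY_COLUMNS).reset_index(drop=True)
        return a.equals(b)

    def __repr__(self) -> str:
        return (
            f"PopulationTable({self.n_strata} strata, "
            f"baseline_year={self.baseline_year}, "
            f"salt={self.salt_mean:.2f} g/day, sbp={self.sbp_mean:.1f} mm Hg)"
        )


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in POPULATION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise SchemaError("population table must contain at least one stratum")
    frame = frame[POPULATION_COLUMNS].copy()
    for col in KEY_COLUMNS:
        frame[col] = frame[col].astype(str)
    for col in NUMERIC_COLUMNS:
        # python float() is correctly rounded, unlike pandas' fast parser,
        # so CSV round trips preserve every bit
        def _convert(value, col=col):
            try:
                result = float(value)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"non-numeric value {value!r} in column {col!r}"
                ) from None
            if not np.isfinite(result):
                raise SchemaError(
                    f"non-finite value {value!r} in column {col!r}"
                )
            return result

        frame[col] = frame[col].map(_convert).astype(float)

    dupes = frame.duplicated(subset=KEY_COLUMNS, keep=False)
    if dupes.any():
        key = tuple(frame.loc[dupes, KEY_COLUMNS].iloc[0])
        raise DuplicateKeyError(f"duplicate stratum key {key}")

    bad_bands = sorted(set(frame["age_band"]) - set(AGE_BANDS))
    if bad_bands:
        raise RangeError(
            f"age_band {bad_bands[0]!r} is not one of {AGE_BANDS}"
        )
    if (frame["population"] <= 0).any():
        raise RangeError("population must be > 0 in every stratum")
    for col in ("salt_mean", "sbp_mean"):
        if (frame[col] <= 0).any():
            raise RangeError(f"{col} must be > 0 in every stratum")
    for col in ("salt_sd", "sbp_sd"):
        if (frame[col] < 0).any():
            raise RangeError(f"{col} must be >= 0 in every stratum")
    for col in _FRACTION_COLUMNS:
        if ((frame[col] < 0) | (frame[col] > 1)).any():
            bad = frame.loc[(frame[col] < 0) | (frame[col] > 1), col].iloc[0]
            raise RangeError(f"{col} must be in [0, 1], got {bad}")
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_population(path: str | Path, baseline_year: int = 2020) -> PopulationTable:
    """Read a population table from CSV (one row per stratum).

    The CSV must carry exactly the documented header
    (:data:`POPULATION_COLUMNS`); comma-separated, UTF-8, '.' decimal.
    All invariants are enforced on load.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty or has no header") from exc
    return PopulationTable(frame, baseline_year=baseline_year)


def write_population(table: PopulationTable, path: str | Path) -> None:
    """Write a population table as CSV, round-trippable by load_population."""
    if not isinstance(table, PopulationTable):
        raise SchemaError("write_population expects a PopulationTable")
    frame = table.frame[POPULATION_COLUMNS].copy()
    # shortest round-trippable float representation, so load o write = id
    for col in NUMERIC_COLUMNS:
        frame[col] = frame[col].map(repr)
    frame.to_csv(Path(path), index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Calibration targets and structural knobs for the synthetic population.

    The national aggregates default to the published Chinese adult figures:
    salt 11.1 +/- 1.6 g/day and SBP 128.1 +/- 13 mm Hg.  Structure beyond
    the aggregates (north-south salt gap, age gradients of blood pressure,
    hypertension, incidence and fatality) is stylised but ordered the way
    Chinese surveillance data order it.
    """

    target_salt_mean: float = 11.1   # g/day, population-weighted
    target_salt_sd: float = 1.6      # g/day
    target_sbp_mean: float = 128.1   # mm Hg, population-weighted
    target_sbp_sd: float = 13.0      # mm Hg
    north_south_salt_gap: float = 1.5  # g/day, north minus south
    htn_prev_target: float = 0.40    # population-weighted prevalence
    htn_prev_by_band: tuple[float, ...] = (0.15, 0.27, 0.40, 0.52, 0.60)
    ihd_incidence_scale: float = 1.0
    stroke_incidence_scale: float = 1.0
    fatal_frac_target: float = 0.44  # event-weighted, both diseases
    total_population: float = 690e6  # adults 35-84
    baseline_year: int = 2020
    seed: int = 0

    # stylised age profiles (per band, young -> old)
    _band_shares = (0.30, 0.27, 0.21, 0.14, 0.08)
    _ihd_base = (0.0009, 0.0020, 0.0044, 0.0096, 0.0211)
    _stroke_base = (0.0012, 0.0028, 0.0064, 0.0146, 0.0336)
    _fatal_base = (0.25, 0.32, 0.42, 0.52, 0.62)

    def validate(self) -> None:
        positive = (
            "target_salt_mean",
            "target_salt_sd",
            "target_sbp_mean",
            "target_sbp_sd",
            "total_population",
            "ihd_incidence_scale",
            "stroke_incidence_scale",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.north_south_salt_gap < 0:
            raise ConfigError(
                f"north_south_salt_gap must be >= 0, got {self.north_south_salt_gap}"
            )
        for name in ("htn_prev_target", "fatal_frac_target"):
            if not 0 < getattr(self, name) < 1:
                raise ConfigError(
                    f"{name} must be in (0, 1), got {getattr(self, name)}"
                )
        if len(self.htn_prev_by_band) != len(AGE_BANDS):
            raise ConfigError(
                f"htn_prev_by_band must have {len(AGE_BANDS)} entries"
            )
        if any(not 0 < p < 1 for p in self.htn_prev_by_band):
            raise ConfigError("htn_prev_by_band entries must be in (0, 1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "GeneratorConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown generator field(s): {sorted(unknown)}")
        cfg = cls(**dict(mapping))
        if isinstance(cfg.htn_prev_by_band, list):
            cfg.htn_prev_by_band = tuple(cfg.htn_prev_by_band)
        cfg.validate()
        return cfg


def generate_population(config: GeneratorConfig | None = None) -> PopulationTable:
    """Generate a synthetic China-like baseline population.

    Twenty strata (2 regions x 2 sexes x 5 age bands).  Structural means
    (regional gap, sex offsets, age gradients) are laid down first, a small
    seeded jitter is added, and the table is then re-centred so that the
    population-weighted salt and SBP means, the north-south gap and the
    weighted hypertension prevalence hit their configured targets exactly.
    Deterministic for a fixed seed.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_bands = len(AGE_BANDS)
    rows: list[dict] = []
    for region in REGIONS:
        for sex in SEXES:
            for i, band in enumerate(AGE_BANDS):
                rows.append({"region": region, "sex": sex, "age_band": band,
                             "_band_idx": i})
    frame = pd.DataFrame(rows)
    idx = frame["_band_idx"].to_numpy()
    is_north = (frame["region"] == "north").to_numpy()
    is_male = (frame["sex"] == "male").to_numpy()

    # --- population counts: band pyramid x region split x sex split, jittered
    band_shares = np.asarray(config._band_shares)
    region_share = np.where(is_north, 0.44, 0.56)
    pop = config.total_population * band_shares[idx] * region_share * 0.5
    pop = pop * rng.lognormal(0.0, 0.05, size=len(frame))
    frame["population"] = np.round(pop).astype(float)
    w = frame["population"].to_numpy()
    w_total = w.sum()

    # --- salt: region gap + sex offset + mild age decline, then exact
    #     per-region recentring (fixes both the national mean and the gap)
    north_share = w[is_north].sum() / w_total
    salt = np.zeros(len(frame))
    salt += np.where(is_male, 0.6 * (1 - 0.5), -0.6 * 0.5)  # ~+/-0.3 by sex
    salt += -0.1 * (idx - 2)                                # mild age decline
    salt += rng.normal(0.0, 0.10, size=len(frame))
    target_north = config.target_salt_mean + config.north_south_salt_gap * (1 - north_share)
    target_south = config.target_salt_mean - config.north_south_salt_gap * north_share
    for region_mask, target in ((is_north, target_north), (~is_north, target_south)):
        current = np.average(salt[region_mask], weights=w[region_mask])
        salt[region_mask] += target - current
    frame["salt_mean"] = salt
    frame["salt_sd"] = config.target_salt_sd * rng.lognormal(0.0, 0.05, len(frame))

    # --- SBP: age gradient + sex + region, recentred to the national mean
    sbp = 8.0 * (idx - 2.0)                 # ~+8 mm Hg per decade of age
    sbp += np.where(is_male, 1.5, -1.5)
    sbp += np.where(is_north, 1.0, -1.0)
    sbp += rng.normal(0.0, 1.0, size=len(frame))
    sbp += config.target_sbp_mean - np.average(sbp, weights=w)
    frame["sbp_mean"] = sbp
    frame["sbp_sd"] = config.target_sbp_sd * rng.lognormal(0.0, 0.05, len(frame))

    # --- hypertension prevalence: age profile scaled to the weighted target
    htn = np.asarray(config.htn_prev_by_band)[idx]
    htn = htn * rng.lognormal(0.0, 0.03, size=len(frame))
    htn = htn * (config.htn_prev_target / np.average(htn, weights=w))
    frame["htn_prev"] = np.clip(htn, 0.0, 0.95)

    # --- incidence: steep age gradient, region/sex multipliers, jitter
    ihd = np.asarray(config._ihd_base)[idx] * config.ihd_incidence_scale
    stroke = np.asarray(config._stroke_base)[idx] * config.stroke_incidence_scale
    region_mult = np.where(is_north, 1.15, 0.88)
    sex_mult = np.where(is_male, 1.25, 0.80)
    jitter_ihd = rng.lognormal(0.0, 0.08, size=len(frame))
    jitter_stroke = rng.lognormal(0.0, 0.08, size=len(frame))
    frame["ihd_incidence"] = np.clip(ihd * region_mult * sex_mult * jitter_ihd, 0, 1)
    frame["stroke_incidence"] = np.clip(
        stroke * region_mult * sex_mult * jitter_stroke, 0, 1
    )

    # --- fatal fractions: age profile, rescaled so the event-weighted
    #     aggregate hits the configured target per disease
    for disease, offset in (("ihd", 0.0), ("stroke", 0.03)):
        fatal = np.asarray(config._fatal_base)[idx] + offset
        fatal = fatal * rng.lognormal(0.0, 0.03, size=len(frame))
        events = w * frame[f"{disease}_incidence"].to_numpy()
        fatal = fatal * (config.fatal_frac_target / np.average(fatal, weights=events))
        frame[f"{disease}_fatal_frac"] = np.clip(fatal, 0.0, 0.95)

    frame = frame.drop(columns="_band_idx")
    return PopulationTable(frame, baseline_year=config.baseline_year)
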