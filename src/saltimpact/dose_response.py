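"""The two-step dose-response chain: salt -> SBP -> relative risk.

Step one converts a salt reduction (g/day) into an SBP fall (mm Hg),
linearly.  Two slope variants exist: ``trial_based`` mixes separate
normotensive and hypertensive per-gram effects by a stratum's
hypertension prevalence; ``population_based`` applies a single per-gram
slope for all adults that reflects the more prolonged effect of salt
reduction observed over several years.

Step two converts the SBP fall into a relative-risk multiplier per
disease and age band.  The gradients r are proportional risk reductions
per 1 mm Hg; a fall of dSBP compounds log-linearly,

    RR = (1 - r) ** dSBP,

the proportional-hazards reading of cohort-derived per-mm-Hg gradients
(naive linear scaling overshoots at the large SBP falls of the stronger
scenarios).

All parameters live in the packaged ``data/defaults.yaml`` with their
95% CIs, so the numbers are versioned data rather than code constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DomainError
from .population import AGE_BANDS, DISEASES, KEY_COLUMNS, PopulationTable
from .scenarios import SaltTrajectory, check_same_strata

SBP_MODEL_VARIANTS = ("trial_based", "population_based")

#: Hypertension prevalence assumed when a stratum does not supply one.
DEFAULT_HTN_PREV = 0.40


def _load_defaults() -> dict:
    text = resources.files("saltimpact").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class SbpEffectModel:
    """Salt->SBP slopes (mm Hg per 1 g/day reduced) with their 95% CIs."""

    variant: str
    beta_normo: float
    beta_normo_ci: tuple[float, float]
    beta_hyper: float
    beta_hyper_ci: tuple[float, float]
    beta_all: float
    beta_all_ci: tuple[float, float]

    def __post_init__(self) -> None:
        if self.variant not in SBP_MODEL_VARIANTS:
            raise ConfigError(
                f"variant must be one of {SBP_MODEL_VARIANTS}, got {self.variant!r}"
            )
        for name in ("beta_normo", "beta_hyper", "beta_all"):
            est = getattr(self, name)
            lo, hi = getattr(self, f"{name}_ci")
            if not est > 0:
                raise ConfigError(f"{name} must be > 0, got {est}")
            if not lo <= est <= hi:
                raise ConfigError(
                    f"{name} CI ({lo}, {hi}) does not bracket the estimate {est}"
                )

    @classmethod
    def default(cls, variant: str) -> "SbpEffectModel":
        params = _load_defaults()["sbp_effect"]
        return cls.from_mapping(variant, params)

    @classmethod
    def from_mapping(cls, variant: str, params: Mapping) -> "SbpEffectModel":
        kwargs = {}
        for name in ("beta_normo", "beta_hyper", "beta_all"):
            entry = params[name]
            kwargs[name] = float(entry["estimate"])
            kwargs[f"{name}_ci"] = (float(entry["ci"][0]), float(entry["ci"][1]))
        return cls(variant=variant, **kwargs)

    def effective_slope(self, htn_prev):
        """mm Hg fall per 1 g/day of salt reduction, given hypertension
        prevalence (ignored by the population_based variant)."""
        if self.variant == "population_based":
            return self.beta_all * np.ones_like(np.asarray(htn_prev, dtype=float))
        htn_prev = np.asarray(htn_prev, dtype=float)
        return htn_prev * self.beta_hyper + (1.0 - htn_prev) * self.beta_normo


@dataclass(frozen=True)
class RiskGradient:
    """Per-disease, per-age-band proportional risk reduction per 1 mm Hg.

    ``frame`` has columns disease, age_band, r, r_lo, r_hi with the five
    age bands per disease, r non-increasing with age.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        required = {"disease", "age_band", "r", "r_lo", "r_hi"}
        if not required <= set(f.columns):
            raise ConfigError(f"risk gradient table needs columns {sorted(required)}")
        cache: dict[tuple[str, str], np.ndarray] = {}
        for disease in DISEASES:
            sub = f[f["disease"] == disease].set_index("age_band")
            missing = set(AGE_BANDS) - set(sub.index)
            if missing:
                raise ConfigError(
                    f"risk gradient for {disease} missing bands {sorted(missing)}"
                )
            for column in ("r", "r_lo", "r_hi"):
                cache[(disease, column)] = sub.loc[
                    list(AGE_BANDS), column
                ].to_numpy(dtype=float)
            r = cache[(disease, "r")]
            if not ((r > 0) & (r < 1)).all():
                raise ConfigError(f"risk gradients for {disease} must lie in (0, 1)")
            if not (np.diff(r) <= 1e-12).all():
                raise ConfigError(
                    f"risk gradients for {disease} must be non-increasing with age"
                )
        object.__setattr__(self, "_band_arrays", cache)

    @classmethod
    def default(cls) -> "RiskGradient":
        return cls.from_mapping(_load_defaults()["risk_gradient"])

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RiskGradient":
        rows = []
        for disease, bands in mapping.items():
            for band, entry in bands.items():
                rows.append(
                    {
                        "disease": disease,
                        "age_band": str(band),
                        "r": float(entry["estimate"]),
                        "r_lo": float(entry["ci"][0]),
                        "r_hi": float(entry["ci"][1]),
                    }
                )
        return cls(pd.DataFrame(rows))

    def r(self, disease: str, age_band: str) -> float:
        sub = self.frame
        sel = sub[(sub["disease"] == disease) & (sub["age_band"] == age_band)]
        if len(sel) != 1:
            raise DomainError(f"no gradient for ({disease}, {age_band})")
        return float(sel["r"].iloc[0])

    def values(self, disease: str, column: str = "r") -> np.ndarray:
        """Gradient values over the five age bands, young to old."""
        try:
            return self._band_arrays[(disease, column)]  # type: ignore[attr-defined]
        except KeyError:
            raise DomainError(f"no gradient column {column!r} for {disease!r}")

    def to_yaml(self, path: str | Path) -> None:
        mapping: dict = {}
        for row in self.frame.to_dict(orient="records"):
            mapping.setdefault(row["disease"], {})[row["age_band"]] = {
                "estimate": row["r"],
                "ci": [row["r_lo"], row["r_hi"]],
            }
        Path(path).write_text(yaml.safe_dump({"risk_gradient": mapping}))


def sbp_drop(delta_salt, model: SbpEffectModel, htn_prev=DEFAULT_HTN_PREV):
    """SBP fall (mm Hg) for a salt reduction (g/day), linear in grams."""
    delta_salt = np.asarray(delta_salt, dtype=float)
    if (delta_salt < 0).any():
        raise DomainError("delta_salt must be >= 0")
    htn_prev = np.asarray(htn_prev, dtype=float)
    if ((htn_prev < 0) | (htn_prev > 1)).any():
        raise DomainError("htn_prev must be in [0, 1]")
    out = model.effective_slope(htn_prev) * delta_salt
    return float(out) if out.ndim == 0 else out


def relative_risk(delta_sbp, r):
    """Relative-risk multiplier (1 - r) ** delta_sbp for an SBP fall."""
    delta_sbp = np.asarray(delta_sbp, dtype=float)
    if (delta_sbp < 0).any():
        raise DomainError("delta_sbp must be >= 0")
    r = np.asarray(r, dtype=float)
    if ((r <= 0) | (r >= 1)).any():
        raise DomainError("r must be in (0, 1)")
    out = (1.0 - r) ** delta_sbp
    return float(out) if out.ndim == 0 else out


def apply_chain(
    trajectory: SaltTrajectory,
    pop: PopulationTable,
    model: SbpEffectModel,
    gradient: RiskGradient,
) -> pd.DataFrame:
    """Run the two-step chain over a whole trajectory.

    Returns a long table with one row per (stratum, year, disease):
    KEY_COLUMNS + year, disease, delta_salt, delta_sbp, rr.  Counterfactual
    exposure equals baseline everywhere, so rows with no reduction carry
    rr = 1 exactly.
    """
    traj = trajectory.frame
    check_same_strata(
        sorted(set(map(tuple, traj[KEY_COLUMNS].itertuples(index=False, name=None)))),
        pop.keys(),
        what="trajectory and population",
    )
    merged = traj.merge(
        pop.frame[KEY_COLUMNS + ["htn_prev"]],
        on=KEY_COLUMNS,
        how="left",
        validate="many_to_one",
    )
    delta_salt = (
        merged["salt_counterfactual"] - merged["salt_intervention"]
    ).to_numpy()
    delta_salt = np.where(np.abs(delta_salt) < 1e-15, 0.0, delta_salt)
    delta_sbp = sbp_drop(delta_salt, model, merged["htn_prev"].to_numpy())

    band_index = {band: i for i, band in enumerate(AGE_BANDS)}
    band_idx = merged["age_band"].map(band_index).to_numpy()

    pieces = []
    for disease in DISEASES:
        r = gradient.values(disease)[band_idx]
        rr = relative_risk(delta_sbp, r)
        piece = merged[KEY_COLUMNS + ["year"]].copy()
        piece["disease"] = disease
        piece["delta_salt"] = delta_salt
        piece["delta_sbp"] = delta_sbp
        piece["rr"] = rr
        pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)
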