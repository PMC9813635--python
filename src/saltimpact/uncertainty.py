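"""Monte Carlo propagation of parameter uncertainty through the chain.

Each iteration draws one value per uncertain parameter — the national
baseline salt mean (normal, SD 1.6 g/day), baseline SBP mean (normal,
SD 13 mm Hg), the salt->SBP slopes and the SBP->risk gradients (normal
on the stated scale with SD derived from their 95% CIs), and a
mean-preserving lognormal multiplier on each disease's incidence — and
runs the whole scenario pipeline with those values.  A draw is shared
across all strata within an iteration (the parameters are estimates of
common effects), and every draw is a deterministic function of
(seed, iteration_index).  Reported central values are medians with
2.5/97.5 percentile uncertainty intervals, over 5000 iterations by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dose_response import RiskGradient, SbpEffectModel
from .errors import ConfigError
from .events import DEFAULT_PREMATURE_FRAC_65_74, premature_weights
from .population import AGE_BANDS, DISEASES, PopulationTable
from .scenarios import Scenario, reduction_path

#: 95% CI half-width in standard deviations.
_Z95 = 1.959963984540054


def ci_to_sd(lo: float, hi: float) -> float:
    """SD implied by a normal 95% CI."""
    return (hi - lo) / (2.0 * _Z95)


@dataclass
class UncertaintyConfig:
    """What to sample, how widely, and with which seed.

    ``salt_mean_sd`` and ``sbp_mean_sd`` are the spreads of the national
    baseline means (the published 11.1 +/- 1.6 and 128.1 +/- 13);
    ``incidence_cv`` is the coefficient of variation of the lognormal
    incidence multiplier; ``sample_effects`` toggles drawing the
    dose-response parameters from their 95% CIs.
    """

    n_iterations: int = 5000
    seed: int = 0
    salt_mean_sd: float = 1.6    # g/day
    sbp_mean_sd: float = 13.0    # mm Hg
    incidence_cv: float = 0.10
    sample_effects: bool = True

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ConfigError(
                f"n_iterations must be >= 1, got {self.n_iterations}"
            )
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")
        for name in ("salt_mean_sd", "sbp_mean_sd", "incidence_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")

    @classmethod
    def zero_spread(cls, n_iterations: int = 1, seed: int = 0) -> "UncertaintyConfig":
        """Degenerate configuration: every draw equals the point estimate."""
        return cls(
            n_iterations=n_iterations,
            seed=seed,
            salt_mean_sd=0.0,
            sbp_mean_sd=0.0,
            incidence_cv=0.0,
            sample_effects=False,
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "UncertaintyConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown uncertainty field(s): {sorted(unknown)}")
        cfg = cls(**dict(mapping))
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class ParameterDraw:
    """One iteration's sampled parameter set."""

    salt_shift: float           # added to every stratum's salt mean (g/day)
    sbp_shift: float            # added to every stratum's SBP mean (mm Hg)
    beta_normo: float
    beta_hyper: float
    beta_all: float
    r: dict                     # disease -> array over the five age bands
    incidence_mult: dict        # disease -> multiplier


def draw_parameters(
    config: UncertaintyConfig,
    iteration_index: int,
    model: SbpEffectModel | None = None,
    gradient: RiskGradient | None = None,
) -> ParameterDraw:
    """Sample one parameter set, deterministically in (seed, iteration)."""
    config.validate()
    model = model or SbpEffectModel.default("population_based")
    gradient = gradient or RiskGradient.default()
    rng = np.random.default_rng((config.seed, int(iteration_index)))

    salt_shift = float(rng.normal(0.0, config.salt_mean_sd))
    sbp_shift = float(rng.normal(0.0, config.sbp_mean_sd))

    betas = {}
    for name in ("beta_normo", "beta_hyper", "beta_all"):
        point = getattr(model, name)
        if config.sample_effects:
            lo, hi = getattr(model, f"{name}_ci")
            betas[name] = float(max(rng.normal(point, ci_to_sd(lo, hi)), 0.0))
        else:
            rng.normal()  # keep the stream aligned across configurations
            betas[name] = float(point)

    r_draw: dict[str, np.ndarray] = {}
    for disease in DISEASES:
        point = gradient.values(disease)
        noise = rng.normal(size=len(AGE_BANDS))
        if config.sample_effects:
            sd = np.array(
                [
                    ci_to_sd(lo, hi)
                    for lo, hi in zip(
                        gradient.values(disease, "r_lo"),
                        gradient.values(disease, "r_hi"),
                    )
                ]
            )
            r_draw[disease] = np.clip(point + sd * noise, 1e-9, 1.0 - 1e-9)
        else:
            r_draw[disease] = point.copy()

    incidence_mult: dict[str, float] = {}
    for disease in DISEASES:
        noise = rng.normal()
        if config.incidence_cv > 0:
            sigma = float(np.sqrt(np.log(1.0 + config.incidence_cv**2)))
            incidence_mult[disease] = float(np.exp(-0.5 * sigma**2 + sigma * noise))
        else:
            incidence_mult[disease] = 1.0

    return ParameterDraw(
        salt_shift=salt_shift,
        sbp_shift=sbp_shift,
        r=r_draw,
        incidence_mult=incidence_mult,
        **betas,
    )


@dataclass(frozen=True)
class UncertaintySummary:
    """Median and 95% uncertainty interval per reported output.

    ``frame`` is indexed by output name with columns median, lo, hi
    (2.5 and 97.5 percentiles).
    """

    frame: pd.DataFrame
    n_iterations: int

    def __post_init__(self) -> None:
        f = self.frame
        bad = f[(f["lo"] > f["median"] + 1e-12) | (f["median"] > f["hi"] + 1e-12)]
        if len(bad):
            raise ConfigError(
                f"summary violates lo <= median <= hi for {list(bad.index)}"
            )

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        row = self.frame.loc[name]
        return (float(row["median"]), float(row["lo"]), float(row["hi"]))

    def median(self, name: str) -> float:
        return float(self.frame.loc[name, "median"])

    @property
    def outputs(self) -> list[str]:
        return list(self.frame.index)

    def to_csv(self, path: str | Path) -> None:
        self.frame.rename_axis("output").to_csv(Path(path))

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: {
                "median": float(row["median"]),
                "lo": float(row["lo"]),
                "hi": float(row["hi"]),
            }
            for name, row in self.frame.iterrows()
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def run_monte_carlo(
    pop: PopulationTable,
    scenario: Scenario,
    model: SbpEffectModel | str,
    gradient: RiskGradient | None = None,
    config: UncertaintyConfig | None = None,
    horizons: tuple[int, ...] = (2030, 2040),
    premature_frac_65_74: float = DEFAULT_PREMATURE_FRAC_65_74,
) -> UncertaintySummary:
    """Run the full pipeline once per iteration with drawn parameters.

    The per-iteration pipeline is vectorised over iterations but applies
    exactly the arithmetic of the deterministic modules
    (:func:`saltimpact.scenarios.reduction_path` for the salt path,
    linear salt->SBP, (1-r)**dSBP for risk, expectation bookkeeping for
    events), so a zero-spread configuration reproduces the deterministic
    run's outputs.
    """
    if isinstance(model, str):
        model = SbpEffectModel.default(model)
    gradient = gradient or RiskGradient.default()
    config = config or UncertaintyConfig()
    config.validate()
    scenario.validate_against(pop.baseline_year)
    for horizon in horizons:
        if horizon > scenario.end_year:
            raise ConfigError(
                f"horizon {horizon} is beyond the scenario end year "
                f"{scenario.end_year}"
            )

    frame = pop.frame
    n_iter = config.n_iterations
    w = frame["population"].to_numpy()
    base_salt = frame["salt_mean"].to_numpy()
    htn = frame["htn_prev"].to_numpy()
    band_index = {band: i for i, band in enumerate(AGE_BANDS)}
    band_idx = frame["age_band"].map(band_index).to_numpy()
    prem_w = frame["age_band"].map(premature_weights(premature_frac_65_74)).to_numpy()
    incidence = {d: frame[f"{d}_incidence"].to_numpy() for d in DISEASES}
    fatal = {d: frame[f"{d}_fatal_frac"].to_numpy() for d in DISEASES}

    draws = [
        draw_parameters(config, i, model=model, gradient=gradient)
        for i in range(n_iter)
    ]
    salt_shift = np.array([d.salt_shift for d in draws])
    beta = {
        name: np.array([getattr(d, name) for d in draws])
        for name in ("beta_normo", "beta_hyper", "beta_all")
    }
    r_draws = {d: np.stack([draw.r[d] for draw in draws]) for d in DISEASES}
    inc_mult = {
        d: np.array([draw.incidence_mult[d] for draw in draws]) for d in DISEASES
    }

    years = np.arange(pop.baseline_year, scenario.end_year + 1)
    i_achieve = int(np.searchsorted(years, scenario.achieve_year))

    # shifted per-iteration baselines; a draw below the scenario's floor
    # simply has nothing left to cut
    base_i = np.clip(base_salt[None, :] + salt_shift[:, None], 1e-3, None)
    salt_path = reduction_path(base_i, scenario, pop.baseline_year, years)
    salt_path = np.clip(salt_path, 0.0, None)
    delta_salt = np.clip(base_i[:, :, None] - salt_path, 0.0, None)  # (I, S, Y)

    if model.variant == "population_based":
        beta_eff = np.broadcast_to(
            beta["beta_all"][:, None], (n_iter, len(frame))
        )
    else:
        beta_eff = (
            htn[None, :] * beta["beta_hyper"][:, None]
            + (1.0 - htn[None, :]) * beta["beta_normo"][:, None]
        )
    delta_sbp = beta_eff[:, :, None] * delta_salt  # (I, S, Y)

    outputs: dict[str, np.ndarray] = {
        "salt_reduction": np.average(
            delta_salt[:, :, i_achieve], weights=w, axis=1
        ),
        "sbp_reduction": np.average(
            delta_sbp[:, :, i_achieve], weights=w, axis=1
        ),
    }

    cum: dict[str, dict] = {h: {} for h in horizons}
    for disease in DISEASES:
        r_strata = r_draws[disease][:, band_idx]  # (I, S)
        rr = (1.0 - r_strata)[:, :, None] ** delta_sbp  # (I, S, Y)
        events_weight = w * incidence[disease]
        outputs[f"{disease}_risk_pct"] = 100.0 * (
            1.0 - np.average(rr[:, :, i_achieve], weights=events_weight, axis=1)
        )
        events_cf = events_weight[None, :] * inc_mult[disease][:, None]  # (I, S)
        prevented = events_cf[:, :, None] * (1.0 - rr)  # (I, S, Y)
        deaths = prevented * fatal[disease][None, :, None]
        premature = deaths * prem_w[None, :, None]
        for horizon in horizons:
            window = (years > pop.baseline_year) & (years <= horizon)
            cum[horizon][disease] = {
                "events": prevented[:, :, window].sum(axis=(1, 2)),
                "deaths": deaths[:, :, window].sum(axis=(1, 2)),
                "premature": premature[:, :, window].sum(axis=(1, 2)),
            }

    for horizon in horizons:
        for disease in list(DISEASES) + ["cvd"]:
            for kind, label in (
                ("events", "events_prevented"),
                ("deaths", "deaths_prevented"),
                ("premature", "premature_prevented"),
            ):
                if disease == "cvd":
                    values = sum(cum[horizon][d][kind] for d in DISEASES)
                else:
                    values = cum[horizon][disease][kind]
                outputs[f"{label}_{disease}_{horizon}"] = values

    rows = {
        name: {
            "median": float(np.median(values)),
            "lo": float(np.percentile(values, 2.5)),
            "hi": float(np.percentile(values, 97.5)),
        }
        for name, values in outputs.items()
    }
    summary_frame = pd.DataFrame.from_dict(rows, orient="index")[
        ["median", "lo", "hi"]
    ]
    return UncertaintySummary(summary_frame, n_iterations=n_iter)
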