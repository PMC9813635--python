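"""Formatting and file outputs for scenario summaries.

Numbers are rendered the way the scenario tables print them: reductions
as negative "median (lo to hi)" strings with one decimal, cumulative
event counts in millions with one decimal.  Rounding is half away from
zero, via :mod:`decimal`, so formatted values are reproducible.
"""

from __future__ import annotations

import decimal
import hashlib
import json
from pathlib import Path

import pandas as pd

from .population import DISEASES
from .uncertainty import UncertaintySummary

#: outputs reported as reductions (rendered with a leading minus)
_REDUCTION_DECIMALS = {
    "salt_reduction": 1,
    "sbp_reduction": 1,
    "ihd_risk_pct": 1,
    "stroke_risk_pct": 1,
}
_REDUCTION_LABELS = {
    "salt_reduction": "Salt intake (g/day)",
    "sbp_reduction": "SBP (mm Hg)",
    "ihd_risk_pct": "IHD risk (%)",
    "stroke_risk_pct": "Stroke risk (%)",
}


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (1.25 -> 1.3, -1.25 -> -1.3)."""
    quantum = decimal.Decimal(1).scaleb(-decimals)
    d = decimal.Decimal(repr(float(value))).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


def format_value(value: float, decimals: int = 1) -> str:
    return f"{round_half_away(value, decimals):.{decimals}f}"


def format_change(
    median: float, lo: float, hi: float, decimals: int = 1, negate: bool = True
) -> str:
    """Render a reduction as "-1.9 (-1.5 to -2.4)".

    With ``negate`` the inputs are magnitudes of reduction and the output
    carries the sign of a fall; the interval keeps the (lo, hi) order of
    the underlying draws.
    """
    sign = -1.0 if negate else 1.0
    m, a, b = (format_value(sign * x, decimals) for x in (median, lo, hi))
    return f"{m} ({a} to {b})"


def format_millions(value: float) -> str:
    """Counts in millions with one decimal: 8 950 000 -> '9.0M'."""
    return f"{format_value(value / 1e6, 1)}M"


def format_summary(summary: UncertaintySummary) -> str:
    """Text table of one scenario's summary: reductions then cumulative
    prevented events/deaths in millions."""
    lines = []
    for name, label in _REDUCTION_LABELS.items():
        if name in summary.outputs:
            m, lo, hi = summary[name]
            lines.append(f"{label}: {format_change(m, lo, hi)}")
    for name in summary.outputs:
        if name in _REDUCTION_LABELS:
            continue
        m, lo, hi = summary[name]
        lines.append(
            f"{name}: {format_millions(m)} "
            f"({format_millions(lo)} to {format_millions(hi)})"
        )
    return "\n".join(lines)


def scenario_summary_frame(
    summaries: dict[tuple[str, str], UncertaintySummary]
) -> pd.DataFrame:
    """Tidy per-(scenario, SBP model) table of the exposure/risk outputs.

    ``summaries`` maps (scenario_name, sbp_model_variant) to a summary.
    """
    rows = []
    for (scenario, variant), summary in summaries.items():
        row: dict = {"scenario": scenario, "sbp_model": variant}
        for name in _REDUCTION_DECIMALS:
            m, lo, hi = summary[name]
            row[f"{name}_median"] = m
            row[f"{name}_lo"] = lo
            row[f"{name}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def events_prevented_frame(
    summaries: dict[tuple[str, str], UncertaintySummary],
    horizons: tuple[int, ...],
) -> pd.DataFrame:
    """Tidy cumulative prevented counts per scenario, model, horizon and
    disease (including combined 'cvd')."""
    rows = []
    for (scenario, variant), summary in summaries.items():
        for horizon in horizons:
            for disease in list(DISEASES) + ["cvd"]:
                row = {
                    "scenario": scenario,
                    "sbp_model": variant,
                    "horizon": horizon,
                    "disease": disease,
                }
                for label in (
                    "events_prevented",
                    "deaths_prevented",
                    "premature_prevented",
                ):
                    m, lo, hi = summary[f"{label}_{disease}_{horizon}"]
                    row[f"{label}_median"] = m
                    row[f"{label}_lo"] = lo
                    row[f"{label}_hi"] = hi
                rows.append(row)
    return pd.DataFrame(rows)


def write_manifest(path: Path, config_text: str, seed: int, n_iterations: int) -> None:
    import numpy
    import saltimpact

    manifest = {
        "package": "saltimpact",
        "version": saltimpact.__version__,
        "seed": seed,
        "n_iterations": n_iterations,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
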