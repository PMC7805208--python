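"""Comparison statistics and tables.

Aggregates per-reactor steady-state results into plant totals (flux-weighted
methane), relative error against plant measurements, and relative change of
the alternative concepts against the modelled classical baseline. The
published full-scale reference figures (validation measurements, modelled
baselines and the per-reactor summaries of the alternative concepts) ship as
a plain-text fixture for cross-checking.
"""

from __future__ import annotations

import importlib.resources
import json
from functools import lru_cache
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "published_tables", "weighted_totals", "relative_error",
    "relative_change", "scenario_table", "write_results", "round_half_up",
]


@lru_cache(maxsize=1)
def published_tables() -> dict:
    """Published reference figures (validation, alternatives, comparison)."""
    ref = importlib.resources.files("adsim.data") / "published.yaml"
    return yaml.safe_load(ref.read_text())


def weighted_totals(records) -> tuple[float, float]:
    """Plant total from per-reactor (flux, CH4%) records.

    Total flux is the sum; total methane content is flux-weighted, i.e. the
    composition of the mixed streams.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    fluxes = [float(f) for f, _ in records]
    if any(f < 0 for f in fluxes):
        raise ValueError("fluxes must be non-negative")
    total = sum(fluxes)
    if total <= 0:
        raise ValueError("all fluxes are zero; methane share undefined")
    ch4 = sum(float(f) * float(c) for f, c in records)
    return total, ch4 / total


def relative_error(experiment: float, model: float) -> float:
    """Unsigned relative deviation of the model from the measurement [%]."""
    if experiment == 0:
        raise ValueError("experimental value must be nonzero")
    return 100.0 * abs(experiment - model) / abs(experiment)


def relative_change(baseline: float, variant: float) -> float:
    """Signed relative change of a variant against its baseline [%]."""
    if baseline == 0:
        raise ValueError("baseline value must be nonzero")
    return 100.0 * (variant - baseline) / baseline


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding at table precision (half away from zero)."""
    import math
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def scenario_table(results, baselines) -> pd.DataFrame:
    """Tabulate scenarios against their classical baselines.

    Parameters
    ----------
    results : iterable of ScenarioResult (or objects with the same fields)
    baselines : mapping case_id -> (flux, ch4) of the modelled classical run

    Returns one row per reactor plus a total row per scenario, with the
    total rows carrying the deltas against the baseline.
    """
    rows = []
    for res in results:
        base = baselines.get(res.case_id) if hasattr(baselines, "get") else None
        if base is None:
            raise ValueError(f"missing classical baseline for case {res.case_id}")
        b_flux, b_ch4 = base
        for rec in res.reactors:
            rows.append({
                "case": res.case_id, "mode": res.mode, "reactor": rec.label,
                "flux_Nm3_d": rec.F_OUT_gas_N, "ch4_pct": rec.ch4_fraction,
                "total_flux": None, "total_ch4": None,
                "delta_flux_pct": None, "delta_ch4_pct": None,
            })
        rows.append({
            "case": res.case_id, "mode": res.mode, "reactor": "total",
            "flux_Nm3_d": res.total_flux, "ch4_pct": res.total_ch4,
            "total_flux": res.total_flux, "total_ch4": res.total_ch4,
            "delta_flux_pct": relative_change(b_flux, res.total_flux),
            "delta_ch4_pct": relative_change(b_ch4, res.total_ch4),
        })
    columns = ["case", "mode", "reactor", "flux_Nm3_d", "ch4_pct",
               "total_flux", "total_ch4", "delta_flux_pct", "delta_ch4_pct"]
    return pd.DataFrame(rows, columns=columns)


def write_results(report: pd.DataFrame, path, format: str = "csv") -> Path:
    """Write a report at full precision with a deterministic column order."""
    path = Path(path)
    if format == "csv":
        report.to_csv(path, index=False)
    elif format == "json":
        payload = report.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")
    return path
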