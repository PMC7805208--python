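"""Feedstock definitions and inflow vectors.

A feedstock is characterised the way full-scale digesters are usually
described: a single COD feeding value ``Xc`` for the raw composite plus four
mass-fractionation factors splitting it into protein, lipid, carbohydrate and
inert pools on disintegration. The four bundled cases describe maize silage
diluted with water or pig manure; their printed fraction sets sum to slightly
more than 1 (rounding), so they are renormalized on load to keep the
disintegration stoichiometry COD-conserving.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .components import IDX, zero_liquid

__all__ = [
    "FeedstockSpec",
    "load_case",
    "load_feedstock_file",
    "renormalize_fractions",
    "inflow_concentrations",
    "synthesize_feedstock",
]

_FRACTION_NAMES = ("f_pr", "f_li", "f_ch", "f_ine")


@dataclass(frozen=True)
class FeedstockSpec:
    """Raw-biomass inflow definition for the first reactor.

    Parameters
    ----------
    label : str
        Human-readable identifier.
    composition : dict
        Ingredient volume fractions (maize silage ``MS``, pig manure ``PM``,
        water ``W``); must sum to 1.
    Xc : float
        COD feeding value of the composite [kgCOD/m3].
    f_pr, f_li, f_ch, f_ine : float
        Mass-fractionation factors (protein, lipid, carbohydrate, inert).
    F_IN : float
        Input volumetric flux [m3/d].
    """

    label: str
    composition: dict
    Xc: float
    f_pr: float
    f_li: float
    f_ch: float
    f_ine: float
    F_IN: float

    def __post_init__(self):
        if self.Xc <= 0:
            raise ValueError(f"Xc must be positive, got {self.Xc}")
        if self.F_IN <= 0:
            raise ValueError(f"F_IN must be positive, got {self.F_IN}")
        for name in _FRACTION_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.composition:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"ingredient volume fractions must sum to 1, got {total}"
                )

    @property
    def fractions(self) -> np.ndarray:
        """(f_pr, f_li, f_ch, f_ine) as an array."""
        return np.array([self.f_pr, self.f_li, self.f_ch, self.f_ine])

    @property
    def fraction_sum(self) -> float:
        return float(self.fractions.sum())


def _spec_from_mapping(raw: dict) -> FeedstockSpec:
    spec = FeedstockSpec(
        label=str(raw["label"]),
        composition={k: float(v) for k, v in (raw.get("composition") or {}).items()},
        Xc=float(raw["Xc"]),
        f_pr=float(raw["f_pr"]),
        f_li=float(raw["f_li"]),
        f_ch=float(raw["f_ch"]),
        f_ine=float(raw["f_ine"]),
        F_IN=float(raw["F_IN"]),
    )
    return renormalize_fractions(spec)


def load_case(case_id: int) -> FeedstockSpec:
    """Load one of the four bundled full-scale feedstock cases.

    Fractions are renormalized to sum to exactly 1.
    """
    if case_id not in (1, 2, 3, 4):
        raise ValueError(f"no such case: {case_id!r} (valid cases are 1-4)")
    ref = importlib.resources.files("adsim.data") / f"case{case_id}.yaml"
    raw = yaml.safe_load(ref.read_text())
    return _spec_from_mapping(raw)


def load_feedstock_file(path) -> FeedstockSpec:
    """Load a feedstock definition from a user YAML file (same keys as the
    bundled case files)."""
    raw = yaml.safe_load(Path(path).read_text())
    return _spec_from_mapping(raw)


def renormalize_fractions(spec: FeedstockSpec) -> FeedstockSpec:
    """Scale the four fractionation factors so they sum to exactly 1.

    Relative proportions are preserved; an all-zero fraction set is invalid.
    """
    total = spec.fraction_sum
    if total <= 0:
        raise ValueError("cannot renormalize: fractionation factors sum to zero")
    if abs(total - 1.0) < 1e-15:
        return spec
    return replace(
        spec,
        f_pr=spec.f_pr / total,
        f_li=spec.f_li / total,
        f_ch=spec.f_ch / total,
        f_ine=spec.f_ine / total,
    )


def inflow_concentrations(spec: FeedstockSpec) -> np.ndarray:
    """Liquid-phase inflow vector for the first reactor.

    The feed is raw, unhydrolyzed biomass, so the composite entry carries the
    whole feeding value Xc and every other component enters at zero.
    """
    c_in = zero_liquid()
    c_in[IDX["X_c"]] = spec.Xc
    return c_in


def synthesize_feedstock(
    seed: int,
    Xc_range: tuple[float, float] = (250.0, 350.0),
    fraction_dirichlet: tuple[float, float, float, float] = (2.0, 1.0, 8.0, 3.0),
    F_IN: float = 87.5,
) -> FeedstockSpec:
    """Generate a random but realistic feedstock for property tests.

    Xc is uniform over ``Xc_range`` (defaults bracket the bundled energy-crop
    cases); fractionation factors are Dirichlet with concentrations weighted
    towards carbohydrate, as for silage-based feeds. Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = Xc_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid Xc_range: {Xc_range}")
    xc = float(rng.uniform(lo, hi))
    f_pr, f_li, f_ch, f_ine = rng.dirichlet(fraction_dirichlet)
    ms = float(rng.uniform(0.4, 0.6))
    pm = float(rng.uniform(0.0, 1.0 - ms))
    spec = FeedstockSpec(
        label=f"synthetic-{seed}",
        composition={"MS": ms, "PM": pm, "W": 1.0 - ms - pm},
        Xc=xc,
        f_pr=float(f_pr),
        f_li=float(f_li),
        f_ch=float(f_ch),
        f_ine=float(f_ine),
        F_IN=F_IN,
    )
    return renormalize_fractions(spec)
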