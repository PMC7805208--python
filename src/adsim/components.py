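"""State-vector layout for the digestion model.

The liquid phase carries 26 components: 14 dissolved species, 5 particulate
pools and 7 microbial guilds. Organic species are expressed in kgCOD/m3;
inorganic carbon (S_IC) and inorganic nitrogen (S_IN) in kmol/m3, as are the
cation/anion balance species. The headspace carries 3 gases in mol/m3.
"""

from __future__ import annotations

import numpy as np

DISSOLVED = [
    "S_su",   # monosaccharides
    "S_aa",   # amino acids
    "S_fa",   # long-chain fatty acids
    "S_va",   # total valerate
    "S_bu",   # total butyrate
    "S_pro",  # total propionate
    "S_ac",   # total acetate
    "S_h2",   # dissolved hydrogen
    "S_ch4",  # dissolved methane
    "S_IC",   # inorganic carbon (CO2 + HCO3-) [kmol C/m3]
    "S_IN",   # inorganic nitrogen (NH4+ + NH3) [kmol N/m3]
    "S_I",    # soluble inerts
    "S_cat",  # metallic cations (strong base) [kmol/m3]
    "S_an",   # metallic anions (strong acid) [kmol/m3]
]

PARTICULATE = [
    "X_c",    # raw composite feedstock
    "X_ch",   # carbohydrates
    "X_pr",   # proteins
    "X_li",   # lipids
    "X_I",    # particulate inerts
]

BIOMASS = [
    "X_su",   # sugar degraders
    "X_aa",   # amino-acid degraders
    "X_fa",   # LCFA degraders
    "X_c4",   # valerate/butyrate degraders
    "X_pro",  # propionate degraders
    "X_ac",   # acetoclastic methanogens
    "X_h2",   # hydrogenotrophic methanogens
]

LIQUID = DISSOLVED + PARTICULATE + BIOMASS
GAS = ["S_gas_ch4", "S_gas_co2", "S_gas_h2"]  # [mol/m3]

N_LIQUID = len(LIQUID)   # 26
N_GAS = len(GAS)         # 3
N_STATE = N_LIQUID + N_GAS

IDX = {name: i for i, name in enumerate(LIQUID)}
GAS_IDX = {name: N_LIQUID + i for i, name in enumerate(GAS)}

# components that do not carry COD (used by conservation checks)
_NON_COD = {"S_IC", "S_IN", "S_cat", "S_an"}
COD_MASK = np.array([name not in _NON_COD for name in LIQUID], dtype=bool)

# gCOD per mol, used for unit conversion of dissolved gases and VFA charge
COD_PER_MOL = {"S_h2": 16.0, "S_ch4": 64.0, "S_ac": 64.0, "S_bu": 160.0,
               "S_pro": 112.0, "S_va": 208.0}


def zero_liquid() -> np.ndarray:
    """A fresh all-zero liquid-phase vector (length 26)."""
    return np.zeros(N_LIQUID)


def zero_state() -> np.ndarray:
    """A fresh all-zero full state (liquid + gas, length 29)."""
    return np.zeros(N_STATE)


def as_series(y):
    """Label a full state vector with component names (pandas Series)."""
    import pandas as pd

    y = np.asarray(y, dtype=float)
    if y.size == N_LIQUID:
        return pd.Series(y, index=LIQUID)
    if y.size == N_STATE:
        return pd.Series(y, index=LIQUID + GAS)
    raise ValueError(f"expected a vector of length {N_LIQUID} or {N_STATE}, got {y.size}")
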