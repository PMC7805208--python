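"""Biochemical reaction network: rates, stoichiometry and pH.

Nineteen processes: composite disintegration, three first-order hydrolyses,
eight Monod-type substrate uptakes (with pH, hydrogen and free-ammonia
inhibition) and seven first-order biomass decays. Stoichiometric columns
conserve COD exactly; the inorganic-carbon and inorganic-nitrogen rows are
computed as elemental closures of each column, so C and N are conserved for
any feedstock fractionation.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .components import COD_MASK, IDX, LIQUID, N_LIQUID
from .params import KineticParams

__all__ = [
    "PROCESSES",
    "build_stoichiometry",
    "reaction_rates",
    "net_production",
    "solve_ph",
    "charge_balance_residual",
]

PROCESSES = [
    "disintegration",
    "hydrolysis_ch", "hydrolysis_pr", "hydrolysis_li",
    "uptake_su", "uptake_aa", "uptake_fa",
    "uptake_va", "uptake_bu", "uptake_pro", "uptake_ac", "uptake_h2",
    "decay_su", "decay_aa", "decay_fa", "decay_c4",
    "decay_pro", "decay_ac", "decay_h2",
]
N_PROC = len(PROCESSES)
PROC = {name: j for j, name in enumerate(PROCESSES)}

# elemental contents indexed by component name; filled per parameter set
_GUILDS = ["X_su", "X_aa", "X_fa", "X_c4", "X_pro", "X_ac", "X_h2"]


def _carbon_contents(p: KineticParams) -> np.ndarray:
    c = np.zeros(N_LIQUID)
    vals = {
        "S_su": p.C_su, "S_aa": p.C_aa, "S_fa": p.C_fa, "S_va": p.C_va,
        "S_bu": p.C_bu, "S_pro": p.C_pro, "S_ac": p.C_ac, "S_ch4": p.C_ch4,
        "S_I": p.C_sI, "X_c": p.C_xc, "X_ch": p.C_ch, "X_pr": p.C_pr,
        "X_li": p.C_li, "X_I": p.C_xI,
    }
    for g in _GUILDS:
        vals[g] = p.C_bac
    for name, v in vals.items():
        c[IDX[name]] = v
    return c


def _nitrogen_contents(p: KineticParams) -> np.ndarray:
    n = np.zeros(N_LIQUID)
    vals = {"S_aa": p.N_aa, "S_I": p.N_I, "X_c": p.N_xc,
            "X_pr": p.N_aa, "X_I": p.N_I}
    for g in _GUILDS:
        vals[g] = p.N_bac
    for name, v in vals.items():
        n[IDX[name]] = v
    return n


@lru_cache(maxsize=16)
def build_stoichiometry(params: KineticParams) -> np.ndarray:
    """Stoichiometric matrix v[i, j] (26 components x 19 processes)."""
    p = params
    V = np.zeros((N_LIQUID, N_PROC))

    def put(proc, **coeffs):
        j = PROC[proc]
        for name, v in coeffs.items():
            V[IDX[name], j] += v

    put("disintegration", X_c=-1.0, X_ch=p.f_ch_xc, X_pr=p.f_pr_xc,
        X_li=p.f_li_xc, X_I=p.f_xI_xc, S_I=p.f_sI_xc)
    put("hydrolysis_ch", X_ch=-1.0, S_su=1.0)
    put("hydrolysis_pr", X_pr=-1.0, S_aa=1.0)
    put("hydrolysis_li", X_li=-1.0, S_fa=p.f_fa_li, S_su=1.0 - p.f_fa_li)

    put("uptake_su", S_su=-1.0, X_su=p.Y_su,
        S_bu=(1 - p.Y_su) * p.f_bu_su, S_pro=(1 - p.Y_su) * p.f_pro_su,
        S_ac=(1 - p.Y_su) * p.f_ac_su, S_h2=(1 - p.Y_su) * p.f_h2_su)
    put("uptake_aa", S_aa=-1.0, X_aa=p.Y_aa,
        S_va=(1 - p.Y_aa) * p.f_va_aa, S_bu=(1 - p.Y_aa) * p.f_bu_aa,
        S_pro=(1 - p.Y_aa) * p.f_pro_aa, S_ac=(1 - p.Y_aa) * p.f_ac_aa,
        S_h2=(1 - p.Y_aa) * p.f_h2_aa)
    put("uptake_fa", S_fa=-1.0, X_fa=p.Y_fa,
        S_ac=(1 - p.Y_fa) * 0.7, S_h2=(1 - p.Y_fa) * 0.3)
    put("uptake_va", S_va=-1.0, X_c4=p.Y_c4,
        S_pro=(1 - p.Y_c4) * 0.54, S_ac=(1 - p.Y_c4) * 0.31,
        S_h2=(1 - p.Y_c4) * 0.15)
    put("uptake_bu", S_bu=-1.0, X_c4=p.Y_c4,
        S_ac=(1 - p.Y_c4) * 0.8, S_h2=(1 - p.Y_c4) * 0.2)
    put("uptake_pro", S_pro=-1.0, X_pro=p.Y_pro,
        S_ac=(1 - p.Y_pro) * 0.57, S_h2=(1 - p.Y_pro) * 0.43)
    put("uptake_ac", S_ac=-1.0, X_ac=p.Y_ac, S_ch4=1 - p.Y_ac)
    put("uptake_h2", S_h2=-1.0, X_h2=p.Y_h2, S_ch4=1 - p.Y_h2)

    for guild in _GUILDS:
        put(f"decay_{guild[2:]}", **{guild: -1.0, "X_c": 1.0})

    # elemental closures: inorganic C and N absorb whatever each column
    # does not balance, conserving total C and N per process
    carbon = _carbon_contents(p)
    nitrogen = _nitrogen_contents(p)
    V[IDX["S_IC"], :] = -carbon @ V
    V[IDX["S_IN"], :] = -nitrogen @ V
    return V


def _hill_ph_inhibition(h: float, pH_UL: float, pH_LL: float) -> float:
    # empirical Hill switch centred between the upper/lower pH limits
    K = 10.0 ** (-(pH_UL + pH_LL) / 2.0)
    n = 3.0 / (pH_UL - pH_LL)
    Kn = K ** n
    return Kn / (h ** n + Kn)


def reaction_rates(state, params: KineticParams, T: float, pH: float) -> np.ndarray:
    """Process rate vector r_j [kgCOD/m3/d] at the given temperature and pH.

    Raises on (materially) negative concentrations, which would signal an
    integrator fault rather than chemistry.
    """
    y = np.asarray(state, dtype=float)[:N_LIQUID]
    if y.min() < -1e-8:
        bad = LIQUID[int(y.argmin())]
        raise ValueError(f"negative concentration in {bad}: {y.min():.3e}")
    y = np.maximum(y, 0.0)
    p = params
    h = 10.0 ** (-pH)

    S_su, S_aa, S_fa = y[IDX["S_su"]], y[IDX["S_aa"]], y[IDX["S_fa"]]
    S_va, S_bu, S_pro = y[IDX["S_va"]], y[IDX["S_bu"]], y[IDX["S_pro"]]
    S_ac, S_h2, S_IN = y[IDX["S_ac"]], y[IDX["S_h2"]], y[IDX["S_IN"]]

    I_ph_aa = _hill_ph_inhibition(h, p.pH_UL_aa, p.pH_LL_aa)
    I_ph_ac = _hill_ph_inhibition(h, p.pH_UL_ac, p.pH_LL_ac)
    I_ph_h2 = _hill_ph_inhibition(h, p.pH_UL_h2, p.pH_LL_h2)
    I_IN = S_IN / (S_IN + p.K_S_IN)
    I_h2_fa = 1.0 / (1.0 + S_h2 / p.K_I_h2_fa)
    I_h2_c4 = 1.0 / (1.0 + S_h2 / p.K_I_h2_c4)
    I_h2_pro = 1.0 / (1.0 + S_h2 / p.K_I_h2_pro)
    K_a_IN = p.K_a_IN(T)
    S_nh3 = S_IN * K_a_IN / (K_a_IN + h)
    I_nh3 = 1.0 / (1.0 + S_nh3 / p.K_I_nh3)

    r = np.zeros(N_PROC)
    r[PROC["disintegration"]] = p.k_dis(T) * y[IDX["X_c"]]
    r[PROC["hydrolysis_ch"]] = p.k_hyd_ch * y[IDX["X_ch"]]
    r[PROC["hydrolysis_pr"]] = p.k_hyd_pr * y[IDX["X_pr"]]
    r[PROC["hydrolysis_li"]] = p.k_hyd_li * y[IDX["X_li"]]

    i1 = I_ph_aa * I_IN
    r[PROC["uptake_su"]] = p.k_m_su * S_su / (p.K_S_su + S_su) * y[IDX["X_su"]] * i1
    r[PROC["uptake_aa"]] = p.k_m_aa * S_aa / (p.K_S_aa + S_aa) * y[IDX["X_aa"]] * i1
    r[PROC["uptake_fa"]] = (p.k_m_fa * S_fa / (p.K_S_fa + S_fa)
                            * y[IDX["X_fa"]] * i1 * I_h2_fa)
    r[PROC["uptake_va"]] = (p.k_m_c4 * S_va / (p.K_S_c4 + S_va) * y[IDX["X_c4"]]
                            * S_va / (S_va + S_bu + 1e-6) * i1 * I_h2_c4)
    r[PROC["uptake_bu"]] = (p.k_m_c4 * S_bu / (p.K_S_c4 + S_bu) * y[IDX["X_c4"]]
                            * S_bu / (S_va + S_bu + 1e-6) * i1 * I_h2_c4)
    r[PROC["uptake_pro"]] = (p.k_m_pro(T) * S_pro / (p.K_S_pro + S_pro)
                             * y[IDX["X_pro"]] * i1 * I_h2_pro)
    r[PROC["uptake_ac"]] = (p.k_m_ac(T) * S_ac / (p.K_S_ac + S_ac)
                            * y[IDX["X_ac"]] * I_ph_ac * I_IN * I_nh3)
    r[PROC["uptake_h2"]] = (p.k_m_h2 * S_h2 / (p.K_S_h2 + S_h2)
                            * y[IDX["X_h2"]] * I_ph_h2 * I_IN)

    for guild in _GUILDS:
        r[PROC[f"decay_{guild[2:]}"]] = p.k_dec * y[IDX[guild]]
    return r


def net_production(state, params: KineticParams, T: float, pH: float) -> np.ndarray:
    """Per-component biochemical source terms: v @ r (length 26)."""
    V = build_stoichiometry(params)
    return V @ reaction_rates(state, params, T, pH)


def cod_total(liquid) -> float:
    """Total COD of a liquid-phase vector [kgCOD/m3]."""
    y = np.asarray(liquid, dtype=float)[:N_LIQUID]
    return float(y[COD_MASK].sum())


# --------------------------------------------------------------------------
# pH from the ionic charge balance
# --------------------------------------------------------------------------

def charge_balance_residual(h: float, state, params: KineticParams,
                            T: float = 25.0) -> float:
    """Net charge [kmol/m3] at hydrogen-ion concentration ``h`` [kmol/m3].

    Positive charges: strong cations, ammonium, H+. Negative: strong anions,
    hydroxide, bicarbonate and the ionised VFAs. Monotone increasing in h,
    hence a unique root.
    """
    y = np.maximum(np.asarray(state, dtype=float)[:N_LIQUID], 0.0)
    p = params
    nh4 = y[IDX["S_IN"]] * h / (p.K_a_IN(T) + h)
    K_a_co2 = p.K_a_co2(T)
    hco3 = y[IDX["S_IC"]] * K_a_co2 / (K_a_co2 + h)
    vfa = (y[IDX["S_ac"]] / 64.0 * p.K_a_ac / (p.K_a_ac + h)
           + y[IDX["S_pro"]] / 112.0 * p.K_a_pro / (p.K_a_pro + h)
           + y[IDX["S_bu"]] / 160.0 * p.K_a_bu / (p.K_a_bu + h)
           + y[IDX["S_va"]] / 208.0 * p.K_a_va / (p.K_a_va + h))
    return (y[IDX["S_cat"]] + nh4 + h
            - y[IDX["S_an"]] - p.K_w(T) / h - hco3 - vfa)


def solve_ph(state, params: KineticParams, T: float = 25.0) -> float:
    """pH solving the charge balance, bracketed on [0, 14].

    Uses safeguarded root finding on pH (the residual is monotone in H+).
    """
    def f(pH):
        return charge_balance_residual(10.0 ** (-pH), state, params, T)

    lo, hi = 0.0, 14.0
    f_lo, f_hi = f(lo), f(hi)
    if f_lo < 0.0 or f_hi > 0.0:  # residual decreases with pH
        raise ValueError(
            f"charge balance has no root in pH [0, 14]: f(0)={f_lo:.3e}, f(14)={f_hi:.3e}")
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16))
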