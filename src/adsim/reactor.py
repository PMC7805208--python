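"""One continuously stirred tank: liquid + headspace, integrated to steady state.

Liquid-phase balances for each component x:

    dC_x/dt = (F_IN*C_x_in - F_OUT*C_x)/V_w + sum_j v_ij * r_j

with F_IN = F_OUT (constant liquid level). Headspace gases obey the same
balance with zero inflow, volume V_g, and the gas-liquid transfer intensity
lgt_i = kLa*(S_liq,i - K_H,i*p_i) as the source, scaled by V_w/V_g. Biogas
leaves through a pipe-resistance law once the total pressure exceeds the
release setpoint P_OP and is reported at normal conditions (0 degC,
1.01325 bar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .components import GAS_IDX, IDX, N_LIQUID, N_STATE, zero_state
from .feedstock import FeedstockSpec, inflow_concentrations
from .kinetics import cod_total, net_production, solve_ph
from .params import KineticParams

__all__ = [
    "ReactorConfig",
    "GasTransferParams",
    "GasPhase",
    "gas_outflow",
    "normalize_flux",
    "gas_transfer",
    "liquid_derivatives",
    "gas_derivatives",
    "default_initial_state",
    "integrate_to_steady_state",
    "SteadyStateResult",
]

R_GAS = 8.314  # J/mol/K
P_NORM = 1.01325  # bar, normal-condition reference
T_NORM = 273.15   # K


@dataclass(frozen=True)
class ReactorConfig:
    """Geometry and operating point of one tank."""

    V_w: float = 2800.0          # working (liquid) volume [m3]
    V_g: float = 500.0           # headspace volume [m3]
    T: float = 39.0              # operating temperature [degC]
    P_OP: float = 1.013          # gas-release pressure setpoint [bar]
    P_atm: float = 1.013         # atmospheric pressure [bar]
    k_p: float = 1e4             # outlet-pipe resistance [1/(d*bar)]
    pH_clamp: Optional[float] = None   # None = free pH from charge balance
    include_water_vapour: bool = True

    def __post_init__(self):
        if self.V_w <= 0 or self.V_g <= 0:
            raise ValueError("volumes must be positive")
        if self.P_OP < self.P_atm - 1e-12:
            raise ValueError("P_OP must be at least atmospheric")
        if self.k_p <= 0:
            raise ValueError("k_p must be positive")
        if self.pH_clamp is not None and not 0.0 < self.pH_clamp < 14.0:
            raise ValueError("pH clamp must lie in (0, 14)")

    @property
    def V_total(self) -> float:
        return self.V_w + self.V_g

    @property
    def T_kelvin(self) -> float:
        return self.T + 273.15

    def hrt(self, F_IN: float) -> float:
        """Hydraulic retention time [d] at the given throughput."""
        if F_IN <= 0:
            raise ValueError("F_IN must be positive")
        return self.V_w / F_IN

    def p_h2o(self) -> float:
        """Saturation water-vapour pressure at T [bar] (Antoine-type)."""
        if not self.include_water_vapour:
            return 0.0
        return 0.0313 * math.exp(5290.0 * (1.0 / 298.15 - 1.0 / self.T_kelvin))


@dataclass(frozen=True)
class GasTransferParams:
    """Overall transfer coefficient and Henry constants.

    Henry constants are in mol/L/bar and treated as temperature-independent;
    CO2 is far more soluble than CH4, which is what makes pressurised
    operation enrich the offgas in methane.
    """

    kLa: float = 200.0          # [1/d]
    K_H_ch4: float = 0.0016     # [mol/L/bar]
    K_H_co2: float = 0.318      # [mol/L/bar]
    K_H_h2: float = 7.8e-4      # [mol/L/bar]

    def __post_init__(self):
        for name in ("kLa", "K_H_ch4", "K_H_co2", "K_H_h2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GasPhase:
    """Headspace snapshot derived from the three gas concentrations."""

    p_ch4: float
    p_co2: float
    p_h2: float
    p_h2o: float

    @classmethod
    def from_concentrations(cls, S_gas, config: ReactorConfig) -> "GasPhase":
        S = np.maximum(np.asarray(S_gas, dtype=float), 0.0)
        f = R_GAS * config.T_kelvin / 1e5  # mol/m3 -> bar
        return cls(p_ch4=S[0] * f, p_co2=S[1] * f, p_h2=S[2] * f,
                   p_h2o=config.p_h2o())

    @property
    def P_Tot(self) -> float:
        return self.p_ch4 + self.p_co2 + self.p_h2 + self.p_h2o

    @property
    def ch4_fraction(self) -> float:
        """Dry-basis methane fraction of the offgas [%]."""
        dry = self.p_ch4 + self.p_co2 + self.p_h2
        return 100.0 * self.p_ch4 / dry if dry > 0 else 0.0


def gas_outflow(P_Tot: float, config: ReactorConfig) -> float:
    """Volumetric biogas outflow [m3/d] through the outlet-pipe resistance.

    F = k_p * V_g * (P_Tot - P_OP) * P_Tot / P_OP, clamped at zero when the
    pressure has not yet reached the release setpoint (no backflow).
    """
    if P_Tot < 0:
        raise ValueError("total pressure cannot be negative")
    if P_Tot <= config.P_OP:
        return 0.0
    return config.k_p * config.V_g * (P_Tot - config.P_OP) * P_Tot / config.P_OP


def normalize_flux(F_OUT_gas: float, P_OP: float, T_kelvin: float) -> float:
    """Convert a gas flux at (P_OP [bar], T [K]) to normal conditions [Nm3/d]."""
    if T_kelvin <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return F_OUT_gas * (P_OP * 1e5) * T_NORM / (T_kelvin * P_NORM * 1e5)


def gas_transfer(state, gas: GasPhase, gtp: GasTransferParams,
                 params: KineticParams, T: float, pH: float) -> np.ndarray:
    """Liquid-to-gas transfer intensities (CH4, CO2, H2) [mol/m3/d].

    Positive means the liquid is supersaturated and degasses. Dissolved CO2
    is the un-ionised share of inorganic carbon at the prevailing pH.
    """
    y = np.maximum(np.asarray(state, dtype=float)[:N_LIQUID], 0.0)
    h = 10.0 ** (-pH)
    K_a_co2 = params.K_a_co2(T)
    co2_free = y[IDX["S_IC"]] * h / (h + K_a_co2)  # [kmol/m3]
    s_ch4 = y[IDX["S_ch4"]] / 0.064   # kgCOD/m3 -> mol/m3
    s_h2 = y[IDX["S_h2"]] / 0.016
    # Henry mol/L/bar -> mol/m3/bar
    return gtp.kLa * np.array([
        s_ch4 - 1e3 * gtp.K_H_ch4 * gas.p_ch4,
        1e3 * co2_free - 1e3 * gtp.K_H_co2 * gas.p_co2,
        s_h2 - 1e3 * gtp.K_H_h2 * gas.p_h2,
    ])


def liquid_derivatives(state, inflow, F_IN: float, config: ReactorConfig,
                       params: KineticParams, pH: Optional[float] = None) -> np.ndarray:
    """Transport plus biochemical source terms for the 26 liquid components.

    Gas stripping is not included here; the full reactor right-hand side adds
    it where liquid and headspace are integrated together.
    """
    y = np.asarray(state, dtype=float)[:N_LIQUID]
    c_in = np.asarray(inflow, dtype=float)[:N_LIQUID]
    if config.V_w <= 0:
        raise ValueError("working volume must be positive")
    if pH is None:
        pH = config.pH_clamp if config.pH_clamp is not None \
            else solve_ph(y, params, config.T)
    transport = F_IN * (c_in - y) / config.V_w  # F_IN = F_OUT
    return transport + net_production(y, params, config.T, pH)


def gas_derivatives(S_gas, F_OUT_gas: float, lgt, config: ReactorConfig) -> np.ndarray:
    """Headspace balances: dilution by the collected biogas, fed by transfer."""
    if config.V_g <= 0:
        raise ValueError("headspace volume must be positive")
    S = np.asarray(S_gas, dtype=float)
    return (-S * F_OUT_gas + np.asarray(lgt) * config.V_w) / config.V_g


def default_initial_state(feedstock: FeedstockSpec) -> np.ndarray:
    """Start-up state mimicking inoculation with active digestate.

    Each guild starts at 10 kgCOD/m3 with an established ammonium/bicarbonate
    buffer; a sparse inoculum (e.g. 1 kgCOD/m3 per guild) acidifies during
    start-up with this feeding strength, as an uninoculated full-scale tank
    would. Composite starts at 10% of the feeding value, headspace near
    atmospheric.
    """
    y = zero_state()
    for g in ("X_su", "X_aa", "X_fa", "X_c4", "X_pro", "X_ac", "X_h2"):
        y[IDX[g]] = 10.0
    for s in ("S_su", "S_aa", "S_fa", "S_va", "S_bu", "S_pro", "S_ac"):
        y[IDX[s]] = 1e-3
    y[IDX["S_h2"]] = 1e-8
    y[IDX["S_ch4"]] = 1e-3
    y[IDX["S_IC"]] = 0.1
    y[IDX["S_IN"]] = 0.2
    y[IDX["X_c"]] = 0.1 * feedstock.Xc
    y[GAS_IDX["S_gas_ch4"]] = 10.0
    y[GAS_IDX["S_gas_co2"]] = 20.0
    y[GAS_IDX["S_gas_h2"]] = 1e-4
    return y


@dataclass
class SteadyStateResult:
    state: np.ndarray            # converged full state (29,)
    gas: GasPhase
    F_OUT_gas: float             # [m3/d] at operating conditions
    F_OUT_gas_N: float           # [Nm3/d]
    ch4_fraction: float          # dry-basis [%]
    pH: float
    t_final: float               # simulated days integrated
    converged: bool
    residual: float              # steady-state criterion value at the end
    cod_closure: float           # relative COD balance gap at steady state


class _RHS:
    """Right-hand side of the coupled liquid + headspace system, with a
    warm-started pH solve in free-pH mode."""

    def __init__(self, inflow, F_IN, config, params, gtp):
        self.inflow = np.asarray(inflow, dtype=float)
        self.F_IN = F_IN
        self.config = config
        self.params = params
        self.gtp = gtp
        self.ph_last = 7.0

    def ph(self, y_liq) -> float:
        cfg = self.config
        if cfg.pH_clamp is not None:
            return cfg.pH_clamp
        ph = solve_ph(y_liq, self.params, cfg.T)
        self.ph_last = ph
        return ph

    def __call__(self, t, y):
        cfg = self.config
        yc = np.maximum(y, 0.0)
        liq = yc[:N_LIQUID]
        pH = self.ph(liq)
        gas = GasPhase.from_concentrations(yc[N_LIQUID:], cfg)
        lgt = gas_transfer(liq, gas, self.gtp, self.params, cfg.T, pH)
        F_out_g = gas_outflow(gas.P_Tot, cfg)

        dliq = liquid_derivatives(liq, self.inflow, self.F_IN, cfg,
                                  self.params, pH=pH)
        # stripping of the dissolved gases into the headspace
        dliq[IDX["S_ch4"]] -= lgt[0] * 0.064   # mol -> kgCOD
        dliq[IDX["S_IC"]] -= lgt[1] / 1e3      # mol -> kmol
        dliq[IDX["S_h2"]] -= lgt[2] * 0.016
        dgas = gas_derivatives(yc[N_LIQUID:], F_out_g, lgt, cfg)
        return np.concatenate([dliq, dgas])


def _criterion(rhs_val, y, tau: float) -> float:
    """max_i |dC_i/dt| * tau / max(C_i, eps) -- relative drift per retention."""
    return float(np.max(np.abs(rhs_val) * tau / np.maximum(np.abs(y), 1e-8)))


def integrate_to_steady_state(
    config: ReactorConfig,
    feedstock: FeedstockSpec,
    params: KineticParams,
    initial: Optional[np.ndarray] = None,
    inflow: Optional[np.ndarray] = None,
    gtp: GasTransferParams = GasTransferParams(),
    tol: float = 1e-6,
    max_chunks: int = 6,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    raise_on_nonconvergence: bool = True,
) -> SteadyStateResult:
    """Integrate the stiff tank ODEs until the steady-state criterion holds.

    The horizon is walked in chunks of 10 retention times; after each chunk a
    Newton polish of the right-hand side is attempted and accepted only if it
    lands on a non-negative state meeting the criterion. Raw biogas flow is
    evaluated from the converged headspace pressure and reported at normal
    conditions.
    """
    if inflow is None:
        inflow = inflow_concentrations(feedstock)
    F_IN = feedstock.F_IN
    tau = config.V_w / F_IN if F_IN > 0 else 32.0
    y = (default_initial_state(feedstock) if initial is None
         else np.asarray(initial, dtype=float).copy())
    if y.size != N_STATE:
        raise ValueError(f"initial state must have length {N_STATE}")
    if y.min() < 0:
        raise ValueError("initial state must be non-negative")

    rhs = _RHS(inflow, F_IN, config, params, gtp)
    t = 0.0
    res = math.inf
    converged = False
    for _ in range(max_chunks):
        sol = solve_ivp(rhs, (t, t + 10.0 * tau), y, method="BDF",
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise RuntimeError(f"stiff integration failed: {sol.message}")
        t = sol.t[-1]
        y = np.maximum(sol.y[:, -1], 0.0)
        res = _criterion(rhs(t, y), y, tau)
        if res < tol:
            converged = True
            break
        # Newton polish towards the exact fixed point
        polished = root(lambda v: rhs(0.0, v), y, method="hybr",
                        options={"xtol": 1e-12})
        if polished.success and polished.x.min() > -1e-9:
            y_pol = np.maximum(polished.x, 0.0)
            res_pol = _criterion(rhs(0.0, y_pol), y_pol, tau)
            if res_pol < tol:
                y, res, converged = y_pol, res_pol, True
                break
    if not converged and raise_on_nonconvergence:
        raise RuntimeError(
            f"no steady state within {t:.0f} d: criterion {res:.3e} > {tol:g}")

    liq = y[:N_LIQUID]
    pH = config.pH_clamp if config.pH_clamp is not None \
        else solve_ph(liq, params, config.T)
    gas = GasPhase.from_concentrations(y[N_LIQUID:], config)
    F_out = gas_outflow(gas.P_Tot, config)
    F_out_N = normalize_flux(F_out, config.P_OP, config.T_kelvin)

    # steady-state COD closure: feed COD vs liquid effluent + gaseous CH4/H2
    cod_in = cod_total(inflow) * F_IN
    cod_liq = cod_total(liq) * F_IN
    S_g = np.maximum(y[N_LIQUID:], 0.0)
    cod_gas = F_out * (S_g[0] * 64.0 + S_g[2] * 16.0) / 1e3  # kg/d
    closure = abs(cod_in - cod_liq - cod_gas) / cod_in if cod_in > 0 else 0.0

    return SteadyStateResult(
        state=y, gas=gas, F_OUT_gas=F_out, F_OUT_gas_N=F_out_N,
        ch4_fraction=gas.ch4_fraction, pH=float(pH), t_final=t,
        converged=converged, residual=res, cod_closure=closure)
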