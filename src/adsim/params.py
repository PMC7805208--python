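"""Kinetic and physico-chemical parameters.

The biochemical network follows the structured anaerobic-digestion model
ADM1; constants not re-estimated for this plant use the standard mesophilic
defaults (Rosen & Jeppsson benchmark set). Three rate constants were
re-estimated for the full-scale plant and carry an exponential temperature
law

    k(T) = k(T0) * exp(theta * (T - T0)),    T0 = 35 degC

with (k(T0), theta): propionate uptake (7.19, 0.02615), acetate uptake
(14.27, 0.00434) and composite disintegration (1.105, -0.06879). Every
constant is an ordinary dataclass field and can be overridden for
calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "KineticParams",
    "adjust_rate_for_temperature",
    "temperature_coefficient",
    "default_params",
]


def adjust_rate_for_temperature(k_T0: float, theta: float, T: float, T0: float) -> float:
    """Exponential temperature correction k(T) = k_T0 * exp(theta*(T-T0)).

    Parameters are in 1/d (rates) and 1/degC (theta); temperatures in degC.
    """
    if k_T0 <= 0:
        raise ValueError(f"rate constant must be positive, got {k_T0}")
    return k_T0 * math.exp(theta * (T - T0))


def temperature_coefficient(k_T: float, k_T0: float, T: float, T0: float) -> float:
    """Invert the exponential law: theta = ln(k_T/k_T0) / (T - T0)."""
    if k_T <= 0 or k_T0 <= 0:
        raise ValueError("rate constants must be positive")
    if T == T0:
        raise ValueError("temperature coefficient undefined for T == T0")
    return math.log(k_T / k_T0) / (T - T0)


@dataclass(frozen=True)
class KineticParams:
    # --- plant-specific rate constants at T0, with temperature coefficients
    T0: float = 35.0            # reference temperature [degC]
    k_dis_T0: float = 1.105     # composite disintegration [1/d]
    k_m_pro_T0: float = 7.19    # max propionate uptake [1/d]
    k_m_ac_T0: float = 14.27    # max acetate uptake [1/d]
    theta_dis: float = -0.06879     # [1/degC]
    theta_pro: float = 0.02615
    theta_ac: float = 0.00434
    # pre-estimation literature values, retained as metadata only
    k_dis_initial: float = 0.5
    k_m_pro_initial: float = 13.0
    k_m_ac_initial: float = 8.0

    # --- first-order hydrolysis [1/d]
    k_hyd_ch: float = 10.0
    k_hyd_pr: float = 10.0
    k_hyd_li: float = 10.0

    # --- Monod uptake: maxima [1/d] and half-saturations [kgCOD/m3]
    k_m_su: float = 30.0
    k_m_aa: float = 50.0
    k_m_fa: float = 6.0
    k_m_c4: float = 20.0
    k_m_h2: float = 35.0
    K_S_su: float = 0.5
    K_S_aa: float = 0.3
    K_S_fa: float = 0.4
    K_S_c4: float = 0.2
    K_S_pro: float = 0.1
    K_S_ac: float = 0.15
    K_S_h2: float = 7e-6

    # --- yields [kgCOD biomass / kgCOD substrate]
    Y_su: float = 0.10
    Y_aa: float = 0.08
    Y_fa: float = 0.06
    Y_c4: float = 0.06
    Y_pro: float = 0.04
    Y_ac: float = 0.05
    Y_h2: float = 0.06

    # --- biomass decay [1/d]
    k_dec: float = 0.02

    # --- product splits of the uptake reactions (COD fractions)
    f_h2_su: float = 0.19
    f_bu_su: float = 0.13
    f_pro_su: float = 0.27
    f_ac_su: float = 0.41
    f_h2_aa: float = 0.06
    f_va_aa: float = 0.23
    f_bu_aa: float = 0.26
    f_pro_aa: float = 0.05
    f_ac_aa: float = 0.40
    f_fa_li: float = 0.95

    # --- disintegration splits; overridden per feedstock (f_sI kept for
    #     completeness, zero for the bundled cases)
    f_ch_xc: float = 0.2
    f_pr_xc: float = 0.2
    f_li_xc: float = 0.3
    f_xI_xc: float = 0.3
    f_sI_xc: float = 0.0

    # --- inhibition constants
    K_S_IN: float = 1e-4        # nitrogen limitation [kmol N/m3]
    K_I_h2_fa: float = 5e-6     # [kgCOD/m3]
    K_I_h2_c4: float = 1e-5
    K_I_h2_pro: float = 3.5e-6
    K_I_nh3: float = 1.8e-3     # free ammonia on acetoclasts [kmol N/m3]
    pH_UL_aa: float = 5.5       # empirical pH inhibition windows
    pH_LL_aa: float = 4.0
    pH_UL_ac: float = 7.0
    pH_LL_ac: float = 6.0
    pH_UL_h2: float = 6.0
    pH_LL_h2: float = 5.0

    # --- elemental contents [kmol C or N per kgCOD]
    C_su: float = 0.0313
    C_aa: float = 0.030
    C_fa: float = 0.0217
    C_va: float = 0.024
    C_bu: float = 0.025
    C_pro: float = 0.0268
    C_ac: float = 0.0313
    C_ch4: float = 0.0156
    C_sI: float = 0.030
    C_ch: float = 0.0313
    C_pr: float = 0.030
    C_li: float = 0.022
    C_xI: float = 0.030
    C_bac: float = 0.0313
    N_aa: float = 0.007
    N_I: float = 0.06 / 14.0
    N_bac: float = 0.08 / 14.0
    N_xc: float = 0.0376 / 14.0

    # --- acid-base (values at 298.15 K; van 't Hoff heats in J/mol)
    K_a_va: float = 10 ** -4.86
    K_a_bu: float = 10 ** -4.82
    K_a_pro: float = 10 ** -4.88
    K_a_ac: float = 10 ** -4.76
    K_a_co2_ref: float = 10 ** -6.35
    K_a_IN_ref: float = 10 ** -9.25
    K_w_ref: float = 10 ** -14.0
    dH_K_a_co2: float = 7646.0
    dH_K_a_IN: float = 51965.0
    dH_K_w: float = 55900.0

    def __post_init__(self):
        for name in ("k_dis_T0", "k_m_pro_T0", "k_m_ac_T0", "k_hyd_ch",
                     "k_m_su", "k_m_aa", "k_m_fa", "k_m_c4", "k_m_h2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("Y_su", "Y_aa", "Y_fa", "Y_c4", "Y_pro", "Y_ac", "Y_h2"):
            y = getattr(self, name)
            if not 0.0 < y < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {y}")

    # temperature-adjusted rates -------------------------------------------
    def k_dis(self, T: float) -> float:
        return adjust_rate_for_temperature(self.k_dis_T0, self.theta_dis, T, self.T0)

    def k_m_pro(self, T: float) -> float:
        return adjust_rate_for_temperature(self.k_m_pro_T0, self.theta_pro, T, self.T0)

    def k_m_ac(self, T: float) -> float:
        return adjust_rate_for_temperature(self.k_m_ac_T0, self.theta_ac, T, self.T0)

    # van 't Hoff corrected equilibrium constants --------------------------
    def K_a_co2(self, T_celsius: float) -> float:
        return self._vant_hoff(self.K_a_co2_ref, self.dH_K_a_co2, T_celsius)

    def K_a_IN(self, T_celsius: float) -> float:
        return self._vant_hoff(self.K_a_IN_ref, self.dH_K_a_IN, T_celsius)

    def K_w(self, T_celsius: float) -> float:
        return self._vant_hoff(self.K_w_ref, self.dH_K_w, T_celsius)

    @staticmethod
    def _vant_hoff(K_ref: float, dH: float, T_celsius: float) -> float:
        R = 8.314  # J/mol/K
        T = T_celsius + 273.15
        return K_ref * math.exp(dH / R * (1.0 / 298.15 - 1.0 / T))

    def with_feedstock_fractions(self, spec) -> "KineticParams":
        """Bind the disintegration splits to a feedstock's fractionation."""
        return replace(
            self,
            f_pr_xc=spec.f_pr,
            f_li_xc=spec.f_li,
            f_ch_xc=spec.f_ch,
            f_xI_xc=spec.f_ine,
            f_sI_xc=0.0,
        )

    @property
    def C_xc(self) -> float:
        """Carbon content of the composite, taken as the fraction-weighted
        carbon of its disintegration products so disintegration is exactly
        carbon-neutral for any fractionation."""
        return (self.f_ch_xc * self.C_ch + self.f_pr_xc * self.C_pr
                + self.f_li_xc * self.C_li + self.f_xI_xc * self.C_xI
                + self.f_sI_xc * self.C_sI)


def default_params(feedstock=None) -> KineticParams:
    """Default parameter set, optionally bound to a feedstock's fractions."""
    p = KineticParams()
    if feedstock is not None:
        p = p.with_feedstock_fractions(feedstock)
    return p
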