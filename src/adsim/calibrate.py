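"""Bounded calibration of the few constants the plant data can identify.

The full-scale measurements constrain only a handful of lumped constants, so
calibration is restricted to the composite disintegration rate, the maximum
acetate uptake rate and the gas-liquid transfer coefficient, each within a
bounded window around its default. The objective matches the modelled daily
biogas flux and methane content of one classical validation case.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.optimize import least_squares

from .params import KineticParams, default_params
from .plant import build_configuration, run_plant
from .reactor import GasTransferParams
from .reporting import published_tables

__all__ = ["calibrate"]


def calibrate(case_id: int = 1, params: KineticParams | None = None,
              bounds: dict | None = None, max_nfev: int = 12,
              verbose: bool = False):
    """Least-squares fit of (k_dis, k_m_ac, kLa) to one classical case.

    Returns ``(params, gtp, result)`` with the fitted constants substituted.
    Each plant evaluation is a full two-tank steady-state run, so keep
    ``max_nfev`` small.
    """
    tab = published_tables()["validation"][case_id]
    target = np.array([tab["model_flux"], tab["model_ch4"]])
    p0 = params if params is not None else default_params()
    x0 = np.array([p0.k_dis_T0, p0.k_m_ac_T0, 200.0])
    default_bounds = {"k_dis": (0.2, 3.0), "k_m_ac": (4.0, 30.0),
                      "kLa": (50.0, 500.0)}
    if bounds:
        default_bounds.update(bounds)
    lo = [default_bounds[k][0] for k in ("k_dis", "k_m_ac", "kLa")]
    hi = [default_bounds[k][1] for k in ("k_dis", "k_m_ac", "kLa")]

    def residuals(x):
        k_dis, k_m_ac, kLa = x
        p = replace(p0, k_dis_T0=k_dis, k_m_ac_T0=k_m_ac)
        gtp = GasTransferParams(kLa=kLa)
        cfg = build_configuration("classical", case_id)
        res = run_plant(cfg, p, gtp=gtp)
        r = np.array([res.total_flux - target[0],
                      res.total_ch4 - target[1]])
        if verbose:
            print(f"  x={x}, flux={res.total_flux:.1f}, ch4={res.total_ch4:.2f}")
        return r / target  # relative residuals

    fit = least_squares(residuals, x0, bounds=(lo, hi), max_nfev=max_nfev,
                        diff_step=0.05)
    k_dis, k_m_ac, kLa = fit.x
    return (replace(p0, k_dis_T0=k_dis, k_m_ac_T0=k_m_ac),
            GasTransferParams(kLa=kLa), fit)
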