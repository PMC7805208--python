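import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from adsim import (adjust_rate_for_temperature, default_params, load_case,
                   net_production, reaction_rates, solve_ph,
                   temperature_coefficient)
from adsim.components import COD_MASK, IDX, N_LIQUID, zero_liquid
from adsim.kinetics import PROC, PROCESSES, build_stoichiometry
from adsim.params import KineticParams


# --- temperature scaling ---------------------------------------------------

def test_rate_unchanged_at_reference_temperature():
    assert adjust_rate_for_temperature(7.19, 0.02615, 35, 35) == 7.19


@pytest.mark.parametrize("k0, theta, T, expected", [
    (1.105, -0.06879, 55.0, 1.105 * math.exp(-0.06879 * 20)),   # ~0.2792
    (7.19, 0.02615, 55.0, 7.19 * math.exp(0.02615 * 20)),       # ~12.13
])
def test_exponential_temperature_law(k0, theta, T, expected):
    k = adjust_rate_for_temperature(k0, theta, T, 35.0)
    assert k == pytest.approx(expected, rel=1e-14)
    assert k > 0


def test_temperature_coefficient_inverts_the_law():
    assert temperature_coefficient(0.27918, 1.105, 55, 35) == \
        pytest.approx(-0.06879, abs=2e-5)
    assert temperature_coefficient(3.0, 3.0, 45, 35) == 0.0
    with pytest.raises(ValueError):
        temperature_coefficient(1.0, 2.0, 35, 35)


@given(st.floats(0.01, 100.0), st.floats(-0.2, 0.2).filter(lambda x: abs(x) > 1e-6),
       st.floats(5.0, 70.0))
def test_scaling_roundtrip_identity(k0, theta, T):
    """The forward law and the coefficient extraction are mutual inverses."""
    T0 = 35.0
    if abs(T - T0) < 1e-3:
        T += 1.0
    k = adjust_rate_for_temperature(k0, theta, T, T0)
    assert temperature_coefficient(k, k0, T, T0) == pytest.approx(theta, rel=1e-12)


def test_monotone_in_temperature_per_theta_sign(params):
    Ts = np.linspace(20, 60, 9)
    k_ac = [params.k_m_ac(t) for t in Ts]     # theta > 0
    k_dis = [params.k_dis(t) for t in Ts]     # theta < 0
    assert np.all(np.diff(k_ac) > 0)
    assert np.all(np.diff(k_dis) < 0)


# --- stoichiometry ---------------------------------------------------------

def test_every_biochemical_process_conserves_cod(params):
    V = build_stoichiometry(params)
    imbalance = np.abs(V[COD_MASK, :].sum(axis=0))
    assert imbalance.max() < 1e-10


def test_stoichiometry_conserves_carbon_and_nitrogen(params):
    from adsim.kinetics import _carbon_contents, _nitrogen_contents
    V = build_stoichiometry(params)
    c = _carbon_contents(params).copy()
    n = _nitrogen_contents(params).copy()
    c[IDX["S_IC"]] = 1.0
    n[IDX["S_IN"]] = 1.0
    assert np.abs(c @ V).max() < 1e-12
    assert np.abs(n @ V).max() < 1e-12


# --- rates -----------------------------------------------------------------

def test_zero_state_gives_zero_rates(params):
    r = reaction_rates(zero_liquid(), params, 39.0, 7.0)
    assert not r.any()


def test_composite_only_state_disintegrates_first_order(case1, params):
    y = zero_liquid()
    y[IDX["X_c"]] = 42.0
    r = reaction_rates(y, params, 39.0, 7.0)
    assert r[PROC["disintegration"]] == pytest.approx(params.k_dis(39.0) * 42.0)
    others = np.delete(r, PROC["disintegration"])
    assert not others.any()


def test_disintegration_splits_follow_feedstock_fractions(case1, params):
    """Composite loss is partitioned onto the four pools in exact proportion
    to the feedstock's fractionation factors."""
    y = zero_liquid()
    y[IDX["X_c"]] = 10.0
    src = net_production(y, params, 39.0, 7.0)
    loss = -src[IDX["X_c"]]
    assert loss > 0
    assert src[IDX["X_pr"]] / loss == pytest.approx(case1.f_pr, rel=1e-12)
    assert src[IDX["X_li"]] / loss == pytest.approx(case1.f_li, rel=1e-12)
    assert src[IDX["X_ch"]] / loss == pytest.approx(case1.f_ch, rel=1e-12)
    assert src[IDX["X_I"]] / loss == pytest.approx(case1.f_ine, rel=1e-12)
    assert src[COD_MASK].sum() == pytest.approx(0.0, abs=1e-10)


def test_monod_uptake_doubles_well_below_half_saturation(params):
    y = zero_liquid()
    y[IDX["X_ac"]] = 1.0
    y[IDX["S_IN"]] = 0.5          # no nitrogen limitation
    y[IDX["S_ac"]] = params.K_S_ac * 1e-4
    r1 = reaction_rates(y, params, 39.0, 7.5)[PROC["uptake_ac"]]
    y[IDX["S_ac"]] *= 2
    r2 = reaction_rates(y, params, 39.0, 7.5)[PROC["uptake_ac"]]
    assert r2 / r1 == pytest.approx(2.0, rel=1e-3)


def test_rates_reject_negative_concentrations(params):
    y = zero_liquid()
    y[IDX["S_ac"]] = -0.5
    with pytest.raises(ValueError, match="negative concentration"):
        reaction_rates(y, params, 39.0, 7.0)


def test_rates_nonnegative_on_random_states(params):
    rng = np.random.default_rng(42)
    for _ in range(25):
        y = rng.uniform(0, 5.0, N_LIQUID)
        r = reaction_rates(y, params, rng.uniform(20, 60), rng.uniform(4, 9))
        assert (r >= 0).all()


def test_net_production_is_stoichiometry_times_rates(params):
    rng = np.random.default_rng(0)
    y = rng.uniform(0, 2.0, N_LIQUID)
    V = build_stoichiometry(params)
    r = reaction_rates(y, params, 39.0, 7.0)
    np.testing.assert_allclose(net_production(y, params, 39.0, 7.0), V @ r)


# --- pH --------------------------------------------------------------------

def _bisection_ph_oracle(state, params, T=25.0, resolution=1e-6):
    """Independent brute-force bisection of the ionic charge balance.

    Reimplements the speciation explicitly (not via the package's residual)
    and bisects pH on [0, 14] down to the requested resolution.
    """
    y = np.maximum(np.asarray(state, float), 0.0)
    p = params
    K_IN, K_co2, K_w = p.K_a_IN(T), p.K_a_co2(T), p.K_w(T)

    def net_charge(pH):
        h = 10.0 ** (-pH)
        pos = y[IDX["S_cat"]] + h + y[IDX["S_IN"]] * h / (K_IN + h)
        neg = (y[IDX["S_an"]] + K_w / h
               + y[IDX["S_IC"]] * K_co2 / (K_co2 + h)
               + y[IDX["S_ac"]] / 64 * p.K_a_ac / (p.K_a_ac + h)
               + y[IDX["S_pro"]] / 112 * p.K_a_pro / (p.K_a_pro + h)
               + y[IDX["S_bu"]] / 160 * p.K_a_bu / (p.K_a_bu + h)
               + y[IDX["S_va"]] / 208 * p.K_a_va / (p.K_a_va + h))
        return pos - neg

    lo, hi = 0.0, 14.0
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if net_charge(mid) > 0:   # too acidic -> move up
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def test_pure_water_is_neutral(params):
    assert solve_ph(zero_liquid(), params, T=25.0) == pytest.approx(7.0, abs=0.01)


def test_ph_matches_bisection_oracle(params):
    from conftest import random_liquid_state
    rng = np.random.default_rng(3)
    for _ in range(20):
        y = random_liquid_state(rng)
        assert solve_ph(y, params, T=39.0) == pytest.approx(
            _bisection_ph_oracle(y, params, T=39.0), abs=1e-4)


def test_acetate_addition_lowers_ph(params):
    y = zero_liquid()
    y[IDX["S_cat"]] = 0.05
    y[IDX["S_IC"]] = 0.05
    ph = [solve_ph(y, params) ]
    for ac in (2.0, 5.0, 10.0):
        y[IDX["S_ac"]] = ac
        ph.append(solve_ph(y, params))
    assert all(a > b for a, b in zip(ph, ph[1:]))
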