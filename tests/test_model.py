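"""Single-cell dynamics: repair term, RHS, events, division rule."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from rejuvasim.model import (CellState, EventKind, ModelParameters, R_MIN,
                             divide, integrate_to_event, ode_rhs, repair_rate,
                             simulate_cell)

from oracles import rk4_simulate_params


# --------------------------------------------------------------------------
# repair term

@pytest.mark.parametrize("D,k2,R,expected", [
    (0.0, 0.138, R_MIN, 0.0),
    (0.0, 1.0, 5.0, 0.0),
    (0.3, 0.092, 1e6, 0.0276),          # small-angle limit k2*D
    (0.5, 0.138, R_MIN, 0.138 / math.pi),  # k2*R*sin(pi/2) = k2/pi
])
def test_repair_rate_values(D, k2, R, expected):
    assert repair_rate(D, k2, R) == pytest.approx(expected, abs=1e-10)


def test_repair_collapses_to_zero_at_full_damage():
    # minimal capacity: the effective rate of repair drops to zero at D = 1
    assert repair_rate(1.0, 0.138, R_MIN) == 0.0


def test_repair_infinite_capacity_is_linear():
    assert repair_rate(0.37, 0.2, math.inf) == 0.37 * 0.2


@pytest.mark.parametrize("D,R", [(-0.1, 1.0), (1.1, 1.0), (0.5, 0.2)])
def test_repair_rate_domain_errors(D, R):
    with pytest.raises(ValueError):
        repair_rate(D, 0.1, R)


@given(D=st.floats(0.0, 1.0), k2=st.floats(0.0, 1.0),
       R=st.floats(1e3, 1e9))
@settings(deadline=None)
def test_repair_converges_to_linear_with_analytic_bound(D, k2, R):
    # |k2*R*sin(D/R) - k2*D| <= k2*D^3 / (6 R^2) from the sine series
    assert abs(repair_rate(D, k2, R) - k2 * D) <= k2 * D ** 3 / (6 * R ** 2) + 1e-15


@given(D=st.floats(1e-6, 1.0), k2=st.floats(0.0, 1.0),
       R1=st.floats(R_MIN, 1e4), R2=st.floats(R_MIN, 1e4))
@settings(deadline=None)
def test_repair_monotone_in_capacity(D, k2, R1, R2):
    lo, hi = sorted((R1, R2))
    assert repair_rate(D, k2, lo) <= repair_rate(D, k2, hi) + 1e-12


# --------------------------------------------------------------------------
# right-hand side

def test_rhs_matches_symbolic_evaluation():
    P, D, g, Q, k1, k2 = 0.3, 0.1, 1.0, 1.0, 0.4, 0.138
    R = R_MIN
    Ps, Ds = sympy.Rational(3, 10), sympy.Rational(1, 10)
    r = k2 * sympy.Rational(1, 1) * R * sympy.sin(Ds / R)
    S = Ps + Q * Ds
    dP_sym = float(sympy.N(g * Ps * (1 - S) - k1 * Ps + r, 30))
    dD_sym = float(sympy.N(k1 * Ps - r, 30))
    params = ModelParameters(g=g, k1=k1, k2=k2, Q=Q, R=R)
    dP, dD = ode_rhs(CellState(0.0, P, D), params)
    assert dP == pytest.approx(dP_sym, rel=1e-12)
    assert dD == pytest.approx(dD_sym, rel=1e-12)


def test_rhs_extinction_fixed_point():
    params = ModelParameters()
    assert ode_rhs(CellState(0.0, 0.0, 0.0), params) == (0.0, 0.0)


def test_rhs_no_damage_source_when_k1_zero():
    params = ModelParameters(k1=0.0)
    dP, dD = ode_rhs(CellState(0.0, 0.2, 0.0), params)
    assert dD == 0.0
    assert dP > 0.0  # S < 1, pure growth


@given(P=st.floats(0.0, 1.0), D=st.floats(0.0, 1.0),
       k1=st.floats(0.0, 1.0), k2=st.floats(0.0, 1.0))
@settings(deadline=None)
def test_rhs_mass_moves_only_between_pools(P, D, k1, k2):
    # formation and repair cancel in the sum: dP + dD = growth flux
    params = ModelParameters(k1=k1, k2=k2)
    dP, dD = ode_rhs(CellState(0.0, P, D), params)
    growth = params.g * P * (1.0 - (P + params.Q * D))
    assert dP + dD == pytest.approx(growth, abs=1e-12)


# --------------------------------------------------------------------------
# division rule

def test_divide_hand_arithmetic():
    params = ModelParameters(s=0.64, re=0.2957)
    out = divide(CellState(1.0, 0.5, 0.2), params)
    assert out.mother.P == pytest.approx(0.32, abs=1e-15)
    assert out.mother.D == pytest.approx(0.1492904, abs=1e-12)
    assert out.daughter.P == pytest.approx(0.18, abs=1e-15)
    assert out.daughter.D == pytest.approx(0.0507096, abs=1e-12)


def test_divide_no_retention_mother_share_is_size_proportion():
    params = ModelParameters(s=0.64, re=0.0)
    out = divide(CellState(0.0, 0.5, 0.3), params)
    assert out.mother.D / 0.3 == pytest.approx(0.64, abs=1e-15)


def test_divide_full_retention_daughter_born_clean():
    params = ModelParameters(re=1.0)
    out = divide(CellState(0.0, 0.5, 0.3), params)
    assert out.daughter.D == 0.0


@given(P=st.floats(1e-6, 1.0), D=st.floats(0.0, 1.0),
       s=st.floats(0.05, 0.95), re=st.floats(0.0, 1.0))
@settings(deadline=None)
def test_division_conserves_both_pools_exactly(P, D, s, re):
    params = ModelParameters(s=s, re=re)
    out = divide(CellState(0.0, P, D), params)
    # the complements are computed by subtraction, so the recombined pools
    # agree to the last unit in the last place
    assert out.mother.P + out.daughter.P == pytest.approx(P, rel=1e-15, abs=1e-300)
    assert out.mother.D + out.daughter.D == pytest.approx(D, rel=1e-15, abs=1e-300)


# --------------------------------------------------------------------------
# event integration and whole lives

def test_event_at_death_boundary_start(wt_decline):
    st0 = CellState(3.0, 0.2, wt_decline.D_death)
    kind, te, state, _, _ = integrate_to_event(st0, wt_decline, 10.0)
    assert kind is EventKind.DEATH
    assert te == 3.0


def test_monotone_growth_divides_without_damage():
    params = ModelParameters(k1=0.0)
    birth = CellState(0.0, 0.1, 0.0)
    kind, te, state, _, _ = integrate_to_event(birth, params, 100.0)
    assert kind is EventKind.DIVISION
    assert state.P == pytest.approx(params.P_div, abs=1e-9)


def test_first_division_time_matches_rk4_oracle(wt_decline):
    birth = CellState(0.0, (1 - wt_decline.s) * wt_decline.P_div, 0.0)
    kind, te, _, _, _ = integrate_to_event(birth, wt_decline, 50.0)
    oracle = rk4_simulate_params(wt_decline)
    assert kind is EventKind.DIVISION
    assert te == pytest.approx(oracle.division_times[0], abs=1e-5)


def test_sterile_cell_dies_without_dividing():
    params = ModelParameters(k1=4.0)  # 10x the grid maximum
    birth = CellState(0.0, (1 - params.s) * params.P_div, 0.0)
    life = simulate_cell(birth, params)
    assert life.rls == 0
    assert not life.censored
    assert life.death_time is not None


def test_no_ageing_source_censors_at_division_cap():
    params = ModelParameters(k1=0.0)
    birth = CellState(0.0, 0.18, 0.0)
    life = simulate_cell(birth, params, max_divisions=30)
    assert life.censored
    assert life.rls == 30
    assert life.death_time is None


@pytest.mark.parametrize("regime", ["decline", "unlimited"])
def test_wildtype_life_matches_rk4_oracle(regime, wt_decline, wt_unlimited):
    params = wt_decline if regime == "decline" else wt_unlimited
    birth = CellState(0.0, (1 - params.s) * params.P_div, 0.0)
    life = simulate_cell(birth, params, engine="scipy")
    oracle = rk4_simulate_params(params)
    assert life.rls == oracle.rls
    assert life.death_time == pytest.approx(oracle.death_time, abs=5e-5)


def test_engines_agree_on_wildtype_life(wt_decline):
    birth = CellState(0.0, (1 - wt_decline.s) * wt_decline.P_div, 0.0)
    fast = simulate_cell(birth, wt_decline, engine="fast")
    ref = simulate_cell(birth, wt_decline, engine="scipy")
    assert fast.rls == ref.rls
    assert fast.death_time == pytest.approx(ref.death_time, abs=5e-5)
    for a, b in zip(fast.division_times, ref.division_times):
        assert a == pytest.approx(b, abs=2e-5)
    assert fast.t_health == pytest.approx(ref.t_health, abs=2e-5)
    assert fast.rls_at_health == ref.rls_at_health


def test_domain_preserved_along_life(wt_decline):
    birth = CellState(0.0, (1 - wt_decline.s) * wt_decline.P_div, 0.0)
    life = simulate_cell(birth, wt_decline)
    for state in life.states_at_divisions:
        assert state.P >= 0.0
        assert state.D <= wt_decline.D_death + 1e-7
    assert life.final_state.D <= wt_decline.D_death + 1e-7


def test_rls_non_increasing_in_retention(wt_decline):
    # sigma = 0 founder lifespan can only drop as more damage is retained
    from rejuvasim.calibration import simulate_rls
    rls_values = [simulate_rls(wt_decline.with_updates(re=re), max_divisions=200)
                  for re in np.linspace(0.0, 1.0, 11)]
    assert all(a >= b for a, b in zip(rls_values, rls_values[1:]))


def test_death_strictly_after_last_division(wt_decline):
    birth = CellState(0.0, (1 - wt_decline.s) * wt_decline.P_div, 0.0)
    life = simulate_cell(birth, wt_decline)
    assert life.division_times == sorted(life.division_times)
    assert life.death_time > life.division_times[-1]
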