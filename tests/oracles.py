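"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the model equations, without
importing any integration code from the package: a fixed-step classical RK4
integrator (default dt = 1e-4) with event detection by linear interpolation
between steps, alternating with the division split.  It is deliberately slow
and simple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class OracleLife:
    division_times: list = field(default_factory=list)
    daughter_states: list = field(default_factory=list)  # (P, D) at birth
    pre_split: list = field(default_factory=list)        # (P, D) before split
    death_time: float | None = None
    censored: bool = False
    t_health: float | None = None
    rls_at_health: int | None = None

    @property
    def rls(self) -> int:
        return len(self.division_times)


def rk4_simulate(P0, D0, g, k1, k2, Q, R, re, s, P_div, D_death, D_health,
                 dt=1e-4, max_divisions=1000, max_time=200.0) -> OracleLife:
    """Whole-life fixed-step RK4 integration of the damage-accumulation model."""
    unlimited = math.isinf(R)
    sin = math.sin
    pi = math.pi

    def f(P, D):
        if unlimited:
            r = k2 * D if D > 0.0 else 0.0
        else:
            x = D / R
            r = k2 * R * sin(x) if 0.0 < x < pi else 0.0
        return g * P * (1.0 - P - Q * D) - k1 * P + r, k1 * P - r

    life = OracleLife()
    t, P, D = 0.0, P0, D0
    if D >= D_health:
        life.t_health, life.rls_at_health = t, 0
    if D >= D_death:
        life.death_time = t
        return life
    while t < max_time:
        aP, aD = f(P, D)
        bP, bD = f(P + 0.5 * dt * aP, D + 0.5 * dt * aD)
        cP, cD = f(P + 0.5 * dt * bP, D + 0.5 * dt * bD)
        dP_, dD_ = f(P + dt * cP, D + dt * cD)
        P1 = P + dt / 6.0 * (aP + 2 * bP + 2 * cP + dP_)
        D1 = D + dt / 6.0 * (aD + 2 * bD + 2 * cD + dD_)
        t1 = t + dt
        if life.t_health is None and D1 >= D_health > D:
            frac = (D_health - D) / (D1 - D)
            life.t_health = t + frac * dt
            life.rls_at_health = life.rls
        crossed_death = D1 >= D_death
        crossed_div = P1 >= P_div
        if crossed_death or crossed_div:
            te_death = t + (D_death - D) / (D1 - D) * dt if crossed_death else math.inf
            te_div = t + (P_div - P) / (P1 - P) * dt if crossed_div else math.inf
            if te_death <= te_div:
                life.death_time = te_death
                return life
            te = te_div
            frac = (te - t) / dt
            Pe = P_div
            De = D + frac * (D1 - D)
            m_frac = s + re * (1.0 - s)
            mP, mD = s * Pe, m_frac * De
            life.division_times.append(te)
            life.pre_split.append((Pe, De))
            life.daughter_states.append((Pe - mP, De - mD))
            if life.rls >= max_divisions:
                life.censored = True
                return life
            t, P, D = te, mP, mD
            continue
        t, P, D = t1, P1, D1
    life.censored = True
    return life


def rk4_simulate_params(params, P0=None, D0=0.0, **kw) -> OracleLife:
    """Convenience wrapper taking a ModelParameters-like object."""
    if P0 is None:
        P0 = (1.0 - params.s) * params.P_div
    return rk4_simulate(P0, D0, params.g, params.k1, params.k2, params.Q,
                        params.R, params.re, params.s, params.P_div,
                        params.D_death, params.D_health, **kw)
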