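"""Single-cell replicative-ageing dynamics.

A budding-yeast cell is described by two protein pools, functional ``P`` and
damaged ``D``, evolving between instantaneous division/death events under

    dP/dt = g * P * (1 - S) - k1 * P + r(D)
    dD/dt = k1 * P - r(D),          S = P + Q * D,

where ``g`` is the growth factor, ``k1`` the damage formation rate, ``Q`` the
resilience to damage (the weight with which damaged proteins count towards the
growth-inhibiting size ``S``) and ``r`` the repair term

    r(D) = k2 * R * sin(D / R),     D in [0, 1],  R in [1/pi, inf].

The repair capacity ``R`` interpolates between a damage-proportional repair
``r = k2 * D`` (``R -> inf``, "unlimited" capacity) and a profile that repairs
efficiently at low damage but collapses to zero as ``D -> 1``
(``R = 1/pi``, "decline" in capacity).

Division fires when ``P`` crosses the critical level ``P_div`` and is an
instantaneous asymmetric split: the mother keeps the size fraction ``s`` of
functional protein and the fraction ``s + re*(1-s)`` of the damage, where the
retention factor ``re`` models active/passive mechanisms pulling daughter-bound
damage back into the mother.  Death fires when ``D`` crosses ``D_death``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParameters",
    "CellState",
    "DivisionOutcome",
    "CellLife",
    "EventKind",
    "Trajectory",
    "repair_rate",
    "ode_rhs",
    "integrate_to_event",
    "divide",
    "simulate_cell",
    "IntegrationError",
]

#: Lower end of the admissible repair-capacity range.
R_MIN = 1.0 / math.pi

# Integration tolerances (see docs/methods.md, "Numerical choices").
RTOL = 1e-8
ATOL = 1e-10
EVENT_TIME_TOL = 1e-9


class IntegrationError(RuntimeError):
    """Adaptive integration failed; carries the last valid state."""

    def __init__(self, message: str, last_state: "CellState"):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class ModelParameters:
    """All rate and partition constants of one cell's dynamics.

    Every quantity is non-dimensional.  Defaults are the repository's
    calibrated wildtype base in the decline-in-repair-capacity regime.
    """

    g: float = 2.0          #: growth factor
    k1: float = 0.4         #: damage formation rate
    k2: float = 0.138       #: damage repair rate
    Q: float = 0.5          #: resilience to damage (weight of D in size S)
    R: float = R_MIN        #: repair capacity, in [1/pi, inf]
    re: float = 0.2957      #: retention factor, fraction of daughter-bound damage kept
    s: float = 0.64         #: size proportion kept by the mother at division
    P_div: float = 0.5      #: critical functional-protein level triggering division
    D_death: float = 1.0    #: critical damage level triggering death
    D_health: float = 0.5   #: damage threshold for health-span accounting

    def __post_init__(self) -> None:
        if not (self.g > 0):
            raise ValueError(f"g must be positive, got {self.g}")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be non-negative")
        if self.Q < 0:
            raise ValueError("Q must be non-negative")
        if not (self.R >= R_MIN or math.isinf(self.R)):
            raise ValueError(f"R must be >= 1/pi (or inf), got {self.R}")
        if not 0.0 <= self.re <= 1.0:
            raise ValueError(f"re must lie in [0, 1], got {self.re}")
        if not 0.0 < self.s < 1.0:
            raise ValueError(f"s must lie in (0, 1), got {self.s}")
        if not (0.0 < self.D_health <= self.D_death <= 1.0):
            raise ValueError("need 0 < D_health <= D_death <= 1")
        if self.P_div <= 0:
            raise ValueError("P_div must be positive")

    def with_updates(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CellState:
    """Instantaneous protein content and clock of one cell."""

    t: float
    P: float
    D: float

    def __post_init__(self) -> None:
        if self.P < 0:
            raise ValueError(f"P must be non-negative, got {self.P}")
        if not -1e-12 <= self.D <= 1.0 + 1e-9:
            raise ValueError(f"D must lie in [0, 1], got {self.D}")

    def size(self, Q: float) -> float:
        """Cell size S = P + Q*D."""
        return self.P + Q * self.D


@dataclass(frozen=True)
class DivisionOutcome:
    """Mother and daughter states immediately after an instantaneous division."""

    mother: CellState
    daughter: CellState


class EventKind(Enum):
    DIVISION = "division"
    DEATH = "death"
    HORIZON = "horizon"


@dataclass
class Trajectory:
    """Dense sampling of one cell's (t, P, D) path, per inter-event segment."""

    t: np.ndarray
    P: np.ndarray
    D: np.ndarray


def repair_rate(D: float, k2: float, R: float) -> float:
    """Repair flux r(D) = k2 * R * sin(D / R).

    For the infinite-capacity sentinel ``R = inf`` this returns the limit
    ``k2 * D`` (damage-proportional repair).  On the admissible domain the
    argument ``D / R`` never exceeds pi; it attains pi only at ``(D=1,
    R=1/pi)`` where the repair collapses to exactly zero.

    Raises
    ------
    ValueError
        If ``D`` lies outside [0, 1] or ``R`` below 1/pi.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError(f"D must lie in [0, 1], got {D}")
    if k2 < 0:
        raise ValueError(f"k2 must be non-negative, got {k2}")
    if math.isinf(R):
        return k2 * D
    if R < R_MIN:
        raise ValueError(f"R must be >= 1/pi, got {R}")
    return _repair_unchecked(D, k2, R)


def _repair_unchecked(D: float, k2: float, R: float) -> float:
    # Clamp the sine argument to [0, pi]: mathematically D/R <= pi on the
    # domain (equality only where sin vanishes), so the clamp changes nothing
    # analytically but pins the boundary to exactly 0.0 and keeps the flux
    # non-negative under solver overshoot.
    if math.isinf(R):
        return k2 * max(D, 0.0)
    x = D / R
    if x <= 0.0:
        return 0.0
    if x >= math.pi:
        return 0.0
    return k2 * R * math.sin(x)


def ode_rhs(state: CellState, params: ModelParameters) -> tuple[float, float]:
    """Time derivatives (dP/dt, dD/dt) of the two protein pools."""
    return _rhs(state.P, state.D, params)


def _rhs(P: float, D: float, p: ModelParameters) -> tuple[float, float]:
    r = _repair_unchecked(D, p.k2, p.R)
    S = P + p.Q * D
    dP = p.g * P * (1.0 - S) - p.k1 * P + r
    dD = p.k1 * P - r
    return dP, dD


def _make_rhs(p: ModelParameters) -> Callable:
    # Closure over plain floats; scalar math keeps solve_ivp overhead low.
    g, k1, k2, Q, R = p.g, p.k1, p.k2, p.Q, p.R
    if math.isinf(R):
        def rhs(t, y):
            P, D = y
            r = k2 * D if D > 0.0 else 0.0
            dP = g * P * (1.0 - P - Q * D) - k1 * P + r
            return (dP, k1 * P - r)
    else:
        sin = math.sin
        pi = math.pi
        def rhs(t, y):
            P, D = y
            x = D / R
            r = k2 * R * sin(x) if 0.0 < x < pi else 0.0
            dP = g * P * (1.0 - P - Q * D) - k1 * P + r
            return (dP, k1 * P - r)
    return rhs


def integrate_to_event(
    state: CellState,
    params: ModelParameters,
    t_max: float,
    *,
    track_health: bool = False,
    dense: bool = False,
):
    """Integrate one inter-event segment and locate the first event.

    Returns ``(kind, t_event, state_at_event, health_time, trajectory)``:
    the earliest upward crossing of ``P`` through ``P_div`` (division) or of
    ``D`` through ``D_death`` (death); ``EventKind.HORIZON`` with the state at
    ``t_max`` if neither occurs.  If division and death are located within
    the event-time tolerance of each other, death wins.  ``health_time`` is
    the first upward crossing of ``D`` through ``D_health`` within the
    segment (or None), reported only when ``track_health``.
    """
    if t_max <= state.t:
        raise ValueError("t_max must exceed the state's clock")
    # Boundary starts: events that have already fired.
    if state.D >= params.D_death:
        return EventKind.DEATH, state.t, state, None, None
    if state.P >= params.P_div:
        return EventKind.DIVISION, state.t, state, None, None

    ev_div = lambda t, y: y[0] - params.P_div
    ev_div.terminal = True
    ev_div.direction = 1.0
    ev_death = lambda t, y: y[1] - params.D_death
    ev_death.terminal = True
    ev_death.direction = 1.0
    events = [ev_div, ev_death]
    if track_health:
        ev_health = lambda t, y: y[1] - params.D_health
        ev_health.terminal = False
        ev_health.direction = 1.0
        events.append(ev_health)

    sol = solve_ivp(
        _make_rhs(params),
        (state.t, t_max),
        (state.P, state.D),
        method="RK45",
        events=events,
        rtol=RTOL,
        atol=ATOL,
        dense_output=dense,
    )
    if sol.status == -1:
        last = CellState(sol.t[-1], max(sol.y[0, -1], 0.0),
                         min(max(sol.y[1, -1], 0.0), 1.0))
        raise IntegrationError(sol.message, last)

    traj = None
    if dense:
        traj = Trajectory(sol.t.copy(), sol.y[0].copy(), sol.y[1].copy())

    health_t = None
    if track_health and sol.t_events[2].size:
        health_t = float(sol.t_events[2][0])

    t_div = float(sol.t_events[0][0]) if sol.t_events[0].size else math.inf
    t_death = float(sol.t_events[1][0]) if sol.t_events[1].size else math.inf
    if math.isinf(t_div) and math.isinf(t_death):
        end = CellState(float(sol.t[-1]), max(float(sol.y[0, -1]), 0.0),
                        min(max(float(sol.y[1, -1]), 0.0), 1.0))
        return EventKind.HORIZON, float(sol.t[-1]), end, health_t, traj
    # Tie rule: death wins within tolerance.
    if t_death <= t_div + EVENT_TIME_TOL:
        kind, te, ye = EventKind.DEATH, t_death, sol.y_events[1][0]
    else:
        kind, te, ye = EventKind.DIVISION, t_div, sol.y_events[0][0]
    st = CellState(te, max(float(ye[0]), 0.0), min(max(float(ye[1]), 0.0), 1.0))
    if health_t is not None and health_t > te:
        health_t = None
    return kind, te, st, health_t, traj


def divide(state: CellState, params: ModelParameters) -> DivisionOutcome:
    """Instantaneous asymmetric split of the protein pools.

    Mother keeps ``s*P`` and ``(s + re*(1-s))*D``; the daughter receives the
    complements ``(1-s)*P`` and ``(1-re)*(1-s)*D``.  Both pools are conserved
    exactly: the complements are computed by subtraction, so mother + daughter
    reproduces the pre-division content to the last bit.
    """
    P, D, t = state.P, state.D, state.t
    mother_P = params.s * P
    mother_D = (params.s + params.re * (1.0 - params.s)) * D
    daughter_P = P - mother_P
    daughter_D = D - mother_D
    return DivisionOutcome(
        mother=CellState(t, mother_P, mother_D),
        daughter=CellState(t, max(daughter_P, 0.0), max(daughter_D, 0.0)),
    )


@dataclass
class CellLife:
    """One completed (or censored) cell life produced by :func:`simulate_cell`."""

    birth_state: CellState
    params: ModelParameters
    division_times: list[float] = field(default_factory=list)
    daughter_states: list[CellState] = field(default_factory=list)
    #: pre-split mother states at each division time
    states_at_divisions: list[CellState] = field(default_factory=list)
    #: pre-split size S at each division time
    sizes_at_divisions: list[float] = field(default_factory=list)
    death_time: float | None = None
    final_state: CellState | None = None
    censored: bool = False
    #: first upward crossing of D through D_health, None if never reached
    t_health: float | None = None
    #: divisions completed before t_health (None if never reached)
    rls_at_health: int | None = None
    trajectory: list[Trajectory] | None = None

    @property
    def rls(self) -> int:
        """Replicative lifespan: number of daughters produced."""
        return len(self.division_times)

    @property
    def size_at_death(self) -> float | None:
        if self.final_state is None:
            return None
        return self.final_state.size(self.params.Q)


def simulate_cell(
    birth: CellState,
    params: ModelParameters,
    *,
    max_divisions: int = 1000,
    max_lifetime: float = 1e4,
    record_trajectory: bool = False,
    engine: str = "auto",
) -> CellLife:
    """Simulate one cell from birth to death or cap.

    Alternates event-located integration and instantaneous division until the
    damage pool crosses ``D_death`` (death), or a cap fires, in which case the
    life is flagged censored.  Immortal parameterisations (e.g. ``k1 = 0``)
    therefore terminate as censored records, never as infinite loops.

    ``engine`` selects the integrator: ``"scipy"`` (the reference path below,
    one :func:`integrate_to_event` call per inter-event segment),
    ``"fast"`` (the compiled whole-life loop in :mod:`rejuvasim._fast`), or
    ``"auto"`` (fast when available and no trajectory is requested).  The two
    engines implement identical dynamics and tolerances; the test suite pins
    their agreement.
    """
    if max_divisions <= 0 or max_lifetime <= 0:
        raise ValueError("caps must be positive")
    if engine not in ("auto", "fast", "scipy"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "auto":
        from ._fast import NUMBA_AVAILABLE
        engine = "fast" if (NUMBA_AVAILABLE and not record_trajectory) else "scipy"
    if engine == "fast":
        if record_trajectory:
            raise ValueError("trajectory recording requires the scipy engine")
        return _simulate_cell_fast(birth, params, max_divisions, max_lifetime)
    life = CellLife(birth_state=birth, params=params,
                    trajectory=[] if record_trajectory else None)
    if birth.D >= params.D_health:
        # born already past the health threshold
        life.t_health = birth.t
        life.rls_at_health = 0
    state = birth
    t_end = birth.t + max_lifetime
    while True:
        kind, te, ev_state, health_t, traj = integrate_to_event(
            state, params, t_end,
            track_health=life.t_health is None, dense=record_trajectory,
        )
        if record_trajectory and traj is not None:
            life.trajectory.append(traj)
        if health_t is not None and life.t_health is None:
            life.t_health = health_t
            life.rls_at_health = len(life.division_times)
        if kind is EventKind.DEATH:
            life.death_time = te
            life.final_state = ev_state
            if life.t_health is None and ev_state.D >= params.D_health:
                # threshold reached exactly at death
                life.t_health = te
                life.rls_at_health = len(life.division_times)
            return life
        if kind is EventKind.HORIZON:
            life.censored = True
            life.final_state = ev_state
            return life
        # division
        life.division_times.append(te)
        life.states_at_divisions.append(ev_state)
        life.sizes_at_divisions.append(ev_state.size(params.Q))
        outcome = divide(ev_state, params)
        life.daughter_states.append(outcome.daughter)
        state = outcome.mother
        if len(life.division_times) >= max_divisions:
            life.censored = True
            life.final_state = state
            return life


def _simulate_cell_fast(birth: CellState, params: ModelParameters,
                        max_divisions: int, max_lifetime: float) -> CellLife:
    from ._fast import simulate_life_fast

    p = params
    (status, n_div, div_times, dau_P, dau_D, pre_P, pre_D,
     death_time, t_health, rls_health, final_t, final_P, final_D) = \
        simulate_life_fast(
            birth.P, birth.D, birth.t, p.g, p.k1, p.k2, p.Q,
            0.0 if math.isinf(p.R) else p.R, math.isinf(p.R),
            p.re, p.s, p.P_div, p.D_death, p.D_health,
            max_divisions, max_lifetime,
        )
    if status == 2:
        raise IntegrationError(
            "step-size underflow",
            CellState(final_t, max(final_P, 0.0), min(max(final_D, 0.0), 1.0)))
    life = CellLife(birth_state=birth, params=params)
    for i in range(n_div):
        life.division_times.append(float(div_times[i]))
        st = CellState(float(div_times[i]), float(pre_P[i]),
                       min(max(float(pre_D[i]), 0.0), 1.0))
        life.states_at_divisions.append(st)
        life.sizes_at_divisions.append(st.size(p.Q))
        life.daughter_states.append(
            CellState(float(div_times[i]), max(float(dau_P[i]), 0.0),
                      max(float(dau_D[i]), 0.0)))
    life.final_state = CellState(final_t, max(float(final_P), 0.0),
                                 min(max(float(final_D), 0.0), 1.0))
    if status == 0:
        life.death_time = float(death_time)
    else:
        life.censored = True
    if t_health >= 0.0:
        life.t_health = float(t_health)
        life.rls_at_health = int(rls_health)
    return life
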