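"""Compiled whole-life integrator (numba).

Same dynamics, events and division rule as the scipy-based reference path in
:mod:`rejuvasim.model`, fused into one adaptive Dormand-Prince (RK45) loop so
that populations of thousands of cells stay cheap.  Event times (division,
death, first health-threshold crossing) are located by bisection on the cubic
Hermite interpolant of the accepted step.  Agreement with the reference
engine is pinned by the test suite; either engine can be selected explicitly
through ``simulate_cell(..., engine=...)``.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is a hard dep of the fast path
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = ["NUMBA_AVAILABLE", "simulate_life_fast"]

RTOL = 1e-8
ATOL = 1e-10
EVENT_TIME_TOL = 1e-9

# Dormand-Prince 5(4) coefficients.
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
    [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
])
_B = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84])
# embedded 4th-order weights
_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                -92097 / 339200, 187 / 2100, 1 / 40])


@njit(cache=False)
def _rhs(P, D, g, k1, k2, Q, R, unlimited):
    if unlimited:
        r = k2 * D if D > 0.0 else 0.0
    else:
        x = D / R
        r = k2 * R * math.sin(x) if 0.0 < x < math.pi else 0.0
    dP = g * P * (1.0 - P - Q * D) - k1 * P + r
    dD = k1 * P - r
    return dP, dD


@njit(cache=False)
def _hermite(theta, h, y0, f0, y1, f1):
    t2 = theta * theta
    t3 = t2 * theta
    return ((2 * t3 - 3 * t2 + 1) * y0 + (t3 - 2 * t2 + theta) * h * f0
            + (-2 * t3 + 3 * t2) * y1 + (t3 - t2) * h * f1)


@njit(cache=False)
def _cross_theta(h, y0, f0, y1, f1, level):
    """Bisection for the first theta in (0, 1] where the Hermite interpolant
    reaches `level` from below; -1.0 if no upward crossing in the step."""
    if y1 < level:
        return -1.0
    if y0 >= level:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _hermite(mid, h, y0, f0, y1, f1) >= level:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@njit(cache=False)
def simulate_life_fast(P0, D0, t0, g, k1, k2, Q, R, unlimited, re, s,
                       P_div, D_death, D_health,
                       max_divisions, max_lifetime):
    """Simulate one cell life; see module docstring.

    Returns (status, n_div, div_times, dau_P, dau_D, pre_P, pre_D,
    death_time, t_health, rls_health, final_t, final_P, final_D) with
    status 0 = died, 1 = censored (cap), 2 = step-size underflow.
    """
    n_max = max_divisions
    div_times = np.empty(n_max)
    dau_P = np.empty(n_max)
    dau_D = np.empty(n_max)
    pre_P = np.empty(n_max)
    pre_D = np.empty(n_max)
    n_div = 0
    t = t0
    P = P0
    D = D0
    t_end = t0 + max_lifetime
    t_health = -1.0
    rls_health = -1
    if D >= D_health:
        t_health = t
        rls_health = 0
    if D >= D_death:
        return (0, 0, div_times, dau_P, dau_D, pre_P, pre_D,
                t, t_health, rls_health, t, P, D)

    h = 1e-3
    fP, fD = _rhs(P, D, g, k1, k2, Q, R, unlimited)
    kP = np.empty(7)
    kD = np.empty(7)
    while True:
        if t >= t_end:
            return (1, n_div, div_times, dau_P, dau_D, pre_P, pre_D,
                    -1.0, t_health, rls_health, t, P, D)
        if h > t_end - t:
            h = t_end - t
        if h < 1e-14 * max(1.0, abs(t)):
            return (2, n_div, div_times, dau_P, dau_D, pre_P, pre_D,
                    -1.0, t_health, rls_health, t, P, D)
        # one Dormand-Prince step
        kP[0] = fP
        kD[0] = fD
        for i in range(1, 6):
            accP = 0.0
            accD = 0.0
            for j in range(i):
                accP += _A[i, j] * kP[j]
                accD += _A[i, j] * kD[j]
            pi_, di_ = _rhs(P + h * accP, D + h * accD, g, k1, k2, Q, R, unlimited)
            kP[i] = pi_
            kD[i] = di_
        accP = 0.0
        accD = 0.0
        for j in range(6):
            accP += _B[j] * kP[j]
            accD += _B[j] * kD[j]
        P1 = P + h * accP
        D1 = D + h * accD
        fP1, fD1 = _rhs(P1, D1, g, k1, k2, Q, R, unlimited)
        kP[6] = fP1
        kD[6] = fD1
        # embedded error estimate
        e4P = 0.0
        e4D = 0.0
        for j in range(7):
            e4P += _B4[j] * kP[j]
            e4D += _B4[j] * kD[j]
        errP = h * (accP - e4P)
        errD = h * (accD - e4D)
        scP = ATOL + RTOL * max(abs(P), abs(P1))
        scD = ATOL + RTOL * max(abs(D), abs(D1))
        err = math.sqrt(0.5 * ((errP / scP) ** 2 + (errD / scD) ** 2))
        if err > 1.0:
            h *= max(0.2, 0.9 * err ** -0.2)
            continue
        # accepted step [t, t+h]
        th_death = _cross_theta(h, D, fD, D1, fD1, D_death)
        th_div = _cross_theta(h, P, fP, P1, fP1, P_div)
        th_hl = _cross_theta(h, D, fD, D1, fD1, D_health) if t_health < 0.0 else -1.0
        # approach events with shrinking steps so the interpolant is only
        # trusted on a ~1e-6 window (its error is then far below tolerance)
        if h > 1e-6:
            th_min = 2.0
            for th in (th_death, th_div, th_hl):
                if 0.0 < th < th_min:
                    th_min = th
            if th_min <= 1.0 and th_min * h > 1e-7:
                h = max(th_min * h * 0.9, 5e-7)
                continue
        if t_health < 0.0 and th_hl >= 0.0:
            t_c = t + th_hl * h
            if th_death < 0.0 or t_c <= t + th_death * h:
                t_health = t_c
                rls_health = n_div
        if th_death >= 0.0 and (th_div < 0.0 or
                                th_death * h <= th_div * h + EVENT_TIME_TOL):
            te = t + th_death * h
            Pe = _hermite(th_death, h, P, fP, P1, fP1)
            De = _hermite(th_death, h, D, fD, D1, fD1)
            return (0, n_div, div_times, dau_P, dau_D, pre_P, pre_D,
                    te, t_health, rls_health, te, Pe, De)
        if th_div >= 0.0:
            te = t + th_div * h
            Pe = _hermite(th_div, h, P, fP, P1, fP1)
            De = _hermite(th_div, h, D, fD, D1, fD1)
            # instantaneous asymmetric split
            mP = s * Pe
            mD = (s + re * (1.0 - s)) * De
            div_times[n_div] = te
            pre_P[n_div] = Pe
            pre_D[n_div] = De
            dau_P[n_div] = Pe - mP
            dau_D[n_div] = De - mD
            n_div += 1
            if n_div >= max_divisions:
                return (1, n_div, div_times, dau_P, dau_D, pre_P, pre_D,
                        -1.0, t_health, rls_health, te, mP, mD)
            t = te
            P = mP
            D = mD
            fP, fD = _rhs(P, D, g, k1, k2, Q, R, unlimited)
            continue
        t = t + h
        P = P1
        D = D1
        fP = fP1
        fD = fD1
        h *= min(5.0, 0.9 * err ** -0.2 if err > 0.0 else 5.0)
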