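"""Wildtype parameter-grid calibration.

The wildtype surface collects (k1, k2, re, R) combinations under which an
initially damage-free founder achieves a fixed replicative lifespan (24
divisions, the average wildtype yeast lifespan).  The parameter plane is
discretised with spacing 0.005 in k1 and k2 and, at each grid point, the
retention factor re is adapted: rls is non-increasing in re (retaining damage
loads the mother), so the set {re : rls(re) = target} is an interval and both
of its edges are located by bisection; the calibrated value is the interval
midpoint.  An alternate mode adapts k2 at fixed (k1, re), exploiting that rls
is non-decreasing in k2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .lineage import average_newborn
from .model import ModelParameters, simulate_cell

__all__ = [
    "IMMORTAL",
    "WildtypeGridEntry",
    "simulate_rls",
    "calibrate_re",
    "calibrate_k2",
    "find_wildtype_point",
    "build_wildtype_grid",
    "grid_frame",
]

log = logging.getLogger(__name__)

#: Sentinel rls for a founder that outlives the division cap (censored).
IMMORTAL = math.inf

#: Grid spacing in k1 and k2.
GRID_SPACING = 0.005

#: Wildtype replicative-lifespan target.
TARGET_RLS = 24

#: Bisection tolerance in the calibrated parameter.
RE_TOL = 1e-7


@dataclass(frozen=True)
class WildtypeGridEntry:
    k1: float
    k2: float
    R: float
    re_star: float | None
    achieved_rls: int | None
    feasible: bool


def simulate_rls(params: ModelParameters, *, max_divisions: int = 1000,
                 max_lifetime: float = 1e4) -> int | float:
    """Deterministic division count of one damage-free founder with average
    initial conditions; :data:`IMMORTAL` if it outlives the caps (censored)."""
    founder = average_newborn(params)
    life = simulate_cell(founder, params, max_divisions=max_divisions,
                         max_lifetime=max_lifetime)
    if life.censored:
        return IMMORTAL
    return life.rls


def _bisect_edge(f: Callable[[float], float], pred, lo: float, hi: float,
                 tol: float, max_iter: int = 60):
    """Smallest x in [lo, hi] with pred(f(x)) true, assuming pred(f) is
    monotone (false then true).  Returns (edge, iterations used)."""
    if pred(f(lo)):
        return lo, 0
    if not pred(f(hi)):
        return None, 0
    it = 0
    while hi - lo > tol and it < max_iter:
        mid = 0.5 * (lo + hi)
        if pred(f(mid)):
            hi = mid
        else:
            lo = mid
        it += 1
    return 0.5 * (lo + hi), it


def calibrate_re(
    k1: float,
    k2: float,
    R: float,
    base_params: ModelParameters | None = None,
    *,
    target_rls: int = TARGET_RLS,
    tol: float = RE_TOL,
    rls_fn: Callable[[float], float] | None = None,
) -> float | None:
    """Retention factor achieving the target rls at (k1, k2, R), or None.

    ``rls_fn`` may inject an arbitrary rls(re) function (used in tests); by
    default the single-cell simulator is run at sigma = 0 with a damage-free
    founder.  rls is non-increasing in re, which is checked at the interval
    ends (violations are logged as anomalies, not errors).  Because rls is
    integer-valued, an interval of re attains the target; the midpoint of
    that plateau is returned.
    """
    if rls_fn is None:
        base = base_params if base_params is not None else ModelParameters()
        def rls_fn(re: float) -> float:
            return simulate_rls(base.with_updates(k1=k1, k2=k2, R=R, re=re))
    r0, r1 = rls_fn(0.0), rls_fn(1.0)
    if r0 < r1:
        log.warning("monotonicity anomaly at k1=%g k2=%g: rls(0)=%s < rls(1)=%s",
                    k1, k2, r0, r1)
    if not (r1 <= target_rls <= r0):
        return None
    # plateau edges: rls(re) steps down through the target as re grows
    lower, _ = _bisect_edge(rls_fn, lambda v: v <= target_rls, 0.0, 1.0, tol)
    upper, _ = _bisect_edge(rls_fn, lambda v: v < target_rls, 0.0, 1.0, tol)
    if lower is None:
        return None
    if upper is None:
        upper = 1.0  # plateau extends to re = 1
    re_star = 0.5 * (lower + upper)
    if rls_fn(re_star) != target_rls:
        return None
    return re_star


def calibrate_k2(
    k1: float,
    re: float,
    R: float,
    base_params: ModelParameters | None = None,
    *,
    target_rls: int = TARGET_RLS,
    k2_max: float = 1.0,
    tol: float = RE_TOL,
    rls_fn: Callable[[float], float] | None = None,
) -> float | None:
    """Alternate mode: repair rate achieving the target rls at fixed (k1, re).

    rls is non-decreasing in k2 (more repair never shortens life)."""
    if rls_fn is None:
        base = base_params if base_params is not None else ModelParameters()
        def rls_fn(k2: float) -> float:
            return simulate_rls(base.with_updates(k1=k1, k2=k2, R=R, re=re))
    r0, r1 = rls_fn(0.0), rls_fn(k2_max)
    if not (r0 <= target_rls <= r1):
        return None
    lower, _ = _bisect_edge(rls_fn, lambda v: v >= target_rls, 0.0, k2_max, tol)
    upper, _ = _bisect_edge(rls_fn, lambda v: v > target_rls, 0.0, k2_max, tol)
    if lower is None:
        return None
    if upper is None:
        upper = k2_max
    k2_star = 0.5 * (lower + upper)
    if rls_fn(k2_star) != target_rls:
        return None
    return k2_star


def find_wildtype_point(
    k1: float,
    k2_start: float,
    R: float,
    base_params: ModelParameters | None = None,
    *,
    target_rls: int = TARGET_RLS,
    spacing: float = GRID_SPACING,
    max_steps: int = 40,
) -> WildtypeGridEntry | None:
    """Calibrate re at (k1, k2_start); if infeasible, walk k2 along the grid
    (alternating up/down in 0.005 steps) until a feasible point is found."""
    base = base_params if base_params is not None else ModelParameters()
    tried: list[float] = []
    for step in range(max_steps + 1):
        for sign in ((1,) if step == 0 else (1, -1)):
            k2 = k2_start + sign * step * spacing
            if k2 <= 0 or k2 in tried:
                continue
            tried.append(k2)
            re_star = calibrate_re(k1, k2, R, base, target_rls=target_rls)
            if re_star is not None:
                achieved = simulate_rls(base.with_updates(k1=k1, k2=k2, R=R, re=re_star))
                return WildtypeGridEntry(k1=k1, k2=k2, R=R, re_star=re_star,
                                         achieved_rls=int(achieved), feasible=True)
    return None


def _grid_points(lo: float, hi: float, spacing: float) -> np.ndarray:
    n = int(round((hi - lo) / spacing))
    return np.round(lo + spacing * np.arange(n + 1), 10)


def build_wildtype_grid(
    k1_range: tuple[float, float],
    k2_range: tuple[float, float],
    R: float,
    base_params: ModelParameters | None = None,
    *,
    spacing: float = GRID_SPACING,
    target_rls: int = TARGET_RLS,
) -> list[WildtypeGridEntry]:
    """One entry per (k1, k2) grid point: the calibrated re or an infeasible
    marker, with the re-simulated achieved rls."""
    base = base_params if base_params is not None else ModelParameters()
    entries = []
    for k1 in _grid_points(*k1_range, spacing):
        for k2 in _grid_points(*k2_range, spacing):
            re_star = calibrate_re(float(k1), float(k2), R, base,
                                   target_rls=target_rls)
            if re_star is None:
                entries.append(WildtypeGridEntry(float(k1), float(k2), R,
                                                 None, None, False))
            else:
                achieved = simulate_rls(
                    base.with_updates(k1=float(k1), k2=float(k2), R=R, re=re_star))
                entries.append(WildtypeGridEntry(float(k1), float(k2), R,
                                                 re_star, int(achieved), True))
    return entries


def grid_frame(entries: list[WildtypeGridEntry]) -> pd.DataFrame:
    """Delimited-table view of a calibrated grid."""
    return pd.DataFrame([
        {
            "k1": e.k1,
            "k2": e.k2,
            "R_regime": "unlimited" if math.isinf(e.R) else "decline",
            "re_star": e.re_star if e.re_star is not None else np.nan,
            "achieved_rls": e.achieved_rls if e.achieved_rls is not None else np.nan,
            "feasible": e.feasible,
        }
        for e in entries
    ])
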