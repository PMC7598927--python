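"""Single-cell and population ageing metrics.

Per cell: replicative lifespan (rls), lifetime, generation times, growth per
cell cycle S(t_n)/S(t_{n-1}), cumulative growth S(t_d)/S(t_0), rejuvenation
index (rls_cell - rls_mother) / mean_rls, and the health span

    h = [(t_c - t_0) / (t_d - t_0)] * [rls_c / rls],

where t_c is the first time damage reaches the health threshold (t_c = t_d,
rls_c = rls if it never does, so h = 1) and rls_c the divisions completed by
then.  Per population: size, mean rls and dispersion, fraction of rejuvenated
cells (rej > 0 among non-founders), fraction of healthy cells (h > h_c) and a
growth-rate proxy (cells born by a snapshot time).

Lifespan-based metrics are undefined for censored cells; rls_c/rls is taken
as 1 for sterile cells (rls = 0), leaving h the pure time fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lineage import CellRecord, LineageTable
from .model import Trajectory

__all__ = [
    "UndefinedMetricError",
    "CellMetrics",
    "PopulationMetrics",
    "rejuvenation_index",
    "health_span",
    "growth_metrics",
    "mean_rls",
    "cell_metrics",
    "metrics_table",
    "population_summary",
    "group_by_lineage_position",
    "health_crossing_from_trajectory",
]


class UndefinedMetricError(ValueError):
    """The requested metric is undefined for this record (censored/founder)."""


@dataclass(frozen=True)
class CellMetrics:
    cell_id: int
    rls: int
    lifetime: float
    generation_times: tuple[float, ...]
    growth_per_cycle: tuple[float, ...]
    cumulative_growth: float
    health_span: float
    rejuvenation_index: float | None
    damage_at_birth: float
    size_at_birth: float


@dataclass(frozen=True)
class PopulationMetrics:
    population_size: int
    mean_rls: float
    sd_rls: float
    fraction_rejuvenated: float
    fraction_healthy: float
    growth_rate_proxy: int | None


def rejuvenation_index(rls_cell: int, rls_mother: int, mean_rls_: float) -> float:
    """Degree of rejuvenation, (rls_cell - rls_mother) / mean_rls.

    A rejuvenated cell has a positive index.  Undefined for founders (no
    mother); callers pass the mother's rls, so only the scale is checked here.
    """
    if mean_rls_ <= 0:
        raise UndefinedMetricError("mean_rls must be positive")
    return (rls_cell - rls_mother) / mean_rls_


def health_span(record: CellRecord) -> float:
    """Health span h in [0, 1] from the event-refined threshold crossing."""
    if record.censored or record.td is None:
        raise UndefinedMetricError("health span undefined for censored cells")
    lifetime = record.td - record.t0
    if record.t_health is None:
        return 1.0
    time_frac = (record.t_health - record.t0) / lifetime if lifetime > 0 else 0.0
    rls = record.rls
    div_frac = 1.0 if rls == 0 else (record.rls_at_health or 0) / rls
    return min(max(time_frac * div_frac, 0.0), 1.0)


def health_crossing_from_trajectory(trajectory: list[Trajectory], threshold: float):
    """(t_c, segment index) of the first upward crossing of D through a
    threshold on a stored dense trajectory, by linear interpolation; None if
    damage never reaches it.  Supports re-evaluating h at thresholds other
    than the one used during simulation."""
    for k, seg in enumerate(trajectory):
        D = np.asarray(seg.D)
        if D[0] >= threshold and k == 0:
            return float(seg.t[0]), 0
        above = np.nonzero(D >= threshold)[0]
        if above.size == 0:
            continue
        i = above[0]
        if i == 0:
            return float(seg.t[0]), k
        t0, t1 = seg.t[i - 1], seg.t[i]
        d0, d1 = D[i - 1], D[i]
        tc = t0 + (threshold - d0) / (d1 - d0) * (t1 - t0)
        return float(tc), k
    return None


def growth_metrics(record: CellRecord):
    """(generation_times, growth_per_cycle, cumulative_growth) of one cell.

    Sizes are the pre-split sizes at each division; cumulative growth relates
    the size at death to the size at birth.  A sterile cell (rls = 0) has
    empty per-cycle lists but a defined cumulative growth.
    """
    if record.censored:
        raise UndefinedMetricError("growth metrics undefined for censored cells")
    times = (record.t0, *record.division_times)
    generation_times = tuple(b - a for a, b in zip(times, times[1:]))
    sizes = (record.size_at_birth, *record.sizes_at_divisions)
    growth_per_cycle = tuple(b / a for a, b in zip(sizes, sizes[1:]))
    cumulative = (record.size_at_death / record.size_at_birth
                  if record.size_at_death is not None else math.nan)
    return generation_times, growth_per_cycle, cumulative


def mean_rls(table: LineageTable, *, include_founders: bool = True) -> float:
    """Mean replicative lifespan over uncensored cells."""
    vals = [r.rls for r in table
            if not r.censored and (include_founders or r.mother_id is not None)]
    if not vals:
        raise UndefinedMetricError("no uncensored cells")
    return float(np.mean(vals))


def cell_metrics(record: CellRecord, table: LineageTable,
                 mean_rls_: float | None = None) -> CellMetrics:
    """All Box-style single-cell properties of one uncensored record."""
    if record.censored:
        raise UndefinedMetricError("metrics undefined for censored cells")
    if mean_rls_ is None:
        mean_rls_ = mean_rls(table)
    gen_times, growth_cycle, cumulative = growth_metrics(record)
    rej = None
    if record.mother_id is not None:
        mother = table[record.mother_id]
        if not mother.censored:
            rej = rejuvenation_index(record.rls, mother.rls, mean_rls_)
    return CellMetrics(
        cell_id=record.cell_id,
        rls=record.rls,
        lifetime=record.td - record.t0,
        generation_times=gen_times,
        growth_per_cycle=growth_cycle,
        cumulative_growth=cumulative,
        health_span=health_span(record),
        rejuvenation_index=rej,
        damage_at_birth=record.damage_at_birth,
        size_at_birth=record.size_at_birth,
    )


def metrics_table(table: LineageTable) -> pd.DataFrame:
    """Per-cell metrics of all uncensored cells, keyed by cell_id."""
    mbar = mean_rls(table)
    rows = []
    for r in sorted(table, key=lambda r: r.cell_id):
        if r.censored:
            continue
        m = cell_metrics(r, table, mbar)
        rows.append({
            "cell_id": m.cell_id,
            "generation": r.generation,
            "i": r.position[0] if len(r.position) >= 1 else np.nan,
            "j": r.position[1] if len(r.position) >= 2 else np.nan,
            "rls": m.rls,
            "lifetime": m.lifetime,
            "mean_generation_time": np.mean(m.generation_times) if m.generation_times else np.nan,
            "mean_growth_per_cycle": np.mean(m.growth_per_cycle) if m.growth_per_cycle else np.nan,
            "cumulative_growth": m.cumulative_growth,
            "health_span": m.health_span,
            "rejuvenation_index": m.rejuvenation_index if m.rejuvenation_index is not None else np.nan,
            "rejuvenated": bool(m.rejuvenation_index is not None and m.rejuvenation_index > 0),
            "damage_at_birth": m.damage_at_birth,
            "size_at_birth": m.size_at_birth,
        })
    return pd.DataFrame(rows)


def population_summary(table: LineageTable, *, h_c: float = 0.5,
                       snapshot_time: float | None = None) -> PopulationMetrics:
    """Box-style population properties of one lineage table."""
    uncensored = [r for r in table if not r.censored]
    if not uncensored:
        raise UndefinedMetricError("no uncensored cells in the table")
    mbar = mean_rls(table)
    rls_vals = [r.rls for r in uncensored]
    non_founders = [r for r in uncensored if r.mother_id is not None
                    and not table[r.mother_id].censored]
    if non_founders:
        rejs = [rejuvenation_index(r.rls, table[r.mother_id].rls, mbar)
                for r in non_founders]
        frac_rej = float(np.mean([rej > 0 for rej in rejs]))
    else:
        raise UndefinedMetricError("no non-founder cells: fractions undefined")
    hs = [health_span(r) for r in uncensored]
    frac_healthy = float(np.mean([h > h_c for h in hs]))
    proxy = None
    if snapshot_time is not None:
        proxy = sum(1 for r in table if r.t0 <= snapshot_time)
    return PopulationMetrics(
        population_size=len(table),
        mean_rls=mbar,
        sd_rls=float(np.std(rls_vals, ddof=1)) if len(rls_vals) > 1 else 0.0,
        fraction_rejuvenated=frac_rej,
        fraction_healthy=frac_healthy,
        growth_rate_proxy=proxy,
    )


def group_by_lineage_position(table: LineageTable, metric: str,
                              depth: int = 2) -> pd.DataFrame:
    """Aggregate a per-cell metric over the (i, j) grid of lineage positions.

    Cells of generation >= 2 are grouped by their first two position indices
    (i: birth order under the mother, j: the mother's birth order under the
    grandmother); generation-1 cells are grouped by i only (j = NaN).
    Founders carry no indices and are excluded; empty groups are omitted.
    """
    df = metrics_table(table)
    df = df[df["generation"] >= 1].copy()
    if depth == 1:
        keys = ["i"]
    else:
        keys = ["i", "j"]
    rows = []
    for key_vals, grp in df.groupby(keys, dropna=False):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        vals = grp[metric].dropna()
        if vals.empty:
            continue
        row = dict(zip(keys, key_vals))
        row.update({
            "metric": metric,
            "n": int(len(vals)),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        })
        rows.append(row)
    return pd.DataFrame(rows)
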