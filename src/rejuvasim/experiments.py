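"""Scripted in-silico experiment drivers.

Each driver grows the required populations with :func:`run_population`,
derives its outputs purely from the resulting lineage tables, and is a
deterministic function of (design, seed).  Compared arms (retention on/off,
repair-capacity regimes, stress on/off, sigma modes) share the random-number
stream: per-cell random effects are keyed by lineage position, so a parameter
override changes rates but never the noise draws (common random numbers).

Default designs mirror the published protocols at reduced pedigree depth
(generation cap 2) so every driver completes in minutes on one CPU; founder
counts and caps are recorded in the outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache

import pandas as pd

from .calibration import TARGET_RLS, calibrate_k2
from .config import RETENTION_WILDTYPE, wildtype_params
from .lineage import LineageTable, MixedEffectsSpec, average_newborn, run_population
from .metrics import (metrics_table, population_summary,
                      group_by_lineage_position, UndefinedMetricError)

__all__ = [
    "ExperimentDesign",
    "InfeasibleArmError",
    "matched_repair_rate",
    "run_wildtype_population",
    "run_retention_sweep",
    "run_division_age_analysis",
    "run_growth_rate_experiment",
    "run_stress_experiment",
    "run_mixed_effects_comparison",
    "run_correlation_analysis",
]

log = logging.getLogger(__name__)

REGIMES = ("decline", "unlimited")


@dataclass(frozen=True)
class ExperimentDesign:
    """Founder schedule, caps and overrides of one in-silico experiment."""

    name: str = "wildtype"
    n_founders: int = 5
    sigma: float = 0.005
    re_values: tuple[float, ...] = (0.0, RETENTION_WILDTYPE)
    regimes: tuple[str, ...] = REGIMES
    max_generation: int | None = 2
    max_cells: int = 100_000
    t_spawn_horizon: float | None = None
    snapshot_time: float = 8.0
    stress_multiplier: float = 1.01
    n_populations: int = 20
    seed: int = 1
    h_c: float = 0.5

    def with_updates(self, **kw) -> "ExperimentDesign":
        return replace(self, **kw)


class InfeasibleArmError(ValueError):
    """No repair rate reaches the wildtype lifespan at this retention factor."""


@lru_cache(maxsize=None)
def matched_repair_rate(regime: str, re: float,
                        target_rls: int = TARGET_RLS) -> float:
    """Repair rate putting (k1, re) on the wildtype grid for one regime.

    Experiment arms always sit on the wildtype surface: the damage formation
    rate stays fixed while k2 is re-adapted so that a damage-free founder
    achieves the target lifespan at the requested retention factor.
    """
    params = wildtype_params(regime, re=re)
    k2 = calibrate_k2(params.k1, re, params.R, params, target_rls=target_rls)
    if k2 is None:
        raise InfeasibleArmError(
            f"no k2 achieves rls={target_rls} at re={re} ({regime})")
    return k2


def run_wildtype_population(
    design: ExperimentDesign,
    *,
    regime: str = "decline",
    re: float = RETENTION_WILDTYPE,
    k1_scale: float = 1.0,
    sigma: float | None = None,
    seed: int | None = None,
    n_founders: int | None = None,
    t_spawn_horizon: float | None = None,
    matched_rls: bool = True,
) -> LineageTable:
    """Grow one wildtype population for the given arm of a design.

    With ``matched_rls`` (the default) the arm's k2 is the grid-calibrated
    value for its (re, regime); otherwise the shipped anchor k2 is used as is.
    """
    params = wildtype_params(regime, re=re)
    if matched_rls:
        params = params.with_updates(k2=matched_repair_rate(regime, re))
    spec = MixedEffectsSpec(k1_bar=params.k1 * k1_scale, k2_bar=params.k2,
                            sigma=design.sigma if sigma is None else sigma)
    n = design.n_founders if n_founders is None else n_founders
    founders = [average_newborn(params) for _ in range(n)]
    return run_population(
        founders, spec, params,
        seed=design.seed if seed is None else seed,
        max_generation=design.max_generation,
        max_cells=design.max_cells,
        t_spawn_horizon=(design.t_spawn_horizon if t_spawn_horizon is None
                         else t_spawn_horizon),
        config={"regime": regime, "re": re, "k1_scale": k1_scale,
                "sigma": spec.sigma, "n_founders": n},
    )


def run_retention_sweep(design: ExperimentDesign) -> pd.DataFrame:
    """Population size and per-cell property summaries per (re, regime)."""
    rows = []
    for regime in design.regimes:
        for re in design.re_values:
            try:
                table = run_wildtype_population(design, regime=regime, re=re)
                pop = population_summary(table, h_c=design.h_c)
            except (InfeasibleArmError, UndefinedMetricError) as exc:
                log.warning("skipping re=%g regime=%s: %s", re, regime, exc)
                continue
            df = metrics_table(table)
            rows.append({
                "re": re,
                "regime": regime,
                "population_size": pop.population_size,
                "mean_rls": pop.mean_rls,
                "sd_rls": pop.sd_rls,
                "fraction_rejuvenated": pop.fraction_rejuvenated,
                "fraction_healthy": pop.fraction_healthy,
                "mean_damage_at_birth": float(df["damage_at_birth"].mean()),
                "sd_damage_at_birth": float(df["damage_at_birth"].std(ddof=1)),
                "mean_generation_time": float(df["mean_generation_time"].mean()),
                "sd_generation_time": float(df["mean_generation_time"].std(ddof=1)),
                "mean_health_span": float(df["health_span"].mean()),
                "sd_health_span": float(df["health_span"].std(ddof=1)),
                "n_founders": design.n_founders,
                "seed": design.seed,
            })
    return pd.DataFrame(rows)


def run_division_age_analysis(design: ExperimentDesign) -> pd.DataFrame:
    """Mother/daughter protein content at division vs the mother's age.

    Long table, one row per recorded division: the mother's replicative age n
    at that division and the post-split P and D of mother and daughter,
    reconstructed exactly from the division rule.
    """
    rows = []
    for regime in design.regimes:
        for re in design.re_values:
            table = run_wildtype_population(design, regime=regime, re=re)
            for rec in table:
                params = rec.params
                # mother pre-split P equals P_div (the division trigger);
                # D follows from the stored pre-split size S = P + Q*D
                for n, S_pre in enumerate(rec.sizes_at_divisions, start=1):
                    P_pre = params.P_div
                    D_pre = (S_pre - P_pre) / params.Q if params.Q > 0 else 0.0
                    frac_m = params.s + params.re * (1.0 - params.s)
                    rows.append({
                        "regime": regime,
                        "re": re,
                        "cell_id": rec.cell_id,
                        "mother_age": n,
                        "P_pre": P_pre,
                        "D_pre": D_pre,
                        "mother_P": params.s * P_pre,
                        "mother_D": frac_m * D_pre,
                        "daughter_P": (1.0 - params.s) * P_pre,
                        "daughter_D": (1.0 - frac_m) * D_pre,
                    })
    return pd.DataFrame(rows)


def run_growth_rate_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Cells born by the snapshot time, per single-founder population."""
    rows = []
    for regime in design.regimes:
        for re in design.re_values:
            for k in range(design.n_populations):
                table = run_wildtype_population(
                    design, regime=regime, re=re, n_founders=1,
                    seed=design.seed + k,
                    t_spawn_horizon=design.snapshot_time,
                )
                count = sum(1 for r in table if r.t0 <= design.snapshot_time)
                rows.append({
                    "regime": regime,
                    "re": re,
                    "population": k,
                    "seed": design.seed + k,
                    "snapshot_time": design.snapshot_time,
                    "cells_at_snapshot": count,
                })
    return pd.DataFrame(rows)


def run_stress_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Rejuvenation and health grouped by grandmother index j, with and
    without stress (a 1% increase of the damage formation rate by default)."""
    rows = []
    for regime in design.regimes:
        for re in design.re_values:
            for stressed, scale in (("unstressed", 1.0),
                                    ("stressed", design.stress_multiplier)):
                table = run_wildtype_population(design, regime=regime,
                                                re=re, k1_scale=scale)
                for metric in ("rejuvenation_index", "health_span"):
                    grouped = group_by_lineage_position(table, metric)
                    grouped["regime"] = regime
                    grouped["re"] = re
                    grouped["arm"] = stressed
                    grouped["k1_scale"] = scale
                    grouped["population_size"] = len(table)
                    rows.append(grouped)
    return pd.concat(rows, ignore_index=True)


def run_mixed_effects_comparison(design: ExperimentDesign,
                                 sigmas: tuple[float, float] = (0.0, 0.005)
                                 ) -> pd.DataFrame:
    """Side-by-side population metrics for homogeneous (sigma = 0) and
    heterogeneous rate parameters, on matched founder schedules."""
    rows = []
    for regime in design.regimes:
        for re in design.re_values:
            for sigma in sigmas:
                table = run_wildtype_population(design, regime=regime, re=re,
                                                sigma=sigma)
                pop = population_summary(table, h_c=design.h_c)
                rows.append({
                    "regime": regime,
                    "re": re,
                    "sigma": sigma,
                    "population_size": pop.population_size,
                    "mean_rls": pop.mean_rls,
                    "sd_rls": pop.sd_rls,
                    "fraction_rejuvenated": pop.fraction_rejuvenated,
                    "fraction_healthy": pop.fraction_healthy,
                })
    return pd.DataFrame(rows)


def run_correlation_analysis(design: ExperimentDesign,
                             table: LineageTable | None = None) -> pd.DataFrame:
    """Paired per-cell metrics for scatter analysis, with a rejuvenated flag.

    Pairs: health span vs rls; mean generation time vs mean growth per cycle;
    lineage index i vs rls; size at birth vs cumulative growth.
    """
    if table is None:
        table = run_wildtype_population(design)
    df = metrics_table(table)
    pairs = [
        ("health_span", "rls"),
        ("mean_generation_time", "mean_growth_per_cycle"),
        ("i", "rls"),
        ("size_at_birth", "cumulative_growth"),
    ]
    rows = []
    for x, y in pairs:
        sub = df[["cell_id", x, y, "rejuvenated"]].dropna(subset=[x, y])
        for _, r in sub.iterrows():
            rows.append({
                "pairing": f"{x}~{y}",
                "cell_id": int(r["cell_id"]),
                "x": float(r[x]),
                "y": float(r[y]),
                "rejuvenated": bool(r["rejuvenated"]),
            })
    return pd.DataFrame(rows)
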