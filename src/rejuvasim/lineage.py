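"""Population growth of a cell lineage.

Starting from one or more founder cells, every division spawns a daughter that
follows its own independent single-cell model, initialised with the protein
content handed over at division.  Cell-to-cell variability follows a
non-linear mixed-effects scheme: each newborn draws its own damage formation
and repair rates

    k1 = k1_bar * exp(eta1),  k2 = k2_bar * exp(eta2),  eta_i ~ N(0, sigma^2),

log-normal so the rates stay strictly positive.  The pedigree is recorded
explicitly: a cell's lineage position is the self-first index list
``(i, j, ...)`` — it is the i-th daughter of its mother, which is the j-th
daughter of its own mother, and so on up to the founder (empty position,
generation 0).

Scheduling uses a birth-time-ordered event queue rather than literal
recursion; the output is identical and memory stays bounded.  Each cell's
random effects are drawn from an RNG substream keyed by (seed, founder index,
lineage position), so results are invariant to traversal order and matched
across experiment arms that share a seed (common random numbers).
"""

from __future__ import annotations

import heapq
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CellState, ModelParameters, simulate_cell

log = logging.getLogger(__name__)

__all__ = [
    "MixedEffectsSpec",
    "CellRecord",
    "LineageTable",
    "sample_cell_parameters",
    "run_population",
    "average_newborn",
    "position_of",
    "generation_of",
    "export_lineage",
    "read_lineage",
    "to_newick",
    "PedigreeError",
]


class PedigreeError(RuntimeError):
    """A mother link does not resolve within the table."""


@dataclass(frozen=True)
class MixedEffectsSpec:
    """Population fixed effects and random-effect spread for (k1, k2)."""

    k1_bar: float
    k2_bar: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.k1_bar <= 0 or self.k2_bar <= 0:
            raise ValueError("fixed effects must be strictly positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def sample_cell_parameters(spec: MixedEffectsSpec, rng: np.random.Generator) -> tuple[float, float]:
    """Draw one cell's (k1, k2) from the log-normal mixed-effects model."""
    if spec.sigma == 0.0:
        return spec.k1_bar, spec.k2_bar
    eta1, eta2 = rng.normal(0.0, spec.sigma, size=2)
    return spec.k1_bar * math.exp(eta1), spec.k2_bar * math.exp(eta2)


@dataclass
class CellRecord:
    """One completed (or censored) cell life inside a lineage."""

    cell_id: int
    mother_id: int | None
    founder_index: int
    position: tuple[int, ...]
    params: ModelParameters
    t0: float
    td: float | None
    censored: bool
    division_times: tuple[float, ...]
    daughter_ids: tuple[int, ...]
    birth_state: CellState
    sizes_at_divisions: tuple[float, ...]
    size_at_death: float | None
    t_health: float | None
    rls_at_health: int | None

    @property
    def rls(self) -> int:
        return len(self.division_times)

    @property
    def generation(self) -> int:
        return len(self.position)

    @property
    def lifetime(self) -> float | None:
        return None if self.td is None else self.td - self.t0

    @property
    def damage_at_birth(self) -> float:
        return self.birth_state.D

    @property
    def size_at_birth(self) -> float:
        return self.birth_state.size(self.params.Q)


@dataclass
class LineageTable:
    """The full pedigree: all cell records plus run provenance."""

    records: dict[int, CellRecord]
    founders: list[int]
    seed: int
    config: dict = field(default_factory=dict)
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __getitem__(self, cell_id: int) -> CellRecord:
        return self.records[cell_id]

    def non_founders(self):
        return (r for r in self if r.mother_id is not None)

    def validate(self) -> None:
        """Check pedigree integrity: mother links resolve, positions consistent."""
        for r in self:
            if r.mother_id is None:
                if r.position != ():
                    raise PedigreeError(f"founder {r.cell_id} has position {r.position}")
                continue
            if r.mother_id not in self.records:
                raise PedigreeError(f"cell {r.cell_id}: mother {r.mother_id} missing")
            mother = self.records[r.mother_id]
            if r.position[1:] != mother.position:
                raise PedigreeError(f"cell {r.cell_id}: inconsistent position")


def average_newborn(params: ModelParameters, t: float = 0.0) -> CellState:
    """Founder with average initial conditions: the damage-free newborn of an
    average division, P0 = (1-s)*P_div, D0 = 0."""
    return CellState(t, (1.0 - params.s) * params.P_div, 0.0)


def _cell_rng(seed: int, founder_index: int, position: tuple[int, ...]) -> np.random.Generator:
    # Substream keyed by lineage coordinates, not by traversal order.
    ss = np.random.SeedSequence([int(seed), int(founder_index) + 1, *position])
    return np.random.default_rng(ss)


def run_population(
    founders: list[CellState],
    spec: MixedEffectsSpec,
    base_params: ModelParameters,
    *,
    seed: int = 0,
    max_generation: int | None = None,
    max_cells: int = 100_000,
    t_spawn_horizon: float | None = None,
    max_divisions: int = 1000,
    max_lifetime: float = 1e4,
    config: dict | None = None,
) -> LineageTable:
    """Grow a lineage from founder cells and return the complete pedigree.

    Every born cell is simulated to death (or cap) with its own sampled
    (k1, k2).  Daughters beyond ``max_generation`` are not spawned; with
    ``t_spawn_horizon`` set, daughters born after the horizon are not spawned
    (growth-rate experiments).  Exceeding ``max_cells`` truncates the table
    and flags it.
    """
    if not founders:
        raise ValueError("need at least one founder")
    if max_generation is not None and max_generation < 0:
        raise ValueError("max_generation must be >= 0")

    records: dict[int, CellRecord] = {}
    table = LineageTable(records=records, founders=[], seed=seed,
                         config=dict(config or {}))
    # queue entries: (birth time, cell_id, mother_id, founder_index, position, state)
    queue: list[tuple] = []
    next_id = 0
    for fi, st in enumerate(founders):
        heapq.heappush(queue, (st.t, next_id, None, fi, (), st))
        table.founders.append(next_id)
        next_id += 1

    while queue:
        t0, cid, mother_id, fi, pos, birth = heapq.heappop(queue)
        rng = _cell_rng(seed, fi, pos)
        k1, k2 = sample_cell_parameters(spec, rng)
        params = base_params.with_updates(k1=k1, k2=k2)
        life = simulate_cell(birth, params,
                             max_divisions=max_divisions,
                             max_lifetime=max_lifetime)
        daughter_ids = []
        spawn = (max_generation is None) or (len(pos) < max_generation)
        if spawn:
            for i, (dt, dstate) in enumerate(
                    zip(life.division_times, life.daughter_states), start=1):
                if t_spawn_horizon is not None and dt > t_spawn_horizon:
                    continue
                if next_id >= max_cells:
                    table.truncated = True
                    break
                heapq.heappush(queue, (dt, next_id, cid, fi, (i, *pos), dstate))
                daughter_ids.append(next_id)
                next_id += 1
        records[cid] = CellRecord(
            cell_id=cid,
            mother_id=mother_id,
            founder_index=fi,
            position=pos,
            params=params,
            t0=t0,
            td=None if life.censored else life.death_time,
            censored=life.censored,
            division_times=tuple(life.division_times),
            daughter_ids=tuple(daughter_ids),
            birth_state=birth,
            sizes_at_divisions=tuple(life.sizes_at_divisions),
            size_at_death=None if life.censored else life.size_at_death,
            t_health=life.t_health,
            rls_at_health=life.rls_at_health,
        )
    if log.isEnabledFor(logging.INFO):
        births: dict[int, int] = {}
        deaths: dict[int, int] = {}
        for r in records.values():
            births[r.generation] = births.get(r.generation, 0) + 1
            if not r.censored:
                deaths[r.generation] = deaths.get(r.generation, 0) + 1
        for gen in sorted(births):
            log.info("generation %d: %d births, %d deaths",
                     gen, births[gen], deaths.get(gen, 0))
    return table


def position_of(record: CellRecord, table: LineageTable) -> tuple[int, ...]:
    """Reconstruct the lineage position by walking mother links to the founder.

    Cross-checks the stored position; raises :class:`PedigreeError` on broken
    links.
    """
    indices: list[int] = []
    r = record
    while r.mother_id is not None:
        if r.mother_id not in table.records:
            raise PedigreeError(f"cell {r.cell_id}: mother {r.mother_id} missing")
        mother = table.records[r.mother_id]
        try:
            idx = mother.daughter_ids.index(r.cell_id) + 1
        except ValueError as exc:
            raise PedigreeError(
                f"cell {r.cell_id} not among daughters of {mother.cell_id}") from exc
        indices.append(idx)
        r = mother
    return tuple(indices)


def generation_of(record: CellRecord) -> int:
    """Pedigree depth relative to the founder (cardinality of the position)."""
    return record.generation


# ---------------------------------------------------------------------------
# I/O: delimited table + Newick tree

_LIST_SEP = ";"

_PARAM_FIELDS = ("g", "k1", "k2", "Q", "R", "re", "s", "P_div", "D_death", "D_health")


def _fmt_float(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _fmt_list(xs) -> str:
    return _LIST_SEP.join(repr(float(x)) for x in xs)


def _record_row(r: CellRecord) -> dict:
    row = {
        "cell_id": r.cell_id,
        "mother_id": "" if r.mother_id is None else r.mother_id,
        "founder_index": r.founder_index,
        "position": ".".join(str(i) for i in r.position),
        "generation": r.generation,
        "t0": _fmt_float(r.t0),
        "td": _fmt_float(r.td),
        "censored": int(r.censored),
        "rls": r.rls,
        "division_times": _fmt_list(r.division_times),
        "daughter_ids": _LIST_SEP.join(str(i) for i in r.daughter_ids),
        "P0": _fmt_float(r.birth_state.P),
        "D0": _fmt_float(r.birth_state.D),
        "sizes_at_divisions": _fmt_list(r.sizes_at_divisions),
        "size_at_death": _fmt_float(r.size_at_death),
        "t_health": _fmt_float(r.t_health),
        "rls_at_health": "" if r.rls_at_health is None else r.rls_at_health,
    }
    for f in _PARAM_FIELDS:
        row[f] = _fmt_float(getattr(r.params, f))
    return row


def lineage_frame(table: LineageTable) -> pd.DataFrame:
    """One row per cell, all pedigree and life-history fields."""
    rows = [_record_row(r) for r in sorted(table, key=lambda r: r.cell_id)]
    return pd.DataFrame(rows)


def to_newick(table: LineageTable) -> str:
    """Serialise the pedigree as a Newick forest (one tree per founder).

    Labels are ``c<cell_id>``; branch lengths are lifetimes (time alive at the
    horizon for censored cells, marked with a ``[&censored]`` comment).
    """
    def span(r: CellRecord) -> float:
        if r.td is not None:
            return r.td - r.t0
        last = r.division_times[-1] if r.division_times else r.t0
        return last - r.t0

    def node(r: CellRecord) -> str:
        children = [table.records[d] for d in r.daughter_ids]
        label = f"c{r.cell_id}"
        mark = "[&censored]" if r.censored else ""
        length = f"{span(r):.10g}"
        if children:
            inner = ",".join(node(c) for c in children)
            return f"({inner}){label}:{length}{mark}"
        return f"{label}:{length}{mark}"

    trees = [node(table.records[f]) + ";" for f in table.founders]
    return "\n".join(trees) + "\n"


def export_lineage(table: LineageTable, destination: str | Path) -> tuple[Path, Path]:
    """Write ``lineage.csv``, ``lineage.nwk`` and a ``manifest.json`` snapshot.

    Returns the (csv, newick) paths.  The CSV round-trips losslessly through
    :func:`read_lineage`.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    csv_path = dest / "lineage.csv"
    nwk_path = dest / "lineage.nwk"
    df = lineage_frame(table)
    df.to_csv(csv_path, index=False)
    nwk_path.write_text(to_newick(table))
    manifest = {
        "seed": table.seed,
        "truncated": table.truncated,
        "n_cells": len(table),
        "founders": table.founders,
        "config": table.config,
    }
    (dest / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return csv_path, nwk_path


def _parse_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _parse_list(v) -> tuple[float, ...]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return ()
    return tuple(float(x) for x in str(v).split(_LIST_SEP))


def read_lineage(csv_path: str | Path) -> LineageTable:
    """Read a lineage table written by :func:`export_lineage`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    records: dict[int, CellRecord] = {}
    founders: list[int] = []
    for _, row in df.iterrows():
        pvals = {f: float(row[f]) for f in _PARAM_FIELDS}
        params = ModelParameters(**pvals)
        pos = tuple(int(i) for i in row["position"].split(".")) if row["position"] else ()
        t0 = float(row["t0"])
        rec = CellRecord(
            cell_id=int(row["cell_id"]),
            mother_id=None if row["mother_id"] == "" else int(row["mother_id"]),
            founder_index=int(row["founder_index"]),
            position=pos,
            params=params,
            t0=t0,
            td=_parse_float(row["td"]),
            censored=bool(int(row["censored"])),
            division_times=_parse_list(row["division_times"]),
            daughter_ids=tuple(int(i) for i in row["daughter_ids"].split(_LIST_SEP))
            if row["daughter_ids"] else (),
            birth_state=CellState(t0, float(row["P0"]), float(row["D0"])),
            sizes_at_divisions=_parse_list(row["sizes_at_divisions"]),
            size_at_death=_parse_float(row["size_at_death"]),
            t_health=_parse_float(row["t_health"]),
            rls_at_health=None if row["rls_at_health"] == "" else int(row["rls_at_health"]),
        )
        records[rec.cell_id] = rec
        if rec.mother_id is None:
            founders.append(rec.cell_id)
    manifest_path = csv_path.parent / "manifest.json"
    seed, config, truncated = 0, {}, False
    if manifest_path.exists():
        m = json.loads(manifest_path.read_text())
        seed = m.get("seed", 0)
        config = m.get("config", {})
        truncated = m.get("truncated", False)
    return LineageTable(records=records, founders=founders, seed=seed,
                        config=config, truncated=truncated)
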