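"""Stochastic intercalary-growth simulator of the sepal abaxial epidermis.

The model abstracts the growing sepal as a basal *generative layer* of
``generative_width`` proliferating columns.  Each generative division emits
one apical daughter that enters three *patterning cell cycles*.  At the end
of each cycle a 2C cell either divides or irreversibly enters the endocycle
(probabilities p1, p2, p3 for cycles 1-3); endocycling cells double their
ploidy every subsequent cycle and terminate after the third, so the earlier
a cell commits the higher its terminal ploidy (up to 16C) and, because all
cells grow exponentially at the same areal rate, the larger it ends up.
Cells that divide at the end of cycle 3 yield terminal 2C daughters, each of
which may undergo up to ``stomatal_max_rounds`` extra stomatal-lineage
divisions with probability ``p_s``.

Cells are axis-aligned rectangles; divisions are transverse (splitting the
apical-basal length) or longitudinal (splitting the width), with the plane
chosen to bring the daughters' length:width ratio closest to 2:1.  Division
asymmetry and per-cell cycle-time sampling are the two noise sources; with
``noise_free=True`` the simulator reduces to the deterministic four-size
limit with terminal areas in ratio 1:2:4:8 for ploidies 2:4:8:16.

Reproducibility contract: a single ``numpy.random.Generator`` stream is
consumed in a documented order (cells processed in ascending ``cell_id``
each step; per completed cycle: one uniform for the fate decision, then any
draws for plane choice and the split fraction, then the daughters' cycle
durations, first daughter first; generative cells cycle deterministically
at the doubling time and draw nothing).  Identical seed and config give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .config import (
    CycleTimeDistribution,
    DivisionNoise,
    FateProbabilities,
    SimulationConfig,
)
from .errors import ConfigError, InvalidStateError, RuntimeLimitError

GENERATIVE = "generative"
PATTERNING = "patterning"
ENDOCYCLING = "endocycling"
TERMINATED = "terminated"

TRANSVERSE = "transverse"
LONGITUDINAL = "longitudinal"

DIVIDE = "divide"
ENDOCYCLE = "endocycle"
STOMATAL_DIVIDE = "stomatal_divide"
TERMINATE = "terminate"

_LOG2 = math.log(2.0)

#: Number of patterning cell cycles available to every apical daughter.
N_PATTERNING_CYCLES = 3

CELL_TABLE_COLUMNS = [
    "cell_id",
    "parent_id",
    "birth_time_h",
    "termination_time_h",
    "ploidy_c",
    "area",
    "length",
    "width",
    "column",
    "n_divisions",
    "stomatal",
]


@dataclass(slots=True)
class CellState:
    """One epidermal cell in the rectangle model (area == length * width)."""

    cell_id: int
    parent_id: int | None
    birth_time: float
    area: float
    length: float
    width: float
    column: int
    phase: str
    cycle_duration: float
    ploidy: int = 2
    patterning_cycle: int = 0
    cycle_elapsed: float = 0.0
    termination_time: float | None = None
    stomatal_rounds_done: int = 0
    n_divisions: int = 0
    pending_stomatal: bool = False


@dataclass
class RunLog:
    """Aggregate event counters plus an optional per-event record."""

    seed: int
    config_hash: str
    counts: dict[str, int] = field(
        default_factory=lambda: {
            "division": 0,
            "endocycle": 0,
            "termination": 0,
            "stomatal_division": 0,
        }
    )
    events: list[tuple[float, str, int]] | None = None
    total_time_h: float = 0.0

    def record(self, time_h: float, event: str, cell_id: int) -> None:
        self.counts[event] += 1
        if self.events is not None:
            self.events.append((time_h, event, cell_id))


class TissueState:
    """The growing cell population with its clock, RNG stream and counters."""

    def __init__(self, config: SimulationConfig, *, collect_events: bool = False):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.time = 0.0
        self.next_id = 0
        self.cells: dict[int, CellState] = {}
        self.terminated: list[CellState] = []
        self.n_nongenerative = 0
        self.stopped = False
        self.log = RunLog(
            seed=config.seed,
            config_hash=config.config_hash(),
            events=[] if collect_events else None,
        )
        length = math.sqrt(config.initial_area * config.initial_aspect)
        width = config.initial_area / length
        for col in range(config.generative_width):
            self._add_cell(
                CellState(
                    cell_id=self._new_id(),
                    parent_id=None,
                    birth_time=0.0,
                    area=config.initial_area,
                    length=length,
                    width=width,
                    column=col,
                    phase=GENERATIVE,
                    # The generative layer is modeled as a steady-state
                    # proliferative zone: it cycles at exactly the areal
                    # doubling time, so each apical daughter is born at the
                    # same area and the tissue's output is stationary.
                    cycle_duration=config.doubling_time,
                )
            )

    def _new_id(self) -> int:
        i = self.next_id
        self.next_id += 1
        return i

    def _add_cell(self, cell: CellState) -> None:
        self.cells[cell.cell_id] = cell

    @property
    def alive_nongenerative(self) -> int:
        return sum(1 for c in self.cells.values() if c.phase != GENERATIVE)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def sample_cycle_time(dist: CycleTimeDistribution, rng: np.random.Generator) -> float:
    """Draw one cell-cycle duration (hours) from the configured distribution."""
    if dist.family == "lognormal":
        if dist.sd_hours == 0:
            t = dist.mean_hours
        else:
            sigma2 = math.log1p((dist.sd_hours / dist.mean_hours) ** 2)
            mu = math.log(dist.mean_hours) - sigma2 / 2
            t = float(rng.lognormal(mu, math.sqrt(sigma2)))
    elif dist.family == "gamma":
        if dist.sd_hours == 0:
            t = dist.mean_hours
        else:
            shape = (dist.mean_hours / dist.sd_hours) ** 2
            scale = dist.sd_hours**2 / dist.mean_hours
            t = float(rng.gamma(shape, scale))
    elif dist.family == "empirical":
        assert dist.histogram is not None
        u = rng.random()
        acc = 0.0
        start = dist.histogram[-1][0]
        for bin_start, p in dist.histogram:
            acc += p
            if u < acc:
                start = bin_start
                break
        t = start + rng.random() * dist.bin_width_hours
    else:  # pragma: no cover - guarded by config validation
        raise ConfigError(f"unknown family {dist.family!r}")
    if dist.quantize_hours is not None:
        q = dist.quantize_hours
        t = max(1.0, math.ceil(t / q - 1e-12)) * q
    if t <= 0:
        t = float(np.nextafter(0, 1))
    return t


def grow_cell(cell: CellState, dt: float, doubling_time: float) -> CellState:
    """Advance a cell by ``dt`` hours of exponential, isotropic areal growth.

    Area scales by ``2**(dt/doubling_time)``; length and width each scale by
    the square root of that factor.  Terminated cells are frozen and
    returned unchanged.  The cell is mutated in place and returned.
    """
    if dt < 0:
        raise ValueError(f"dt must be nonnegative, got {dt}")
    if cell.phase == TERMINATED or dt == 0:
        return cell
    factor = 2.0 ** (dt / doubling_time)
    lin = math.sqrt(factor)
    cell.area *= factor
    cell.length *= lin
    cell.width *= lin
    cell.cycle_elapsed += dt
    return cell


def decide_fate(
    cell: CellState,
    fate: FateProbabilities,
    rng: np.random.Generator,
    stomatal_max_rounds: int = 1,
) -> str:
    """Decide a cell's fate at the end of a patterning cell cycle.

    Endocycling cells always continue endocycling (commitment is
    irreversible).  A 2C patterning cell that just completed cycle
    k in {1,2,3} enters the endocycle with probability p_k, else divides.  A
    2C cell that has already completed its third cycle undergoes a stomatal
    division with probability ``p_s`` while rounds remain, else terminates.

    Exactly one uniform variate is consumed per call, whatever the outcome
    (part of the seeded-reproducibility contract).
    """
    if cell.phase not in (PATTERNING, ENDOCYCLING):
        raise InvalidStateError(
            f"fate decision on {cell.phase} cell {cell.cell_id}"
        )
    u = float(rng.random())
    if cell.phase == ENDOCYCLING:
        return ENDOCYCLE
    if cell.patterning_cycle >= N_PATTERNING_CYCLES:
        if cell.stomatal_rounds_done < stomatal_max_rounds and u < fate.p_s:
            return STOMATAL_DIVIDE
        return TERMINATE
    p_k = (fate.p1, fate.p2, fate.p3)[cell.patterning_cycle]
    return ENDOCYCLE if u < p_k else DIVIDE


def _sample_split(noise: DivisionNoise, rng: np.random.Generator, noise_free: bool) -> float:
    if noise_free or noise.split_sd == 0:
        return 0.5
    while True:
        s = float(rng.normal(0.5, noise.split_sd))
        if noise.split_min <= s <= noise.split_max:
            return s


def choose_division_plane(
    cell: CellState,
    noise: DivisionNoise,
    rng: np.random.Generator,
    *,
    noise_free: bool = False,
) -> tuple[str, float]:
    """Pick the division plane and split fraction for a dividing cell.

    For each candidate orientation the even-split daughter aspect ratio
    ``r = max(L', W') / min(L', W')`` is evaluated and the orientation
    minimizing ``|log r - log 2|`` wins (daughters closest to 2:1).  Exact
    ties are resolved by one 50/50 RNG draw.  The split fraction ``s`` is
    drawn from Normal(0.5, split_sd) truncated to [split_min, split_max]
    (0.5 exactly in noise-free mode).
    """
    if cell.phase not in (GENERATIVE, PATTERNING):
        raise InvalidStateError(f"cannot divide {cell.phase} cell {cell.cell_id}")
    if cell.length <= 0 or cell.width <= 0:
        raise InvalidStateError(
            f"cell {cell.cell_id} has nonpositive dimensions "
            f"({cell.length} x {cell.width})"
        )

    def _dist(l: float, w: float) -> float:
        r = max(l, w) / min(l, w)
        return abs(math.log(r) - _LOG2)

    d_trans = _dist(cell.length / 2, cell.width)
    d_long = _dist(cell.length, cell.width / 2)
    if abs(d_trans - d_long) < 1e-12:
        orientation = TRANSVERSE if rng.random() < 0.5 else LONGITUDINAL
    else:
        orientation = TRANSVERSE if d_trans < d_long else LONGITUDINAL
    s = _sample_split(noise, rng, noise_free)
    return orientation, s


def divide_cell(
    tissue: TissueState, cell: CellState, orientation: str, s: float
) -> tuple[CellState, CellState]:
    """Execute a division, replacing ``cell`` with its two daughters.

    The first daughter is apical and receives a fraction ``s`` of the
    parent's area (transverse divisions split the length, longitudinal the
    width); areas sum exactly to the parent's.  Both daughters are 2C with
    freshly sampled cycle durations (first daughter sampled first).  A
    generative parent yields one apical patterning daughter (a new
    patterning-lineage founder) and one basal generative daughter that
    stays in the parent's column.
    """
    if not (0.0 < s < 1.0):
        raise ValueError(f"split fraction must be in (0, 1), got {s}")
    if cell.phase == TERMINATED or cell.phase == ENDOCYCLING:
        raise InvalidStateError(f"cannot divide {cell.phase} cell {cell.cell_id}")
    if orientation == TRANSVERSE:
        dims1 = (s * cell.length, cell.width)
        dims2 = (cell.length - s * cell.length, cell.width)
    elif orientation == LONGITUDINAL:
        dims1 = (cell.length, s * cell.width)
        dims2 = (cell.length, cell.width - s * cell.width)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    now = tissue.time
    cfg = tissue.config
    stomatal = cell.phase == PATTERNING and cell.patterning_cycle >= N_PATTERNING_CYCLES
    if cell.phase == GENERATIVE:
        pc, rounds = 0, 0
        n_div = 0
    elif stomatal:
        pc, rounds = N_PATTERNING_CYCLES, cell.stomatal_rounds_done + 1
        n_div = cell.n_divisions + 1
    else:
        pc, rounds = cell.patterning_cycle + 1, 0
        n_div = cell.n_divisions + 1

    daughters = []
    for i, (length, width) in enumerate((dims1, dims2)):
        basal_generative = cell.phase == GENERATIVE and i == 1
        daughters.append(
            CellState(
                cell_id=tissue._new_id(),
                parent_id=cell.cell_id,
                birth_time=now,
                area=length * width,
                length=length,
                width=width,
                column=cell.column,
                phase=GENERATIVE if basal_generative else PATTERNING,
                cycle_duration=(
                    cfg.doubling_time
                    if basal_generative
                    else sample_cycle_time(cfg.cycle_dist, tissue.rng)
                ),
                patterning_cycle=0 if basal_generative else pc,
                stomatal_rounds_done=0 if basal_generative else rounds,
                n_divisions=0 if basal_generative else n_div,
            )
        )
    del tissue.cells[cell.cell_id]
    cell.phase = TERMINATED  # parent object no longer part of the tissue
    for d in daughters:
        tissue._add_cell(d)
    tissue.n_nongenerative += 1  # net gain of one non-generative cell
    return daughters[0], daughters[1]


# ---------------------------------------------------------------------------
# Scheduler
# ---------------------------------------------------------------------------


def _terminate(tissue: TissueState, cell: CellState, now: float) -> None:
    cell.phase = TERMINATED
    cell.termination_time = now
    del tissue.cells[cell.cell_id]
    tissue.terminated.append(cell)
    tissue.log.record(now, "termination", cell.cell_id)


def _birth_decision(tissue: TissueState, cell: CellState, now: float) -> None:
    """Stomatal-entry decision for a newborn terminal 2C cell."""
    fate = decide_fate(
        cell, tissue.config.fate, tissue.rng, tissue.config.stomatal_max_rounds
    )
    if fate == STOMATAL_DIVIDE:
        cell.pending_stomatal = True
    else:
        _terminate(tissue, cell, now)


def _complete_cycle(
    tissue: TissueState, cell: CellState, now: float
) -> tuple[CellState, CellState] | None:
    """Handle one cycle completion; returns daughters if a division occurred."""
    cfg = tissue.config
    tissue.time = now
    if cell.phase == GENERATIVE:
        if tissue.stopped:
            # No new generative divisions once the target is reached.
            cell.cycle_duration = math.inf
            return None
        # Generative divisions are exactly even: division noise belongs to
        # the patterning cell cycles, where it was measured.
        d1, d2 = divide_cell(tissue, cell, TRANSVERSE, 0.5)
        tissue.log.record(now, "division", cell.cell_id)
        if tissue.n_nongenerative >= cfg.target_cells:
            tissue.stopped = True
        return d1, d2

    if cell.pending_stomatal:
        orientation, s = choose_division_plane(
            cell, cfg.noise, tissue.rng, noise_free=cfg.noise_free
        )
        d1, d2 = divide_cell(tissue, cell, orientation, s)
        tissue.log.record(now, "stomatal_division", cell.cell_id)
        for d in (d1, d2):
            _birth_decision(tissue, d, now)
        return d1, d2

    fate = decide_fate(cell, cfg.fate, tissue.rng, cfg.stomatal_max_rounds)
    if fate == ENDOCYCLE:
        cell.patterning_cycle += 1
        cell.ploidy = min(cell.ploidy * 2, 16)
        cell.phase = ENDOCYCLING
        tissue.log.record(now, "endocycle", cell.cell_id)
        if cell.patterning_cycle >= N_PATTERNING_CYCLES:
            _terminate(tissue, cell, now)
        else:
            cell.cycle_duration = sample_cycle_time(cfg.cycle_dist, tissue.rng)
            cell.cycle_elapsed = 0.0
        return None
    # fate == DIVIDE (decide_fate never returns stomatal/terminate here:
    # those decisions are made at birth for terminal 2C daughters)
    orientation, s = choose_division_plane(
        cell, cfg.noise, tissue.rng, noise_free=cfg.noise_free
    )
    d1, d2 = divide_cell(tissue, cell, orientation, s)
    tissue.log.record(now, "division", cell.cell_id)
    for d in (d1, d2):
        if d.patterning_cycle >= N_PATTERNING_CYCLES:
            _birth_decision(tissue, d, now)
    return d1, d2


def _advance(tissue: TissueState, cell: CellState, start: float, span: float) -> None:
    """Advance one cell through ``span`` hours, handling cycle completions
    exactly at their scheduled times (growth never overshoots a cycle)."""
    doubling = tissue.config.doubling_time
    elapsed = 0.0
    while cell.phase != TERMINATED:
        rem_step = span - elapsed
        if rem_step <= 1e-12:
            return
        rem_cycle = cell.cycle_duration - cell.cycle_elapsed
        if rem_cycle > rem_step:
            grow_cell(cell, rem_step, doubling)
            return
        grow_cell(cell, rem_cycle, doubling)
        elapsed += rem_cycle
        cell.cycle_elapsed = cell.cycle_duration  # exact, avoids fp drift
        result = _complete_cycle(tissue, cell, start + elapsed)
        if result is not None:
            for d in result:
                if d.phase != TERMINATED:
                    _advance(tissue, d, start + elapsed, span - elapsed)
            return
    return


def step(tissue: TissueState, dt: float) -> TissueState:
    """Advance the whole tissue by one fixed scheduler step of ``dt`` hours.

    Cells are processed in ascending ``cell_id``; each is grown and any
    cycle completions inside the step are executed at their exact times
    (daughters created mid-step are advanced through the remainder of the
    step immediately, preserving synchrony).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t0 = tissue.time
    for cell in list(tissue.cells.values()):
        if cell.phase != TERMINATED:
            _advance(tissue, cell, t0, dt)
    tissue.time = t0 + dt
    tissue.log.total_time_h = tissue.time
    if not tissue.stopped and tissue.n_nongenerative >= tissue.config.target_cells:
        tissue.stopped = True
    return tissue


def cell_table(tissue: TissueState) -> pd.DataFrame:
    """Terminal cell table: one record per terminated non-generative cell."""
    rows = sorted(tissue.terminated, key=lambda c: c.cell_id)
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in rows],
            "parent_id": [c.parent_id for c in rows],
            "birth_time_h": [c.birth_time for c in rows],
            "termination_time_h": [c.termination_time for c in rows],
            "ploidy_c": [c.ploidy for c in rows],
            "area": [c.area for c in rows],
            "length": [c.length for c in rows],
            "width": [c.width for c in rows],
            "column": [c.column for c in rows],
            "n_divisions": [c.n_divisions for c in rows],
            "stomatal": [int(c.stomatal_rounds_done > 0) for c in rows],
        },
        columns=CELL_TABLE_COLUMNS,
    )


def run_simulation(
    config: SimulationConfig, *, collect_events: bool = False
) -> tuple[pd.DataFrame, RunLog]:
    """Run one full simulation to completion.

    Steps the tissue until the number of non-generative cells reaches
    ``target_cells``, then lets all in-progress cells run to termination
    with no further generative divisions.  Returns the terminal cell table
    and the run log.
    """
    tissue = TissueState(config, collect_events=collect_events)
    # Generous safety cap: enough generative cycles to mint target_cells
    # founders even if every founder yields a single terminal cell.
    cap_hours = (
        (config.target_cells / config.generative_width + 20)
        * max(config.cycle_dist.mean, 1.0)
        * 4.0
        + 1000.0
    )
    while True:
        step(tissue, config.dt_hours)
        if tissue.stopped and tissue.alive_nongenerative == 0:
            break
        if tissue.time > cap_hours:
            raise RuntimeLimitError(
                f"simulation exceeded {cap_hours:.0f} h without terminating"
            )
    return cell_table(tissue), tissue.log
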