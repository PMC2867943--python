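"""Summary statistics for simulated cell tables and tracked-lineage tables.

Two kinds of input are handled here:

* the terminal *cell table* written by the simulator (one row per
  terminated cell), summarized into ploidy fractions, per-ploidy area
  statistics and a distinct-size count; and
* long-format *lineage tables* emulating tracked live-imaging data (one row
  per cell per 6-h timepoint), from which cell-cycle durations and
  daughter-division asymmetry are measured.  A seeded synthetic generator
  produces such tables for testing the measurement utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .config import CycleTimeDistribution, DivisionNoise
from .engine import CellState, PATTERNING, choose_division_plane, sample_cycle_time
from .errors import ConfigError, SepalSimError

LINEAGE_COLUMNS = ["cell_id", "parent_id", "time_h", "area", "fate"]


# ---------------------------------------------------------------------------
# Cell-table summaries
# ---------------------------------------------------------------------------


def count_distinct_areas(areas: np.ndarray, rel_tol: float = 1e-6) -> int:
    """Number of area clusters under a relative gap tolerance.

    Sorted areas are split into clusters wherever the relative gap between
    consecutive values exceeds ``rel_tol``; intended for noise-free runs
    where terminal areas are exactly discrete up to float rounding.
    """
    a = np.sort(np.asarray(areas, dtype=float))
    if a.size == 0:
        return 0
    gaps = np.diff(a) / a[:-1]
    return int(1 + np.sum(gaps > rel_tol))


def summarize_cell_table(
    table: pd.DataFrame, *, count_distinct: bool = False, rel_tol: float = 1e-6
) -> dict:
    """Summarize a terminal cell table.

    Returns ploidy fractions, per-ploidy area mean/SD/CV, the giant-cell
    (16C) count, and — when ``count_distinct`` is set, meaningful for
    noise-free runs only — the number of distinct terminal areas among
    non-stomatal cells.
    """
    if table is None or len(table) == 0:
        raise SepalSimError("cannot summarize an empty cell table")
    n = len(table)
    summary: dict = {"n_cells": int(n), "mean_area": float(table["area"].mean())}
    counts = table["ploidy_c"].value_counts().to_dict()
    summary["counts"] = {int(p): int(counts.get(p, 0)) for p in (2, 4, 8, 16)}
    summary["fractions"] = {p: c / n for p, c in summary["counts"].items()}
    per_ploidy = {}
    for p, grp in table.groupby("ploidy_c"):
        mean = float(grp["area"].mean())
        sd = float(grp["area"].std(ddof=0)) if len(grp) > 1 else 0.0
        per_ploidy[int(p)] = {"mean": mean, "sd": sd, "cv": sd / mean if mean else 0.0,
                              "n": int(len(grp))}
    summary["area_by_ploidy"] = per_ploidy
    summary["giant_cells"] = summary["counts"][16]
    if count_distinct:
        mask = (
            table["stomatal"] == 0 if "stomatal" in table.columns else slice(None)
        )
        summary["distinct_sizes"] = count_distinct_areas(
            table.loc[mask, "area"].to_numpy(), rel_tol
        )
    return summary


def compare_area_distributions(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test on log2 cell areas.

    Returns ``(D, p)``; symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SepalSimError("area samples must be nonempty")
    res = ks_2samp(np.log2(a), np.log2(b))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Lineage-table measurements
# ---------------------------------------------------------------------------


def _per_cell(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(LINEAGE_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigError(f"lineage table missing column(s): {sorted(missing)}")
    ids = set(table["cell_id"])
    bad = table[
        table["parent_id"].notna() & ~table["parent_id"].isin(ids)
    ]
    if len(bad):
        row = bad.iloc[0]
        raise SepalSimError(
            f"malformed parentage: cell {row['cell_id']} references missing "
            f"parent {row['parent_id']}"
        )
    grp = table.sort_values("time_h").groupby("cell_id", sort=True)
    per = pd.DataFrame(
        {
            "parent_id": grp["parent_id"].first(),
            "fate": grp["fate"].first(),
            "first_time": grp["time_h"].min(),
            "last_time": grp["time_h"].max(),
            "first_area": grp["area"].first(),
        }
    )
    return per


def cycle_times_from_lineage(
    table: pd.DataFrame,
    bin_hours: float = 6.0,
    max_first_time_h: float | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Cell-cycle durations and their histogram from a tracked-lineage table.

    For every cell that divided, the duration is estimated from its
    observation span on the sampling grid (``last - first + bin_hours``,
    unbiased for birth times uniform over the grid phase).  Cells that never
    divided within the window (censored or endoreduplicating) contribute no
    duration.  Because cells born close to the window end are observed only
    if their cycle was short, durations are length-biased near the end of
    the recording; ``max_first_time_h`` restricts the estimate to cells
    first observed early enough (several mean cycles before the window
    closes) to suppress that censoring bias.  Returns
    ``(durations, (bin_edges, counts))`` with ``bin_hours``-wide bins.
    """
    per = _per_cell(table)
    divided = per[per["fate"] == "divided"]
    if max_first_time_h is not None:
        divided = divided[divided["first_time"] <= max_first_time_h]
    durations = (divided["last_time"] - divided["first_time"] + bin_hours).to_numpy()
    if durations.size:
        top = bin_hours * math.ceil(durations.max() / bin_hours + 1e-9)
        edges = np.arange(0.0, top + bin_hours, bin_hours)
    else:
        edges = np.array([0.0, bin_hours])
    counts, _ = np.histogram(durations, bins=edges)
    return durations, (edges, counts)


def daughter_asymmetry(table: pd.DataFrame) -> float:
    """SD of the relative daughter-area deviation over tracked divisions.

    For each division the deviation is ``2 a1 / (a1 + a2) - 1`` computed
    from the daughters' first observed areas (both daughters are first seen
    at the same timepoint, so equal growth cancels); the reported value is
    the standard deviation of this quantity over all complete divisions.
    """
    per = _per_cell(table)
    children = per[per["parent_id"].notna()]
    devs = []
    for parent, grp in children.groupby("parent_id"):
        if len(grp) != 2:
            continue
        grp = grp.sort_index()
        a1, a2 = grp["first_area"].iloc[0], grp["first_area"].iloc[1]
        devs.append(2 * a1 / (a1 + a2) - 1)
    if not devs:
        raise SepalSimError("no divisions with both daughters observed")
    return float(np.std(devs, ddof=1)) if len(devs) > 1 else 0.0


# ---------------------------------------------------------------------------
# Synthetic lineage fixture
# ---------------------------------------------------------------------------


def generate_lineage_fixture(
    cycle_dist: CycleTimeDistribution | None = None,
    split_sd: float = 0.05,
    duration_hours: float = 72.0,
    sampling_interval_h: float = 6.0,
    seed: int = 0,
    n_initial: int = 6,
    endo_prob: float = 0.0,
    doubling_time_hours: float | None = None,
    initial_area: float = 100.0,
) -> pd.DataFrame:
    """Simulate a tracked-lineage table emulating live-imaging output.

    ``n_initial`` progenitor cells grow exponentially (one area doubling
    per ``doubling_time_hours``, default the mean cycle time) and divide at
    sampled cycle times with split fraction Normal(0.5, ``split_sd``)
    truncated to [0.3, 0.7].  With probability ``endo_prob`` a cell is
    endoreduplicating and never divides.  Areas are recorded on a fixed
    ``sampling_interval_h`` grid; cells alive at the window end are
    censored.  Seeded and reproducible.
    """
    if cycle_dist is None:
        cycle_dist = CycleTimeDistribution()
    if duration_hours < 0:
        raise ConfigError("duration_hours must be nonnegative")
    if sampling_interval_h <= 0:
        raise ConfigError("sampling_interval_h must be positive")
    noise = DivisionNoise(split_sd=split_sd)
    doubling = (
        doubling_time_hours if doubling_time_hours is not None else cycle_dist.mean
    )
    rng = np.random.default_rng(seed)
    h = sampling_interval_h

    rows: list[tuple[int, float | None, float, float, str]] = []
    next_id = [0]

    def _emit(cell_id, parent_id, birth, birth_area, death, fate):
        """Record one cell's grid observations; death==None means censored."""
        t = math.ceil(birth / h - 1e-9) * h
        end = duration_hours if death is None else death
        while (death is None and t <= end + 1e-9) or (death is not None and t < end - 1e-9):
            area = birth_area * 2 ** ((t - birth) / doubling)
            rows.append((cell_id, parent_id, t, area, fate))
            t += h

    def _cell(parent_id, birth, area):
        cid = next_id[0]
        next_id[0] += 1
        if endo_prob > 0 and rng.random() < endo_prob:
            _emit(cid, parent_id, birth, area, None, "endoreduplicating")
            return
        # Tracking at interval h cannot resolve cycles shorter than h; clip
        # so every divided cell is observed at least once (affects <0.02%
        # of draws at the default distribution).
        cycle = max(sample_cycle_time(cycle_dist, rng), h + 1e-3)
        death = birth + cycle
        # Daughters must be observable at least once inside the window,
        # otherwise the division is treated as censored.
        if death >= duration_hours or math.ceil(death / h - 1e-9) * h > duration_hours + 1e-9:
            _emit(cid, parent_id, birth, area, None, "censored")
            return
        _emit(cid, parent_id, birth, area, death, "divided")
        area_at_div = area * 2 ** (cycle / doubling)
        if split_sd > 0:
            while True:
                s = float(rng.normal(0.5, split_sd))
                if noise.split_min <= s <= noise.split_max:
                    break
        else:
            s = 0.5
        _cell(cid, death, s * area_at_div)
        _cell(cid, death, (1 - s) * area_at_div)

    for _ in range(n_initial):
        area0 = float(initial_area * rng.lognormal(0.0, 0.3))
        _cell(None, 0.0, area0)

    df = pd.DataFrame(rows, columns=LINEAGE_COLUMNS)
    df["parent_id"] = df["parent_id"].astype("Int64")
    return df.sort_values(["cell_id", "time_h"], ignore_index=True)


def simulate_division_asymmetry(
    noise: DivisionNoise | None = None, n_divisions: int = 10_000, seed: int = 0
) -> float:
    """SD of the relative daughter-area deviation over simulated divisions.

    Runs ``n_divisions`` independent divisions through the engine's plane
    choice and split machinery on a reference cell and measures
    ``2 a1 / (a1 + a2) - 1`` from the daughter areas.
    """
    if noise is None:
        noise = DivisionNoise()
    rng = np.random.default_rng(seed)
    devs = np.empty(n_divisions)
    for i in range(n_divisions):
        cell = CellState(
            cell_id=0,
            parent_id=None,
            birth_time=0.0,
            area=100.0,
            length=20.0,
            width=5.0,
            column=0,
            phase=PATTERNING,
            cycle_duration=24.0,
        )
        _, s = choose_division_plane(cell, noise, rng)
        a1, a2 = s * cell.area, (1 - s) * cell.area
        devs[i] = 2 * a1 / (a1 + a2) - 1
    return float(np.std(devs, ddof=1))
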