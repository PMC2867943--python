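"""Reading and writing the package's file formats.

Cell tables and event logs are CSV with a single ``#``-prefixed metadata
line embedding the seed and config hash; summaries and fit reports are
JSON carrying the full config so a run can be reproduced from its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import SimulationConfig
from .engine import RunLog
from .errors import ConfigError


def write_cell_table(
    table: pd.DataFrame, path: str | Path, config: SimulationConfig
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sepalsim cell table seed={config.seed} config_hash={config.config_hash()}\n")
        table.to_csv(fh, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"ploidy_c", "area"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"cell table missing column(s): {sorted(missing)}")
    return df


def write_event_log(log: RunLog, path: str | Path, config: SimulationConfig) -> None:
    if log.events is None:
        raise ConfigError("run was executed without event collection")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sepalsim event log seed={config.seed} config_hash={config.config_hash()}\n")
        fh.write("time_h,event,cell_id\n")
        for t, event, cid in log.events:
            fh.write(f"{t!r},{event},{cid}\n")


def run_summary(table: pd.DataFrame, log: RunLog, config: SimulationConfig) -> dict:
    from .lineage import summarize_cell_table

    summary = summarize_cell_table(table, count_distinct=config.noise_free)
    summary.update(
        {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "total_time_h": log.total_time_h,
            "events": dict(log.counts),
        }
    )
    return summary


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
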