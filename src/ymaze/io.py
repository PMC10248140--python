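"""Readers, writers, and run manifests for the pipeline's file formats.

Tabular data is CSV (UTF-8, header row, comma-separated): trajectories as
``fly_id,t_s,x_mm,y_mm``, turn tables as ``fly_id,predator,drug,t_s,turn``
with turn in {L,R}, survival tables as
``jar_id,predator,drug,n_initial,n_survived``. Reports are JSON. Factor
levels are lowercase tokens: predator in {yes,no}, drug in
{none,5htp,amw}. Every stochastic output carries the seed that produced it
in a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .turns import (
    DRUG_LEVELS,
    PREDATOR_LEVELS,
    FlyRecord,
    Trajectory,
    TurnSequence,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every command's outputs."""

    tool: str
    version: str
    seed: int | None
    config_hash: str | None
    inputs: list[str]
    outputs: list[str]
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def hash_config(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_trajectories(path) -> list[Trajectory]:
    """Load per-fly trajectories from CSV, grouped by fly and time-sorted.

    Out-of-order timestamps are sorted with a warning; duplicate timestamps
    within one fly are an error (reported with the fly id and row numbers).
    """
    df = pd.read_csv(path)
    _require_columns(df, ["fly_id", "t_s", "x_mm", "y_mm"], path)
    for col in ("t_s", "x_mm", "y_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col!r} at row(s) {list(bad[:5])}")
        df[col] = vals
    out = []
    for fly_id, g in df.groupby("fly_id", sort=True):
        if not g["t_s"].is_monotonic_increasing:
            logger.warning("%s: timestamps out of order for %s; sorting", path, fly_id)
            g = g.sort_values("t_s")
        dup = g.index[g["t_s"].duplicated()]
        if len(dup):
            raise ValueError(
                f"{path}: duplicate timestamps for fly {fly_id} at row(s) {list(dup[:5])}"
            )
        out.append(
            Trajectory(
                fly_id=str(fly_id),
                t=g["t_s"].to_numpy(),
                x=g["x_mm"].to_numpy(),
                y=g["y_mm"].to_numpy(),
            )
        )
    return out


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    pd.concat([tr.to_frame() for tr in trajectories], ignore_index=True).to_csv(
        path, index=False
    )


def read_turn_table(path, duration_min: float | None = None) -> pd.DataFrame:
    """Load a per-event turn table, validating factor levels and turn codes."""
    df = pd.read_csv(path)
    _require_columns(df, ["fly_id", "predator", "drug", "t_s", "turn"], path)
    if len(df) == 0:
        return df
    bad_turn = ~df["turn"].isin(["L", "R"])
    if bad_turn.any():
        raise ValueError(
            f"{path}: turn values outside {{L,R}} at row(s) "
            f"{list(df.index[bad_turn][:5])}"
        )
    for col, levels in (("predator", PREDATOR_LEVELS), ("drug", DRUG_LEVELS)):
        bad = ~df[col].isin(levels)
        if bad.any():
            raise ValueError(
                f"{path}: unknown {col} level(s) {sorted(df.loc[bad, col].unique())}; "
                f"admissible values are {list(levels)}"
            )
    return df


def write_turn_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=["fly_id", "predator", "drug", "t_s", "turn"])


def turn_table_to_records(
    table: pd.DataFrame,
    duration_min: float,
    min_turns: int = 30,
) -> list[FlyRecord]:
    """Per-fly records (bias, rate, inclusion flag) from a turn event table."""
    from .turns import make_fly_record

    records = []
    for fly_id, g in table.groupby("fly_id", sort=True):
        seq = TurnSequence(
            times=g["t_s"].to_numpy(),
            directions=g["turn"].to_numpy(),
            duration_min=duration_min,
        )
        records.append(
            make_fly_record(
                str(fly_id),
                str(g["predator"].iloc[0]),
                str(g["drug"].iloc[0]),
                seq,
                min_turns=min_turns,
            )
        )
    return records


def read_survival_table(path) -> pd.DataFrame:
    from .survival import validate_survival_table

    df = pd.read_csv(path)
    return validate_survival_table(df)


def write_survival_table(df: pd.DataFrame, path) -> None:
    df.to_csv(
        path, index=False,
        columns=["jar_id", "predator", "drug", "n_initial", "n_survived"],
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_report(report: dict, path) -> None:
    """Serialise an analysis report (dataclasses and numpy included) to JSON."""
    Path(path).write_text(json.dumps(report, indent=2, cls=_NumpyEncoder))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
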