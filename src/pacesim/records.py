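"""Trial records and their on-disk representation.

A :class:`TrialRecord` is the complete log of one closed-loop pacing trial:
a per-control-step table (volumes, stimulation amplitudes, charge, fatigue
states, flags), a per-cycle summary table, and a metadata mapping (mode,
seed, baseline calibration, config hash).  Records are written as a pair of
CSV files plus a JSON sidecar; floats are formatted with ``%.9g`` so a
rewritten record is byte-identical and a read-back record equals the
original to that precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.9g"

STEP_COLUMNS = [
    "time_s",
    "cycle_index",
    "phase",
    "V_desired",
    "V_true",
    "V_measured",
    "cpg_phase",
    "u_preclip",
    "I_dia_mA",
    "I_eic_mA",
    "q_dia_mC",
    "q_eic_mC",
    "F_dia",
    "F_eic",
    "sigh_flag",
    "learning_flag",
]

CYCLE_COLUMNS = [
    "cycle_index",
    "irmse_pct",
    "charge_dia_mC",
    "charge_eic_mC",
    "tidal_volume_ml",
    "is_sigh",
    "learning_paused",
    "onset_phase_error",
]

__all__ = ["TrialRecord", "SchemaError", "write_trial", "read_trial", "STEP_COLUMNS", "CYCLE_COLUMNS"]


class SchemaError(ValueError):
    """A trial file is missing a required column."""


@dataclass
class TrialRecord:
    """Per-step and per-cycle time series of one trial, plus metadata."""

    steps: pd.DataFrame
    cycles: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in STEP_COLUMNS:
            if col not in self.steps.columns:
                raise SchemaError(f"step table missing column {col!r}")
        for col in CYCLE_COLUMNS:
            if col not in self.cycles.columns:
                raise SchemaError(f"cycle table missing column {col!r}")


def _check_columns(df: pd.DataFrame, required, what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table at {path} missing column {missing[0]!r}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(
            f"{what} table at {path} has unrecognized columns {extra}; "
            "accepted for forward compatibility",
            stacklevel=3,
        )


def write_trial(record: TrialRecord, path) -> Path:
    """Write a trial as ``<stem>_steps.csv``, ``<stem>_cycles.csv`` and
    ``<stem>_meta.json``; returns the stem path."""
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    try:
        record.steps.to_csv(f"{stem}_steps.csv", index=False, float_format=FLOAT_FORMAT)
        record.cycles.to_csv(f"{stem}_cycles.csv", index=False, float_format=FLOAT_FORMAT)
        with open(f"{stem}_meta.json", "w") as fh:
            json.dump(record.meta, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"failed writing trial record at {stem}: {exc}") from exc
    return stem


def read_trial(path) -> TrialRecord:
    """Read a trial written by :func:`write_trial`.

    Missing required columns raise :class:`SchemaError` naming the column;
    files from newer writers with extra columns are accepted with a warning.
    """
    stem = Path(path)
    try:
        steps = pd.read_csv(f"{stem}_steps.csv")
        cycles = pd.read_csv(f"{stem}_cycles.csv")
        with open(f"{stem}_meta.json") as fh:
            meta = json.load(fh)
    except OSError as exc:
        raise OSError(f"failed reading trial record at {stem}: {exc}") from exc
    _check_columns(steps, STEP_COLUMNS, "step", stem)
    _check_columns(cycles, CYCLE_COLUMNS, "cycle", stem)
    for col in ("sigh_flag", "learning_flag"):
        steps[col] = steps[col].astype(bool)
    for col in ("is_sigh", "learning_paused"):
        cycles[col] = cycles[col].astype(bool)
    return TrialRecord(steps=steps, cycles=cycles, meta=meta)
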