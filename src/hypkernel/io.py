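"""Trial-table dialect, validation, and provenance records.

Trial tables travel as UTF-8 CSV with a header row.  Required columns:
``participant_id``, ``culture``, ``stimulus_key``, ``face_id``,
``response``; AU amplitudes live in columns named ``AU01`` … ``AU43``
with L/R suffixes where lateralized (e.g. ``AU12L``), as decimals in
[0, 1].  Unknown columns are preserved but ignored; a missing AU column
means amplitude 0 everywhere (logged once).  ``response`` holds a task
category label or the task's "other" label; "other" rows carry no
category hypothesis and are excluded on read, with the count reported.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .au_space import AU_COLUMNS
from .models import other_label, task_categories
from .noise_ceiling import assign_keys

__all__ = ["TrialTable", "read_trials", "write_trials", "provenance_record"]

logger = logging.getLogger("hypkernel")

REQUIRED_COLUMNS = ("participant_id", "culture", "stimulus_key", "face_id", "response")


@dataclass
class TrialTable:
    """A validated trial table with its preprocessing bookkeeping."""

    frame: pd.DataFrame
    task: str
    excluded_other: int = 0

    def __len__(self) -> int:
        return len(self.frame)


def _validate_amplitudes(df: pd.DataFrame, path: str) -> None:
    present = [c for c in AU_COLUMNS if c in df.columns]
    missing = [c for c in AU_COLUMNS if c not in df.columns]
    if missing:
        logger.info(
            "%s: %d AU columns absent (treated as amplitude 0): %s",
            path, len(missing), ", ".join(missing[:5]) + ("…" if len(missing) > 5 else ""),
        )
    for col in present:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals > 1)
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header + 1-based
            raise ValueError(
                f"{path}: amplitude outside [0, 1] (or non-numeric) in column "
                f"{col}, line {row}"
            )
        df[col] = vals


def read_trials(path: str | Path, task: str = "basic6") -> TrialTable:
    """Read, validate and preprocess a trial-table CSV.

    Responses are checked against the task's category vocabulary; rows
    labeled with the task's "other" option are excluded (no hypothesis
    covers them) and counted.  A missing ``stimulus_key`` column is
    recomputed from the AU amplitudes.
    """
    path = Path(path)
    cats = set(task_categories(task))
    other = other_label(task)
    df = pd.read_csv(path, dtype={"participant_id": str, "culture": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            if col == "stimulus_key":
                continue
            raise ValueError(f"{path}: missing required column {col!r}")
    _validate_amplitudes(df, str(path))
    unknown = set(df["response"].unique()) - cats - {other}
    if unknown:
        raise ValueError(
            f"{path}: responses outside the {task!r} vocabulary: {sorted(unknown)}"
        )
    if "stimulus_key" not in df.columns:
        df["stimulus_key"] = assign_keys(df)
    n_other = int((df["response"] == other).sum())
    kept = df.loc[df["response"] != other].reset_index(drop=True)
    if n_other:
        logger.info("%s: excluded %d %r trials of %d", path, n_other, other, len(df))
    return TrialTable(frame=kept, task=task, excluded_other=n_other)


def write_trials(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table in the canonical CSV dialect."""
    frame.to_csv(path, index=False)


def _file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance_record(
    parameters: Mapping,
    inputs: Mapping[str, str | Path] | None = None,
    seed: int | None = None,
) -> dict:
    """Machine-readable record of a run: versions, seed, parameters, hashes."""
    from . import __version__

    return {
        "hypkernel_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "parameters": {k: _jsonable(v) for k, v in parameters.items()},
        "input_hashes": {
            name: _file_sha256(p) for name, p in (inputs or {}).items()
        },
    }


def _jsonable(v):
    try:
        json.dumps(v)
        return v
    except TypeError:
        return str(v)
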