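"""Trial-log CSV persistence, the phase grid, and YAML configs.

Trial logs are plain CSV (RFC-4180, UTF-8, '.' decimal) with the header
``trial_index,method,level_index,level_value,response,seed``.  The
``method`` and ``seed`` columns carry session metadata repeated on every
row so a log is self-describing.  Level values are written with ``repr``
so floats round-trip bit-exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from .core import RESPONSES, LevelGrid, TrialRecord
from .fitting import ValidityRule
from .harness import HarnessConfig

__all__ = [
    "TRIAL_LOG_HEADER",
    "TrialLog",
    "write_trials",
    "read_trials",
    "read_trial_log",
    "default_phase_grid",
    "load_config",
    "dump_config",
]

TRIAL_LOG_HEADER = ("trial_index", "method", "level_index", "level_value", "response", "seed")

# Interocular phase shifts (degrees) of the 15-level Pulfrich task grid,
# sign-symmetric about zero, displayed as labels -7..7.
_PHASE_VALUES = (
    -1.5, -0.75, -0.375, -0.1875, -0.0938, -0.0469, -0.0234,
    0.0, 0.0234, 0.0469, 0.0938, 0.1875, 0.375, 0.75, 1.5,
)


def default_phase_grid() -> LevelGrid:
    """The 15 interocular phase-shift levels in degrees, labelled -7..7."""
    return LevelGrid(_PHASE_VALUES, labels=range(-7, 8))


@dataclass(frozen=True)
class TrialLog:
    """Trial records plus session metadata read back from a CSV log."""

    records: tuple[TrialRecord, ...]
    method: str | None
    seed: int | None


def write_trials(
    records: Sequence[TrialRecord],
    path,
    method: str | None = None,
    seed: int | None = None,
) -> None:
    """Write a trial log as CSV; an empty record list yields a header-only file."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_LOG_HEADER)
        m = "" if method is None else method
        s = "" if seed is None else str(int(seed))
        for r in records:
            writer.writerow(
                [r.trial_index, m, r.level_index, repr(float(r.level_value)), r.response, s]
            )


def read_trial_log(path) -> TrialLog:
    """Parse a trial-log CSV; malformed rows raise with their line number."""
    records: list[TrialRecord] = []
    method: str | None = None
    seed: int | None = None
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header {','.join(TRIAL_LOG_HEADER)}")
        if tuple(header) != TRIAL_LOG_HEADER:
            raise ValueError(
                f"{path}: line 1: bad header {header!r}, expected {list(TRIAL_LOG_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(TRIAL_LOG_HEADER):
                raise ValueError(f"{path}: line {lineno}: expected {len(TRIAL_LOG_HEADER)} fields, got {len(row)}")
            try:
                trial_index = int(row[0])
                level_index = int(row[2])
                level_value = float(row[3])
            except ValueError as e:
                raise ValueError(f"{path}: line {lineno}: {e}") from None
            if row[4] not in RESPONSES:
                raise ValueError(
                    f"{path}: line {lineno}: unknown response {row[4]!r}, expected one of {RESPONSES}"
                )
            if row[1]:
                method = row[1]
            if row[5]:
                seed = int(row[5])
            records.append(TrialRecord(trial_index, level_index, level_value, row[4]))
    return TrialLog(tuple(records), method, seed)


def read_trials(path) -> list[TrialRecord]:
    """Trial records only (see ``read_trial_log`` for the metadata)."""
    return list(read_trial_log(path).records)


def dump_config(config: HarnessConfig, path) -> None:
    """Write a harness config as YAML (grid normalized to explicit values)."""
    doc = {
        "grid": {
            "values": [float(v) for v in config.grid.values],
            "labels": None if config.grid.labels is None else list(config.grid.labels),
        },
        "pivot": float(config.pivot),
        "sigmas": [float(s) for s in config.sigmas],
        "methods": list(config.methods),
        "n_trials": int(config.n_trials),
        "repetitions": int(config.repetitions),
        "n_boot": int(config.n_boot),
        "seed": int(config.seed),
        "lapse_rate": float(config.lapse_rate),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path, **overrides) -> HarnessConfig:
    """Load a YAML harness config; keyword overrides win over file values."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {}
    grid_spec = doc.get("grid")
    if grid_spec is not None:
        if isinstance(grid_spec, str):
            if grid_spec != "phase":
                raise ValueError(f"{path}: unknown named grid {grid_spec!r}")
            kwargs["grid"] = default_phase_grid()
        else:
            kwargs["grid"] = LevelGrid(grid_spec["values"], grid_spec.get("labels"))
    for key in ("pivot", "lapse_rate"):
        if key in doc:
            kwargs[key] = float(doc[key])
    if "sigmas" in doc:
        kwargs["sigmas"] = tuple(float(s) for s in doc["sigmas"])
    if "methods" in doc:
        kwargs["methods"] = tuple(doc["methods"])
    for key in ("n_trials", "repetitions", "n_boot", "seed"):
        if key in doc:
            kwargs[key] = int(doc[key])
    kwargs.update(overrides)
    return HarnessConfig(**kwargs)
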