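"""CSV/JSON readers and writers with schema validation.

Column schemas (units fixed repository-wide: ms for MT, cm for space,
trials for t and tau):

* trials:       subject, group, global_trial, t, target, mt_ms
* params:       subject, group, A, tau, C, D1..D5
* test phases:  subject, group, mt_pre1_ms, mt_1month_ms, long_term_change
* trajectories: t_s, x_cm, y_cm (one file per trial)
* targets:      target, x_cm, y_cm, diameter_cm

Unknown extra columns are preserved on read; missing required columns and
malformed rows are rejected with names/row numbers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

TRIALS_COLUMNS = ("subject", "group", "global_trial", "t", "target", "mt_ms")
PARAMS_COLUMNS = ("subject", "group", "A", "tau", "C", "D1", "D2", "D3", "D4", "D5")
PHASES_COLUMNS = ("subject", "group", "mt_pre1_ms", "mt_1month_ms", "long_term_change")


class SchemaError(ValueError):
    pass


def _check_columns(frame: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table missing column(s): {missing}")


def _check_numeric(frame: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    for c in cols:
        vals = pd.to_numeric(frame[c], errors="coerce")
        bad = frame.index[vals.isna()].tolist()
        if bad:
            raise SchemaError(f"{what} table: non-numeric {c!r} at rows {bad[:5]}")
        frame[c] = vals


def read_trials(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, TRIALS_COLUMNS, "trials")
    _check_numeric(frame, ("global_trial", "t", "target", "mt_ms"), "trials")
    bad = frame.index[frame["mt_ms"] <= 0].tolist()
    if bad:
        raise SchemaError(f"trials table: non-positive mt_ms at rows {bad[:5]}")
    return frame


def write_trials(frame: pd.DataFrame, path: str | Path) -> Path:
    _check_columns(frame, TRIALS_COLUMNS, "trials")
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_params(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, PARAMS_COLUMNS, "params")
    _check_numeric(frame, PARAMS_COLUMNS[2:], "params")
    bad = frame.index[frame["tau"] <= 0].tolist()
    if bad:
        raise SchemaError(f"params table: non-positive tau at rows {bad[:5]}")
    return frame


def write_params(frame: pd.DataFrame, path: str | Path) -> Path:
    _check_columns(frame, PARAMS_COLUMNS, "params")
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_test_phases(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, PHASES_COLUMNS, "test-phase")
    _check_numeric(frame, PHASES_COLUMNS[2:], "test-phase")
    return frame


def write_test_phases(frame: pd.DataFrame, path: str | Path) -> Path:
    _check_columns(frame, PHASES_COLUMNS, "test-phase")
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, ("t_s", "x_cm", "y_cm"), "trajectory")
    return frame


def write_trajectory(frame: pd.DataFrame, path: str | Path) -> Path:
    _check_columns(frame, ("t_s", "x_cm", "y_cm"), "trajectory")
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_targets(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, ("target", "x_cm", "y_cm", "diameter_cm"), "targets")
    return frame


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
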