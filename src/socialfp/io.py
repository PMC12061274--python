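"""File dialects: events table, photometry trace, metadata, manifest.

Everything is plain UTF-8 comma-separated text with "." decimals; floats
are written with 17 significant digits so that write -> read round-trips
bit-exactly.  Times are seconds on a 0-based session clock, intervals
half-open.

Events table columns::

    animal_id, session_id, task, condition, stimulus, start_s, end_s

Photometry trace columns::

    t_s, f465, f405

Conditions combine a satiety state and a light state as
``<satiety|deprived>+<none|light_on|light_off>``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import STIMULI, ContactIntervals
from .photometry import PhotometryTrace

__all__ = [
    "read_events_table",
    "write_events_table",
    "read_photometry",
    "write_photometry",
    "write_manifest",
    "read_manifest",
    "CONDITIONS",
    "FLOAT_FMT",
]

FLOAT_FMT = "%.17g"

CONDITIONS = tuple(
    f"{s}+{l}" for s in ("satiety", "deprived") for l in ("none", "light_on", "light_off")
)

EVENT_COLS = ["animal_id", "session_id", "task", "condition", "stimulus", "start_s", "end_s"]


class LoadError(ValueError):
    pass


def write_events_table(path, rows: pd.DataFrame) -> None:
    rows = rows[EVENT_COLS]
    rows.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_events_table(path) -> dict[tuple, dict[str, ContactIntervals]]:
    """Load an events table into per-session ContactIntervals.

    Returns a mapping from session key ``(animal_id, session_id, task,
    condition)`` to ``{stimulus: ContactIntervals}``.  Invariants are
    enforced on load; violations name the offending row.
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "session_id": str})
    missing = set(EVENT_COLS) - set(df.columns)
    if missing:
        raise LoadError(f"{path}: missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        if row["stimulus"] not in STIMULI:
            raise LoadError(f"{path} row {i}: unknown stimulus {row['stimulus']!r}")
        if row["condition"] not in CONDITIONS:
            raise LoadError(f"{path} row {i}: unknown condition {row['condition']!r}")
        if not row["end_s"] > row["start_s"]:
            raise LoadError(f"{path} row {i}: end_s <= start_s")
        if row["start_s"] < 0:
            raise LoadError(f"{path} row {i}: negative start_s")
    out: dict[tuple, dict[str, ContactIntervals]] = {}
    keys = ["animal_id", "session_id", "task", "condition"]
    for key, grp in df.groupby(keys, sort=True):
        per_stim = {}
        for stim, g in grp.groupby("stimulus", sort=True):
            iv = g[["start_s", "end_s"]].to_numpy(dtype=float)
            iv = iv[np.argsort(iv[:, 0], kind="stable")]
            try:
                per_stim[stim] = ContactIntervals(stim, iv)
            except ValueError as e:
                raise LoadError(f"{path} session {key}: {e}") from e
        out[tuple(key)] = per_stim
    return out


def write_photometry(path, t, s465, s405) -> None:
    df = pd.DataFrame({"t_s": t, "f465": s465, "f405": s405})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_photometry(path, max_gap_s: float = 1.0) -> PhotometryTrace:
    """Load a photometry trace, inferring fs from the median sample interval.

    Non-monotone or non-uniform time stamps are rejected.  NaN runs longer
    than ``max_gap_s`` are fatal; shorter gaps are linearly interpolated
    and logged.
    """
    df = pd.read_csv(path)
    missing = {"t_s", "f465", "f405"} - set(df.columns)
    if missing:
        raise LoadError(f"{path}: missing columns {sorted(missing)}")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise LoadError(f"{path}: too few samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise LoadError(f"{path}: time column not strictly increasing")
    med = float(np.median(dt))
    fs = 1.0 / med
    if np.max(np.abs(dt - med)) > 1e-6 * med:
        raise LoadError(f"{path}: non-uniform sampling beyond tolerance")
    chans = {}
    for col in ("f465", "f405"):
        y = df[col].to_numpy(dtype=float)
        nan = ~np.isfinite(y)
        if nan.any():
            # length of the longest NaN run, in seconds
            runs = np.diff(np.flatnonzero(np.diff(np.concatenate([[0], nan.view(np.int8), [0]]))))
            longest = runs[::2].max() if runs.size else 0
            if longest * med > max_gap_s:
                raise LoadError(f"{path}: NaN run longer than {max_gap_s} s in {col}")
            logging.getLogger(__name__).info(
                "%s: interpolated %d NaN samples in %s", path, int(nan.sum()), col
            )
            y = np.interp(t, t[~nan], y[~nan])
        chans[col] = y
    return PhotometryTrace(t=t, s465=chans["f465"], s405=chans["f405"], fs=fs)


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, files: list[dict], config_dict: dict, version: str,
                   extra: dict | None = None) -> dict:
    """Write the run manifest: every output file with its role and seed."""
    names = [f["path"] for f in files]
    if len(names) != len(set(names)):
        raise ValueError("duplicate file entries in manifest")
    man = {
        "version": version,
        "config_hash": config_hash(config_dict),
        "config": config_dict,
        "files": files,
    }
    if extra:
        man.update(extra)
    Path(path).write_text(json.dumps(man, indent=1, sort_keys=True, default=str) + "\n")
    return man


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
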