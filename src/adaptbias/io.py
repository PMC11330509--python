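"""Readers and writers for trial tables and photometry sessions.

Trial tables travel as flat CSV, one trial per row, UTF-8 with a header.
Required columns: ``session_id, trial_index, environment, side,
signed_contrast, choice, outcome, response_time``; ``contrast`` and
``altitude`` are optional (``contrast`` is reconstructed from the signed
value when absent).  Validation is structural only — behavioral exclusion
(e.g. the 12 s response-time cut) belongs to
:func:`adaptbias.psychometric.apply_exclusion`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .photometry import PhotometrySession

REQUIRED_COLUMNS = ("session_id", "trial_index", "environment", "side",
                    "signed_contrast", "choice", "outcome", "response_time")
SIDE_VALUES = {"L", "R"}
CHOICE_VALUES = {"L", "R", "none"}


def write_sessions(trials: pd.DataFrame, path) -> None:
    """Write a trial table to CSV (column order normalised)."""
    cols = [c for c in REQUIRED_COLUMNS if c in trials.columns]
    extra = [c for c in trials.columns if c not in cols]
    trials[cols + extra].to_csv(path, index=False)


def read_sessions(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Raises ``ValueError`` naming the offending column or row for missing
    columns, unknown enumeration values, or a non-increasing
    ``trial_index`` within a session.
    """
    trials = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_side = ~trials["side"].isin(SIDE_VALUES)
    if bad_side.any():
        row = int(np.flatnonzero(bad_side)[0])
        raise ValueError(f"{path}: unknown side value "
                         f"{trials['side'].iloc[row]!r} at row {row}")
    bad_choice = ~trials["choice"].isin(CHOICE_VALUES)
    if bad_choice.any():
        row = int(np.flatnonzero(bad_choice)[0])
        raise ValueError(f"{path}: unknown choice value "
                         f"{trials['choice'].iloc[row]!r} at row {row}")
    if not trials["outcome"].isin((0, 1)).all():
        raise ValueError(f"{path}: outcome must be 0 or 1")
    for sid, grp in trials.groupby("session_id", sort=False):
        idx = grp["trial_index"].to_numpy()
        if len(idx) > 1 and not (np.diff(idx) > 0).all():
            raise ValueError(f"{path}: trial_index not strictly increasing "
                             f"in session {sid!r}")
    if "contrast" not in trials.columns:
        trials["contrast"] = trials["signed_contrast"].abs()
    return trials


def write_photometry(session: PhotometrySession, trace_path, events_path) -> None:
    """Write the two-channel trace as CSV and the event table as JSON."""
    pd.DataFrame({
        "time_470": session.time_470, "signal_470": session.signal_470,
        "time_415": session.time_415, "control_415": session.control_415,
    }).to_csv(trace_path, index=False)
    with open(events_path, "w") as fh:
        json.dump({"stim_onsets": session.stim_onsets.tolist(),
                   "outcome_times": session.outcome_times.tolist(),
                   "rewarded": np.asarray(session.rewarded).astype(int).tolist(),
                   "fs": session.fs}, fh)


def read_photometry(trace_path, events_path) -> PhotometrySession:
    df = pd.read_csv(trace_path)
    with open(events_path) as fh:
        ev = json.load(fh)
    return PhotometrySession(
        time_470=df["time_470"].to_numpy(), signal_470=df["signal_470"].to_numpy(),
        time_415=df["time_415"].to_numpy(), control_415=df["control_415"].to_numpy(),
        stim_onsets=np.asarray(ev["stim_onsets"], float),
        outcome_times=np.asarray(ev["outcome_times"], float),
        rewarded=np.asarray(ev["rewarded"], int), fs=float(ev.get("fs", 20.0)))


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonify)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
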