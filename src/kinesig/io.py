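"""Tidy-CSV reading and writing of labeled trial trajectories.

Schema (one sample per row, UTF-8, header required)::

    participant_id,group,item_id,condition,session,trial_index,t_s,x_mm,y_mm,z_mm

plus optional ``home_x_mm,home_y_mm,home_z_mm`` columns (constant per trial).
An empty position cell marks a missing sample. When home columns are absent
the home point defaults to the first non-missing sample of the trial.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import DataError, IntegrityError, Trajectory, TrialRecord, check_no_duplicates

REQUIRED_COLUMNS = [
    "participant_id",
    "group",
    "item_id",
    "condition",
    "session",
    "trial_index",
    "t_s",
    "x_mm",
    "y_mm",
    "z_mm",
]
HOME_COLUMNS = ["home_x_mm", "home_y_mm", "home_z_mm"]
LABEL_COLUMNS = REQUIRED_COLUMNS[:6]


def write_trials(trials: list[TrialRecord], path: str | Path) -> None:
    """Serialize trials to the tidy CSV schema (missing samples as empty cells)."""
    frames = []
    for tr in trials:
        traj = tr.trajectory
        df = pd.DataFrame(
            {
                "participant_id": tr.participant_id,
                "group": tr.group,
                "item_id": tr.item_id,
                "condition": tr.condition,
                "session": tr.session,
                "trial_index": tr.trial_index,
                "t_s": traj.t,
                "x_mm": np.where(traj.missing, np.nan, traj.x),
                "y_mm": np.where(traj.missing, np.nan, traj.y),
                "z_mm": np.where(traj.missing, np.nan, traj.z),
                "home_x_mm": traj.home_point[0],
                "home_y_mm": traj.home_point[1],
                "home_z_mm": traj.home_point[2],
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials(path: str | Path, format: str = "tidy_csv") -> list[TrialRecord]:
    """Read validated trial records from a tidy CSV file.

    Raises
    ------
    DataError
        On schema violations (missing columns, non-monotone time), with the
        offending columns or trial named in the message.
    IntegrityError
        On duplicate (labels, sample) rows.
    """
    if format != "tidy_csv":
        raise DataError(f"unsupported format {format!r}; only 'tidy_csv' is implemented")
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"missing required columns: {missing_cols}")
    has_home = all(c in df.columns for c in HOME_COLUMNS)

    trials: list[TrialRecord] = []
    for key, g in df.groupby(LABEL_COLUMNS, sort=False):
        pid, group, item, cond, session, trial_idx = key
        t = g["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(
                f"non-monotone time column in trial {pid}/{item}/{cond} "
                f"(first offending row index {int(g.index[np.argmin(np.diff(t) > 0)])})"
            )
        x = g["x_mm"].to_numpy(dtype=float)
        y = g["y_mm"].to_numpy(dtype=float)
        z = g["z_mm"].to_numpy(dtype=float)
        missing = ~(np.isfinite(x) & np.isfinite(y) & np.isfinite(z))
        dt = np.median(np.diff(t)) if t.size > 1 else 1.0
        if has_home:
            home = tuple(float(g[c].iloc[0]) for c in HOME_COLUMNS)
        else:
            first = int(np.flatnonzero(~missing)[0]) if (~missing).any() else 0
            home = (float(x[first]), float(y[first]), float(z[first]))
        traj = Trajectory(
            t=t, x=x, y=y, z=z, missing=missing, sampling_hz=1.0 / dt, home_point=home
        )
        trials.append(
            TrialRecord(
                participant_id=str(pid),
                group=str(group),
                item_id=str(item),
                condition=str(cond),
                session=int(session),
                trial_index=int(trial_idx),
                trajectory=traj,
            )
        )
    check_no_duplicates(trials)
    return trials
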