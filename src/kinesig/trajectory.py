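"""Core containers: a single-marker 3D trajectory and its labeled trial record.

Coordinates follow the recording convention of tabletop motion capture:
``x`` and ``y`` are horizontal to the table (millimeters), ``z`` is vertical.
Every trial starts with the hand at a fixed *home point* on the table, which
serves as the origin for displacement and covered-area measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

GROUPS = ("speaker", "signer")
CONDITIONS = ("non_communicative", "communicative")


class KinesigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(KinesigError):
    """A configuration value is invalid; the message names the field."""


class DataError(KinesigError):
    """Input data violate a precondition of an operation."""


class IntegrityError(KinesigError):
    """Labeled records violate a structural invariant (duplicates, missing pairs)."""


@dataclass
class Trajectory:
    """Time-stamped 3D marker positions for one trial.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing.
    x, y, z : array of float
        Marker position in millimeters. Missing samples hold NaN.
    missing : array of bool
        Per-sample missing flag. After gap interpolation the flag is kept so
        that exclusion rules can still count the original missing runs.
    sampling_hz : float
        Nominal sampling rate; must agree with the median time step.
    home_point : tuple of 3 floats
        Table position (mm) where the hand rests before and after the trial.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    missing: np.ndarray
    sampling_hz: float
    home_point: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.missing is None:
            self.missing = ~(
                np.isfinite(self.x) & np.isfinite(self.y) & np.isfinite(self.z)
            )
        self.missing = np.asarray(self.missing, dtype=bool)
        n = self.t.size
        for name in ("x", "y", "z", "missing"):
            if getattr(self, name).size != n:
                raise DataError(f"channel '{name}' length differs from t")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise DataError("time column must be strictly increasing")
            if abs(np.median(dt) - 1.0 / self.sampling_hz) > 1e-6:
                raise DataError(
                    "sampling_hz inconsistent with median time step "
                    f"({1.0 / np.median(dt):.3f} Hz observed vs {self.sampling_hz})"
                )

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def xy_home_centered(self) -> np.ndarray:
        """(n, 2) horizontal coordinates relative to the home point."""
        return np.column_stack(
            (self.x - self.home_point[0], self.y - self.home_point[1])
        )

    def max_displacement_mm(self) -> float:
        """Maximal horizontal Euclidean distance from home over retained samples."""
        xy = self.xy_home_centered()[~self.missing]
        if xy.shape[0] == 0:
            return float("nan")
        return float(np.max(np.hypot(xy[:, 0], xy[:, 1])))

    def copy(self) -> "Trajectory":
        return Trajectory(
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            z=self.z.copy(),
            missing=self.missing.copy(),
            sampling_hz=self.sampling_hz,
            home_point=tuple(self.home_point),
        )


@dataclass
class TrialRecord:
    """A trajectory bound to its experimental labels.

    ``participant_id`` / ``item_id`` identify the random-effect units;
    ``condition`` distinguishes the re-enactment (non-communicative) from the
    description (communicative) of the same item, which makes the two records
    of a pair identifiable by sharing every label except ``condition``.
    """

    participant_id: str
    group: str
    item_id: str
    condition: str
    session: int
    trial_index: int
    trajectory: Trajectory

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def pair_key(self) -> tuple:
        """Labels shared by the two conditions of one trial pair."""
        return (self.participant_id, self.group, self.item_id, self.session, self.trial_index)

    @property
    def uid(self) -> str:
        return (
            f"{self.participant_id}/{self.item_id}/s{self.session}"
            f"/t{self.trial_index}/{self.condition}"
        )

    def labels(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "group": self.group,
            "item_id": self.item_id,
            "condition": self.condition,
            "session": self.session,
            "trial_index": self.trial_index,
        }

    def with_trajectory(self, traj: Trajectory) -> "TrialRecord":
        return replace(self, trajectory=traj)


def check_no_duplicates(trials: Iterable[TrialRecord]) -> None:
    seen = set()
    for tr in trials:
        key = tr.pair_key + (tr.condition,)
        if key in seen:
            raise IntegrityError(f"duplicate trial record {tr.uid}")
        seen.add(key)
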