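import numpy as np
import pytest

from kinesig.trajectory import Trajectory, TrialRecord


def min_jerk_trajectory(
    amplitude_mm: float = 1.0,
    duration_s: float = 1.0,
    hz: float = 120.0,
    axis: str = "x",
) -> Trajectory:
    """Single straight minimum-jerk stroke along one axis (closed-form oracle)."""
    t = np.arange(0.0, duration_s + 1e-9, 1.0 / hz)
    tau = t / duration_s
    s = amplitude_mm * tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)
    zeros = np.zeros_like(t)
    coords = {"x": zeros, "y": zeros, "z": zeros}
    coords[axis] = s
    return Trajectory(
        t=t,
        x=coords["x"],
        y=coords["y"],
        z=coords["z"],
        missing=np.zeros(t.size, dtype=bool),
        sampling_hz=hz,
    )


def square_path_trajectory(
    side_mm: float = 100.0, hz: float = 120.0, duration_s: float = 2.0
) -> Trajectory:
    """Deterministic square loop from/back to home; max displacement = side·√2."""
    n = int(duration_s * hz) + 1
    t = np.arange(n) / hz
    u = np.linspace(0.0, 4.0, n)  # perimeter coordinate
    x = np.empty(n)
    y = np.empty(n)
    for i, ui in enumerate(u):
        leg, frac = int(ui) % 4, ui % 1.0
        if ui >= 4.0:
            leg, frac = 3, 1.0
        if leg == 0:
            x[i], y[i] = side_mm * frac, 0.0
        elif leg == 1:
            x[i], y[i] = side_mm, side_mm * frac
        elif leg == 2:
            x[i], y[i] = side_mm * (1 - frac), side_mm
        else:
            x[i], y[i] = 0.0, side_mm * (1 - frac)
    return Trajectory(
        t=t, x=x, y=y, z=np.zeros(n), missing=np.zeros(n, dtype=bool), sampling_hz=hz
    )


def make_record(traj: Trajectory, participant="P01", group="speaker", item="item01",
                condition="non_communicative", session=1, trial_index=0) -> TrialRecord:
    return TrialRecord(
        participant_id=participant,
        group=group,
        item_id=item,
        condition=condition,
        session=session,
        trial_index=trial_index,
        trajectory=traj,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
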