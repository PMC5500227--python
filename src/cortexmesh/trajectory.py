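"""Trajectory containers and CSV round-trip I/O.

A :class:`Trajectory` is a uniformly sampled 2D track (times in seconds,
positions in micrometres); a :class:`TrajectoryEnsemble` is a collection of
tracks sharing one frame interval, the unit over which ensemble averages run.

The on-disk format is a flat CSV with columns
``track_id,frame,t_s,x_um,y_um`` (frame is 0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, EmptyInputError, InvalidParameterError, SchemaError

TRAJECTORY_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]

#: Acquisition frame interval in seconds (50 frames/s).
DEFAULT_FRAME_INTERVAL = 0.02


@dataclass
class Trajectory:
    """One particle track: strictly increasing, uniformly spaced times (s)
    and 2D positions (μm)."""

    track_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise InvalidParameterError("positions must have shape (n, 2)")
        if len(self.times) != len(self.positions):
            raise InvalidParameterError("times and positions length mismatch")
        if len(self.times) < 1:
            raise InvalidParameterError("trajectory must contain >= 1 sample")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise DataError(f"track {self.track_id}: times not strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise DataError(f"track {self.track_id}: non-uniform time spacing")

    @property
    def dt(self) -> float:
        """Sampling interval in seconds (0.0 for a single-point track)."""
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Total experimental time T in seconds."""
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TrajectoryEnsemble:
    """A set of trajectories sharing one frame interval (s)."""

    trajectories: list = field(default_factory=list)
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be > 0")
        for traj in self.trajectories:
            if len(traj) > 1 and not np.isclose(traj.dt, self.frame_interval, rtol=1e-6):
                raise DataError(
                    f"track {traj.track_id}: dt {traj.dt} != ensemble frame interval "
                    f"{self.frame_interval}"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def positions_array(self) -> np.ndarray:
        """Stack all equally long trajectories into (n_traj, n_samples, 2).

        Raises if trajectory lengths differ.
        """
        lengths = {len(t) for t in self.trajectories}
        if len(lengths) != 1:
            raise InvalidDataLengths(sorted(lengths))
        return np.stack([t.positions for t in self.trajectories])

    def to_dataframe(self) -> pd.DataFrame:
        frames_list = []
        for traj in self.trajectories:
            frames = np.round(
                (traj.times - traj.times[0]) / self.frame_interval
            ).astype(int)
            frames_list.append(
                pd.DataFrame(
                    {
                        "track_id": traj.track_id,
                        "frame": frames,
                        "t_s": traj.times,
                        "x_um": traj.positions[:, 0],
                        "y_um": traj.positions[:, 1],
                    }
                )
            )
        if not frames_list:
            return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
        return pd.concat(frames_list, ignore_index=True)


class InvalidDataLengths(DataError):
    def __init__(self, lengths):
        super().__init__(f"trajectories have differing lengths: {lengths}")


def write_trajectories(ensemble: TrajectoryEnsemble, path) -> None:
    """Write an ensemble as ``track_id,frame,t_s,x_um,y_um`` CSV."""
    ensemble.to_dataframe().to_csv(path, index=False, float_format="%.9g")


def read_trajectories(path, frame_interval: float | None = None) -> TrajectoryEnsemble:
    """Read a trajectory CSV back into an ensemble.

    Raises :class:`SchemaError` when a required column is missing and
    :class:`DataError` (naming the track) on duplicated frames or
    non-monotone times within a track.
    """
    table = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if table.empty:
        raise EmptyInputError(f"{path}: no trajectory rows")
    trajectories = []
    for track_id, group in table.groupby("track_id", sort=False):
        group = group.sort_values("frame")
        frames = group["frame"].to_numpy()
        if len(np.unique(frames)) != len(frames):
            raise DataError(f"track {track_id}: duplicated frame index")
        times = group["t_s"].to_numpy(dtype=float)
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise DataError(f"track {track_id}: times not strictly increasing")
        positions = group[["x_um", "y_um"]].to_numpy(dtype=float)
        trajectories.append(Trajectory(str(track_id), times, positions))
    if frame_interval is None:
        dts = [t.dt for t in trajectories if len(t) > 1]
        frame_interval = dts[0] if dts else DEFAULT_FRAME_INTERVAL
    return TrajectoryEnsemble(trajectories, frame_interval=frame_interval)
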