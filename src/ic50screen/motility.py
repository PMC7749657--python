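"""Single-cell migration statistics: speed and time-penalized persistence.

Tracks are sequences of (t, x, y) observations from time-lapse imaging.
Speed is the total travelled path length divided by the tracked
duration. Persistence is the directionality ratio — net displacement
over path length — multiplied by sqrt(t_tracked / t_max), which
penalizes cells tracked for only part of the acquisition window: short
tracks of a meandering cell can look spuriously straight, and the
square-root-time factor down-weights them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellTrack",
    "MotilityStats",
    "track_speed",
    "track_persistence",
    "track_stats",
    "summarize_condition",
    "tracks_from_table",
]


@dataclass
class CellTrack:
    """One cell's trajectory; times in minutes, positions in µm."""

    track_id: str
    times: np.ndarray
    positions: np.ndarray  # (n, 2)
    t_max: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.positions.shape != (self.times.size, 2):
            raise ValueError("positions must be (n_times, 2)")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.t_tracked > self.t_max + 1e-9:
            raise ValueError("tracked duration exceeds t_max")

    @property
    def t_tracked(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def path_length(self) -> float:
        steps = np.diff(self.positions, axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())

    @property
    def net_displacement(self) -> float:
        d = self.positions[-1] - self.positions[0]
        return float(np.hypot(d[0], d[1]))


@dataclass
class MotilityStats:
    track_id: str
    speed: float            # µm/min
    persistence: float      # unitless, in [0, 1]
    path_length: float      # µm
    net_displacement: float  # µm
    t_tracked: float        # min
    degenerate: bool = False  # stationary cell (zero path length)


def track_speed(track: CellTrack) -> float:
    """Total travelled distance divided by tracked duration, µm/min."""
    if track.times.size < 2:
        raise ValueError("speed requires at least 2 track points")
    return track.path_length / track.t_tracked


def track_persistence(track: CellTrack) -> float:
    """(net displacement / path length) * sqrt(t_tracked / t_max).

    A stationary cell (zero path length) has undefined directionality;
    it is reported as 0, consistent with "no persistent motion".
    """
    L = track.path_length
    if L == 0:
        return 0.0
    return (track.net_displacement / L) * float(
        np.sqrt(track.t_tracked / track.t_max)
    )


def track_stats(track: CellTrack) -> MotilityStats:
    return MotilityStats(
        track_id=track.track_id,
        speed=track_speed(track),
        persistence=track_persistence(track),
        path_length=track.path_length,
        net_displacement=track.net_displacement,
        t_tracked=track.t_tracked,
        degenerate=track.path_length == 0,
    )


def summarize_condition(
    tracks: list[CellTrack], conditions: list[str] | None = None
) -> pd.DataFrame:
    """Per-condition mean/sd/n of speed and persistence.

    ``conditions`` gives one label per track (e.g., drug dose); omitted,
    all tracks form a single group. Groups with fewer than 2 tracks get
    NaN standard deviations.
    """
    if not tracks:
        raise ValueError("no tracks to summarize")
    if conditions is None:
        conditions = ["all"] * len(tracks)
    if len(conditions) != len(tracks):
        raise ValueError("conditions must match tracks in length")
    rows = [
        {
            "condition": cond,
            "speed": s.speed,
            "persistence": s.persistence,
        }
        for cond, s in zip(conditions, map(track_stats, tracks))
    ]
    df = pd.DataFrame(rows)
    out = df.groupby("condition", sort=True).agg(
        speed_mean=("speed", "mean"),
        speed_sd=("speed", "std"),
        persistence_mean=("persistence", "mean"),
        persistence_sd=("persistence", "std"),
        n=("speed", "size"),
    )
    return out.reset_index()


def tracks_from_table(table: pd.DataFrame, t_max: float) -> list[CellTrack]:
    """Build CellTracks from a long table (track_id, frame, t_min, x_um, y_um)."""
    required = {"track_id", "t_min", "x_um", "y_um"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    tracks = []
    for tid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("t_min")
        tracks.append(
            CellTrack(
                track_id=str(tid),
                times=grp["t_min"].to_numpy(dtype=float),
                positions=grp[["x_um", "y_um"]].to_numpy(dtype=float),
                t_max=t_max,
            )
        )
    return tracks
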