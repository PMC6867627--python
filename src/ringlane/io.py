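"""Trajectory containers and I/O for ring micro-lane tracking data.

Single cells confined to a ring-shaped adhesive lane move effectively in one
dimension; their position is fully described by the unwrapped angular
coordinate ``phi`` on the ring.  This module reads tracking tables (CSV),
projects Cartesian coordinates onto the ring geometry, unwraps the angle into
a continuous series, and writes normalized trajectory tables back out.

Conventions: angles in radians, positive counter-clockwise (``atan2``);
arc length in micrometers (``radius * phi``); time internally in hours.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    ProjectionError,
    SamplingError,
    UnwrapError,
)

logger = logging.getLogger(__name__)

#: relative tolerance on uniform time spacing
DT_RTOL = 1e-6
#: cells whose mean radial deviation exceeds this fraction of the radius are flagged
RADIAL_FLAG_FRACTION = 0.2


@dataclass(frozen=True)
class RingGeometry:
    """Center and radius (micrometers) of a circular micro-lane.

    The default radius of 75 um corresponds to the 150 um ring diameter of
    the micro-lane arrays this pipeline targets.
    """

    center_x: float = 0.0
    center_y: float = 0.0
    radius: float = 75.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ConfigurationError(f"ring radius must be > 0, got {self.radius}")

    def to_json(self) -> str:
        return json.dumps(
            {"center_x": self.center_x, "center_y": self.center_y, "radius": self.radius}
        )

    @classmethod
    def from_json(cls, text: str) -> "RingGeometry":
        d = json.loads(text)
        return cls(float(d["center_x"]), float(d["center_y"]), float(d["radius"]))


@dataclass
class Trajectory:
    """One cell's uniformly sampled, unwrapped angular position series.

    Attributes
    ----------
    cell_id : str
    times : ndarray
        Strictly increasing, uniformly spaced times in hours.
    phi : ndarray
        Unwrapped angular position in radians; successive steps have
        magnitude < pi.
    flagged_off_lane : bool
        True when the mean radial deviation of the original (x, y) points
        exceeded 20% of the ring radius (quality-control flag; the cell is
        kept).
    """

    cell_id: str
    times: np.ndarray
    phi: np.ndarray
    flagged_off_lane: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.phi.shape:
            raise FormatError(f"cell {self.cell_id}: times/phi must be equal-length 1-D")
        if len(self.times) < 2:
            raise FormatError(f"cell {self.cell_id}: need at least 2 time points")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise SamplingError(f"cell {self.cell_id}: times not strictly increasing")
        dt = steps.mean()
        if np.max(np.abs(steps - dt)) > DT_RTOL * dt:
            raise SamplingError(
                f"cell {self.cell_id}: non-uniform sampling "
                f"(max deviation {np.max(np.abs(steps - dt)):.3g} h from dt={dt:.3g} h)"
            )
        if np.any(np.abs(np.diff(self.phi)) >= np.pi):
            raise UnwrapError(f"cell {self.cell_id}: angular step of magnitude >= pi")

    @property
    def dt(self) -> float:
        """Sampling interval in hours."""
        return float(np.diff(self.times).mean())

    @property
    def duration(self) -> float:
        """Track duration in hours."""
        return float(self.times[-1] - self.times[0])

    def arc(self, geometry: RingGeometry) -> np.ndarray:
        """Arc-length position ``radius * phi`` in micrometers."""
        return geometry.radius * self.phi


@dataclass
class TrajectoryCollection:
    """Trajectories sharing one ring geometry and sampling interval."""

    trajectories: list[Trajectory]
    geometry: RingGeometry
    dt: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise FormatError("empty trajectory collection")
        ids = [t.cell_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate cell ids in collection")
        dts = np.array([t.dt for t in self.trajectories])
        dt = float(dts[0])
        if np.max(np.abs(dts - dt)) > DT_RTOL * dt:
            raise SamplingError("trajectories do not share a common sampling interval")
        self.dt = dt

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, cell_id: str) -> Trajectory:
        for t in self.trajectories:
            if t.cell_id == cell_id:
                return t
        raise KeyError(cell_id)


class RingProjection(NamedTuple):
    """Raw (wrapped) angles and per-point radial deviation from the lane."""

    angles: np.ndarray
    radial_deviation: np.ndarray


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping and time unit for trajectory CSV files.

    Either (`x`, `y`) columns in micrometers or a `phi` column in radians
    must be present.  ``time_unit`` is one of "h", "min", "s", or "frames";
    for "frames" the `frame_interval_h` converts frame indices to hours.
    """

    cell_id: str = "cell_id"
    time: str = "time_h"
    x: str = "x_um"
    y: str = "y_um"
    phi: str = "phi_rad"
    time_unit: str = "h"
    frame_interval_h: float = 1.0 / 6.0

    def time_to_hours(self, values: np.ndarray) -> np.ndarray:
        if self.time_unit == "h":
            return values
        if self.time_unit == "min":
            return values / 60.0
        if self.time_unit == "s":
            return values / 3600.0
        if self.time_unit == "frames":
            return values * self.frame_interval_h
        raise ConfigurationError(f"unknown time unit {self.time_unit!r}")


def project_to_ring(
    xy_points: Sequence[tuple[float, float]] | np.ndarray, geometry: RingGeometry
) -> RingProjection:
    """Project Cartesian points onto the ring, returning raw angles in (-pi, pi].

    The radial deviation ``|distance_from_center - radius|`` is returned per
    point for lane-adherence quality control.

    Raises
    ------
    ProjectionError
        If any point coincides with the ring center (angle undefined).
    """
    pts = np.asarray(xy_points, dtype=float)
    dx = pts[:, 0] - geometry.center_x
    dy = pts[:, 1] - geometry.center_y
    dist = np.hypot(dx, dy)
    if np.any(dist == 0):
        bad = int(np.flatnonzero(dist == 0)[0])
        raise ProjectionError(f"point {bad} coincides with the ring center")
    angles = np.arctan2(dy, dx)
    # atan2 yields [-pi, pi]; fold -pi onto +pi for the (-pi, pi] convention
    angles[angles == -np.pi] = np.pi
    return RingProjection(angles, np.abs(dist - geometry.radius))


def unwrap_angles(raw_angles: Sequence[float] | np.ndarray) -> np.ndarray:
    """Unwrap a raw angle sequence into a continuous series.

    Each successive step is shifted by a multiple of 2*pi so that its
    magnitude is below pi; ``phi[0] = raw[0]``.

    Raises
    ------
    UnwrapError
        If a wrapped step has magnitude exactly pi (the 2*pi branch is
        ambiguous); the offending index is reported.
    """
    raw = np.asarray(raw_angles, dtype=float)
    if raw.ndim != 1 or len(raw) == 0:
        raise FormatError("raw angle sequence must be non-empty 1-D")
    d = np.diff(raw)
    rem = np.mod(d, 2.0 * np.pi)  # in [0, 2pi)
    ties = np.flatnonzero(rem == np.pi)
    if ties.size:
        raise UnwrapError(f"ambiguous angular step of exactly pi at index {int(ties[0])}")
    wrapped = np.where(rem > np.pi, rem - 2.0 * np.pi, rem)
    out = np.empty_like(raw)
    out[0] = raw[0]
    out[1:] = raw[0] + np.cumsum(wrapped)
    return out


def read_trajectories(
    path,
    geometry: RingGeometry | None = None,
    dialect: CsvDialect | Mapping[str, object] | None = None,
) -> TrajectoryCollection:
    """Read a tracking CSV into a :class:`TrajectoryCollection`.

    The table must contain a cell-id column, a time column, and either
    Cartesian ``(x, y)`` columns (projected onto `geometry`) or an angular
    position column.  Rows are sorted per cell by time.  Cells with fewer
    than two time points are dropped with a warning.  Cells whose mean radial
    deviation exceeds 20% of the ring radius are flagged, not dropped.
    """
    if isinstance(dialect, Mapping):
        dialect = CsvDialect(**dialect)
    elif dialect is None:
        dialect = CsvDialect()
    geometry = geometry or RingGeometry()

    df = pd.read_csv(path)
    if dialect.cell_id not in df.columns or dialect.time not in df.columns:
        raise FormatError(
            f"missing required columns {dialect.cell_id!r}/{dialect.time!r}; "
            f"found {list(df.columns)}"
        )
    has_xy = dialect.x in df.columns and dialect.y in df.columns
    has_phi = dialect.phi in df.columns
    if not has_xy and not has_phi:
        raise FormatError(
            f"need either ({dialect.x!r}, {dialect.y!r}) or {dialect.phi!r} columns"
        )

    trajectories: list[Trajectory] = []
    for cell_id, group in df.groupby(dialect.cell_id, sort=True):
        group = group.sort_values(dialect.time)
        if len(group) < 2:
            logger.warning("cell %s has < 2 time points; dropped", cell_id)
            continue
        times = dialect.time_to_hours(group[dialect.time].to_numpy(dtype=float))
        flagged = False
        if has_xy:
            proj = project_to_ring(
                group[[dialect.x, dialect.y]].to_numpy(dtype=float), geometry
            )
            raw = proj.angles
            mean_dev = float(proj.radial_deviation.mean())
            if mean_dev > RADIAL_FLAG_FRACTION * geometry.radius:
                flagged = True
                logger.warning(
                    "cell %s: mean radial deviation %.1f um exceeds %d%% of radius; flagged",
                    cell_id,
                    mean_dev,
                    int(RADIAL_FLAG_FRACTION * 100),
                )
        else:
            raw = group[dialect.phi].to_numpy(dtype=float)
        phi = unwrap_angles(raw)
        trajectories.append(
            Trajectory(str(cell_id), times, phi, flagged_off_lane=flagged)
        )
    if not trajectories:
        raise FormatError(f"no usable trajectories in {path}")
    return TrajectoryCollection(trajectories, geometry)


def write_trajectories(collection: TrajectoryCollection, path) -> None:
    """Write a normalized trajectory CSV (cell_id, time_h, phi_rad, arc_um)."""
    frames = []
    for traj in collection:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": traj.cell_id,
                    "time_h": traj.times,
                    "phi_rad": traj.phi,
                    "arc_um": traj.arc(collection.geometry),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")
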