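"""Per-frame kinematics from centroid tracks.

Tracks are time-stamped 2-D centroid positions of a single larva, sampled at
a constant frame interval (0.5 s, i.e. 2 frames/s, by default).  A full
50-minute recording is 6000 frames.  This module provides:

* a constant-velocity Kalman filter for smoothing the raw (x, y) coordinates,
* backward-difference velocity, unit heading, scalar speed and instantaneous
  turn rate arccos(H(t_{j-1}) . H(t_j)) / dt,
* readers/writers for the tracker CSV dialect
  (columns ``larva_id, frame, x_mm, y_mm``, 0-based frames).

Zero-displacement frames have no defined heading; for turn-rate purposes the
last defined heading is propagated and the frame is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataQualityError, InsufficientDataError, InvalidArgumentError

DEFAULT_DT_S = 0.5
FRAMES_PER_MINUTE = 120  # at 2 frames/s
DEFAULT_MEASUREMENT_SD_MM = 0.1
DEFAULT_PROCESS_SD = 0.05  # white-acceleration sd, mm/s^2


@dataclass
class Trajectory:
    """Centroid track of one larva: positions (N, 2) in mm at constant dt."""

    times: np.ndarray
    positions: np.ndarray
    larva_id: str = "larva0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise InvalidArgumentError("positions must have shape (N, 2)")
        if len(self.times) != len(self.positions):
            raise InvalidArgumentError("times and positions must have equal length")
        if len(self.times) < 2:
            raise InsufficientDataError("a trajectory needs at least 2 frames")
        steps = np.diff(self.times)
        if not np.all(steps > 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise InvalidArgumentError("times must have a constant frame interval")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @classmethod
    def from_positions(
        cls, positions, dt: float = DEFAULT_DT_S, larva_id: str = "larva0"
    ) -> "Trajectory":
        positions = np.asarray(positions, dtype=float)
        times = np.arange(len(positions)) * dt
        return cls(times=times, positions=positions, larva_id=larva_id)


@dataclass
class KinematicSeries:
    """Per-frame kinematics; undefined entries are NaN and flagged.

    ``velocity[j]`` is the backward difference (R(t_j) - R(t_{j-1})) / dt, so
    the first frame carries no velocity.  ``heading`` is the unit velocity
    where speed > 0.  ``turn_rate`` is in rad/s, in [0, pi/dt]; at
    zero-speed frames it is reported as 0 and flagged.
    """

    velocity: np.ndarray
    heading: np.ndarray
    speed: np.ndarray
    turn_rate: np.ndarray
    heading_defined: np.ndarray = field(default=None)
    turn_rate_defined: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# Kalman smoothing


def _kalman_matrices(dt: float, process_sd: float, measurement_sd: float):
    F = np.array(
        [[1, 0, dt, 0], [0, 1, 0, dt], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float
    )
    H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
    # Discrete white-acceleration process noise, isotropic in x and y.
    q = process_sd**2
    Qa = q * np.array([[dt**4 / 4, dt**3 / 2], [dt**3 / 2, dt**2]])
    Q = np.zeros((4, 4))
    Q[np.ix_([0, 2], [0, 2])] = Qa
    Q[np.ix_([1, 3], [1, 3])] = Qa
    R = measurement_sd**2 * np.eye(2)
    return F, H, Q, R


def smooth(
    raw: Trajectory,
    process_noise: float = DEFAULT_PROCESS_SD,
    measurement_noise: float = DEFAULT_MEASUREMENT_SD_MM,
    rts: bool = False,
) -> Trajectory:
    """Kalman-smooth the (x, y) coordinates of one larva.

    A linear-Gaussian constant-velocity model (state x, y, vx, vy) filtered
    forward; with ``rts=True`` a Rauch-Tung-Striebel backward pass is applied
    on top.  ``process_noise`` is the white-acceleration sd (mm/s^2) and
    ``measurement_noise`` the centroid measurement sd (mm); as the
    measurement noise goes to zero the output converges to the input.
    """
    z = raw.positions
    if not np.all(np.isfinite(z)):
        bad = np.nonzero(~np.isfinite(z).all(axis=1))[0]
        raise DataQualityError(f"non-finite coordinates at frames {bad.tolist()}")
    n = raw.n_frames
    F, H, Q, R = _kalman_matrices(raw.dt, process_noise, measurement_noise)

    x = np.zeros(4)
    x[:2] = z[0]
    P = np.diag([measurement_noise**2, measurement_noise**2, 1.0, 1.0])

    xs_filt = np.zeros((n, 4))
    Ps_filt = np.zeros((n, 4, 4))
    xs_pred = np.zeros((n, 4))
    Ps_pred = np.zeros((n, 4, 4))
    xs_filt[0], Ps_filt[0] = x, P
    xs_pred[0], Ps_pred[0] = x, P

    for j in range(1, n):
        xp = F @ x
        Pp = F @ P @ F.T + Q
        y = z[j] - H @ xp
        S = H @ Pp @ H.T + R
        K = Pp @ H.T @ np.linalg.solve(S, np.eye(2))
        x = xp + K @ y
        P = (np.eye(4) - K @ H) @ Pp
        xs_pred[j], Ps_pred[j] = xp, Pp
        xs_filt[j], Ps_filt[j] = x, P

    if rts:
        xs = xs_filt.copy()
        Ps = Ps_filt.copy()
        for j in range(n - 2, -1, -1):
            C = Ps_filt[j] @ F.T @ np.linalg.inv(Ps_pred[j + 1])
            xs[j] = xs_filt[j] + C @ (xs[j + 1] - xs_pred[j + 1])
            Ps[j] = Ps_filt[j] + C @ (Ps[j + 1] - Ps_pred[j + 1]) @ C.T
        out = xs[:, :2]
    else:
        out = xs_filt[:, :2]

    return Trajectory(times=raw.times.copy(), positions=out, larva_id=raw.larva_id)


# ---------------------------------------------------------------------------
# Kinematic quantities


def kinematics(traj: Trajectory) -> KinematicSeries:
    """Velocity, heading, speed and turn rate of a track.

    Requires at least 3 frames (the turn rate compares consecutive headings).
    The arccos argument is clamped to [-1, 1] for floating-point safety.
    """
    if traj.n_frames < 3:
        raise InsufficientDataError("turn rate needs at least 3 frames")
    dt = traj.dt
    n = traj.n_frames

    velocity = np.full((n, 2), np.nan)
    velocity[1:] = np.diff(traj.positions, axis=0) / dt
    speed = np.full(n, np.nan)
    speed[1:] = np.linalg.norm(velocity[1:], axis=1)

    heading = np.full((n, 2), np.nan)
    heading_defined = np.zeros(n, dtype=bool)
    moving = speed > 0
    heading[moving] = velocity[moving] / speed[moving, None]
    heading_defined[moving] = True

    # Headings used for the turn rate: propagate the last defined heading
    # across zero-speed frames.
    h_eff = heading.copy()
    last = None
    for j in range(1, n):
        if heading_defined[j]:
            last = heading[j]
        elif last is not None:
            h_eff[j] = last

    turn_rate = np.full(n, np.nan)
    turn_rate_defined = np.zeros(n, dtype=bool)
    for j in range(2, n):
        if not heading_defined[j]:
            turn_rate[j] = 0.0  # zero-speed frame: flagged, reported as 0
        elif np.all(np.isfinite(h_eff[j - 1])):
            dot = float(np.clip(np.dot(h_eff[j - 1], h_eff[j]), -1.0, 1.0))
            turn_rate[j] = np.arccos(dot) / dt
            turn_rate_defined[j] = True

    return KinematicSeries(
        velocity=velocity,
        heading=heading,
        speed=speed,
        turn_rate=turn_rate,
        heading_defined=heading_defined,
        turn_rate_defined=turn_rate_defined,
    )


# ---------------------------------------------------------------------------
# Tracker CSV I/O


def read_tracks(path, dt: float = DEFAULT_DT_S) -> dict[str, Trajectory]:
    """Read a tracker CSV (larva_id, frame, x_mm, y_mm) into trajectories."""
    df = pd.read_csv(path)
    required = {"larva_id", "frame", "x_mm", "y_mm"}
    missing = required - set(df.columns)
    if missing:
        raise DataQualityError(f"tracker CSV missing columns: {sorted(missing)}")
    out: dict[str, Trajectory] = {}
    for larva_id, g in df.groupby("larva_id", sort=True):
        g = g.sort_values("frame")
        times = g["frame"].to_numpy(dtype=float) * dt
        pos = g[["x_mm", "y_mm"]].to_numpy(dtype=float)
        out[str(larva_id)] = Trajectory(times=times, positions=pos, larva_id=str(larva_id))
    return out


def write_tracks(trajectories, path, kinematic_columns: bool = False) -> None:
    """Write trajectories in the tracker CSV dialect.

    With ``kinematic_columns=True`` the per-frame speed and turn rate are
    appended as ``speed_mm_s`` and ``turn_rate_rad_s``.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if isinstance(trajectories, dict):
        trajectories = list(trajectories.values())
    frames = []
    for traj in trajectories:
        df = pd.DataFrame(
            {
                "larva_id": traj.larva_id,
                "frame": np.round(traj.times / traj.dt).astype(int),
                "x_mm": traj.positions[:, 0],
                "y_mm": traj.positions[:, 1],
            }
        )
        if kinematic_columns:
            k = kinematics(traj)
            df["speed_mm_s"] = k.speed
            df["turn_rate_rad_s"] = k.turn_rate
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
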