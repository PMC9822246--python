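"""Turn detection and characterization.

A larva's path is simplified with the Ramer-Douglas-Peucker (RDP) algorithm;
the retained interior vertices are the turning points.  At each turning
point the signed turning angle (atan2 of cross and dot of the incoming and
outgoing segment vectors, CCW positive) gives the turn direction, and the
handedness score H = N_CCW / (N_CCW + N_CW) summarises the larva's rotational
bias.  With a patch layout supplied, each turn is classified as inward or
outward: with V1 the incoming segment, V2 the outgoing segment and U the
vector from the turning point to the nearest patch centre, the turn is
inward iff angle(V2, U) < angle(V1, U).

RDP epsilon defaults are keyed by substrate: 2.5 mm for agar, sucrose and
apple juice, 1.25 mm for yeast (yeast tracks are slower and tighter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError
from .geometry import PatchLayout, nearest_patch
from .kinematics import FRAMES_PER_MINUTE, Trajectory

#: RDP tolerance (mm) by substrate label.
EPSILON_BY_SUBSTRATE = {
    "agar": 2.5,
    "sucrose": 2.5,
    "apple_juice": 2.5,
    "yeast": 1.25,
}
DEFAULT_EPSILON_MM = 2.5

#: Angular tie tolerance for the inward/outward rule (radians).
_TIE_TOL = 1e-12


@dataclass
class SimplifiedPath:
    """RDP-simplified polyline with indices back into the source trajectory."""

    vertices: np.ndarray  # (K, 2) mm
    frame_indices: np.ndarray  # (K,) indices into the source track
    epsilon: float

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class TurnEvent:
    """One detected (or simulated) turn."""

    vertex_index: int
    location: tuple[float, float]
    angle: float  # signed radians, CCW positive
    direction: str  # "CW" | "CCW" | "none" (angle exactly 0)
    orientation: str = "unclassified"  # "inward" | "outward" | "unclassified"
    distance_to_center: float = math.nan


@dataclass
class HandednessScore:
    H: float
    n_ccw: int
    n_cw: int
    defined: bool = True


def epsilon_for(substrate: str) -> float:
    return EPSILON_BY_SUBSTRATE.get(substrate, DEFAULT_EPSILON_MM)


# ---------------------------------------------------------------------------
# RDP simplification


def _point_line_distances(points: np.ndarray, start: np.ndarray, end: np.ndarray):
    """Perpendicular distance of each point to the line through start-end.

    Falls back to the distance to ``start`` when the chord is degenerate.
    """
    chord = end - start
    norm = math.hypot(chord[0], chord[1])
    if norm == 0.0:
        return np.linalg.norm(points - start, axis=1)
    cross = (points[:, 0] - start[0]) * chord[1] - (points[:, 1] - start[1]) * chord[0]
    return np.abs(cross) / norm


def rdp_simplify(traj, epsilon: float) -> SimplifiedPath:
    """Ramer-Douglas-Peucker simplification of a trajectory.

    ``traj`` may be a :class:`Trajectory` or a bare (N, 2) point array.
    Interior vertices of the result are the turning points; every removed
    point lies within ``epsilon`` of the simplified polyline.
    """
    if not epsilon > 0:
        raise InvalidArgumentError(f"epsilon must be positive, got {epsilon}")
    points = traj.positions if isinstance(traj, Trajectory) else np.asarray(traj, float)
    n = len(points)
    if n < 2:
        raise InsufficientDataError("RDP needs at least 2 points")

    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    # Explicit stack: recursion depth can reach the track length on smooth arcs.
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        seg = points[i + 1 : j]
        d = _point_line_distances(seg, points[i], points[j])
        k_rel = int(np.argmax(d))
        if d[k_rel] > epsilon:
            k = i + 1 + k_rel
            keep[k] = True
            stack.append((i, k))
            stack.append((k, j))
    idx = np.nonzero(keep)[0]
    return SimplifiedPath(vertices=points[idx], frame_indices=idx, epsilon=epsilon)


# ---------------------------------------------------------------------------
# Turning angles and handedness


def signed_angle(v1, v2) -> float:
    """Signed angle from v1 to v2 in [-pi, pi]; CCW positive."""
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    return math.atan2(cross, dot)


def turning_angles(path: SimplifiedPath, return_flags: bool = False):
    """Signed turning angle at each interior vertex of a simplified path.

    Positive angles are counter-clockwise, negative clockwise.  Vertices with
    a degenerate (zero-length) adjacent segment are skipped and flagged NaN.
    """
    v = path.vertices
    if len(v) < 3:
        raise InsufficientDataError("turning angles need at least 3 vertices")
    angles = np.full(len(v) - 2, np.nan)
    for k in range(1, len(v) - 1):
        a = v[k] - v[k - 1]
        b = v[k + 1] - v[k]
        if (a[0] == 0 and a[1] == 0) or (b[0] == 0 and b[1] == 0):
            continue  # degenerate segment: flagged NaN
        angles[k - 1] = signed_angle(a, b)
    if return_flags:
        return angles, np.isfinite(angles)
    return angles


def handedness(angles) -> HandednessScore:
    """Handedness H = N_CCW / (N_CCW + N_CW); H > 0.5 means a CCW bias.

    Angles of exactly 0 count as neither direction; with no nonzero angles
    the score is flagged undefined (H = NaN) rather than raising.
    """
    angles = np.asarray(angles, dtype=float)
    finite = angles[np.isfinite(angles)]
    n_ccw = int(np.sum(finite > 0))
    n_cw = int(np.sum(finite < 0))
    total = n_ccw + n_cw
    if total == 0:
        return HandednessScore(H=math.nan, n_ccw=0, n_cw=0, defined=False)
    return HandednessScore(H=n_ccw / total, n_ccw=n_ccw, n_cw=n_cw)


def turn_indicator(path: SimplifiedPath, n_frames: int) -> np.ndarray:
    """Binary per-frame vector: 1 at the frame of each interior RDP vertex."""
    ind = np.zeros(n_frames, dtype=int)
    ind[path.frame_indices[1:-1]] = 1
    return ind


def turns_per_minute(turn_frames, window: int = FRAMES_PER_MINUTE) -> float:
    """Mean turns per minute from a rolling window over a turn indicator.

    Sums the indicator within every full window of ``window`` frames
    (default 120 frames = 1 min at 2 frames/s) and averages the sums.
    """
    ind = np.asarray(turn_frames, dtype=float)
    if len(ind) < window:
        raise InsufficientDataError(
            f"indicator has {len(ind)} frames, shorter than the {window}-frame window"
        )
    c = np.concatenate([[0.0], np.cumsum(ind)])
    window_sums = c[window:] - c[:-window]
    return float(np.mean(window_sums))


# ---------------------------------------------------------------------------
# Inward / outward classification


def classify_turn(path: SimplifiedPath, k: int, layout: PatchLayout) -> str:
    """Classify the interior vertex ``k`` as ``"inward"`` or ``"outward"``.

    theta1 = angle(V1, U), theta2 = angle(V2, U) with U toward the nearest
    patch centre; inward iff theta2 < theta1.  Exact ties (within 1e-12) are
    labelled outward (conservative).  Degenerate V1, V2 or U give
    ``"unclassifiable"``.
    """
    v = path.vertices
    if not (1 <= k <= len(v) - 2):
        raise InvalidArgumentError(f"k={k} is not an interior vertex index")
    s_prev, s_k, s_next = v[k - 1], v[k], v[k + 1]
    patch, _ = nearest_patch(layout, s_k)
    v1 = s_k - s_prev
    v2 = s_next - s_k
    u = np.asarray(patch.center) - s_k
    n1, n2, nu = (math.hypot(*v1), math.hypot(*v2), math.hypot(*u))
    if n1 == 0 or n2 == 0 or nu == 0:
        return "unclassifiable"
    theta1 = math.acos(max(-1.0, min(1.0, float(np.dot(v1, u)) / (n1 * nu))))
    theta2 = math.acos(max(-1.0, min(1.0, float(np.dot(v2, u)) / (n2 * nu))))
    if theta2 < theta1 - _TIE_TOL:
        return "inward"
    return "outward"


def detect_turn_events(
    traj: Trajectory,
    epsilon: float = DEFAULT_EPSILON_MM,
    layout: PatchLayout | None = None,
) -> list[TurnEvent]:
    """Full per-track turn detection: RDP, signed angles, orientation labels."""
    path = rdp_simplify(traj, epsilon)
    if path.n_vertices < 3:
        return []
    angles = turning_angles(path)
    events = []
    for k in range(1, path.n_vertices - 1):
        ang = angles[k - 1]
        if not math.isfinite(ang):
            continue
        direction = "CCW" if ang > 0 else ("CW" if ang < 0 else "none")
        orientation = "unclassified"
        dist = math.nan
        if layout is not None and layout.patches:
            orientation = classify_turn(path, k, layout)
            _, dist = nearest_patch(layout, path.vertices[k])
        events.append(
            TurnEvent(
                vertex_index=int(path.frame_indices[k]),
                location=(float(path.vertices[k, 0]), float(path.vertices[k, 1])),
                angle=float(ang),
                direction=direction,
                orientation=orientation,
                distance_to_center=dist,
            )
        )
    return events


DEFAULT_BIN_WIDTH_MM = 10.0
DEFAULT_MAX_DISTANCE_MM = 60.0


def inward_fraction_by_distance(
    events,
    bin_width: float = DEFAULT_BIN_WIDTH_MM,
    max_distance: float = DEFAULT_MAX_DISTANCE_MM,
) -> pd.DataFrame:
    """Fraction of inward turns per distance bin from the nearest patch centre.

    Bins are half-open [a, a + bin_width) up to ``max_distance``; events
    beyond the cap or without an inward/outward label are excluded.  Bins with
    no classified events have NaN fraction and ``n`` = 0.
    """
    if not bin_width > 0:
        raise InvalidArgumentError("bin_width must be positive")
    edges = np.arange(0.0, max_distance + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    inward = np.zeros(n_bins, dtype=int)
    total = np.zeros(n_bins, dtype=int)
    for ev in events:
        if ev.orientation not in ("inward", "outward"):
            continue
        d = ev.distance_to_center
        if not math.isfinite(d) or d < 0 or d >= max_distance:
            continue
        b = int(d // bin_width)
        total[b] += 1
        if ev.orientation == "inward":
            inward[b] += 1
    frac = np.where(total > 0, inward / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo_mm": edges[:-1],
            "bin_hi_mm": edges[1:],
            "fraction_inward": frac,
            "n": total,
        }
    )


def turn_event_table(events, larva_id: str = "larva0") -> pd.DataFrame:
    """Long-format per-larva turn-event table (one row per turn)."""
    return pd.DataFrame(
        {
            "larva_id": larva_id,
            "frame": [ev.vertex_index for ev in events],
            "x": [ev.location[0] for ev in events],
            "y": [ev.location[1] for ev in events],
            "angle_rad": [ev.angle for ev in events],
            "direction": [ev.direction for ev in events],
            "orientation": [ev.orientation for ev in events],
            "dist_mm": [ev.distance_to_center for ev in events],
        }
    )
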