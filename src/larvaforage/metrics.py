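"""Residence and exploration summaries.

Computed identically for recorded-style and simulated tracks: fraction of
time inside food patches (the food-exploitation measure), fraction of
distinct non-source patches visited, total distance traveled, and pause
fraction.  "Inside" is evaluated per frame on the centroid against closed
patch discs, with no dwell hysteresis at the border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError, InvalidLayoutError
from .geometry import PatchLayout
from .kinematics import Trajectory, kinematics

#: Speed below which a frame counts as paused on recorded-style tracks (mm/s).
#: For simulated data the ground-truth state log is authoritative instead.
DEFAULT_PAUSE_SPEED_MM_S = 0.1


@dataclass
class ResidenceSummary:
    fraction_inside: float
    fraction_visited: float
    distance_traveled: float
    pause_fraction: float
    per_larva: pd.DataFrame | None = None


def _inside_any_patch(traj: Trajectory, layout: PatchLayout) -> np.ndarray:
    pos = traj.positions
    inside = np.zeros(len(pos), dtype=bool)
    for patch in layout.patches:
        d2 = (pos[:, 0] - patch.center[0]) ** 2 + (pos[:, 1] - patch.center[1]) ** 2
        inside |= d2 <= patch.radius**2
    return inside


def fraction_time_inside(traj: Trajectory, layout: PatchLayout) -> float:
    """Fraction of frames whose centroid lies inside any patch (closed disc)."""
    if not layout.patches:
        raise InvalidLayoutError("layout has no patches")
    if traj.n_frames == 0:
        raise InsufficientDataError("empty trajectory")
    return float(np.mean(_inside_any_patch(traj, layout)))


def fraction_visited(traj: Trajectory, layout: PatchLayout, source_patch: int) -> float:
    """Distinct non-source patches entered, divided by (N_p - 1).

    The source patch is discounted because every run starts inside one.
    With a single patch the fraction is defined as 0.
    """
    n_p = layout.n_patches
    if not 0 <= source_patch < max(n_p, 1):
        raise InvalidArgumentError(f"source_patch {source_patch} out of range for {n_p} patches")
    if n_p < 2:
        return 0.0
    pos = traj.positions
    visited = 0
    for i, patch in enumerate(layout.patches):
        if i == source_patch:
            continue
        d2 = (pos[:, 0] - patch.center[0]) ** 2 + (pos[:, 1] - patch.center[1]) ** 2
        if np.any(d2 <= patch.radius**2):
            visited += 1
    return visited / (n_p - 1)


def distance_traveled(traj: Trajectory) -> float:
    """Total path length: sum of consecutive inter-frame displacements (mm)."""
    steps = np.diff(traj.positions, axis=0)
    return float(np.sum(np.linalg.norm(steps, axis=1)))


def pause_fraction(
    traj: Trajectory, speed_threshold: float = DEFAULT_PAUSE_SPEED_MM_S
) -> float:
    """Fraction of frames with scalar speed below the threshold.

    A threshold-based proxy for recorded-style tracks; simulated runs carry
    an exact state log (see :meth:`SimResult.state_fractions`).
    """
    if speed_threshold < 0:
        raise InvalidArgumentError("speed_threshold must be >= 0")
    k = kinematics(traj)
    speeds = k.speed[1:]  # first frame has no velocity
    return float(np.mean(speeds < speed_threshold))


def residence_summary(
    trajectories,
    layout: PatchLayout,
    source_patches=None,
    speed_threshold: float = DEFAULT_PAUSE_SPEED_MM_S,
) -> ResidenceSummary:
    """Per-larva table plus equal-weight means across larvae."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    rows = []
    for i, traj in enumerate(trajectories):
        src = source_patches[i] if source_patches is not None else 0
        rows.append(
            {
                "larva_id": traj.larva_id,
                "fraction_inside": fraction_time_inside(traj, layout),
                "fraction_visited": fraction_visited(traj, layout, src),
                "distance_traveled": distance_traveled(traj),
                "pause_fraction": pause_fraction(traj, speed_threshold),
            }
        )
    per_larva = pd.DataFrame(rows)
    return ResidenceSummary(
        fraction_inside=float(per_larva["fraction_inside"].mean()),
        fraction_visited=float(per_larva["fraction_visited"].mean()),
        distance_traveled=float(per_larva["distance_traveled"].mean()),
        pause_fraction=float(per_larva["pause_fraction"].mean()),
        per_larva=per_larva,
    )
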