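"""Tracker-style synthetic recordings with known ground truth.

The study's raw videos are not deposited, so every analysis stage is tested
against generated tracks that emulate the tracker output: piecewise-
ballistic crawl bouts at sampled speeds, instantaneous heading changes at
discrete turn events, frozen positions during pauses, and isotropic
Gaussian centroid jitter applied post hoc (a measurement-noise model — the
jitter never feeds back into the dynamics).

Two generators are provided: :func:`generate_recording` draws the motor
states stochastically with the same statistical structure as the simulator,
and :func:`track_from_schedule` builds a fully deterministic track from an
explicit list of turn frames and signed angles (the basis of exact
round-trip tests: at zero jitter, RDP recovers the scheduled corners to the
frame and the angles to numerical precision).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError
from .geometry import ArenaSpec, PatchLayout, fragment_radius, random_layout, total_food_area, two_patch_layout
from .kinematics import DEFAULT_DT_S, Trajectory, write_tracks
from .simulator import (
    SubstrateParams,
    TurnAngleModel,
    load_substrate_params,
    sample_speed,
    sample_turn_angle,
)

DEFAULT_JITTER_SD_MM = 0.1


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst must recover."""

    turn_times: list = field(default_factory=list)  # frame indices, increasing
    turn_angles: list = field(default_factory=list)  # signed radians
    pause_intervals: list = field(default_factory=list)  # [start, stop) frame pairs
    segment_speeds: list = field(default_factory=list)  # mm/s per crawl bout
    handedness_true: float = math.nan
    layout: PatchLayout | None = None

    def to_dict(self) -> dict:
        return {
            "turn_times": [int(t) for t in self.turn_times],
            "turn_angles": [float(a) for a in self.turn_angles],
            "pause_intervals": [[int(a), int(b)] for a, b in self.pause_intervals],
            "segment_speeds": [float(s) for s in self.segment_speeds],
            "handedness_true": self.handedness_true,
        }


def _true_handedness(angles) -> float:
    n_ccw = sum(1 for a in angles if a > 0)
    n_cw = sum(1 for a in angles if a < 0)
    return n_ccw / (n_ccw + n_cw) if (n_ccw + n_cw) else math.nan


def generate_recording(
    params,
    turn_model: TurnAngleModel,
    n_frames: int = 6000,
    jitter_sd: float = DEFAULT_JITTER_SD_MM,
    rng_seed: int = 0,
    dt: float = DEFAULT_DT_S,
    layout: PatchLayout | None = None,
    start: tuple | None = None,
    larva_id: str = "synthetic",
) -> tuple[Trajectory, GroundTruth]:
    """Stochastic tracker-style recording with complete ground truth.

    ``params`` is a single :class:`SubstrateParams` (homogeneous substrate)
    or a dict label -> params together with a ``layout`` (patchy substrate,
    parameters looked up under the current position).  Crawl-bout speeds are
    sampled once per bout; turns freeze the position for one frame while the
    heading rotates; jitter of sd ``jitter_sd`` (mm) is added at the end.
    """
    if n_frames < 2:
        raise InvalidArgumentError("n_frames must be >= 2")
    if jitter_sd < 0:
        raise InvalidArgumentError("jitter_sd must be >= 0")
    if isinstance(params, SubstrateParams):
        lookup = None
        homogeneous = params
    else:
        if layout is None:
            raise ConfigurationError("a substrate map requires a layout")
        lookup = dict(params)
        homogeneous = None

    rng = np.random.default_rng(rng_seed)
    arena = layout.arena if layout is not None else ArenaSpec()
    if start is not None:
        x, y = float(start[0]), float(start[1])
    elif layout is not None and layout.patches:
        patch = layout.patches[rng.integers(len(layout.patches))]
        r = patch.radius * math.sqrt(rng.random())
        a = rng.uniform(0.0, 2 * math.pi)
        x, y = patch.center[0] + r * math.cos(a), patch.center[1] + r * math.sin(a)
    else:
        x, y = arena.width / 2.0, arena.height / 2.0
    a0 = rng.uniform(0.0, 2 * math.pi)
    hx, hy = math.cos(a0), math.sin(a0)

    positions = np.empty((n_frames, 2))
    positions[0] = (x, y)
    truth = GroundTruth(layout=layout)
    bout_speed = None
    pause_start = None

    for j in range(1, n_frames):
        if lookup is not None:
            label = layout.outside_substrate
            for patch in layout.patches:
                if patch.contains((x, y)):
                    label = patch.substrate
                    break
            p = lookup[label]
        else:
            p = homogeneous
        pt, pp = p.per_step(dt)
        u = rng.random()
        if u < pt:  # turn: frozen frame, heading rotates
            ang = sample_turn_angle(turn_model, rng)
            ca, sa = math.cos(ang), math.sin(ang)
            hx, hy = ca * hx - sa * hy, sa * hx + ca * hy
            truth.turn_times.append(j)
            truth.turn_angles.append(ang)
            bout_speed = None
            if pause_start is not None:
                truth.pause_intervals.append((pause_start, j))
                pause_start = None
        elif u < pt + pp:  # pause
            if pause_start is None:
                pause_start = j
            bout_speed = None
        else:  # crawl
            if pause_start is not None:
                truth.pause_intervals.append((pause_start, j))
                pause_start = None
            if bout_speed is None:
                bout_speed = sample_speed(p, rng)
                truth.segment_speeds.append(bout_speed)
            nx, ny = x + hx * bout_speed * dt, y + hy * bout_speed * dt
            if 0.0 <= nx <= arena.width and 0.0 <= ny <= arena.height:
                x, y = nx, ny
            else:  # bounce back into the arena
                x = min(max(nx, 0.0), arena.width)
                y = min(max(ny, 0.0), arena.height)
                while True:
                    a = rng.uniform(0.0, 2 * math.pi)
                    chx, chy = math.cos(a), math.sin(a)
                    if (
                        0.0 <= x + chx * 1e-6 <= arena.width
                        and 0.0 <= y + chy * 1e-6 <= arena.height
                    ):
                        hx, hy = chx, chy
                        break
                bout_speed = None
        positions[j] = (x, y)

    if pause_start is not None:
        truth.pause_intervals.append((pause_start, n_frames))
    truth.handedness_true = _true_handedness(truth.turn_angles)
    if jitter_sd > 0:
        positions = positions + rng.normal(0.0, jitter_sd, positions.shape)
    traj = Trajectory.from_positions(positions, dt=dt, larva_id=larva_id)
    return traj, truth


def track_from_schedule(
    turn_times,
    turn_angles,
    n_frames: int,
    speed: float = 1.0,
    dt: float = DEFAULT_DT_S,
    start: tuple = (120.0, 120.0),
    initial_heading: float = 0.0,
    jitter_sd: float = 0.0,
    rng_seed: int = 0,
    larva_id: str = "scheduled",
) -> tuple[Trajectory, GroundTruth]:
    """Deterministic track from explicit turn frames and signed angles.

    A turn at frame t rotates the heading instantaneously at the corner
    point: the segment entering frame t follows the old heading and the
    segment leaving it the new one, with crawling at the fixed speed on
    every step.  With zero jitter the resulting polyline has its corners
    exactly at the scheduled frames, which is what makes exact round-trip
    tests possible.
    """
    turn_times = [int(t) for t in turn_times]
    turn_angles = [float(a) for a in turn_angles]
    if len(turn_times) != len(turn_angles):
        raise InvalidArgumentError("turn_times and turn_angles must have equal length")
    if any(t2 <= t1 for t1, t2 in zip(turn_times, turn_times[1:])):
        raise InvalidArgumentError("turn_times must be strictly increasing")
    if turn_times and not (1 <= turn_times[0] and turn_times[-1] <= n_frames - 2):
        raise InvalidArgumentError("turn frames must lie in [1, n_frames - 2]")

    schedule = dict(zip(turn_times, turn_angles))
    x, y = float(start[0]), float(start[1])
    hx, hy = math.cos(initial_heading), math.sin(initial_heading)
    positions = np.empty((n_frames, 2))
    positions[0] = (x, y)
    for j in range(1, n_frames):
        if j - 1 in schedule:  # rotate at the corner, then keep crawling
            ang = schedule[j - 1]
            ca, sa = math.cos(ang), math.sin(ang)
            hx, hy = ca * hx - sa * hy, sa * hx + ca * hy
        x += hx * speed * dt
        y += hy * speed * dt
        positions[j] = (x, y)
    if jitter_sd > 0:
        rng = np.random.default_rng(rng_seed)
        positions = positions + rng.normal(0.0, jitter_sd, positions.shape)
    truth = GroundTruth(
        turn_times=turn_times,
        turn_angles=turn_angles,
        segment_speeds=[speed],
        handedness_true=_true_handedness(turn_angles),
    )
    traj = Trajectory.from_positions(positions, dt=dt, larva_id=larva_id)
    return traj, truth


# ---------------------------------------------------------------------------
# Fixture suite


def make_fixture_suite(seed: int, out_dir) -> dict:
    """Write a deterministic set of fixture recordings and their ground truth.

    Covers homogeneous agar/sucrose/yeast statistics, two- and eight-patch
    layouts, and edge cases (all-pause, straight line, wall-hugging).  The
    same seed always produces byte-identical files.  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(8)]
    manifest: dict = {"seed": seed, "files": {}}

    def _write(name: str, traj: Trajectory, truth: GroundTruth) -> None:
        csv_path = out / f"{name}.csv"
        json_path = out / f"{name}.json"
        write_tracks(traj, csv_path)
        with open(json_path, "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)
        manifest["files"][name] = [csv_path.name, json_path.name]

    model = TurnAngleModel(mu=0.1, kappa=1.0)
    for i, substrate in enumerate(["agar", "sucrose", "yeast"]):
        params = load_substrate_params("rover", substrate)
        traj, truth = generate_recording(
            params, model, n_frames=3000, jitter_sd=DEFAULT_JITTER_SD_MM,
            rng_seed=seeds[i], larva_id=f"rover_{substrate}",
        )
        _write(f"homogeneous_{substrate}_rover", traj, truth)

    # patchy: yeast patches on agar, two-patch reference and an 8-patch layout
    two = two_patch_layout(substrate="yeast")
    pmap = {
        "yeast": load_substrate_params("rover", "yeast"),
        "agar": load_substrate_params("rover", "agar"),
    }
    traj, truth = generate_recording(
        pmap, model, n_frames=3000, layout=two, rng_seed=seeds[3], larva_id="two_patch"
    )
    _write("two_patch_yeast", traj, truth)

    r8 = fragment_radius(total_food_area(25.0), 8)
    eight = random_layout(ArenaSpec(), 8, r8, "yeast", rng_seed=seeds[4])
    traj, truth = generate_recording(
        pmap, model, n_frames=3000, layout=eight, rng_seed=seeds[5], larva_id="eight_patch"
    )
    _write("eight_patch_yeast", traj, truth)

    # edge cases
    still = Trajectory.from_positions(np.tile([120.0, 120.0], (600, 1)), larva_id="all_pause")
    _write("all_pause", still, GroundTruth(pause_intervals=[(0, 600)]))

    straight, straight_truth = track_from_schedule(
        [], [], n_frames=600, speed=0.8, start=(10.0, 120.0), larva_id="straight_line"
    )
    _write("straight_line", straight, straight_truth)

    hug, hug_truth = track_from_schedule(
        [200, 400], [math.pi / 2, math.pi / 2], n_frames=600, speed=1.0,
        start=(1.0, 1.0), initial_heading=0.0, larva_id="wall_hugging",
    )
    _write("wall_hugging", hug, hug_truth)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
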