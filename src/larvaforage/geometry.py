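"""Arena and food-patch geometry.

Coordinate frame: origin at the arena's lower-left corner, x to the right,
y up, all lengths in millimetres.  Points are continuous.  A patch is a
closed disc: a point at distance exactly R from the centre counts as inside.

The fragmentation helpers implement the area-conserving patch redesign used
throughout the package: the reference design places a total food area
S = 2*pi*R^2 (two discs of radius R) and redistributes it over N discs of
radius R' = sqrt(S / (N*pi)).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import (
    InvalidArgumentError,
    InvalidGeometryError,
    InvalidLayoutError,
    OutOfBoundsError,
    PackingFailureError,
)

# Reference experimental design: two 25-mm-radius patches, centres 120 mm
# apart on the arena midline.
DEFAULT_ARENA_SIDE_MM = 240.0
DEFAULT_PATCH_RADIUS_MM = 25.0
DEFAULT_TWO_PATCH_SEPARATION_MM = 120.0
N_REFERENCE_PATCHES = 2

#: Cap on rejection-sampling attempts per patch in :func:`random_layout`.
MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class ArenaSpec:
    """Rectangular arena with rigid boundaries (mm)."""

    width: float = DEFAULT_ARENA_SIDE_MM
    height: float = DEFAULT_ARENA_SIDE_MM

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise InvalidGeometryError(
                f"arena dimensions must be positive, got {self.width}x{self.height}"
            )

    def contains(self, point) -> bool:
        x, y = point
        return 0.0 <= x <= self.width and 0.0 <= y <= self.height


@dataclass(frozen=True)
class Patch:
    """Circular food patch: centre (mm), radius (mm), substrate label."""

    center: tuple[float, float]
    radius: float
    substrate: str = "yeast"

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise InvalidGeometryError(f"patch radius must be positive, got {self.radius}")

    def contains(self, point) -> bool:
        """Closed-disc membership test."""
        dx = point[0] - self.center[0]
        dy = point[1] - self.center[1]
        return dx * dx + dy * dy <= self.radius * self.radius


@dataclass
class PatchLayout:
    """An arena plus an ordered list of non-overlapping circular patches.

    Every point of the arena maps to exactly one substrate label; if a
    user-supplied layout overlaps, the first patch in list order wins.
    """

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    patches: list[Patch] = field(default_factory=list)
    outside_substrate: str = "agar"

    def __post_init__(self) -> None:
        for i, p in enumerate(self.patches):
            cx, cy = p.center
            if not (
                p.radius <= cx <= self.arena.width - p.radius
                and p.radius <= cy <= self.arena.height - p.radius
            ):
                raise InvalidGeometryError(
                    f"patch {i} (centre {p.center}, r={p.radius}) extends outside the arena"
                )

    @property
    def n_patches(self) -> int:
        return len(self.patches)


def total_food_area(radius: float, n_reference: int = N_REFERENCE_PATCHES) -> float:
    """Total food area S of ``n_reference`` discs of the given radius (mm^2)."""
    if not radius > 0:
        raise InvalidGeometryError(f"radius must be positive, got {radius}")
    return n_reference * math.pi * radius * radius


def fragment_radius(total_area: float, n_patches: int) -> float:
    """Radius R' = sqrt(S / (N*pi)) of N discs jointly covering ``total_area``."""
    if n_patches < 1:
        raise InvalidArgumentError(f"n_patches must be >= 1, got {n_patches}")
    if not total_area > 0:
        raise InvalidGeometryError(f"total_area must be positive, got {total_area}")
    return math.sqrt(total_area / (n_patches * math.pi))


def two_patch_layout(
    substrate: str = "yeast",
    radius: float = DEFAULT_PATCH_RADIUS_MM,
    separation: float = DEFAULT_TWO_PATCH_SEPARATION_MM,
    arena: ArenaSpec | None = None,
    outside_substrate: str = "agar",
) -> PatchLayout:
    """The fixed two-patch reference design.

    Centres sit symmetrically on the horizontal midline of the arena,
    ``separation`` mm apart (default 120 mm).
    """
    arena = arena or ArenaSpec()
    cx = arena.width / 2.0
    cy = arena.height / 2.0
    half = separation / 2.0
    patches = [
        Patch((cx - half, cy), radius, substrate),
        Patch((cx + half, cy), radius, substrate),
    ]
    return PatchLayout(arena=arena, patches=patches, outside_substrate=outside_substrate)


def random_layout(
    arena: ArenaSpec,
    n_patches: int,
    radius: float,
    substrate: str,
    rng_seed: int,
    outside_substrate: str = "agar",
) -> PatchLayout:
    """Place ``n_patches`` disjoint discs uniformly at random inside the arena.

    Rejection sampling with a cap of :data:`MAX_PLACEMENT_ATTEMPTS` attempts
    per patch; reproducible for a fixed ``rng_seed``.
    """
    if not radius > 0:
        raise InvalidGeometryError(f"radius must be positive, got {radius}")
    if n_patches < 1:
        raise InvalidArgumentError(f"n_patches must be >= 1, got {n_patches}")
    lo_x, hi_x = radius, arena.width - radius
    lo_y, hi_y = radius, arena.height - radius
    if lo_x > hi_x or lo_y > hi_y:
        raise PackingFailureError(
            f"a disc of radius {radius} does not fit in a "
            f"{arena.width}x{arena.height} arena"
        )
    rng = np.random.default_rng(rng_seed)
    centers: list[tuple[float, float]] = []
    min_sep_sq = (2.0 * radius) ** 2
    for i in range(n_patches):
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            if all((cx - ox) ** 2 + (cy - oy) ** 2 > min_sep_sq for ox, oy in centers):
                centers.append((cx, cy))
                break
        else:
            raise PackingFailureError(
                f"failed to place patch {i + 1}/{n_patches} after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    patches = [Patch(c, radius, substrate) for c in centers]
    return PatchLayout(arena=arena, patches=patches, outside_substrate=outside_substrate)


def substrate_at(layout: PatchLayout, point) -> str:
    """Substrate label at a point: first containing patch, else the outside label."""
    if not layout.arena.contains(point):
        raise OutOfBoundsError(f"point {tuple(point)} lies outside the arena")
    for patch in layout.patches:
        if patch.contains(point):
            return patch.substrate
    return layout.outside_substrate


def nearest_patch(layout: PatchLayout, point) -> tuple[Patch, float]:
    """Patch whose centre is closest to ``point``, with that distance (mm).

    Ties break to the lowest-index patch.
    """
    if not layout.patches:
        raise InvalidLayoutError("layout has no patches")
    best_i = 0
    best_d2 = math.inf
    x, y = point
    for i, patch in enumerate(layout.patches):
        d2 = (x - patch.center[0]) ** 2 + (y - patch.center[1]) ** 2
        if d2 < best_d2:
            best_d2 = d2
            best_i = i
    return layout.patches[best_i], math.sqrt(best_d2)


# ---------------------------------------------------------------------------
# Serialization


def layout_to_dict(layout: PatchLayout) -> dict:
    return {
        "arena": {"width": layout.arena.width, "height": layout.arena.height},
        "patches": [
            {"cx": p.center[0], "cy": p.center[1], "r": p.radius, "substrate": p.substrate}
            for p in layout.patches
        ],
        "outside": layout.outside_substrate,
    }


def layout_from_dict(d: dict) -> PatchLayout:
    arena = ArenaSpec(d["arena"]["width"], d["arena"]["height"])
    patches = [Patch((p["cx"], p["cy"]), p["r"], p["substrate"]) for p in d["patches"]]
    return PatchLayout(arena=arena, patches=patches, outside_substrate=d.get("outside", "agar"))


def save_layout(layout: PatchLayout, path) -> None:
    """Write a layout as JSON (``.json``) or YAML (anything else)."""
    d = layout_to_dict(layout)
    text = json.dumps(d, indent=2) if str(path).endswith(".json") else yaml.safe_dump(d)
    with open(path, "w") as fh:
        fh.write(text)


def load_layout(path) -> PatchLayout:
    with open(path) as fh:
        text = fh.read()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return layout_from_dict(d)
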