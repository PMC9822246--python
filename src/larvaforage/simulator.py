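"""Phenomenological crawl/turn/pause model of larval foraging.

At every time step (dt = 0.5 s) a simulated larva is in exactly one of three
motor states, drawn with constant per-step probabilities:

* crawl (probability 1 - P_turn*dt - P_pause*dt): advance along the current
  heading with a speed freshly sampled from a normal distribution truncated
  to v > 0;
* turn (probability P_turn*dt): rotate the heading by an angle sampled from
  a von Mises distribution, with no translation this step;
* pause (probability P_pause*dt): no translation, heading preserved.

Motor parameters (mean/sd speed, turn and pause rates) depend on the
substrate under the larva's current position, so in a patchy arena the food
parameters apply inside patches and the agar parameters outside.  Each
larva carries its own von Mises turning-angle model, capturing individual
handedness.  Optionally, turn directions are biased toward the nearest
patch centre with a distance-binned probability Pbias (zero beyond a 60 mm
cutoff): after drawing a turning magnitude, the left/right candidate whose
resulting movement vector makes the smaller angle with the vector toward
the patch centre is taken with probability Pbias, the other candidate
otherwise.  When the fixed total food area S = 2*pi*R^2 is fragmented into
N patches of radius R' = sqrt(S/(N*pi)), bias-profile distances rescale by
R'/R.

The arena has rigid boundaries: a crawl step that would exit is truncated
at the wall and the heading is re-sampled uniformly into the interior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError, InvalidArgumentError
from .geometry import PatchLayout, nearest_patch, two_patch_layout
from .kinematics import DEFAULT_DT_S, Trajectory
from .turns import TurnEvent

DEFAULT_N_STEPS = 6000  # 50 min at 2 frames/s

# Default stand-in for per-larva turning individuality: mu drawn once per
# larva from U(-MU_HALF_RANGE, MU_HALF_RANGE), fixed concentration kappa.
DEFAULT_MU_HALF_RANGE_RAD = 0.3
DEFAULT_KAPPA = 1.0

_TWO_PI = 2.0 * math.pi

CRAWL, TURN, PAUSE = 0, 1, 2
STATE_NAMES = {CRAWL: "crawl", TURN: "turn", PAUSE: "pause"}


@dataclass(frozen=True)
class SubstrateParams:
    """Motor parameters of one (genotype, substrate) combination.

    Speeds in mm/s; ``p_turn_per_s`` and ``p_pause_per_s`` are per-second
    event probabilities, converted to per-step probabilities by multiplying
    with dt.
    """

    mean_v: float
    sd_v: float
    p_turn_per_s: float
    p_pause_per_s: float

    def __post_init__(self) -> None:
        if not self.mean_v > 0:
            raise ConfigurationError(f"mean_v must be positive, got {self.mean_v}")
        if self.sd_v < 0:
            raise ConfigurationError(f"sd_v must be non-negative, got {self.sd_v}")
        if self.p_turn_per_s < 0 or self.p_pause_per_s < 0:
            raise ConfigurationError("event probabilities must be non-negative")

    def per_step(self, dt: float) -> tuple[float, float]:
        """(P_turn, P_pause) per step of length dt; their sum must be <= 1."""
        pt = self.p_turn_per_s * dt
        pp = self.p_pause_per_s * dt
        if pt + pp > 1.0 + 1e-12:
            raise ConfigurationError(
                f"P_turn*dt + P_pause*dt = {pt + pp:.3f} exceeds 1 at dt={dt}"
            )
        return pt, pp


@dataclass(frozen=True)
class TurnAngleModel:
    """Per-larva von Mises turning-angle distribution (mu in rad, kappa >= 0)."""

    mu: float = 0.0
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ConfigurationError(f"kappa must be >= 0, got {self.kappa}")


@dataclass(frozen=True)
class BiasProfile:
    """Distance-binned probability of turning toward the nearest patch centre.

    ``bin_edges`` (mm, ascending, half-open bins [e_i, e_{i+1})) with one
    probability per bin; beyond ``cutoff`` no bias is applied.
    """

    bin_edges: tuple
    p_bias: tuple
    cutoff: float = 60.0

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.bin_edges)
        probs = tuple(float(p) for p in self.p_bias)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "p_bias", probs)
        if len(edges) != len(probs) + 1:
            raise ConfigurationError("bin_edges must have one more entry than p_bias")
        if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
            raise ConfigurationError("bin_edges must be strictly increasing")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("bias probabilities must lie in [0, 1]")

    def pbias_at(self, distance: float) -> float:
        """Pbias at a distance from the patch centre; 0 beyond the cutoff."""
        if distance > self.cutoff or distance < self.bin_edges[0]:
            return 0.0
        for i in range(len(self.p_bias)):
            if self.bin_edges[i] <= distance < self.bin_edges[i + 1]:
                return self.p_bias[i]
        return 0.0

    @classmethod
    def zero(cls) -> "BiasProfile":
        return cls(bin_edges=(0.0, 60.0), p_bias=(0.0,), cutoff=60.0)


def scale_bias_profile(bias: BiasProfile, r_new: float, r_ref: float) -> BiasProfile:
    """Rescale all distances in a bias profile by r_new / r_ref.

    Used for patch fragmentation: probabilities are unchanged, bin edges and
    cutoff shrink with the patch radius.
    """
    if not (r_new > 0 and r_ref > 0):
        raise InvalidArgumentError("radii must be positive")
    f = r_new / r_ref
    return BiasProfile(
        bin_edges=tuple(e * f for e in bias.bin_edges),
        p_bias=bias.p_bias,
        cutoff=bias.cutoff * f,
    )


@dataclass
class SimConfig:
    """Everything one simulation run needs.

    ``params_by_substrate`` maps each substrate label appearing in the layout
    (including the outside label) to its :class:`SubstrateParams`.  If
    ``start_point`` is None the larva starts uniformly inside a uniformly
    chosen patch (or uniformly in the arena when there are no patches), with
    a heading uniform on the circle.
    """

    layout: PatchLayout
    params_by_substrate: dict
    turn_model: TurnAngleModel = field(default_factory=TurnAngleModel)
    bias: BiasProfile | None = None
    dt: float = DEFAULT_DT_S
    n_steps: int = DEFAULT_N_STEPS
    seed: int = 0
    start_point: tuple | None = None

    def validate(self) -> None:
        if not self.dt > 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 1:
            raise ConfigurationError(f"n_steps must be >= 1, got {self.n_steps}")
        labels = {p.substrate for p in self.layout.patches}
        labels.add(self.layout.outside_substrate)
        missing = labels - set(self.params_by_substrate)
        if missing:
            raise ConfigurationError(f"no parameters for substrates: {sorted(missing)}")
        for params in self.params_by_substrate.values():
            params.per_step(self.dt)  # raises if probabilities exceed 1
        if self.start_point is not None and not self.layout.arena.contains(self.start_point):
            raise ConfigurationError(f"start point {self.start_point} outside arena")


@dataclass
class SimResult:
    """Simulated track plus ground truth."""

    trajectory: Trajectory
    state_log: np.ndarray  # int8 per step: 0 crawl, 1 turn, 2 pause
    turn_log: list  # list[TurnEvent], ground truth

    def state_fractions(self) -> dict:
        n = len(self.state_log)
        return {
            name: float(np.sum(self.state_log == code)) / n
            for code, name in STATE_NAMES.items()
        }


# ---------------------------------------------------------------------------
# Elementary draws


def step_state(params: SubstrateParams, dt: float, rng) -> str:
    """Draw one motor state: 'turn', 'pause' or 'crawl' (mutually exclusive)."""
    pt, pp = params.per_step(dt)
    u = rng.random()
    if u < pt:
        return "turn"
    if u < pt + pp:
        return "pause"
    return "crawl"


def sample_speed(params: SubstrateParams, rng) -> float:
    """Crawl speed ~ Normal(mean_v, sd_v) truncated to > 0 by resampling."""
    while True:
        v = rng.normal(params.mean_v, params.sd_v)
        if v > 0:
            return v


def sample_turn_angle(model: TurnAngleModel, rng) -> float:
    """Von Mises turning angle wrapped to [-pi, pi]."""
    a = rng.vonmises(model.mu, model.kappa) if model.kappa > 0 else rng.uniform(-math.pi, math.pi)
    return (a + math.pi) % _TWO_PI - math.pi


def choose_turn_direction(
    magnitude: float,
    position,
    heading,
    layout: PatchLayout,
    bias: BiasProfile,
    rng,
) -> float:
    """Signed turning angle after applying the inward-turn bias.

    The two candidate post-turn headings rotate the current heading by
    +|magnitude| (left) and -|magnitude| (right).  The inward candidate is
    the one whose movement vector makes the smaller angle with
    u = P - position (P the nearest patch centre); it is returned with
    probability Pbias(d), the other candidate otherwise.  Beyond the bias
    cutoff — or at the patch centre, where u degenerates — the originally
    signed magnitude is returned unchanged.
    """
    patch, d = nearest_patch(layout, position)
    pb = bias.pbias_at(d)
    if pb <= 0.0:
        return magnitude
    ux = patch.center[0] - position[0]
    uy = patch.center[1] - position[1]
    if ux == 0.0 and uy == 0.0:
        return magnitude
    mag = abs(magnitude)
    ca, sa = math.cos(mag), math.sin(mag)
    hx, hy = heading
    # candidate headings: rotate by +mag (CCW) and -mag (CW)
    lx, ly = ca * hx - sa * hy, sa * hx + ca * hy
    rx, ry = ca * hx + sa * hy, -sa * hx + ca * hy
    un = math.hypot(ux, uy)
    cos_left = (lx * ux + ly * uy) / un
    cos_right = (rx * ux + ry * uy) / un
    if cos_left == cos_right:  # exactly radial: no inward option
        return magnitude
    inward_sign = 1.0 if cos_left > cos_right else -1.0
    if rng.random() < pb:
        return inward_sign * mag
    return -inward_sign * mag


# ---------------------------------------------------------------------------
# The simulation loop


def _uniform_point_in_patch(patch, rng) -> tuple[float, float]:
    r = patch.radius * math.sqrt(rng.random())
    a = rng.uniform(0.0, _TWO_PI)
    return (patch.center[0] + r * math.cos(a), patch.center[1] + r * math.sin(a))


class _NormalBuffer:
    """Block-drawn standard normals consumed one at a time (deterministic)."""

    def __init__(self, rng, block: int):
        self._rng = rng
        self._block = block
        self._buf = rng.standard_normal(block)
        self._i = 0

    def next(self) -> float:
        if self._i >= self._block:
            self._buf = self._rng.standard_normal(self._block)
            self._i = 0
        v = self._buf[self._i]
        self._i += 1
        return v


def simulate(config: SimConfig, rng=None) -> SimResult:
    """Run one larva for ``config.n_steps`` steps; fully seed-reproducible.

    Substrate parameters are looked up at the larva's current position every
    step.  Turn events are logged as ground truth, including the inward /
    outward label of the chosen candidate when patches exist.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.dt
    n_steps = config.n_steps
    layout = config.layout
    arena_w, arena_h = layout.arena.width, layout.arena.height
    model = config.turn_model
    bias = config.bias

    # flat per-substrate lookup: label -> (pt_step, pp_step, mean_v, sd_v)
    tab = {}
    for label, params in config.params_by_substrate.items():
        pt, pp = params.per_step(dt)
        tab[label] = (pt, pp, params.mean_v, params.sd_v)
    patch_data = [
        (p.center[0], p.center[1], p.radius * p.radius, p.substrate) for p in layout.patches
    ]
    outside = layout.outside_substrate

    # initial position and heading
    if config.start_point is not None:
        x, y = float(config.start_point[0]), float(config.start_point[1])
    elif patch_data:
        patch = layout.patches[rng.integers(len(patch_data))]
        x, y = _uniform_point_in_patch(patch, rng)
    else:
        x = rng.uniform(0.0, arena_w)
        y = rng.uniform(0.0, arena_h)
    a0 = rng.uniform(0.0, _TWO_PI)
    hx, hy = math.cos(a0), math.sin(a0)

    state_u = rng.random(n_steps)  # one pre-drawn uniform per step
    normals = _NormalBuffer(rng, max(n_steps, 256))

    positions = np.empty((n_steps + 1, 2))
    positions[0] = (x, y)
    state_log = np.empty(n_steps, dtype=np.int8)
    turn_log: list[TurnEvent] = []

    for k in range(n_steps):
        # substrate under the current position (first containing patch wins)
        label = outside
        for cx, cy, r2, sub in patch_data:
            dx = x - cx
            dy = y - cy
            if dx * dx + dy * dy <= r2:
                label = sub
                break
        pt, pp, mean_v, sd_v = tab[label]

        u = state_u[k]
        if u < pt:
            # ---- turn: rotate heading, no translation
            mag = sample_turn_angle(model, rng)
            if bias is not None and patch_data:
                ang = choose_turn_direction(mag, (x, y), (hx, hy), layout, bias, rng)
            else:
                ang = mag
            ca, sa = math.cos(ang), math.sin(ang)
            nhx = ca * hx - sa * hy
            nhy = sa * hx + ca * hy
            direction = "CCW" if ang > 0 else ("CW" if ang < 0 else "none")
            orientation = "unclassified"
            dist = math.nan
            if patch_data:
                patch, dist = nearest_patch(layout, (x, y))
                ux = patch.center[0] - x
                uy = patch.center[1] - y
                un = math.hypot(ux, uy)
                if un > 0:
                    chosen = nhx * ux + nhy * uy
                    # alternative candidate: rotation by -ang
                    ax_, ay_ = ca * hx + sa * hy, -sa * hx + ca * hy
                    alt = ax_ * ux + ay_ * uy
                    if chosen > alt:
                        orientation = "inward"
                    elif chosen < alt:
                        orientation = "outward"
            turn_log.append(
                TurnEvent(
                    vertex_index=k,
                    location=(x, y),
                    angle=ang,
                    direction=direction,
                    orientation=orientation,
                    distance_to_center=dist,
                )
            )
            hx, hy = nhx, nhy
            state_log[k] = TURN
        elif u < pt + pp:
            # ---- pause: frozen in place
            state_log[k] = PAUSE
        else:
            # ---- crawl
            while True:
                v = mean_v + sd_v * normals.next()
                if v > 0:
                    break
            dx = hx * v * dt
            dy = hy * v * dt
            nx, ny = x + dx, y + dy
            if 0.0 <= nx <= arena_w and 0.0 <= ny <= arena_h:
                x, y = nx, ny
            else:
                # truncate the step at the wall, then point back inside
                t = 1.0
                if dx > 0:
                    t = min(t, (arena_w - x) / dx)
                elif dx < 0:
                    t = min(t, -x / dx)
                if dy > 0:
                    t = min(t, (arena_h - y) / dy)
                elif dy < 0:
                    t = min(t, -y / dy)
                t = max(t, 0.0)
                x = min(max(x + dx * t, 0.0), arena_w)
                y = min(max(y + dy * t, 0.0), arena_h)
                eps = 1e-6
                while True:
                    a = rng.uniform(0.0, _TWO_PI)
                    chx, chy = math.cos(a), math.sin(a)
                    if (
                        0.0 <= x + chx * eps <= arena_w
                        and 0.0 <= y + chy * eps <= arena_h
                    ):
                        hx, hy = chx, chy
                        break
            state_log[k] = CRAWL
        positions[k + 1] = (x, y)

    traj = Trajectory.from_positions(positions, dt=dt, larva_id=f"sim-{config.seed}")
    return SimResult(trajectory=traj, state_log=state_log, turn_log=turn_log)


# ---------------------------------------------------------------------------
# Cohort experiments


def draw_turn_models(
    n_larvae: int,
    rng,
    mu_half_range: float = DEFAULT_MU_HALF_RANGE_RAD,
    kappa: float = DEFAULT_KAPPA,
) -> list[TurnAngleModel]:
    """Per-larva turning individuality: mu ~ U(-mu_half_range, +mu_half_range)."""
    return [
        TurnAngleModel(mu=float(rng.uniform(-mu_half_range, mu_half_range)), kappa=kappa)
        for _ in range(n_larvae)
    ]


def residence_ensemble(
    inside_params: SubstrateParams,
    outside_params: SubstrateParams,
    *,
    layout: PatchLayout | None = None,
    bias: BiasProfile | None = None,
    n_larvae: int = 30,
    n_runs: int = 30,
    n_steps: int = DEFAULT_N_STEPS,
    dt: float = DEFAULT_DT_S,
    seed: int = 0,
    mu_half_range: float = DEFAULT_MU_HALF_RANGE_RAD,
    kappa: float = DEFAULT_KAPPA,
) -> np.ndarray:
    """Patch-residence experiment: per-larva mean fraction of time inside.

    Each of ``n_larvae`` larvae gets its own turning-angle model and is
    simulated ``n_runs`` times (fresh layout start each run, always inside a
    patch); the fraction of frames inside any patch is averaged over runs.
    Returns an array of length ``n_larvae``.  The default layout is the
    two-patch 25 mm reference design with food patches on agar.
    """
    from .metrics import fraction_time_inside

    if layout is None:
        layout = two_patch_layout(substrate="food")
    params = {layout.outside_substrate: outside_params}
    for p in layout.patches:
        params[p.substrate] = inside_params

    ss = np.random.SeedSequence(seed)
    larva_seeds = ss.spawn(n_larvae)
    fractions = np.empty(n_larvae)
    for i, child in enumerate(larva_seeds):
        rng_i = np.random.default_rng(child)
        model = TurnAngleModel(
            mu=float(rng_i.uniform(-mu_half_range, mu_half_range)), kappa=kappa
        )
        run_fracs = np.empty(n_runs)
        for j, run_seed in enumerate(child.spawn(n_runs)):
            config = SimConfig(
                layout=layout,
                params_by_substrate=params,
                turn_model=model,
                bias=bias,
                dt=dt,
                n_steps=n_steps,
            )
            result = simulate(config, rng=np.random.default_rng(run_seed))
            run_fracs[j] = fraction_time_inside(result.trajectory, layout)
        fractions[i] = run_fracs.mean()
    return fractions


# ---------------------------------------------------------------------------
# Packaged parameter tables and bias-profile I/O


def _load_yaml_resource(name: str) -> dict:
    with resources.files("larvaforage.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_substrate_params(genotype: str, substrate: str) -> SubstrateParams:
    """Motor parameters measured in homogeneous substrates (predictive model)."""
    table = _load_yaml_resource("homogeneous_params.yaml")
    try:
        d = table["params"][genotype][substrate]
    except KeyError as exc:
        raise ConfigurationError(f"no parameters for ({genotype}, {substrate})") from exc
    return SubstrateParams(**d)


def load_corrected_params(genotype: str, substrate: str) -> tuple[SubstrateParams, SubstrateParams]:
    """(inside, outside) parameters measured in patchy substrates (corrected model)."""
    table = _load_yaml_resource("patchy_params.yaml")
    try:
        d = table["params"][genotype][substrate]
    except KeyError as exc:
        raise ConfigurationError(f"no parameters for ({genotype}, {substrate})") from exc
    return SubstrateParams(**d["inside"]), SubstrateParams(**d["outside"])


def load_bias_profile(path) -> BiasProfile:
    """Read a bias-profile YAML: bin_edges, p_bias, cutoff_mm."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return BiasProfile(
        bin_edges=tuple(d["bin_edges"]),
        p_bias=tuple(d["p_bias"]),
        cutoff=float(d.get("cutoff_mm", 60.0)),
    )


def example_bias_profile() -> BiasProfile:
    """The packaged synthetic example profile (illustrative, not measured)."""
    with resources.files("larvaforage.data").joinpath("bias_example.yaml").open() as fh:
        d = yaml.safe_load(fh)
    return BiasProfile(
        bin_edges=tuple(d["bin_edges"]),
        p_bias=tuple(d["p_bias"]),
        cutoff=float(d.get("cutoff_mm", 60.0)),
    )
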