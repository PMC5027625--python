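"""Correlated-random-walk motion of oriented squares in a bounded arena.

The stimulus world is a set of square "prey" items moving at constant speed
inside a central arena on the screen.  Each frame, a square's heading is
incremented by a draw from a wrapped normal (circular Gaussian) distribution
with mean zero and standard deviation ``turn_sd``; the square then advances by
``speed / frame_rate`` pixels along the new heading.  Orientation is locked to
heading, which is what lets striped coloration be defined relative to motion.

Coordinates: origin at the top-left of the screen, x rightward, y downward,
positions continuous (sub-pixel).  Heading 0 points rightward; positive
headings rotate clockwise on screen.  Containment is by specular reflection:
a step that would carry a square's center out of the (inset) arena has the
offending displacement component mirrored, so speed is conserved exactly at
every frame, including boundary frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArenaSpec",
    "MotionParams",
    "AgentState",
    "Track",
    "wrap_angle",
    "sample_turn",
    "step",
    "init_agents",
    "simulate_tracks",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angle(s) into [-pi, pi)."""
    return (np.asarray(theta) + np.pi) % TWO_PI - np.pi


@dataclass(frozen=True)
class ArenaSpec:
    """Screen and arena geometry, in pixels.

    The arena is centered on the screen.  Agent *centers* are confined to the
    arena rectangle inset by ``square_size / 2`` so the square body never
    leaves the arena.
    """

    screen_w: int = 1024
    screen_h: int = 768
    arena_w: int = 268
    arena_h: int = 268
    square_size: int = 32

    def __post_init__(self) -> None:
        if self.square_size <= 0:
            raise ValueError("square_size must be positive")
        if self.arena_w < self.square_size or self.arena_h < self.square_size:
            raise ValueError("arena must be at least one square wide")
        if self.arena_w > self.screen_w or self.arena_h > self.screen_h:
            raise ValueError("arena must fit inside the screen")

    @property
    def x_bounds(self) -> tuple[float, float]:
        """Allowed x range for agent centers (arena inset by half a square)."""
        left = (self.screen_w - self.arena_w) / 2.0
        half = self.square_size / 2.0
        return (left + half, left + self.arena_w - half)

    @property
    def y_bounds(self) -> tuple[float, float]:
        top = (self.screen_h - self.arena_h) / 2.0
        half = self.square_size / 2.0
        return (top + half, top + self.arena_h - half)

    def contains(self, x, y) -> bool:
        xlo, xhi = self.x_bounds
        ylo, yhi = self.y_bounds
        return bool(np.all((x >= xlo) & (x <= xhi) & (y >= ylo) & (y <= yhi)))


@dataclass(frozen=True)
class MotionParams:
    """Kinematics of the correlated random walk.

    speed        pixels/second (default 200)
    frame_rate   frames/second (default 100)
    turn_sd      SD of the per-frame wrapped-normal heading increment, radians
                 (default pi/8)
    duration_ms  trial length in milliseconds (default 5000)
    """

    speed: float = 200.0
    frame_rate: float = 100.0
    turn_sd: float = np.pi / 8
    duration_ms: float = 5000.0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.turn_sd < 0:
            raise ValueError("turn_sd must be non-negative")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")

    @property
    def step_px(self) -> float:
        """Per-frame displacement magnitude in pixels."""
        return self.speed / self.frame_rate

    @property
    def frame_count(self) -> int:
        """Number of per-frame states in a trial (one per frame tick)."""
        return int(round(self.duration_ms * self.frame_rate / 1000.0))


@dataclass(frozen=True)
class AgentState:
    """Continuous center position and heading of one square."""

    x: float
    y: float
    heading: float


@dataclass
class Track:
    """Per-frame states of one agent over a trial.

    ``x``, ``y``, ``heading`` are arrays of length ``frame_count``; entry 0 is
    the initial state and entry k the state after k steps.  ``reflected[k]``
    marks frames whose step hit an arena wall (the initial frame is False).
    Frame k occurs at time ``k / frame_rate`` seconds.
    """

    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    reflected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.reflected is None:
            self.reflected = np.zeros(len(self.x), dtype=bool)

    def __len__(self) -> int:
        return len(self.x)

    @property
    def positions(self) -> np.ndarray:
        """(frame_count, 2) array of center positions."""
        return np.column_stack([self.x, self.y])

    def state(self, frame: int) -> AgentState:
        return AgentState(float(self.x[frame]), float(self.y[frame]),
                          float(self.heading[frame]))


def sample_turn(rng: np.random.Generator, turn_sd: float, size=None):
    """Draw heading increment(s) from a wrapped normal(0, turn_sd).

    The unwrapped normal draw is wrapped into [-pi, pi); for ``turn_sd`` well
    below pi the wrap is a no-op in practice but it is always applied.  With
    ``turn_sd = 0`` the increment is exactly zero.
    """
    if turn_sd < 0:
        raise ValueError("turn_sd must be non-negative")
    draw = rng.normal(0.0, turn_sd, size=size)
    return wrap_angle(draw) if size is not None else float(wrap_angle(draw))


def _reflect_displacement(x, y, dx, dy, arena: ArenaSpec):
    """Mirror displacement components that would exit the arena.

    Returns (dx, dy, reflected) with the same magnitude as the input
    displacement.  Scalar or array inputs.  Assumes the step length is small
    relative to the arena so one mirror per axis suffices.
    """
    xlo, xhi = arena.x_bounds
    ylo, yhi = arena.y_bounds
    nx, ny = x + dx, y + dy
    flip_x = (nx < xlo) | (nx > xhi)
    flip_y = (ny < ylo) | (ny > yhi)
    dx = np.where(flip_x, -dx, dx)
    dy = np.where(flip_y, -dy, dy)
    return dx, dy, flip_x | flip_y


def step(state: AgentState, params: MotionParams, arena: ArenaSpec,
         rng: np.random.Generator) -> AgentState:
    """Advance one agent by one frame.

    The heading update precedes displacement, so even the first step of a
    trial is already correlated with the initial heading.  If the proposed
    step exits the arena the offending displacement component is mirrored
    (specular reflection) and the heading re-derived from the final
    displacement; speed is conserved exactly.
    """
    if not arena.contains(state.x, state.y):
        raise ValueError("agent state lies outside the arena")
    heading = wrap_angle(state.heading + sample_turn(rng, params.turn_sd))
    d = params.step_px
    dx, dy = d * np.cos(heading), d * np.sin(heading)
    dx, dy, refl = _reflect_displacement(state.x, state.y, dx, dy, arena)
    if refl and d > 0:
        heading = wrap_angle(np.arctan2(dy, dx))
    return AgentState(float(state.x + dx), float(state.y + dy), float(heading))


def init_agents(n: int, arena: ArenaSpec, rng: np.random.Generator) -> list[AgentState]:
    """Place n agents uniformly in the arena interior with uniform headings."""
    if n < 1:
        raise ValueError("need at least one agent")
    xlo, xhi = arena.x_bounds
    ylo, yhi = arena.y_bounds
    # Soft capacity guard: total square area must fit in the arena area.
    capacity = int((arena.arena_w * arena.arena_h) // (arena.square_size ** 2))
    if n > capacity:
        raise ValueError(f"{n} agents exceed arena capacity {capacity}")
    xs = rng.uniform(xlo, xhi, size=n)
    ys = rng.uniform(ylo, yhi, size=n)
    hs = rng.uniform(-np.pi, np.pi, size=n)
    return [AgentState(float(x), float(y), float(h)) for x, y, h in zip(xs, ys, hs)]


def simulate_tracks(n: int, params: MotionParams, arena: ArenaSpec,
                    seed) -> list[Track]:
    """Simulate n independent correlated-random-walk tracks.

    Each agent turns from its own seeded stream (spawned from ``seed``), so
    agent i's turning sequence does not depend on how many other agents are
    present.  Returns one Track per agent, each with ``params.frame_count``
    states (the initial state plus ``frame_count - 1`` steps).
    """
    if n < 1:
        raise ValueError("need at least one agent")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_ss, *agent_ss = ss.spawn(n + 1)
    agents = init_agents(n, arena, np.random.default_rng(init_ss))

    frames = params.frame_count
    d = params.step_px
    x = np.empty((frames, n))
    y = np.empty((frames, n))
    h = np.empty((frames, n))
    refl = np.zeros((frames, n), dtype=bool)
    x[0] = [a.x for a in agents]
    y[0] = [a.y for a in agents]
    h[0] = [a.heading for a in agents]

    # Pre-draw each agent's turn stream from its own generator.
    turns = np.column_stack([
        sample_turn(np.random.default_rng(s), params.turn_sd, size=frames - 1)
        for s in agent_ss
    ]) if frames > 1 else np.empty((0, n))

    for k in range(1, frames):
        heading = wrap_angle(h[k - 1] + turns[k - 1])
        dx, dy = d * np.cos(heading), d * np.sin(heading)
        dx, dy, flipped = _reflect_displacement(x[k - 1], y[k - 1], dx, dy, arena)
        if d > 0:
            heading = np.where(flipped, wrap_angle(np.arctan2(dy, dx)), heading)
        x[k] = x[k - 1] + dx
        y[k] = y[k - 1] + dy
        h[k] = heading
        refl[k] = flipped

    return [Track(x[:, i].copy(), y[:, i].copy(), h[:, i].copy(), refl[:, i].copy())
            for i in range(n)]
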