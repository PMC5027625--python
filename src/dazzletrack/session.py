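"""Session schedules and end-to-end trial execution.

A session crosses 3 target colorations with 2 backgrounds into 6 blocks,
presented in seeded random order.  Within a block, each of the 7 group sizes
(1, 10, 20, 30, 40, 50, 60 squares) appears ``reps_per_size`` times in seeded
random order; with the default 8 repetitions a session is 336 scored trials,
preceded by 4 practice trials that are flagged and excluded from analysis.

A trial simulates ``group_size`` correlated-random-walk tracks, designates a
seeded-random target (the square that would be highlighted for the first
1000 ms), lets the mechanistic observer produce a cursor trace, and scores
the mean cursor-to-target distance over the final 4000 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import ErrorWindow, tracking_error
from .models import BACKGROUNDS, COLORATIONS, GROUP_SIZES
from .motion import ArenaSpec, MotionParams, Track, simulate_tracks
from .observer import ObserverParams, cursor_agent

__all__ = [
    "TrialSpec",
    "SessionSchedule",
    "TrialResult",
    "build_schedule",
    "run_trial",
    "run_session",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ["participant", "block", "block_order", "trial", "coloration",
                 "background", "group_size", "target_index", "error_px",
                 "log_error", "seed", "practice"]


@dataclass(frozen=True)
class TrialSpec:
    """One trial's condition and timing."""

    coloration: str
    background: str
    group_size: int
    highlight_ms: float = 1000.0
    duration_ms: float = 5000.0
    sample_interval_ms: float = 10.0
    seed: int = 0
    practice: bool = False

    def __post_init__(self) -> None:
        if self.coloration not in COLORATIONS:
            raise ValueError(f"unknown coloration {self.coloration!r}")
        if self.background not in BACKGROUNDS:
            raise ValueError(f"unknown background {self.background!r}")
        if self.group_size < 1:
            raise ValueError("group_size must be at least 1")
        if not np.isclose(self.duration_ms % self.sample_interval_ms, 0):
            raise ValueError("sample interval must divide the trial duration")

    @property
    def window(self) -> ErrorWindow:
        """Scored window: everything after the highlight period."""
        return ErrorWindow(self.highlight_ms, self.duration_ms,
                           self.sample_interval_ms)


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered blocks of trials for one participant.

    ``blocks`` maps presentation order to (coloration, background); practice
    trials come first within the session and carry ``practice=True``.
    """

    participant_id: int
    blocks: tuple[tuple[str, str], ...]
    trials: tuple[TrialSpec, ...]
    practice_count: int

    def __post_init__(self) -> None:
        if len(self.blocks) != len(set(self.blocks)):
            raise ValueError("blocks must be distinct condition combinations")

    @property
    def analysis_trials(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if not t.practice)


@dataclass
class TrialResult:
    spec: TrialSpec
    target_index: int
    tracks: list[Track]
    cursor: np.ndarray
    error_px: float

    @property
    def log_error(self) -> float:
        return float(np.log(self.error_px))


def build_schedule(participant_id: int, reps_per_size: int = 8, seed=0,
                   practice_trials: int = 4) -> SessionSchedule:
    """Randomized 6-block factorial schedule for one participant.

    Block order and the within-block order of group sizes are shuffled from
    the participant's seeded stream; each (coloration, background, size) cell
    appears exactly ``reps_per_size`` times among the scored trials.  Practice
    trials reuse the first block's condition at shuffled group sizes.
    """
    if reps_per_size < 1:
        raise ValueError("reps_per_size must be at least 1")
    rng = np.random.default_rng(seed)
    combos = [(c, b) for c in COLORATIONS for b in BACKGROUNDS]
    order = rng.permutation(len(combos))
    blocks = tuple(combos[i] for i in order)

    trial_seed_root = np.random.SeedSequence(
        int(np.random.default_rng(seed).integers(2 ** 31)))
    n_total = practice_trials + 6 * 7 * reps_per_size
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in trial_seed_root.spawn(n_total)]
    seed_iter = iter(seeds)

    trials: list[TrialSpec] = []
    for k in range(practice_trials):
        c, b = blocks[0]
        g = int(rng.choice(GROUP_SIZES))
        trials.append(TrialSpec(c, b, g, seed=next(seed_iter), practice=True))
    for c, b in blocks:
        sizes = np.repeat(GROUP_SIZES, reps_per_size)
        rng.shuffle(sizes)
        for g in sizes:
            trials.append(TrialSpec(c, b, int(g), seed=next(seed_iter)))
    return SessionSchedule(participant_id, blocks, tuple(trials), practice_trials)


def run_trial(spec: TrialSpec, observer: ObserverParams,
              params: MotionParams | None = None,
              arena: ArenaSpec | None = None) -> TrialResult:
    """Simulate and score one trial, fully determined by ``spec.seed``."""
    params = params or MotionParams(duration_ms=spec.duration_ms)
    arena = arena or ArenaSpec()
    if not np.isclose(params.duration_ms, spec.duration_ms):
        params = replace(params, duration_ms=spec.duration_ms)
    ss = np.random.SeedSequence(spec.seed)
    track_ss, target_ss, observer_ss = ss.spawn(3)
    tracks = simulate_tracks(spec.group_size, params, arena, track_ss)
    target_index = int(np.random.default_rng(target_ss).integers(spec.group_size))
    cursor = cursor_agent(tracks, target_index, observer,
                          np.random.default_rng(observer_ss),
                          frame_rate=params.frame_rate,
                          sample_interval_ms=spec.sample_interval_ms,
                          coloration=spec.coloration,
                          background=spec.background)
    stride = int(round(spec.sample_interval_ms * params.frame_rate / 1000.0))
    target_samples = tracks[target_index].positions[::stride]
    error = tracking_error(target_samples, cursor, spec.window)
    return TrialResult(spec, target_index, tracks, cursor, error)


def run_session(schedule: SessionSchedule, observer: ObserverParams,
                params: MotionParams | None = None,
                arena: ArenaSpec | None = None,
                include_practice: bool = False) -> pd.DataFrame:
    """Run every trial of a schedule; returns the analysis trial table.

    One row per trial with the shared trial-table schema; practice trials are
    excluded unless ``include_practice`` (they stay flagged either way).
    """
    rows = []
    block_of = {cb: i + 1 for i, cb in enumerate(schedule.blocks)}
    for t_idx, spec in enumerate(schedule.trials, start=1):
        if spec.practice and not include_practice:
            continue
        result = run_trial(spec, observer, params, arena)
        rows.append({
            "participant": schedule.participant_id,
            "block": f"{spec.coloration}/{spec.background}",
            "block_order": block_of[(spec.coloration, spec.background)],
            "trial": t_idx,
            "coloration": spec.coloration,
            "background": spec.background,
            "group_size": spec.group_size,
            "target_index": result.target_index,
            "error_px": result.error_px,
            "log_error": result.log_error,
            "seed": spec.seed,
            "practice": spec.practice,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
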