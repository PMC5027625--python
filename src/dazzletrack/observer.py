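"""Synthetic participants.

No human data exist for this task, so the pipeline supplies two stand-ins
that emit the same trial-table schema:

* ``cursor_agent`` — a mechanistic tracker.  It follows a "believed" target
  with lag and positional jitter and, whenever distractors crowd the believed
  target, occasionally swaps its belief to the nearest one.  More neighbors
  mean more swap opportunities, so mean tracking error grows with group size:
  the confusion effect emerges from the mechanism rather than being scripted.

* ``generate_error_table`` — a direct generative model of per-trial log
  errors with the structure the mixed-model analysis assumes: a quadratic
  group-size trend, coloration and background main effects, coloration x
  group-size interactions, a normal participant random intercept, and normal
  residuals (errors are therefore log-normal in pixels).

The default generative coefficients are configuration, not estimates: they
encode the qualitative finding that parallel-striped targets have a steeper
group-size slope while orthogonally striped and trinary targets behave
identically, with magnitudes chosen to be realistic for a tracking task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import BACKGROUNDS, COLORATIONS, GROUP_SIZES, MODEL_LADDER, build_design
from .motion import Track

__all__ = [
    "ObserverParams",
    "ErrorModelParams",
    "cursor_agent",
    "generate_error_table",
    "default_confusion_params",
    "null_confusion_params",
    "default_design",
]


@dataclass(frozen=True)
class ObserverParams:
    """Mechanistic tracker settings.

    lag_ms            cursor latency behind the believed target
    pos_noise_sd      isotropic Gaussian cursor jitter per sample, pixels
    swap_base_rate    per-second probability of swapping belief to the nearest
                      distractor when exactly one sits within swap_radius
    swap_radius       neighborhood radius around the believed target, pixels
    confusion_gain    multiplicative increase in swap probability per
                      additional distractor inside the radius
    condition_multipliers  (coloration, background) -> scale on the swap rate
                      and jitter; unlisted conditions scale by 1
    """

    lag_ms: float = 80.0
    pos_noise_sd: float = 4.0
    swap_base_rate: float = 0.12
    swap_radius: float = 60.0
    confusion_gain: float = 1.30
    condition_multipliers: dict = field(default_factory=lambda: {
        ("parallel", "plain"): 1.40,
        ("parallel", "trinary"): 1.30,
        ("orthogonal", "plain"): 1.00,
        ("orthogonal", "trinary"): 1.05,
        ("trinary", "plain"): 1.00,
        ("trinary", "trinary"): 1.05,
    })

    def __post_init__(self) -> None:
        if self.lag_ms < 0 or self.pos_noise_sd < 0:
            raise ValueError("lag and noise must be non-negative")
        if not 0.0 <= self.swap_base_rate:
            raise ValueError("swap_base_rate must be non-negative")

    def multiplier(self, coloration: str, background: str) -> float:
        return float(self.condition_multipliers.get((coloration, background), 1.0))


def cursor_agent(tracks: list[Track], target_index: int, params: ObserverParams,
                 rng: np.random.Generator, frame_rate: float = 100.0,
                 sample_interval_ms: float = 10.0,
                 coloration: str = "trinary", background: str = "plain") -> np.ndarray:
    """Generate a cursor trace for one trial; returns (n_samples, 2) positions.

    The belief starts on the true target (the highlight cue).  At each sample
    the swap probability is ``swap_base_rate * dt * multiplier *
    confusion_gain**(m - 1)`` for m distractors within ``swap_radius`` of the
    believed target (0 if none), capped at 1; on a swap the belief moves to
    the nearest such distractor.  The cursor sits on the believed target's
    position ``lag_ms`` earlier, plus isotropic jitter.
    """
    n = len(tracks)
    if not 0 <= target_index < n:
        raise ValueError("target_index out of range")
    frames = len(tracks[0])
    pos = np.stack([t.positions for t in tracks], axis=1)  # (frames, n, 2)
    stride = sample_interval_ms * frame_rate / 1000.0
    if not np.isclose(stride, round(stride)) or stride < 1:
        raise ValueError("sample interval must be a whole number of frames")
    stride = int(round(stride))
    sample_frames = np.arange(0, frames, stride)
    lag_frames = int(round(params.lag_ms * frame_rate / 1000.0))

    mult = params.multiplier(coloration, background)
    dt = sample_interval_ms / 1000.0
    base_p = params.swap_base_rate * dt * mult
    noise_sd = params.pos_noise_sd * mult

    believed = target_index
    cursor = np.empty((len(sample_frames), 2))
    for s, f in enumerate(sample_frames):
        if n > 1 and base_p > 0:
            delta = pos[f] - pos[f, believed]
            dists = np.hypot(delta[:, 0], delta[:, 1])
            dists[believed] = np.inf
            near = np.flatnonzero(dists <= params.swap_radius)
            if near.size:
                p = min(1.0, base_p * params.confusion_gain ** (near.size - 1))
                if rng.random() < p:
                    believed = int(near[np.argmin(dists[near])])
        f_lag = max(0, f - lag_frames)
        jitter = rng.normal(0.0, noise_sd, size=2) if noise_sd > 0 else 0.0
        cursor[s] = pos[f_lag, believed] + jitter
    return cursor


# ---------------------------------------------------------------------------
# Generative log-error model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModelParams:
    """Coefficients of the generative log-error model (natural-log pixels).

    The fixed-effect structure is exactly the target + background + number +
    target x number design with trinary coloration / plain background as
    reference levels and the shared centered orthogonal number polynomial.
    """

    beta0: float = 3.40
    beta_n1: float = 0.35
    beta_n2: float = -0.10
    coloration_effects: dict = field(default_factory=lambda: {
        "parallel": 0.08, "orthogonal": 0.0})
    background_effect: float = 0.05
    interaction_linear: dict = field(default_factory=lambda: {
        "parallel": 0.12, "orthogonal": 0.0})
    interaction_quad: dict = field(default_factory=lambda: {
        "parallel": -0.04, "orthogonal": 0.0})
    participant_sd: float = 0.25
    resid_sd: float = 0.50

    def __post_init__(self) -> None:
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be non-negative")
        if self.resid_sd <= 0:
            raise ValueError("resid_sd must be positive")

    def coefficient(self, column: str) -> float:
        """Generating value for one design-matrix column of model 4."""
        if column == "const":
            return self.beta0
        if column == "n1":
            return self.beta_n1
        if column == "n2":
            return self.beta_n2
        if column == "background[trinary]":
            return self.background_effect
        if column.startswith("target[") and ":" not in column:
            return float(self.coloration_effects[column[7:-1]])
        if column.endswith(":n1"):
            return float(self.interaction_linear[column[7:-4]])
        if column.endswith(":n2"):
            return float(self.interaction_quad[column[7:-4]])
        raise KeyError(column)

    def coefficients(self, columns) -> np.ndarray:
        return np.array([self.coefficient(c) for c in columns])


def default_confusion_params() -> ErrorModelParams:
    """Defaults with the parallel-only steeper slope (merged-coding truth)."""
    return ErrorModelParams()


def null_confusion_params() -> ErrorModelParams:
    """Same defaults with every coloration x number interaction zeroed."""
    return replace(default_confusion_params(),
                   interaction_linear={"parallel": 0.0, "orthogonal": 0.0},
                   interaction_quad={"parallel": 0.0, "orthogonal": 0.0})


def default_design(reps_per_size: int = 8) -> pd.DataFrame:
    """One participant's full-factorial design: 6 conditions x 7 sizes x reps."""
    rows = [
        {"coloration": c, "background": b, "group_size": g}
        for c in COLORATIONS for b in BACKGROUNDS
        for g in GROUP_SIZES for _ in range(reps_per_size)
    ]
    return pd.DataFrame(rows)


def generate_error_table(design: pd.DataFrame, params: ErrorModelParams,
                         n_participants: int, seed) -> pd.DataFrame:
    """Simulate per-trial log errors for ``n_participants`` copies of a design.

    Each participant receives one random intercept ~ N(0, participant_sd^2);
    each trial's log error is the fixed-effect linear predictor plus the
    intercept plus N(0, resid_sd^2) residual noise.  ``error_px`` is the
    exponential of the log error.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    exog = build_design(design, MODEL_LADDER[4])
    lp = exog.to_numpy() @ params.coefficients(exog.columns)
    intercepts = rng.normal(0.0, params.participant_sd, size=n_participants)
    frames = []
    for p in range(n_participants):
        resid = rng.normal(0.0, params.resid_sd, size=len(design))
        log_err = lp + intercepts[p] + resid
        df = design.copy()
        df.insert(0, "participant", p + 1)
        df["log_error"] = log_err
        df["error_px"] = np.exp(log_err)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
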