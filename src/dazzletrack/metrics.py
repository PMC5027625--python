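"""Tracking-error dependent variable.

The study's response measure is the mean Euclidean distance, in pixels,
between the cursor center and the target center over the scored part of the
trial (by default the final 4000 ms of a 5000 ms trial, sampled every 10 ms;
the initial 1000 ms is the target-highlight period and is unscored).
Distances are computed center-to-center in continuous coordinates, never on
the rasterized frame.  Errors are natural-log transformed for analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ErrorWindow", "tracking_error", "log_error"]


@dataclass(frozen=True)
class ErrorWindow:
    """Scored time window: samples with start_ms <= t < end_ms contribute."""

    start_ms: float = 1000.0
    end_ms: float = 5000.0
    sample_interval_ms: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.start_ms < self.end_ms:
            raise ValueError("need 0 <= start_ms < end_ms")
        span = self.end_ms - self.start_ms
        if not np.isclose(span % self.sample_interval_ms, 0) and not np.isclose(
                span % self.sample_interval_ms, self.sample_interval_ms):
            raise ValueError("sample interval must divide the window span")

    def mask(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        return (t >= self.start_ms) & (t < self.end_ms)


def tracking_error(target_samples, cursor_samples, window: ErrorWindow,
                   t_ms=None) -> float:
    """Mean cursor-to-target distance (pixels) over the scored window.

    ``target_samples`` and ``cursor_samples`` are (n, 2) position arrays on a
    common clock.  ``t_ms`` gives each sample's timestamp; if omitted, sample
    k is taken at ``k * window.sample_interval_ms``.
    """
    target = np.asarray(target_samples, dtype=float)
    cursor = np.asarray(cursor_samples, dtype=float)
    if target.shape != cursor.shape or target.ndim != 2 or target.shape[1] != 2:
        raise ValueError("target and cursor must be matching (n, 2) arrays")
    if t_ms is None:
        t_ms = np.arange(len(target)) * window.sample_interval_ms
    t_ms = np.asarray(t_ms, dtype=float)
    if len(t_ms) != len(target):
        raise ValueError("timestamps do not align with samples")
    keep = window.mask(t_ms)
    if not keep.any():
        raise ValueError("no samples fall inside the scored window")
    d = np.linalg.norm(cursor[keep] - target[keep], axis=1)
    return float(d.mean())


def log_error(error_px: float) -> float:
    """Natural log of the tracking error; flags non-positive input.

    A zero error is only possible for an idealized noiseless observer; such
    trials are rejected (with a warning) rather than offset-corrected.
    """
    if error_px <= 0:
        warnings.warn("non-positive tracking error excluded from log transform",
                      RuntimeWarning, stacklevel=2)
        raise ValueError("log_error requires error_px > 0")
    return float(np.log(error_px))
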