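"""Pipeline configuration: nested stage parameters with YAML round-tripping.

Defaults reproduce the study constants throughout: 1024x768 screen, 268x268
arena, 32-px squares at 200 px/s under a 100 Hz refresh, pi/8 rad turn SD,
8-px gratings at 100% contrast, 4-px trinary elements at levels
35.7/71.4/107.1 around mean 71.4, 5000 ms trials with a 1000 ms highlight and
10 ms sampling, 7 group sizes x 6 blocks x 8 reps = 336 scored trials, and
16 participants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .motion import ArenaSpec, MotionParams
from .observer import ErrorModelParams, ObserverParams
from .stimuli import BackgroundSpec, PatternSpec

__all__ = ["PipelineConfig"]


def _to_plain(obj):
    """Recursively convert dataclasses/tuples/dict keys to YAML-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {("/".join(k) if isinstance(k, tuple) else k): _to_plain(v)
                for k, v in obj.items()}
    return obj


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run."""

    motion: MotionParams = field(default_factory=MotionParams)
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    grating: PatternSpec = field(default_factory=PatternSpec)
    background_plain: BackgroundSpec = field(
        default_factory=lambda: BackgroundSpec(background="plain"))
    background_trinary: BackgroundSpec = field(
        default_factory=lambda: BackgroundSpec(background="trinary"))
    n_participants: int = 16
    reps_per_size: int = 8
    practice_trials: int = 4
    observer_kind: str = "generative"  # 'generative' | 'mechanistic'
    observer: ObserverParams = field(default_factory=ObserverParams)
    error_model: ErrorModelParams = field(default_factory=ErrorModelParams)
    model_ids: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    seed: int = 0
    out_dir: str = "dazzletrack_run"

    def __post_init__(self) -> None:
        if self.observer_kind not in ("generative", "mechanistic"):
            raise ValueError("observer_kind must be generative or mechanistic")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return _to_plain(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)

        def load(key, typ, **fixes):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for name, fn in fixes.items():
                    if name in sub:
                        sub[name] = fn(sub[name])
                d[key] = typ(**sub)

        as_tuple = tuple
        load("motion", MotionParams)
        load("arena", ArenaSpec)
        load("grating", PatternSpec, luminance_levels=as_tuple)
        load("background_plain", BackgroundSpec, luminance_levels=as_tuple)
        load("background_trinary", BackgroundSpec, luminance_levels=as_tuple)
        load("observer", ObserverParams,
             condition_multipliers=lambda m: {tuple(k.split("/")): v
                                              for k, v in m.items()})
        load("error_model", ErrorModelParams)
        if "model_ids" in d:
            d["model_ids"] = tuple(int(i) for i in d["model_ids"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
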