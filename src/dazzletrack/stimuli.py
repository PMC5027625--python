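"""Target and background textures, and frame rasterization.

Three coloration treatments are applied to the moving squares: a square-wave
grating striped *parallel* to the heading, one striped *orthogonal* to the
heading, and a *trinary* noise texture that matches the background statistics.
Backgrounds are either plain (uniform at the mean target luminance) or trinary
noise built from 4x4-pixel elements.

Raster values store the luminance numbers directly as abstract floats on the
cd/m^2 scale used throughout (mean 71.4, trinary levels 35.7/71.4/107.1, full
contrast grating 0/142.8); photometric display calibration is out of scope.
PNG export maps [0, 2 * mean] linearly onto [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motion import AgentState, ArenaSpec, wrap_angle

__all__ = [
    "PatternSpec",
    "BackgroundSpec",
    "make_grating",
    "make_trinary",
    "render_frame",
    "frame_to_image",
    "save_frame_png",
]

PARALLEL = "parallel_stripes"
ORTHOGONAL = "orthogonal_stripes"
TRINARY = "trinary"
STRIPE_PATTERNS = (PARALLEL, ORTHOGONAL)


@dataclass(frozen=True)
class PatternSpec:
    """Target texture parameters.

    pattern           parallel_stripes | orthogonal_stripes | trinary
    wavelength        full period of the square-wave grating, pixels (even)
    contrast          Michelson contrast of the grating, in [0, 1]
    phase_deg         0 or 180; which band polarity starts the grating
    luminance_levels  the three trinary levels (low, mean, high)
    mean_luminance    mean raster value of every texture
    """

    pattern: str = PARALLEL
    wavelength: int = 8
    contrast: float = 1.0
    phase_deg: int = 0
    luminance_levels: tuple[float, float, float] = (35.7, 71.4, 107.1)
    mean_luminance: float = 71.4

    def __post_init__(self) -> None:
        if self.pattern not in (PARALLEL, ORTHOGONAL, TRINARY):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.wavelength <= 0 or self.wavelength % 2:
            raise ValueError("wavelength must be a positive even pixel count")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        if self.phase_deg not in (0, 180):
            raise ValueError("phase_deg must be 0 or 180")
        if not np.isclose(np.mean(self.luminance_levels), self.mean_luminance):
            raise ValueError("luminance_levels must average to mean_luminance")


@dataclass(frozen=True)
class BackgroundSpec:
    """Background parameters: plain mean-luminance field or trinary noise."""

    background: str = "plain"
    element_size: int = 4
    mean_luminance: float = 71.4
    luminance_levels: tuple[float, float, float] = (35.7, 71.4, 107.1)

    def __post_init__(self) -> None:
        if self.background not in ("plain", "trinary"):
            raise ValueError(f"unknown background {self.background!r}")
        if self.element_size <= 0:
            raise ValueError("element_size must be positive")


def make_grating(square_size: int, spec: PatternSpec) -> np.ndarray:
    """Build a square-wave grating texture of side ``square_size``.

    Bands run along the texture's x axis (rows are constant-luminance), with
    band width ``wavelength / 2``.  Luminances are ``mean * (1 - contrast)``
    and ``mean * (1 + contrast)``, giving Michelson contrast exactly
    ``spec.contrast``; ``phase_deg = 180`` swaps the two bands.
    """
    if spec.pattern not in STRIPE_PATTERNS:
        raise ValueError("make_grating requires a stripe pattern")
    lo = spec.mean_luminance * (1.0 - spec.contrast)
    hi = spec.mean_luminance * (1.0 + spec.contrast)
    half = spec.wavelength // 2
    rows = (np.arange(square_size) // half) % 2
    if spec.phase_deg == 180:
        rows = 1 - rows
    band = np.where(rows == 0, lo, hi)
    return np.tile(band[:, None], (1, square_size)).astype(float)


def make_trinary(size: int, element_size: int, spec, rng: np.random.Generator) -> np.ndarray:
    """Build a trinary noise texture: element-sized blocks, levels iid 1/3 each.

    ``spec`` may be a PatternSpec or BackgroundSpec (only ``luminance_levels``
    is used).  If ``element_size`` does not divide ``size`` the block grid is
    generated one block larger and cropped.
    """
    if element_size <= 0:
        raise ValueError("element_size must be positive")
    levels = np.asarray(spec.luminance_levels, dtype=float)
    blocks = -(-size // element_size)  # ceil
    grid = levels[rng.integers(0, 3, size=(blocks, blocks))]
    return np.kron(grid, np.ones((element_size, element_size)))[:size, :size]


def make_texture(square_size: int, spec: PatternSpec,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Dispatch on pattern type; trinary textures need an rng."""
    if spec.pattern == TRINARY:
        if rng is None:
            raise ValueError("trinary texture requires an rng")
        return make_trinary(square_size, 4, spec, rng)
    return make_grating(square_size, spec)


def _rotate_nearest(texture: np.ndarray, angle_rad: float):
    """Rotate a texture by ``angle_rad`` (clockwise on a y-down screen).

    Nearest-neighbor resampling preserves the exact luminance level set; at
    multiples of 90 deg the rotation is an exact grid rotation.  Returns the
    rotated texture plus a boolean support mask (pixels outside the rotated
    square take the background when composited).
    """
    angle = float(wrap_angle(angle_rad))
    quarter = angle / (np.pi / 2)
    if np.isclose(quarter, round(quarter), atol=1e-12):
        # Positive heading is clockwise on screen; rot90 is CCW in array
        # coordinates, which with y pointing down is clockwise. Exact.
        k = int(round(quarter)) % 4
        return np.rot90(texture, k), np.ones_like(texture, dtype=bool)
    from scipy import ndimage

    # ndimage rotates CCW in array coords == CW on the y-down screen.
    deg = np.degrees(angle)
    rot = ndimage.rotate(texture, deg, reshape=False, order=0,
                         mode="constant", cval=np.nan, prefilter=False)
    mask = ~np.isnan(rot)
    return np.where(mask, rot, 0.0), mask


def render_background(background: BackgroundSpec, arena: ArenaSpec,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Full-screen background raster."""
    shape = (arena.screen_h, arena.screen_w)
    if background.background == "plain":
        return np.full(shape, background.mean_luminance, dtype=float)
    if rng is None:
        raise ValueError("trinary background requires an rng")
    side = max(shape)
    tex = make_trinary(side, background.element_size, background, rng)
    return tex[: shape[0], : shape[1]].copy()


def render_frame(states: list[AgentState], pattern: PatternSpec,
                 background: BackgroundSpec, arena: ArenaSpec,
                 rng: np.random.Generator | None = None,
                 textures: list[np.ndarray] | None = None) -> np.ndarray:
    """Rasterize one frame: background plus one oriented square per state.

    Each square's texture is rotated to its heading (parallel stripes end up
    aligned with motion, orthogonal stripes perpendicular; trinary squares
    rotate too) and composited at its rounded center position.  Later-listed
    squares draw on top.  ``textures`` may supply one pre-drawn (unrotated)
    texture per square, as used for per-trial phase/trinary freezing;
    otherwise textures are drawn here from ``rng``.
    """
    frame = render_background(background, arena, rng)
    size = arena.square_size
    half = size // 2
    for i, st in enumerate(states):
        if not (0 <= st.x < arena.screen_w and 0 <= st.y < arena.screen_h):
            raise ValueError("agent center lies outside the screen")
        tex = textures[i] if textures is not None else make_texture(size, pattern, rng)
        if pattern.pattern == ORTHOGONAL:
            # Base grating bands are horizontal; orthogonal stripes sit at
            # 90 deg to the heading, so pre-rotate by a quarter turn.
            rot, mask = _rotate_nearest(tex, st.heading + np.pi / 2)
        else:
            rot, mask = _rotate_nearest(tex, st.heading)
        r0 = int(round(st.y)) - half
        c0 = int(round(st.x)) - half
        r1, c1 = r0 + size, c0 + size
        fr0, fc0 = max(r0, 0), max(c0, 0)
        fr1, fc1 = min(r1, arena.screen_h), min(c1, arena.screen_w)
        tr0, tc0 = fr0 - r0, fc0 - c0
        sub = mask[tr0: tr0 + fr1 - fr0, tc0: tc0 + fc1 - fc0]
        patch = rot[tr0: tr0 + fr1 - fr0, tc0: tc0 + fc1 - fc0]
        region = frame[fr0:fr1, fc0:fc1]
        region[sub] = patch[sub]
    return frame


def frame_to_image(frame: np.ndarray, mean_luminance: float = 71.4):
    """Map a raster frame to an 8-bit grayscale PIL image.

    [0, 2 * mean_luminance] maps linearly onto [0, 255].
    """
    from PIL import Image

    scaled = np.clip(frame / (2.0 * mean_luminance), 0.0, 1.0) * 255.0
    return Image.fromarray(np.round(scaled).astype(np.uint8), mode="L")


def save_frame_png(frame: np.ndarray, path, mean_luminance: float = 71.4) -> None:
    frame_to_image(frame, mean_luminance).save(path)
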