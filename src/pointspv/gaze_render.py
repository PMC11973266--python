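"""Offline gaze-contingent presentation.

Reproduces, frame by frame, the display logic of a gaze-contingent
discrimination experiment: for each gaze sample a patch is cropped around
the gaze location, processed by a representation method — the trained
encoder+simulator pipeline or a Canny edge-detection baseline — and the
result is composited within a circular aperture at the gaze location on an
otherwise blank screen frame.

Both methods produce frames of identical geometry (same aperture, same
placement), differing only in content, so behavioral comparisons are
apples-to-apples.  In ``through_simulator`` mode the Canny edge map is
max-pooled onto the electrode grid, binarized and rendered by the same
phosphene simulator; ``raw_edges`` shows the resized edge map directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.transform import resize

from . import simulator as sim
from .encoder import Encoder, encode
from .sampling import SegmentedImage, ViewingPoint, ViewingPatch, _window_origin
from .simulator import PhospheneFrame, SimulatorConfig
from .synthetic import SyntheticGazeLog


@dataclass(frozen=True)
class RenderConfig:
    """Screen geometry, aperture and baseline parameters.

    Canny thresholds are expressed on the 8-bit intensity scale (0-255)
    and applied to the grayscale patch; aperture_radius defaults to half
    the patch size.
    """

    screen_size: tuple[int, int] = (1080, 1920)
    patch_size: int = 100
    aperture_radius: int | None = None
    method: str = "pointspv"
    canny_low: float = 100.0
    canny_high: float = 200.0
    canny_sigma: float = 1.0
    canny_mode: str = "through_simulator"
    sim_config: SimulatorConfig = field(default_factory=SimulatorConfig)
    blank_saccades: bool = False

    def __post_init__(self):
        if self.method not in ("pointspv", "canny"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.canny_mode not in ("through_simulator", "raw_edges"):
            raise ValueError(f"unknown canny_mode {self.canny_mode!r}")
        if not 0 <= self.canny_low < self.canny_high:
            raise ValueError("require 0 <= canny_low < canny_high")
        r = self.radius
        if 2 * r + 1 > min(self.screen_size):
            raise ValueError("aperture does not fit on screen")

    @property
    def radius(self) -> int:
        return (self.aperture_radius if self.aperture_radius is not None
                else self.patch_size // 2)


@dataclass
class ScreenFrame:
    """One displayed frame: zero everywhere outside the gaze aperture."""

    pixels: np.ndarray
    gaze: tuple[int, int]      # (y, x)
    method: str


def canny_representation(patch, config: RenderConfig = RenderConfig()) -> PhospheneFrame:
    """Edge-detection baseline for a viewing patch.

    Grayscale conversion, Canny at (canny_low, canny_high)/255, then either
    phosphene rendering of the grid-pooled edge map (default) or a plain
    resize of the edge map to the frame size.
    """
    pixels = np.asarray(getattr(patch, "pixels", patch), dtype=np.float64)
    gray = rgb2gray(pixels) if pixels.ndim == 3 else pixels
    edges = canny(gray, sigma=config.canny_sigma,
                  low_threshold=config.canny_low / 255.0,
                  high_threshold=config.canny_high / 255.0)
    sc = config.sim_config
    if config.canny_mode == "raw_edges":
        frame = resize(edges.astype(np.float64), (sc.frame_size, sc.frame_size),
                       order=1, anti_aliasing=False, preserve_range=True)
        return PhospheneFrame(np.clip(frame, 0.0, 1.0))
    # max-pool the edge map onto the electrode grid: a cell is active if
    # any edge pixel falls inside it
    g = sc.grid_size
    p = gray.shape[0]
    grid = np.zeros((g, g), dtype=np.float64)
    ys, xs = np.nonzero(edges)
    if ys.size:
        gy = np.minimum((ys * g) // p, g - 1)
        gx = np.minimum((xs * g) // p, g - 1)
        grid[gy, gx] = 1.0
    return sim.simulate(grid, sc)


def _extract_screen_patch(image: np.ndarray, gaze: tuple[int, int],
                          patch_size: int) -> ViewingPatch:
    h, w = image.shape[:2]
    pt = ViewingPoint(y=int(gaze[0]), x=int(gaze[1]))
    y0, x0 = _window_origin(pt, patch_size, (h, w))
    window = image[y0:y0 + patch_size, x0:x0 + patch_size]
    if window.ndim == 2:
        window = np.repeat(window[..., None], 3, axis=2)
    return ViewingPatch(pixels=np.asarray(window, dtype=np.float64), center=pt,
                        source_id="screen", label=-1, background_removed=False)


def render_frame(image: np.ndarray, gaze: tuple[int, int],
                 encoder: Encoder | None,
                 config: RenderConfig = RenderConfig()) -> ScreenFrame:
    """Render one gaze-contingent screen frame.

    A patch is cropped around the gaze location (clamped at borders),
    processed by the selected method, resized into the aperture's bounding
    box, masked by the circular aperture of radius r (pixels p with
    euclidean distance(p, gaze) <= r), and composited at the gaze location
    on a black screen.
    """
    sh, sw = config.screen_size
    gy, gx = int(gaze[0]), int(gaze[1])
    if not (0 <= gy < sh and 0 <= gx < sw):
        raise ValueError(f"gaze {gaze} off-screen {config.screen_size}")
    if image.shape[:2] != (sh, sw):
        raise ValueError(f"image shape {image.shape[:2]} != screen {config.screen_size}")

    patch = _extract_screen_patch(image, (gy, gx), config.patch_size)
    if config.method == "pointspv":
        if encoder is None:
            raise ValueError("pointspv rendering requires an encoder")
        frame = sim.simulate(encode(encoder, patch), config.sim_config)
    else:
        frame = canny_representation(patch, config)

    r = config.radius
    d = 2 * r + 1
    content = resize(frame.pixels, (d, d), order=1, anti_aliasing=False,
                     preserve_range=True)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    content = np.where(yy ** 2 + xx ** 2 <= r * r, content, 0.0)

    screen = np.zeros((sh, sw), dtype=np.float64)
    y0, y1 = max(gy - r, 0), min(gy + r + 1, sh)
    x0, x1 = max(gx - r, 0), min(gx + r + 1, sw)
    screen[y0:y1, x0:x1] = content[y0 - (gy - r):y1 - (gy - r),
                                   x0 - (gx - r):x1 - (gx - r)]
    return ScreenFrame(pixels=np.clip(screen, 0.0, 1.0), gaze=(gy, gx),
                       method=config.method)


def simulate_session(image: np.ndarray, gaze_log: SyntheticGazeLog,
                     encoder: Encoder | None,
                     config: RenderConfig = RenderConfig()) -> list[ScreenFrame]:
    """Replay a gaze log into an ordered frame sequence (one per sample).

    Frames are rendered during saccades too (the display updates
    continuously); ``config.blank_saccades`` blanks them instead, for
    fixation-only visualization.
    """
    frames: list[ScreenFrame] = []
    for s in sorted(gaze_log.samples, key=lambda s: s.t_ms):
        gaze = (int(round(s.y)), int(round(s.x)))
        if config.blank_saccades and s.event == "saccade":
            frames.append(ScreenFrame(pixels=np.zeros(config.screen_size),
                                      gaze=gaze, method=config.method))
        else:
            frames.append(render_frame(image, gaze, encoder, config))
    return frames
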