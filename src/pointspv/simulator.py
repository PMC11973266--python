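"""Non-trainable phosphene simulator.

Each element of the binary electrode grid is mapped to a preassigned
location in the output frame and, when active, rendered as a dot-shaped
phosphene of fixed size and brightness.  The default mimics a cortical
prosthesis with homogeneously distributed, equally sized phosphenes: a
32x32 grid rendered into a 256x256 frame, one cell per electrode, a
cell-centered isotropic Gaussian dot truncated so neighboring phosphenes
never touch.

Rendering is a fixed linear operator over the activation map (before the
final clip to [0,1]), which makes it deterministic and lets gradients flow
through it during end-to-end training.

Coordinate convention: 0-based (row, col) = (y, x), origin at the top-left.
Grid element (r, c) is centered at pixel coordinate ((r+0.5)*s, (c+0.5)*s)
with s = frame_size / grid_size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import autograd as ag


@dataclass(frozen=True)
class SimulatorConfig:
    """Geometry and dot profile of the phosphene display.

    dot_sigma defaults to spacing/4 (Gaussian width, px); dot_radius
    defaults to spacing/2 - 1 so a dot's footprint stays strictly inside
    its own grid cell and active elements remain countable as disjoint
    blobs.
    """

    frame_size: int = 256
    grid_size: int = 32
    dot_profile: str = "gaussian"
    dot_sigma: float | None = None
    dot_radius: float | None = None
    brightness: float = 1.0

    def __post_init__(self):
        if self.frame_size % self.grid_size != 0:
            raise ValueError("frame_size must be divisible by grid_size")
        if self.dot_profile not in ("gaussian", "disk"):
            raise ValueError(f"unknown dot_profile {self.dot_profile!r}")
        if self.spacing < 2:
            raise ValueError("grid spacing below 2 px cannot render a dot")

    @property
    def spacing(self) -> int:
        return self.frame_size // self.grid_size

    @property
    def sigma(self) -> float:
        return self.dot_sigma if self.dot_sigma is not None else self.spacing / 4.0

    @property
    def radius(self) -> float:
        return self.dot_radius if self.dot_radius is not None else self.spacing / 2.0 - 1.0


@dataclass
class PhospheneFrame:
    """A rendered simulated-prosthetic-vision frame, values in [0,1]."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("frame must be 2-D grayscale")


def phosphene_centers(config: SimulatorConfig = SimulatorConfig()) -> np.ndarray:
    """(grid_size^2, 2) array of (row, col) phosphene centers in pixels."""
    s = config.spacing
    g = config.grid_size
    rc = np.arange(g, dtype=np.float64)
    centers = np.stack(np.meshgrid((rc + 0.5) * s, (rc + 0.5) * s, indexing="ij"),
                       axis=-1)
    return centers.reshape(-1, 2)


def dot_template(config: SimulatorConfig = SimulatorConfig()) -> np.ndarray:
    """The (spacing x spacing) single-phosphene footprint, peak value 1."""
    s = config.spacing
    k = np.arange(s, dtype=np.float64)
    dy = k - s / 2.0
    d2 = dy[:, None] ** 2 + dy[None, :] ** 2
    if config.dot_profile == "gaussian":
        tmpl = np.exp(-d2 / (2.0 * config.sigma ** 2))
    else:
        tmpl = np.ones((s, s))
    tmpl[np.sqrt(d2) > config.radius] = 0.0
    return tmpl


def _map_values(activation_map) -> np.ndarray:
    values = getattr(activation_map, "values", activation_map)
    return np.asarray(values, dtype=np.float64)


def simulate(activation_map, config: SimulatorConfig = SimulatorConfig()) -> PhospheneFrame:
    """Render an activation map into a phosphene frame.

    frame = clip(brightness * sum over active elements of the dot template
    placed at that element's preassigned center, 0, 1).  An all-zero map
    yields an all-zero frame.
    """
    m = _map_values(activation_map)
    g = config.grid_size
    if m.shape != (g, g):
        raise ValueError(f"activation map shape {m.shape} != ({g},{g})")
    frame = np.kron(m, dot_template(config)) * config.brightness
    return PhospheneFrame(np.clip(frame, 0.0, 1.0))


def simulate_tensor(m: ag.Tensor, config: SimulatorConfig = SimulatorConfig()) -> ag.Tensor:
    """Differentiable batched rendering: (N,G,G) -> (N,F,F) tensor."""
    if m.ndim != 3 or m.shape[1] != config.grid_size or m.shape[2] != config.grid_size:
        raise ValueError(f"expected (N,{config.grid_size},{config.grid_size}), got {m.shape}")
    return ag.phosphene_render(m, dot_template(config), config.brightness)
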