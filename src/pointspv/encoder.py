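"""The encoder: a fully convolutional network mapping a gaze-centered
viewing patch to a binary electrode activation map.

Architecture (13 layer groups): four 3x3 conv layers ramping channels
3-8-16-32-64 (the 3rd and 4th followed by 2x2 max pooling), four two-conv
residual blocks at 64 channels, then a decoding ramp 64-32-16-8-3-1 (the
first decoder conv followed by pooling).  Batch normalization on groups
1-11, leaky rectifiers on groups 1-12, sigmoid on the output conv.  All
kernels 3x3, stride 1, padding 1.

Three pooling stages divide the spatial size by 8, so the input patch is
first resized to ``internal_size = grid_size * 8`` (256 by default) and the
network emits a ``grid_size`` x ``grid_size`` map (32x32 by default).  The
sigmoid output is thresholded by a strict Heaviside step (soft > threshold)
to produce binary stimulation values; during training a straight-through
rule passes gradients to the pre-threshold activations so the whole
pipeline remains trainable despite the hard binarization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from skimage.transform import resize

from . import nn
from .nn import autograd as ag
from .nn import layers as L

# channel ramps of the 13 layer groups (fixed by the architecture)
ENCODER_CHANNELS = (3, 8, 16, 32, 64)
DECODER_CHANNELS = (64, 32, 16, 8, 3, 1)
N_RESIDUAL_BLOCKS = 4
N_POOL_STAGES = 3


@dataclass(frozen=True)
class EncoderConfig:
    patch_size: int = 100
    internal_size: int = 256
    grid_size: int = 32
    binarize_threshold: float = 0.5
    leaky_slope: float = 0.01
    # initial bias of the output conv: negative so freshly initialized
    # encoders emit sparse activation maps (near-blank frames) rather than
    # half-on noise, which stabilizes early joint training
    output_bias_init: float = -1.5

    def __post_init__(self):
        if self.internal_size != self.grid_size * 2 ** N_POOL_STAGES:
            raise ValueError(
                f"internal_size must equal grid_size * {2 ** N_POOL_STAGES} "
                f"(got {self.internal_size} vs grid {self.grid_size})")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0,1)")
        if self.patch_size < 1 or self.grid_size < 1:
            raise ValueError("sizes must be positive")


@dataclass
class ActivationMap:
    """Binary electrode stimulation pattern plus its pre-threshold values.

    ``values`` is the hard {0,1} map driving the simulator; ``soft_values``
    are the sigmoid outputs retained for gradient flow and inspection.
    """

    values: np.ndarray
    soft_values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.soft_values = np.asarray(self.soft_values)
        if self.values.shape != self.soft_values.shape:
            raise ValueError("values and soft_values must share a shape")


class Encoder(L.Module):
    """The 13-group fully convolutional encoder."""

    def __init__(self, config: EncoderConfig = EncoderConfig(), rng_seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(rng_seed)
        s = config.leaky_slope
        g: list[L.Module] = []
        # groups 1-4: conv ramp, pooling on groups 3 and 4
        for i, pool in zip(range(4), (False, False, True, True)):
            mods = [L.Conv2d3x3(ENCODER_CHANNELS[i], ENCODER_CHANNELS[i + 1], rng),
                    L.BatchNorm2d(ENCODER_CHANNELS[i + 1]), L.LeakyReLU(s)]
            if pool:
                mods.append(L.MaxPool2x2())
            g.append(L.Sequential(*mods))
        # groups 5-8: residual blocks at 64 channels
        for _ in range(N_RESIDUAL_BLOCKS):
            g.append(L.ResidualBlock(64, rng, slope=s))
        # group 9: first decoder conv, with pooling
        g.append(L.Sequential(L.Conv2d3x3(64, 32, rng), L.BatchNorm2d(32),
                              L.LeakyReLU(s), L.MaxPool2x2()))
        # groups 10-11: BN + leaky
        g.append(L.Sequential(L.Conv2d3x3(32, 16, rng), L.BatchNorm2d(16), L.LeakyReLU(s)))
        g.append(L.Sequential(L.Conv2d3x3(16, 8, rng), L.BatchNorm2d(8), L.LeakyReLU(s)))
        # group 12: no normalization
        g.append(L.Sequential(L.Conv2d3x3(8, 3, rng), L.LeakyReLU(s)))
        # group 13: sigmoid output, 1 channel
        out_conv = L.Conv2d3x3(3, 1, rng)
        out_conv.bias.data[...] = config.output_bias_init
        g.append(L.Sequential(out_conv, L.Sigmoid()))
        self.layer_groups = g
        for i, m in enumerate(g):
            setattr(self, f"group{i + 1:02d}", m)

    def forward(self, x: ag.Tensor) -> ag.Tensor:
        """(N,3,S,S) -> (N,1,S/8,S/8) sigmoid activations."""
        for m in self.layer_groups:
            x = m(x)
        return x


def init_encoder(config: EncoderConfig = EncoderConfig(), rng_seed: int = 0) -> Encoder:
    """Build an encoder with reproducible initial weights."""
    return Encoder(config, rng_seed)


def param_count(encoder: Encoder) -> int:
    return sum(p.data.size for p in encoder.parameters())


def _prepare_batch(patches: np.ndarray, config: EncoderConfig) -> np.ndarray:
    """(N,P,P,3) in [0,1] -> (N,3,S,S) float, resized to internal_size."""
    n, p1, p2, c = patches.shape
    if c != 3 or p1 != p2:
        raise ValueError(f"expected (N,P,P,3) patches, got {patches.shape}")
    s = config.internal_size
    if p1 != s:
        out = np.empty((n, s, s, 3), dtype=np.float32)
        for i in range(n):
            out[i] = resize(patches[i], (s, s), order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)
        patches = out
    return np.ascontiguousarray(patches.transpose(0, 3, 1, 2), dtype=ag.get_default_dtype())


def encode(encoder: Encoder, patch) -> ActivationMap:
    """Encode one viewing patch into a binary activation map (eval mode).

    Accepts a ViewingPatch or a (P,P,3) array in [0,1].  The patch is
    resized to the encoder's internal size, passed through the network in
    evaluation mode, and the sigmoid output is binarized by a strict
    threshold (soft values exactly at threshold map to 0).
    """
    pixels = np.asarray(getattr(patch, "pixels", patch), dtype=np.float64)
    if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"patch must be (P,P,3), got {pixels.shape}")
    cfg = encoder.config
    was_training = encoder.training
    encoder.eval()
    try:
        with ag.no_grad():
            x = ag.Tensor(_prepare_batch(pixels[None], cfg))
            soft = encoder(x).data[0, 0]
    finally:
        encoder.train(was_training)
    hard = (soft > cfg.binarize_threshold).astype(soft.dtype)
    return ActivationMap(values=hard, soft_values=soft)


def encode_for_training(encoder: Encoder, patches: np.ndarray) -> tuple[ag.Tensor, ag.Tensor]:
    """Batched encoding with the straight-through gradient contract.

    Returns ``(hard, soft)`` tensors of shape (N,G,G).  ``hard`` carries
    binary forward values; its backward treats the Heaviside step as the
    identity on the sigmoid activations, so any downstream scalar yields
    finite, generically nonzero gradients for the encoder weights.
    """
    cfg = encoder.config
    x = ag.Tensor(_prepare_batch(np.asarray(patches, dtype=np.float64), cfg))
    soft4 = encoder(x)
    n = soft4.shape[0]
    soft = ag.reshape(soft4, (n, cfg.grid_size, cfg.grid_size))
    hard = ag.heaviside_st(soft, cfg.binarize_threshold)
    return hard, soft


# ---------------------------------------------------------------------------
# checkpoint I/O: opaque npz weights plus a JSON sidecar with the config
# ---------------------------------------------------------------------------

def save_checkpoint(path, module: L.Module, config=None, seed: int | None = None) -> None:
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz", **module.state_dict())
    sidecar = {"seed": seed}
    if config is not None:
        sidecar["config"] = asdict(config)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_encoder_checkpoint(path) -> Encoder:
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        sidecar = json.load(fh)
    cfg = EncoderConfig(**sidecar["config"])
    enc = Encoder(cfg, rng_seed=sidecar.get("seed") or 0)
    with np.load(base + ".npz") as data:
        enc.load_state_dict(dict(data))
    return enc
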