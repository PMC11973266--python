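"""Blind and sighted recognition units.

A classification backbone is split into an early feature extractor and a
classifier head.  Two copies of the extractor play different roles:

* the **sighted unit** is a frozen extractor applied to the original,
  background-free viewing patch — it provides the reference features for
  the perceptual (feature-matching) loss and never receives gradients;
* the **blind unit** is a trainable extractor + classifier that perceives
  only the simulated phosphene frame, acting as a surrogate prosthesis
  user.

Backbones are pluggable through a registry.  The default is a small
8-stage residual network sized for desk-scale experiments with synthetic
scenes (its split index defaults to 4, mirroring the early/late split of
large pretrained classifiers whose first stages retain spatially coherent
low-level features).  The sighted input is resized to the simulator frame
size before feature extraction so both paths produce feature maps of
identical shape — a precondition of the perceptual loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.transform import resize

from .nn import autograd as ag
from .nn import layers as L

# channel normalization convention shared by both units: map [0,1] inputs
# to zero mean, unit-ish scale
_NORM_MEAN = 0.5
_NORM_STD = 0.5


@dataclass
class FeatureMap:
    """C x H x W activations at the backbone's split layer."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("feature map must be (C,H,W)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values")


class Backbone(L.Module):
    """A staged classifier: ordered stages, the last mapping to class logits."""

    def __init__(self, stages: list[L.Module], n_classes: int, default_split: int):
        super().__init__()
        self.stages = stages
        self.n_classes = n_classes
        self.default_split = default_split
        for i, m in enumerate(stages):
            setattr(self, f"stage{i:02d}", m)

    def forward(self, x):
        for m in self.stages:
            x = m(x)
        return x


class StageStack(L.Module):
    """A contiguous run of backbone stages (shares the stage modules)."""

    def __init__(self, stages: list[L.Module]):
        super().__init__()
        self.stages = stages
        for i, m in enumerate(stages):
            setattr(self, f"stage{i:02d}", m)

    def __len__(self):
        return len(self.stages)

    def forward(self, x):
        for m in self.stages:
            x = m(x)
        return x


def make_surrogate_backbone(n_classes: int = 2, rng_seed: int = 0) -> Backbone:
    """The default desk-scale backbone: 8 stages, residual mid-stages.

    Works for any input size that is a multiple of 64 (six 2x pooling
    stages followed by global average pooling).
    """
    rng = np.random.default_rng(rng_seed)
    stages: list[L.Module] = [
        L.Sequential(L.Conv2d3x3(3, 8, rng), L.BatchNorm2d(8), L.LeakyReLU(), L.MaxPool2x2()),
        L.Sequential(L.Conv2d3x3(8, 16, rng), L.BatchNorm2d(16), L.LeakyReLU(), L.MaxPool2x2()),
        L.Sequential(L.ResidualBlock(16, rng), L.MaxPool2x2()),
        L.Sequential(L.Conv2d3x3(16, 32, rng), L.BatchNorm2d(32), L.LeakyReLU(), L.MaxPool2x2()),
        L.Sequential(L.ResidualBlock(32, rng), L.MaxPool2x2()),
        L.Sequential(L.Conv2d3x3(32, 64, rng), L.BatchNorm2d(64), L.LeakyReLU(), L.MaxPool2x2()),
        L.GlobalAvgPool(),
        L.Linear(64, n_classes, rng),
    ]
    return Backbone(stages, n_classes=n_classes, default_split=4)


_REGISTRY: dict[str, Callable[..., Backbone]] = {"surrogate": make_surrogate_backbone}


def register_backbone(name: str, factory: Callable[..., Backbone]) -> None:
    _REGISTRY[name] = factory


def make_backbone(name: str = "surrogate", **kwargs) -> Backbone:
    if name not in _REGISTRY:
        raise KeyError(f"unknown backbone {name!r}; registered: {sorted(_REGISTRY)}")
    return _REGISTRY[name](**kwargs)


def split_backbone(backbone: Backbone, split_index: int | None = None
                   ) -> tuple[StageStack, StageStack]:
    """Split into (feature_extractor, classifier); composing them
    reproduces the full backbone exactly (the stages are shared, not
    copied)."""
    idx = backbone.default_split if split_index is None else split_index
    if not 1 <= idx < len(backbone.stages):
        raise ValueError(f"split_index {idx} out of range 1..{len(backbone.stages) - 1}")
    return StageStack(backbone.stages[:idx]), StageStack(backbone.stages[idx:])


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

class SightedUnit:
    """Frozen feature extractor applied to background-free patches."""

    def __init__(self, extractor: StageStack, frame_size: int):
        self.extractor = copy.deepcopy(extractor)
        self.extractor.eval()
        self.extractor.freeze()
        self.frame_size = frame_size


class BlindUnit:
    """Trainable extractor + classifier perceiving only phosphene frames."""

    def __init__(self, extractor: StageStack, classifier: StageStack, frame_size: int):
        self.extractor = extractor
        self.classifier = classifier
        self.frame_size = frame_size

    def train(self, mode: bool = True):
        self.extractor.train(mode)
        self.classifier.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def parameters(self):
        yield from self.extractor.parameters()
        yield from self.classifier.parameters()


def make_units(backbone: Backbone, split_index: int | None = None,
               frame_size: int = 256) -> tuple[BlindUnit, SightedUnit]:
    """Build the blind and sighted units from one backbone.

    The blind unit shares the backbone's stages (training it trains the
    backbone); the sighted unit receives a frozen deep copy of the feature
    extractor, so the perceptual reference is fixed for the whole run.
    """
    extractor, classifier = split_backbone(backbone, split_index)
    return (BlindUnit(extractor, classifier, frame_size),
            SightedUnit(extractor, frame_size))


def _normalize(x: ag.Tensor) -> ag.Tensor:
    return ag.affine_const(x, 1.0 / _NORM_STD, -_NORM_MEAN / _NORM_STD)


def prepare_patch_batch(patches: np.ndarray, frame_size: int) -> ag.Tensor:
    """(N,P,P,3) patches -> resized, normalized (N,3,F,F) tensor."""
    n = patches.shape[0]
    if patches.shape[1] != frame_size:
        out = np.empty((n, frame_size, frame_size, 3), dtype=np.float64)
        for i in range(n):
            out[i] = resize(patches[i], (frame_size, frame_size), order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)
        patches = out
    x = ag.Tensor(np.ascontiguousarray(patches.transpose(0, 3, 1, 2)))
    return _normalize(x)


def prepare_sighted_batch(unit: SightedUnit, patches: np.ndarray) -> ag.Tensor:
    """(N,P,P,3) background-free patches -> normalized (N,3,F,F) tensor."""
    return prepare_patch_batch(patches, unit.frame_size)


def sighted_features(unit: SightedUnit, patch) -> FeatureMap:
    """Frozen reference features of a background-free viewing patch.

    The patch is resized to the simulator frame size (so the feature shape
    matches the blind path), channel-normalized and passed through the
    frozen extractor.  Gradients never reach the sighted weights.
    """
    if not getattr(patch, "background_removed", False):
        raise ValueError("sighted unit requires a background-removed patch")
    pixels = np.asarray(patch.pixels, dtype=np.float64)
    with ag.no_grad():
        feats = unit.extractor(prepare_sighted_batch(unit, pixels[None]))
    return FeatureMap(values=feats.data[0])


def sighted_features_tensor(unit: SightedUnit, patches: np.ndarray) -> ag.Tensor:
    """Batched frozen features (constant tensors; no graph is built)."""
    with ag.no_grad():
        return unit.extractor(prepare_sighted_batch(unit, patches))


def prepare_blind_frames_np(frames: np.ndarray, frame_size: int) -> np.ndarray:
    """(N,F,F) frames -> replicated, normalized (N,3,F,F) numpy array."""
    if frames.ndim != 3 or frames.shape[1] != frame_size:
        raise ValueError(f"expected (N,{frame_size},{frame_size}), got {frames.shape}")
    x = np.repeat(frames[:, None, :, :], 3, axis=1)
    return (x - _NORM_MEAN) / _NORM_STD


def prepare_blind_frames(unit: BlindUnit, frames: ag.Tensor | np.ndarray) -> ag.Tensor:
    """(N,F,F) phosphene frames -> replicated, normalized (N,3,F,F)."""
    t = frames if isinstance(frames, ag.Tensor) else ag.Tensor(np.asarray(frames))
    if t.ndim != 3:
        raise ValueError("expected a batch of 2-D frames")
    if t.shape[1] != unit.frame_size or t.shape[2] != unit.frame_size:
        raise ValueError(f"frame size {t.shape[1:]} != {unit.frame_size}")
    n = t.shape[0]
    x = ag.reshape(t, (n, 1, unit.frame_size, unit.frame_size))
    return _normalize(ag.concat_channels(x, 3))


def blind_features(unit: BlindUnit, frame) -> FeatureMap:
    """Features the blind (trainable) extractor sees in a phosphene frame."""
    pixels = np.asarray(getattr(frame, "pixels", frame), dtype=np.float64)
    was_training = unit.extractor.training
    unit.eval()
    try:
        with ag.no_grad():
            feats = unit.extractor(prepare_blind_frames(unit, pixels[None]))
    finally:
        unit.train(was_training)
    return FeatureMap(values=feats.data[0])


def blind_forward_tensor(unit: BlindUnit, frames: ag.Tensor) -> tuple[ag.Tensor, ag.Tensor]:
    """Batched training path: returns (features, logits) tensors."""
    feats = unit.extractor(prepare_blind_frames(unit, frames))
    logits = unit.classifier(feats)
    return feats, logits


def classify(unit: BlindUnit, frame) -> np.ndarray:
    """Class probability vector for one phosphene frame (softmax over logits)."""
    pixels = np.asarray(getattr(frame, "pixels", frame), dtype=np.float64)
    was_training = unit.extractor.training
    unit.eval()
    try:
        with ag.no_grad():
            feats = unit.extractor(prepare_blind_frames(unit, pixels[None]))
            logits = unit.classifier(feats).data[0]
    finally:
        unit.train(was_training)
    z = logits - logits.max()
    p = np.exp(z)
    return p / p.sum()
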