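"""Viewing-point sampling: random points inside an object's segmentation
mask, fixed-size patches centered on them, and background-masked twins.

A viewing point simulates a possible gaze location on the target object;
the patch around it is what the encoder "sees" at that gaze position.
Sampling is uniform over mask-foreground pixels.  Patches whose sampled
point lies near the image border are clamped (the window is shifted to lie
fully inside the image), so every patch contains only real pixels; the
stored center remains the sampled point.

Coordinates are 0-based (row, col) = (y, x), origin top-left.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class SegmentedImage:
    image: np.ndarray      # (H,W,3) float in [0,1]
    mask: np.ndarray       # (H,W) binary
    label: int
    source_id: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask shapes must match")
        if not np.any(self.mask):
            raise ValueError("mask must be nonempty")


@dataclass(frozen=True)
class ViewingPoint:
    y: int
    x: int


@dataclass
class ViewingPatch:
    pixels: np.ndarray     # (P,P,3) float in [0,1]
    center: ViewingPoint
    source_id: str
    label: int
    background_removed: bool = False

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 3 or p.shape[0] != p.shape[1] or p.shape[2] != 3:
            raise ValueError(f"patch must be square (P,P,3), got {p.shape}")


@dataclass
class PatchPair:
    """A viewing patch with its background-masked twin and label."""

    patch: ViewingPatch
    patch_no_bg: ViewingPatch
    label: int
    source_id: str


def as_segmented(scene) -> SegmentedImage:
    """Adapt a SyntheticScene (or any scene-like object) to SegmentedImage."""
    if isinstance(scene, SegmentedImage):
        return scene
    source_id = getattr(scene, "source_id", None) or getattr(scene, "scene_id")
    return SegmentedImage(image=scene.image, mask=scene.mask,
                          label=scene.label, source_id=source_id)


def sample_viewing_point(seg: SegmentedImage, rng: np.random.Generator) -> ViewingPoint:
    """Draw a viewing point uniformly over the mask's foreground pixels."""
    fg = np.argwhere(np.asarray(seg.mask) != 0)
    if fg.shape[0] == 0:
        raise ValueError("cannot sample a viewing point from an empty mask")
    y, x = fg[rng.integers(fg.shape[0])]
    return ViewingPoint(y=int(y), x=int(x))


def _window_origin(pt: ViewingPoint, patch_size: int, shape) -> tuple[int, int]:
    h, w = shape
    y0 = min(max(pt.y - patch_size // 2, 0), h - patch_size)
    x0 = min(max(pt.x - patch_size // 2, 0), w - patch_size)
    return y0, x0


def extract_patch(seg: SegmentedImage, pt: ViewingPoint, patch_size: int = 100) -> ViewingPatch:
    """Extract the ``patch_size`` window centered on ``pt`` (clamped at borders)."""
    h, w = seg.mask.shape
    if patch_size > min(h, w):
        raise ValueError(f"patch_size {patch_size} exceeds image size {(h, w)}")
    if not (0 <= pt.y < h and 0 <= pt.x < w):
        raise ValueError(f"viewing point {pt} outside image bounds {(h, w)}")
    y0, x0 = _window_origin(pt, patch_size, (h, w))
    pixels = np.array(seg.image[y0:y0 + patch_size, x0:x0 + patch_size], copy=True)
    return ViewingPatch(pixels=pixels, center=pt, source_id=seg.source_id,
                        label=seg.label, background_removed=False)


def mask_background(patch: ViewingPatch, seg: SegmentedImage) -> ViewingPatch:
    """Zero every patch pixel outside the object mask (idempotent)."""
    if patch.source_id != seg.source_id:
        raise ValueError(f"patch source {patch.source_id!r} does not match "
                         f"segmentation {seg.source_id!r}")
    p = patch.pixels.shape[0]
    y0, x0 = _window_origin(patch.center, p, seg.mask.shape)
    window_mask = np.asarray(seg.mask[y0:y0 + p, x0:x0 + p]) != 0
    pixels = np.where(window_mask[..., None], patch.pixels, 0.0)
    return ViewingPatch(pixels=pixels, center=patch.center, source_id=patch.source_id,
                        label=patch.label, background_removed=True)


def build_patch_dataset(scenes, points_per_object: int = 5, split_fraction: float = 0.8,
                        rng: np.random.Generator | None = None, patch_size: int = 100,
                        split_level: str = "image") -> tuple[list[PatchPair], list[PatchPair]]:
    """Sample patches from scenes and split into train/validation sets.

    The split is performed at the source-image level by default (all
    patches from one image land in the same split) to prevent
    near-duplicate leakage between splits; ``split_level="patch"`` assigns
    each patch independently.
    """
    if points_per_object < 1:
        raise ValueError("points_per_object must be >= 1")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie in (0,1)")
    rng = rng if rng is not None else np.random.default_rng(0)
    segs = [as_segmented(s) for s in scenes]

    pairs: list[PatchPair] = []
    for seg in segs:
        for _ in range(points_per_object):
            pt = sample_viewing_point(seg, rng)
            patch = extract_patch(seg, pt, patch_size)
            pairs.append(PatchPair(patch=patch, patch_no_bg=mask_background(patch, seg),
                                   label=seg.label, source_id=seg.source_id))

    if split_level == "patch":
        n_val = int(round((1.0 - split_fraction) * len(pairs)))
        if n_val < 1 or n_val >= len(pairs):
            raise ValueError("too few patches for a nonempty train/validation split")
        order = rng.permutation(len(pairs))
        val_idx = set(order[:n_val].tolist())
        train = [p for i, p in enumerate(pairs) if i not in val_idx]
        val = [p for i, p in enumerate(pairs) if i in val_idx]
        return train, val

    n_scenes = len(segs)
    n_val = int(round((1.0 - split_fraction) * n_scenes))
    if n_val < 1 or n_val >= n_scenes:
        raise ValueError("too few scenes for a nonempty train/validation split")
    order = rng.permutation(n_scenes)
    val_ids = {segs[i].source_id for i in order[:n_val]}
    train = [p for p in pairs if p.source_id not in val_ids]
    val = [p for p in pairs if p.source_id in val_ids]
    return train, val


# ---------------------------------------------------------------------------
# on-disk patch datasets: directory of PNGs plus an index CSV
# ---------------------------------------------------------------------------

def write_patch_dataset(train: list[PatchPair], val: list[PatchPair], out_dir) -> None:
    from PIL import Image

    out = Path(out_dir)
    (out / "patches").mkdir(parents=True, exist_ok=True)
    with open(out / "index.csv", "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["patch_id", "source_id", "label", "y", "x", "split",
                      "background_removed", "file"])
        i = 0
        for split, pairs in (("train", train), ("val", val)):
            for pair in pairs:
                for patch, bg in ((pair.patch, 0), (pair.patch_no_bg, 1)):
                    pid = f"patch_{i:05d}"
                    fname = f"patches/{pid}.png"
                    Image.fromarray(np.round(patch.pixels * 255).astype(np.uint8)
                                    ).save(out / fname)
                    wtr.writerow([pid, pair.source_id, pair.label,
                                  patch.center.y, patch.center.x, split, bg, fname])
                    i += 1


def read_patch_dataset(in_dir) -> tuple[list[PatchPair], list[PatchPair]]:
    from PIL import Image

    root = Path(in_dir)
    rows = list(csv.DictReader(open(root / "index.csv", newline="")))
    out = {"train": [], "val": []}
    for plain, masked in zip(rows[0::2], rows[1::2]):
        assert plain["source_id"] == masked["source_id"]
        patches = []
        for row, bg in ((plain, False), (masked, True)):
            pixels = np.asarray(Image.open(root / row["file"]), dtype=np.float64) / 255.0
            patches.append(ViewingPatch(
                pixels=pixels, center=ViewingPoint(int(row["y"]), int(row["x"])),
                source_id=row["source_id"], label=int(row["label"]),
                background_removed=bg))
        out[plain["split"]].append(PatchPair(patch=patches[0], patch_no_bg=patches[1],
                                             label=int(plain["label"]),
                                             source_id=plain["source_id"]))
    return out["train"], out["val"]
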