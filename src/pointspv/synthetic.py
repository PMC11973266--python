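"""Synthetic segmented scenes and gaze logs.

Real training data for the pipeline is a photo dataset with per-object
segmentation masks plus eye-tracking recordings.  This module generates
structurally equivalent stand-ins so every downstream stage is testable
without external downloads or human data:

* scenes: one target object from one of K visually distinct shape families
  rendered on a textured background, with an exact binary mask.  The two
  default families are separable by coarse shape statistics — class 0 is a
  roundish blob with protrusions, class 1 an elongated ellipse — standing
  in for a two-category animal discrimination task.
* gaze logs: fixation/saccade event sequences biased toward the object,
  mimicking how an observer scans a target during recognition.

Coordinates are 0-based (row, col) = (y, x) with the origin at the
top-left; gaze-log CSVs store x = column, y = row.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.ndimage import gaussian_filter


@dataclass
class SyntheticScene:
    image: np.ndarray        # (H,W,3) float in [0,1]
    mask: np.ndarray         # (H,W) uint8, 1 = target object
    label: int
    scene_id: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("mask dimensions must equal image dimensions")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground pixel")


class GazeSample(NamedTuple):
    t_ms: float
    x: float
    y: float
    event: str  # "fixation" | "saccade"


@dataclass
class SyntheticGazeLog:
    trial_id: str
    samples: list[GazeSample]
    response_t: float

    def __post_init__(self):
        ts = [s.t_ms for s in self.samples]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be strictly increasing")
        if self.samples and self.response_t < self.samples[-1].t_ms:
            raise ValueError("response_t must be >= last sample time")

    @property
    def fixations(self) -> list[tuple[float, float]]:
        """Fixation centers as (y, x)."""
        return [(s.y, s.x) for s in self.samples if s.event == "fixation"]

    @property
    def n_saccades(self) -> int:
        return sum(1 for s in self.samples if s.event == "saccade")


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, size, plain: bool) -> np.ndarray:
    h, w = size
    if plain:
        return np.ones((h, w, 3), dtype=np.float64)
    bg = np.empty((h, w, 3))
    for c in range(3):
        noise = gaussian_filter(rng.random((h, w)), sigma=6.0)
        lo, hi = noise.min(), noise.max()
        bg[..., c] = 0.3 + 0.4 * (noise - lo) / max(hi - lo, 1e-12)
    return bg


def _shape_mask(rng: np.random.Generator, class_label: int, size) -> np.ndarray:
    """Rasterize one object of the given shape family."""
    h, w = size
    m = min(h, w)
    cy = h / 2.0 + rng.uniform(-0.07, 0.07) * h
    cx = w / 2.0 + rng.uniform(-0.07, 0.07) * w
    yy, xx = np.mgrid[0:h, 0:w]
    theta_img = np.arctan2(yy - cy, xx - cx)

    if class_label == 0:
        # roundish blob with low-order wobble and a few protrusions
        r0 = rng.uniform(0.18, 0.25) * m
        radius = np.full((h, w), r0)
        for k in (2, 3, 4, 5):
            radius += r0 * rng.uniform(0.03, 0.10) * np.sin(k * theta_img + rng.uniform(0, 2 * np.pi))
        for _ in range(rng.integers(2, 5)):
            t0 = rng.uniform(-np.pi, np.pi)
            width = rng.uniform(0.15, 0.3)
            amp = rng.uniform(0.25, 0.45) * r0
            dtheta = np.angle(np.exp(1j * (theta_img - t0)))
            radius += amp * np.exp(-(dtheta / width) ** 2)
        dist = np.hypot(yy - cy, xx - cx)
        return (dist <= radius).astype(np.uint8)

    # elongated family: class k >= 1 is an ellipse; aspect grows with k so
    # additional classes remain separable by elongation
    aspect = rng.uniform(2.6, 3.8) + 1.2 * (class_label - 1)
    a = rng.uniform(0.30, 0.38) * m / 2.0 * np.sqrt(aspect)
    b = a / aspect
    phi = rng.uniform(0, np.pi)
    u = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    v = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
    wobble = 1.0
    for k in (3, 5):
        wobble = wobble + 0.04 * np.sin(k * theta_img + rng.uniform(0, 2 * np.pi))
    return ((u / a) ** 2 + (v / b) ** 2 <= wobble ** 2).astype(np.uint8)


def generate_scene(class_label: int, size=(256, 256), rng_seed: int = 0,
                   n_classes: int = 2, plain_background: bool = False,
                   scene_id: str | None = None) -> SyntheticScene:
    """Render one segmented scene, deterministic for a fixed seed."""
    h, w = size
    if h < 128 or w < 128:
        raise ValueError("scene size must be at least 128x128")
    if not 0 <= class_label < n_classes:
        raise ValueError(f"class_label {class_label} outside 0..{n_classes - 1}")
    rng = np.random.default_rng(rng_seed)
    image = _background(rng, size, plain_background)
    mask = _shape_mask(rng, class_label, size)
    if not mask.any():  # pragma: no cover - shape families always cover center
        raise RuntimeError("degenerate shape rendered")

    # object color pushed away from the background mean for guaranteed
    # figure/ground contrast, plus mild within-object texture
    bg_mean = image.mean(axis=(0, 1))
    color = rng.uniform(0.0, 1.0, size=3)
    for c in range(3):
        if abs(color[c] - bg_mean[c]) < 0.2:
            color[c] = bg_mean[c] + 0.35 * (1 if color[c] >= bg_mean[c] else -1)
    color = np.clip(color, 0.0, 1.0)
    texture = gaussian_filter(rng.random(size), sigma=2.0)
    texture = 0.10 * (texture - texture.mean())
    fg = np.clip(color[None, None, :] + texture[..., None], 0.0, 1.0)
    image = np.where(mask[..., None].astype(bool), fg, image)
    return SyntheticScene(image=image.astype(np.float64), mask=mask,
                          label=int(class_label),
                          scene_id=scene_id or f"scene_{rng_seed}")


def generate_dataset(n: int, K: int = 2, size=(256, 256), rng_seed: int = 0,
                     plain_background: bool = False) -> list[SyntheticScene]:
    """Generate ``n`` scenes with class labels balanced to within one."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = np.random.SeedSequence(rng_seed).generate_state(n + 1)
    order = np.random.default_rng(seeds[-1]).permutation(n)
    labels = np.array([i % K for i in range(n)])[order]
    scenes = []
    for i in range(n):
        scenes.append(generate_scene(int(labels[i]), size=size,
                                     rng_seed=int(seeds[i] % (2 ** 31)),
                                     n_classes=K,
                                     plain_background=plain_background,
                                     scene_id=f"scene_{i:04d}"))
    return scenes


# ---------------------------------------------------------------------------
# gaze-log generation
# ---------------------------------------------------------------------------

def generate_gaze_log(scene: SyntheticScene, n_fixations: int, rng_seed: int = 0,
                      in_bbox_prob: float = 0.75,
                      trial_id: str | None = None) -> SyntheticGazeLog:
    """Synthesize a fixation/saccade event sequence over a scene.

    Fixation centers fall inside the object's bounding box with probability
    ``in_bbox_prob`` (default 0.75), emulating target-directed scanning.
    Each fixation is preceded by a saccade event; timestamps use plausible
    fixation (150-400 ms) and saccade (20-60 ms) durations.
    """
    if n_fixations < 0:
        raise ValueError("n_fixations must be >= 0")
    rng = np.random.default_rng(rng_seed)
    h, w = scene.mask.shape
    ys, xs = np.nonzero(scene.mask)
    y0, y1, x0, x1 = ys.min(), ys.max(), xs.min(), xs.max()
    samples: list[GazeSample] = []
    t = 0.0
    for _ in range(n_fixations):
        if rng.random() < in_bbox_prob:
            fy = rng.uniform(y0, y1)
            fx = rng.uniform(x0, x1)
        else:
            fy = rng.uniform(0, h - 1)
            fx = rng.uniform(0, w - 1)
        t += rng.uniform(20.0, 60.0)
        samples.append(GazeSample(t_ms=t, x=fx, y=fy, event="saccade"))
        t += rng.uniform(150.0, 400.0)
        samples.append(GazeSample(t_ms=t, x=fx, y=fy, event="fixation"))
    response_t = t + rng.uniform(200.0, 800.0)
    return SyntheticGazeLog(trial_id=trial_id or scene.scene_id,
                            samples=samples, response_t=response_t)


# ---------------------------------------------------------------------------
# on-disk formats: PNG image/mask pairs + index CSV; gaze CSV
# ---------------------------------------------------------------------------

def write_scene_dataset(scenes: list[SyntheticScene], out_dir, coco: bool = False) -> None:
    """Write scenes as PNG image/mask pairs plus an index CSV.

    With ``coco=True`` an annotations.json with uncompressed-RLE masks is
    written alongside, so the COCO-style reader can be exercised on the
    same fixtures.
    """
    from pathlib import Path
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    with open(out / "index.csv", "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["scene_id", "label", "image", "mask"])
        for sc in scenes:
            img8 = np.round(sc.image * 255).astype(np.uint8)
            Image.fromarray(img8).save(out / "images" / f"{sc.scene_id}.png")
            Image.fromarray((sc.mask * 255).astype(np.uint8)).save(
                out / "masks" / f"{sc.scene_id}.png")
            wtr.writerow([sc.scene_id, sc.label,
                          f"images/{sc.scene_id}.png", f"masks/{sc.scene_id}.png"])
    if coco:
        from .coco import write_coco_annotations
        write_coco_annotations(scenes, out / "annotations.json")


def read_scene_dataset(in_dir) -> list[SyntheticScene]:
    from pathlib import Path
    from PIL import Image

    root = Path(in_dir)
    scenes = []
    with open(root / "index.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            image = np.asarray(Image.open(root / row["image"]), dtype=np.float64) / 255.0
            mask = (np.asarray(Image.open(root / row["mask"])) > 127).astype(np.uint8)
            scenes.append(SyntheticScene(image=image, mask=mask,
                                         label=int(row["label"]),
                                         scene_id=row["scene_id"]))
    return scenes


def write_gaze_log(log: SyntheticGazeLog, path) -> None:
    with open(path, "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["trial_id", "t_ms", "x", "y", "event"])
        for s in log.samples:
            wtr.writerow([log.trial_id, f"{s.t_ms:.3f}", f"{s.x:.3f}", f"{s.y:.3f}", s.event])
        wtr.writerow([log.trial_id, f"{log.response_t:.3f}", "", "", "response"])


def read_gaze_log(path) -> SyntheticGazeLog:
    samples: list[GazeSample] = []
    trial_id = ""
    response_t = 0.0
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            trial_id = row["trial_id"]
            if row["event"] == "response":
                response_t = float(row["t_ms"])
            else:
                samples.append(GazeSample(t_ms=float(row["t_ms"]), x=float(row["x"]),
                                          y=float(row["y"]), event=row["event"]))
    if response_t == 0.0 and samples:
        response_t = samples[-1].t_ms
    return SyntheticGazeLog(trial_id=trial_id, samples=samples, response_t=response_t)
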