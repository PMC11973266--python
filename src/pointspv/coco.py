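"""Minimal COCO-style annotation I/O.

Supports the subset this package's fixtures use: per-object segmentation
given either as polygons (list of [x0,y0,x1,y1,...] rings) or as
uncompressed run-length encodings ({"counts": [...], "size": [H,W]} with
column-major, background-first counts).  Compressed (string) RLE is not
supported.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from skimage.draw import polygon as sk_polygon


def encode_rle(mask: np.ndarray) -> dict:
    """Binary mask -> uncompressed RLE (column-major counts, background first)."""
    flat = np.asarray(mask, dtype=np.uint8).flatten(order="F")
    counts: list[int] = []
    val = 0
    run = 0
    for v in flat:
        if v == val:
            run += 1
        else:
            counts.append(run)
            val = v
            run = 1
    counts.append(run)
    return {"counts": counts, "size": [int(mask.shape[0]), int(mask.shape[1])]}


def decode_rle(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=np.uint8)
    pos = 0
    val = 0
    for run in rle["counts"]:
        if val:
            flat[pos:pos + run] = 1
        pos += run
        val ^= 1
    if pos != h * w:
        raise ValueError("RLE counts do not cover the mask")
    return flat.reshape((h, w), order="F")


def polygons_to_mask(polys: list[list[float]], size: tuple[int, int]) -> np.ndarray:
    h, w = size
    mask = np.zeros((h, w), dtype=np.uint8)
    for ring in polys:
        xs = np.asarray(ring[0::2], dtype=np.float64)
        ys = np.asarray(ring[1::2], dtype=np.float64)
        rr, cc = sk_polygon(ys, xs, shape=(h, w))
        mask[rr, cc] = 1
    return mask


def write_coco_annotations(scenes, path) -> None:
    """Write scenes as a COCO-style JSON with uncompressed-RLE segmentation."""
    images, annotations, categories = [], [], {}
    for i, sc in enumerate(scenes):
        h, w = sc.mask.shape
        images.append({"id": i, "file_name": f"images/{sc.scene_id}.png",
                       "height": h, "width": w, "scene_id": sc.scene_id})
        annotations.append({"id": i, "image_id": i, "category_id": int(sc.label),
                            "segmentation": encode_rle(sc.mask),
                            "area": int(sc.mask.sum()), "iscrowd": 0})
        categories[int(sc.label)] = {"id": int(sc.label), "name": f"class_{sc.label}"}
    doc = {"images": images, "annotations": annotations,
           "categories": sorted(categories.values(), key=lambda c: c["id"])}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_coco_annotations(json_path, images_dir=None):
    """Read a COCO-style JSON into SegmentedImage objects.

    ``images_dir`` is the directory file_name entries are relative to
    (defaults to the JSON's directory).  One segmented image is produced
    per annotation; polygon and uncompressed-RLE segmentations are decoded.
    """
    from PIL import Image
    from .sampling import SegmentedImage

    json_path = Path(json_path)
    root = Path(images_dir) if images_dir is not None else json_path.parent
    with open(json_path) as fh:
        doc = json.load(fh)
    by_id = {im["id"]: im for im in doc["images"]}
    out = []
    for ann in doc["annotations"]:
        im = by_id[ann["image_id"]]
        pixels = np.asarray(Image.open(root / im["file_name"]).convert("RGB"),
                            dtype=np.float64) / 255.0
        seg = ann["segmentation"]
        if isinstance(seg, dict):
            mask = decode_rle(seg)
        else:
            mask = polygons_to_mask(seg, (im["height"], im["width"]))
        out.append(SegmentedImage(image=pixels, mask=mask,
                                  label=int(ann["category_id"]),
                                  source_id=im.get("scene_id", str(im["id"]))))
    return out
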