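"""Reading and writing LabelMe-style point annotations and cohort manifests.

The on-disk dialect is the one produced by the LabelMe tool for point
shapes: a JSON document with ``version``, ``imagePath``, ``imageHeight``,
``imageWidth`` and a ``shapes`` list of
``{"label": name, "points": [[x, y]], "shape_type": "point"}`` entries.
The reader is tolerant of label order and of full anatomical names used
as aliases; the writer is deterministic (sorted keys, fixed float format).
"""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .schemas import (
    AnnotatedImage,
    LandmarkSchema,
    PointAnnotation,
    SchemaError,
)

logger = logging.getLogger(__name__)

LABELME_VERSION = "5.0.1"
MANIFEST_COLUMNS = ("subject_id", "view", "image_path", "width", "height")


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/JPEG image as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def save_image(pixels: np.ndarray, path: str | os.PathLike) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path)


def read_labelme_json(path: str | os.PathLike, schema: LandmarkSchema,
                      subject_id: str | None = None,
                      load_pixels: bool = True) -> AnnotatedImage:
    """Read one LabelMe point-annotation file into an AnnotatedImage.

    Landmarks are reordered to schema order regardless of file order.
    Unknown extra labels are ignored with a warning; missing or duplicate
    schema landmarks and non-point shapes raise :class:`SchemaError`.
    """
    with open(path) as fh:
        doc = json.load(fh)

    found: dict[str, PointAnnotation] = {}
    for shape in doc.get("shapes", []):
        label = str(shape.get("label", ""))
        name = schema.resolve_name(label)
        if name is None:
            logger.warning("%s: ignoring unknown label %r", path, label)
            continue
        if shape.get("shape_type") != "point":
            raise SchemaError(
                f"{path}: shape for {label!r} has shape_type "
                f"{shape.get('shape_type')!r}, expected 'point'")
        pts = shape.get("points", [])
        if len(pts) != 1 or len(pts[0]) != 2:
            raise SchemaError(f"{path}: shape for {label!r} is not a single point")
        if name in found:
            raise SchemaError(f"{path}: duplicate landmark {name!r}")
        found[name] = PointAnnotation(name, float(pts[0][0]), float(pts[0][1]))

    missing = [n for n in schema.names if n not in found]
    if missing:
        raise SchemaError(f"{path}: missing landmarks: {', '.join(missing)}")
    landmarks = [found[n] for n in schema.names]

    width = int(doc["imageWidth"])
    height = int(doc["imageHeight"])
    image_path = doc.get("imagePath", "")
    pixels = None
    source = ""
    if load_pixels and image_path:
        source = os.path.join(os.path.dirname(os.fspath(path)), image_path)
        pixels = load_image(source)
        height, width = pixels.shape[:2]

    if subject_id is None:
        stem = os.path.splitext(os.path.basename(os.fspath(path)))[0]
        # simulator files are named "<subject>_<view>"; fall back to the stem
        suffix = f"_{schema.view}"
        subject_id = stem[: -len(suffix)] if stem.endswith(suffix) else stem

    return AnnotatedImage(
        subject_id=subject_id, view=schema.view, pixels=pixels,
        width=width, height=height, landmarks=landmarks, source_path=source,
    )


def write_labelme_json(img: AnnotatedImage, path: str | os.PathLike,
                       image_path: str | None = None) -> None:
    """Write the LabelMe point-annotation dialect for one image."""
    if image_path is None:
        image_path = os.path.basename(img.source_path) if img.source_path else ""
    doc = {
        "version": LABELME_VERSION,
        "flags": {},
        "imagePath": image_path,
        "imageData": None,
        "imageHeight": int(img.height),
        "imageWidth": int(img.width),
        "shapes": [
            {
                "label": p.name,
                "points": [[round(float(p.x), 6), round(float(p.y), 6)]],
                "group_id": None,
                "shape_type": "point",
                "flags": {},
            }
            for p in img.landmarks
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_manifest(images: Iterable[AnnotatedImage], path: str | os.PathLike,
                   image_paths: Sequence[str] | None = None) -> None:
    """Write a cohort manifest TSV (subject_id, view, image path, size)."""
    images = list(images)
    if image_paths is None:
        image_paths = [img.source_path for img in images]
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for img, ipath in zip(images, image_paths):
            fh.write(f"{img.subject_id}\t{img.view}\t{ipath}\t"
                     f"{img.width}\t{img.height}\n")


def read_manifest(path: str | os.PathLike) -> list[dict]:
    """Read a cohort manifest TSV into a list of row dicts."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MANIFEST_COLUMNS:
            raise ValueError(f"{path}: unexpected manifest header {header}")
        for line in fh:
            if not line.strip():
                continue
            sid, view, ipath, w, h = line.rstrip("\n").split("\t")
            rows.append({"subject_id": sid, "view": view, "image_path": ipath,
                         "width": int(w), "height": int(h)})
    return rows
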