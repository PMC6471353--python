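"""Image, annotation and report I/O.

All writes are atomic (write to a temp file in the target directory, then
rename), so a crashed run never leaves a truncated artifact behind.
Annotation files use 0-based row/col coordinates and half-open bounding
boxes throughout.
"""

from __future__ import annotations

import csv
import io as _io
import json
import os
import tempfile
from pathlib import Path

import numpy as np
from PIL import Image

from .synthetic import WormAnnotation

ANNOTATION_FORMAT = {
    "coordinates": "0-based (row, col)",
    "boxes": "half-open [row0, col0, row1, col1)",
}


def atomic_write_bytes(path, blob: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(blob)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path, text: str) -> None:
    atomic_write_bytes(path, text.encode())


def write_json(path, payload) -> None:
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_image(path, image: np.ndarray) -> None:
    buf = _io.BytesIO()
    Image.fromarray(image).save(buf, format="PNG")
    atomic_write_bytes(path, buf.getvalue())


def read_image(path) -> np.ndarray:
    with Image.open(path) as img:
        if img.mode not in ("L", "RGB"):
            img = img.convert("RGB" if img.mode in ("RGBA", "P", "CMYK") else "L")
        return np.asarray(img)


def write_annotations_json(path, annotations: list[WormAnnotation]) -> None:
    payload = {
        "format": ANNOTATION_FORMAT,
        "annotations": [ann.to_dict() for ann in annotations],
    }
    write_json(path, payload)


def read_annotations_json(path) -> list[WormAnnotation]:
    payload = read_json(path)
    return [WormAnnotation.from_dict(d) for d in payload["annotations"]]


def write_annotations_csv(path, annotations: list[WormAnnotation]) -> None:
    """Flat interchange format: one half-open bounding box per line."""
    buf = _io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["row0", "col0", "row1", "col1", "stage_label"])
    for ann in annotations:
        writer.writerow([*ann.bounding_box, ann.stage_label])
    atomic_write_text(path, buf.getvalue())


def write_grid_csv(path, grid) -> None:
    buf = _io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["row0", "col0"])
    for r, c in grid.offsets:
        writer.writerow([r, c])
    atomic_write_text(path, buf.getvalue())
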