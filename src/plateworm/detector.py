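"""Full-plate sliding-window detection.

The plate image is preprocessed globally (the blur and adaptive threshold
see the whole image, as on the capture device), tiled into overlapping
windows, and every window's HOG descriptor is scored by the trained SVM.
Every positively classified window becomes a detection — there is no
non-maximum suppression by default, so a worm straddling several windows
is framed several times, exactly as the plate overlays show; an optional
flag merges overlapping frames for downstream counting.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .classifier import TrainedModel, predict
from .hog import HogConfig, feature_fingerprint, window_descriptor
from .metrics import ConfusionCounts
from .preprocess import PreprocessConfig, preprocess
from .synthetic import WormAnnotation
from .windows import WindowGrid, tile


@dataclass(frozen=True)
class Detection:
    window: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    decision_value: float
    label: str = "positive"

    def to_dict(self) -> dict:
        return {"window": list(self.window),
                "decision_value": self.decision_value,
                "label": self.label}


@dataclass
class DetectionResult:
    detections: list[Detection]
    config: dict
    durations: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.detections)

    def grid(self) -> WindowGrid:
        c = self.config
        return tile(c["image_height"], c["image_width"],
                    c["window_size"], c["overlap_fraction"])

    def to_dict(self) -> dict:
        return {
            "detections": [d.to_dict() for d in self.detections],
            "config": self.config,
            "durations": self.durations,
        }


def detect(
    plate_image: np.ndarray,
    model: TrainedModel,
    hog_config: HogConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
    window_size: int = 168,
    overlap: float = 0.5,
    preprocess_on: bool = True,
    model_load_seconds: float = 0.0,
) -> DetectionResult:
    """Run the detection pipeline over one plate image.

    Refuses to run if the model's feature fingerprint does not match the
    requested preprocessing + HOG configuration.  Detections come out in
    row-major window order and are deterministic for fixed inputs.
    """
    hog_cfg = hog_config or HogConfig(window_size=window_size)
    if hog_cfg.window_size != window_size:
        hog_cfg = HogConfig(**{**hog_cfg.as_dict(), "window_size": window_size})
    pre_cfg = preprocess_config or PreprocessConfig()
    if pre_cfg.enabled != preprocess_on:
        pre_cfg = PreprocessConfig(**{**pre_cfg.as_dict(), "enabled": preprocess_on})
    model.check_fingerprint(feature_fingerprint(hog_cfg, pre_cfg))

    t0 = time.perf_counter()
    field_ = preprocess(plate_image, pre_cfg)
    grid = tile(field_.shape[0], field_.shape[1], window_size, overlap)
    descriptors = np.empty((len(grid), hog_cfg.descriptor_length))
    for i, offset in enumerate(grid.offsets):
        descriptors[i] = window_descriptor(field_, offset, hog_cfg)
    t_hog = time.perf_counter()

    labels, values = predict(model, descriptors)
    t_cls = time.perf_counter()

    w = grid.window_size
    detections = [
        Detection(window=(r, c, r + w, c + w), decision_value=float(values[i]))
        for i, (r, c) in enumerate(grid.offsets)
        if labels[i] > 0
    ]
    return DetectionResult(
        detections=detections,
        config={
            "image_height": field_.shape[0],
            "image_width": field_.shape[1],
            "window_size": window_size,
            "overlap_fraction": overlap,
            "preprocess_on": preprocess_on,
            "hog": hog_cfg.as_dict(),
            "preprocess": pre_cfg.as_dict(),
        },
        durations={
            "model_load": model_load_seconds,
            "hog": t_hog - t0,
            "classify": t_cls - t_hog,
        },
    )


def overlay(plate_image: np.ndarray, result: DetectionResult,
            color: tuple[int, int, int] = (0, 255, 0),
            thickness: int = 2) -> np.ndarray:
    """Draw a green frame around every detection on an RGB copy."""
    if plate_image.ndim == 2:
        canvas = np.stack([plate_image] * 3, axis=-1).astype(np.uint8)
    else:
        canvas = plate_image.astype(np.uint8).copy()
    col = np.array(color, dtype=np.uint8)
    h, w = canvas.shape[:2]
    for det in result.detections:
        r0, c0, r1, c1 = det.window
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"detection window {det.window} outside image {(h, w)}")
        t = thickness
        canvas[r0 : r0 + t, c0:c1] = col
        canvas[r1 - t : r1, c0:c1] = col
        canvas[r0:r1, c0 : c0 + t] = col
        canvas[r0:r1, c1 - t : c1] = col
    return canvas


def _boxes_intersect(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def match_detections(
    result: DetectionResult, truth: list[WormAnnotation]
) -> ConfusionCounts:
    """Score detections against ground truth at the plate level.

    A worm counts as detected (one true positive) when at least one
    positive window intersects its bounding box; an undetected worm is a
    false negative.  Windows are scored individually on the negative side:
    a positive window touching no worm box is a false positive, a negative
    window touching no worm box is a true negative.  Negative windows that
    touch a worm box are not counted — the worm-level tally already covers
    them.
    """
    worm_boxes = [ann.bounding_box for ann in truth]
    detected = [False] * len(worm_boxes)
    positive_windows = {det.window for det in result.detections}

    fp = 0
    for det in result.detections:
        hit = False
        for k, box in enumerate(worm_boxes):
            if _boxes_intersect(det.window, box):
                detected[k] = True
                hit = True
        if not hit:
            fp += 1

    tn = 0
    grid = result.grid()
    w = grid.window_size
    for r, c in grid.offsets:
        window = (r, c, r + w, c + w)
        if window in positive_windows:
            continue
        if not any(_boxes_intersect(window, box) for box in worm_boxes):
            tn += 1

    tp = sum(detected)
    return ConfusionCounts(tp=tp, fn=len(worm_boxes) - tp, tn=tn, fp=fp)


def merge_detections(result: DetectionResult) -> list[tuple[int, int, int, int]]:
    """Greedy union of overlapping detection windows (optional NMS stand-in).

    Returns merged bounding boxes ordered by first window; useful for
    counting rather than framing.
    """
    remaining = [det.window for det in result.detections]
    merged: list[tuple[int, int, int, int]] = []
    while remaining:
        box = remaining.pop(0)
        changed = True
        while changed:
            changed = False
            keep = []
            for other in remaining:
                if _boxes_intersect(box, other):
                    box = (min(box[0], other[0]), min(box[1], other[1]),
                           max(box[2], other[2]), max(box[3], other[3]))
                    changed = True
                else:
                    keep.append(other)
            remaining = keep
        merged.append(box)
    return merged
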