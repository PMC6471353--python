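"""Seeded procedural generator of backlit Petri-dish scenes.

Adult *C. elegans* are ~1 mm long and nearly transparent; under backlight
they appear as dark, slender, sinusoidally curved bodies on a bright
diffuse field.  At smartphone-capture resolution (3024 x 4032 over a 35 mm
dish) one worm spans roughly 100 px, i.e. about the diagonal of a 168-px
detection window.  This module renders plates at that geometry together
with the confounders that drive false positives on real dishes — hairline
scratches, pen inscriptions, and adhesive-tape corners — plus sensor noise
and a mild illumination gradient, and emits exact ground-truth annotations
so detection quality can be scored mechanically.

Worm bodies are drawn as bounded-curvature random walks with a sinusoidal
curvature profile (giving the characteristic undulating silhouette without
simulating locomotion) and a tapered width ``w(s) = w_max * sin(pi*s/L)``
that peaks at midbody and vanishes at head and tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .errors import PlacementError

DEFAULT_CROP_SIZE = 168


@dataclass(frozen=True)
class SceneConfig:
    """Everything that determines one rendered plate.

    Intensities are 8-bit gray levels; worms must be darker than the
    background (backlit contrast) and at least 3x longer than wide
    (slenderness), both enforced at construction.
    """

    image_height: int = 3024
    image_width: int = 4032
    n_worms: int = 50
    worm_length_range: tuple[float, float] = (70.0, 120.0)
    worm_width_range: tuple[float, float] = (6.0, 12.0)
    worm_intensity: int = 60
    background_intensity: int = 200
    noise_sigma: float = 6.0
    n_scratches: int = 2
    n_glyphs: int = 1
    n_tape_corners: int = 1
    dish_margin: int = 40
    illumination_gradient_amplitude: float = 15.0
    min_center_spacing: float = 130.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.worm_length_range[0] < 3.0 * self.worm_width_range[1]:
            raise ValueError(
                "slenderness violated: min worm length "
                f"{self.worm_length_range[0]} < 3 x max width "
                f"{self.worm_width_range[1]}"
            )
        if not (0 <= self.worm_intensity <= 255 and 0 <= self.background_intensity <= 255):
            raise ValueError("intensities must lie in [0, 255]")
        if self.worm_intensity >= self.background_intensity:
            raise ValueError(
                "worm_intensity must be below background_intensity "
                "(worms attenuate the backlight)"
            )
        if self.n_worms < 0:
            raise ValueError("n_worms must be nonnegative")

    @property
    def dish_center(self) -> tuple[float, float]:
        return (self.image_height / 2.0, self.image_width / 2.0)

    @property
    def dish_radius(self) -> float:
        return min(self.image_height, self.image_width) / 2.0 - self.dish_margin

    def as_dict(self) -> dict:
        return {
            "image_height": self.image_height,
            "image_width": self.image_width,
            "n_worms": self.n_worms,
            "worm_length_range": list(self.worm_length_range),
            "worm_width_range": list(self.worm_width_range),
            "worm_intensity": self.worm_intensity,
            "background_intensity": self.background_intensity,
            "noise_sigma": self.noise_sigma,
            "n_scratches": self.n_scratches,
            "n_glyphs": self.n_glyphs,
            "n_tape_corners": self.n_tape_corners,
            "dish_margin": self.dish_margin,
            "illumination_gradient_amplitude": self.illumination_gradient_amplitude,
            "min_center_spacing": self.min_center_spacing,
            "seed": self.seed,
        }


@dataclass
class WormAnnotation:
    """Ground truth for one rendered worm.

    ``centerline`` is an ordered (n, 2) array of (row, col) points spaced
    one pixel apart along the body axis; ``bounding_box`` is 0-based and
    half-open and contains every centerline point with the body half-width
    added on each side.
    """

    centerline: np.ndarray
    bounding_box: tuple[int, int, int, int]
    stage_label: str = "adult"
    max_width: float = 0.0

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)))

    @property
    def center(self) -> tuple[float, float]:
        r0, c0, r1, c1 = self.bounding_box
        return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)

    def to_dict(self) -> dict:
        return {
            "centerline": np.round(self.centerline, 2).tolist(),
            "bounding_box": list(self.bounding_box),
            "stage_label": self.stage_label,
            "max_width": round(self.max_width, 2),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WormAnnotation":
        return cls(
            centerline=np.asarray(d["centerline"], dtype=np.float64),
            bounding_box=tuple(d["bounding_box"]),
            stage_label=d.get("stage_label", "adult"),
            max_width=float(d.get("max_width", 0.0)),
        )


@dataclass
class LabeledCropSet:
    """Window-sized crops with labels and per-crop generation provenance."""

    crops: np.ndarray  # (n, size, size) uint8
    labels: list[str]  # "positive" / "negative"
    provenance: list[dict]

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def crop_size(self) -> int:
        return self.crops.shape[1]


_MAX_PLACEMENT_TRIES = 200


def _worm_shape_local(config: SceneConfig, rng: np.random.Generator):
    """Centerline of a worm around the origin, plus its maximal half-width."""
    length = rng.uniform(*config.worm_length_range)
    w_max = rng.uniform(*config.worm_width_range)
    n_steps = int(round(length))
    # sinusoidal curvature -> undulating body; bounded so the short body
    # cannot curl back onto itself
    amplitude = rng.uniform(0.02, 0.06)
    wavelength = rng.uniform(0.6, 1.4) * length
    phase = rng.uniform(0.0, 2.0 * np.pi)
    jitter = rng.uniform(-0.01, 0.01, size=n_steps)
    s = np.arange(n_steps)
    curvature = amplitude * np.sin(2.0 * np.pi * s / wavelength + phase) + jitter

    heading = rng.uniform(0.0, 2.0 * np.pi) + np.concatenate([[0.0], np.cumsum(curvature[:-1])])
    steps = np.column_stack([np.sin(heading), np.cos(heading)])
    points = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    points -= points.mean(axis=0)
    return points, w_max, length


def generate_worm_shape(config: SceneConfig, rng: np.random.Generator) -> WormAnnotation:
    """Place one worm-shaped curve inside the dish region.

    The local shape is recentred and translated to a uniformly sampled
    position whose whole body stays inside the dish; if the dish cannot
    contain the body at all a :class:`PlacementError` is raised.
    """
    cy, cx = config.dish_center
    for _ in range(_MAX_PLACEMENT_TRIES):
        points, w_max, _ = _worm_shape_local(config, rng)
        body_radius = float(np.max(np.linalg.norm(points, axis=1))) + w_max / 2.0 + 1.0
        free = config.dish_radius - body_radius
        if free <= 0:
            continue
        radius = free * np.sqrt(rng.uniform())
        angle = rng.uniform(0.0, 2.0 * np.pi)
        offset = np.array([cy + radius * np.sin(angle), cx + radius * np.cos(angle)])
        centerline = points + offset
        return _annotate(centerline, w_max, config)
    raise PlacementError(
        "could not place a worm inside the dish region: body exceeds "
        f"dish radius {config.dish_radius:.0f} px"
    )


def _annotate(centerline: np.ndarray, w_max: float, config: SceneConfig) -> WormAnnotation:
    half = w_max / 2.0
    r0 = int(np.floor(centerline[:, 0].min() - half))
    c0 = int(np.floor(centerline[:, 1].min() - half))
    r1 = int(np.ceil(centerline[:, 0].max() + half)) + 1
    c1 = int(np.ceil(centerline[:, 1].max() + half)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1 = min(r1, config.image_height)
    c1 = min(c1, config.image_width)
    return WormAnnotation(
        centerline=centerline, bounding_box=(r0, c0, r1, c1), max_width=w_max
    )


def _paint_worm(image: np.ndarray, ann: WormAnnotation, intensity: int) -> None:
    n = len(ann.centerline)
    arclen = np.arange(n)
    widths = ann.max_width * np.sin(np.pi * arclen / max(n - 1, 1))
    for (r, c), w in zip(ann.centerline, widths):
        rr, cc = draw_disk((r, c), max(w / 2.0, 0.6), shape=image.shape)
        image[rr, cc] = np.minimum(image[rr, cc], intensity)


def _thick_line(image, p0, p1, width, intensity) -> None:
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    n = max(int(np.linalg.norm(p1 - p0)), 2)
    for t in np.linspace(0.0, 1.0, n):
        r, c = p0 + t * (p1 - p0)
        rr, cc = draw_disk((r, c), max(width / 2.0, 0.6), shape=image.shape)
        image[rr, cc] = np.minimum(image[rr, cc], intensity)


def _box_of(points: np.ndarray, pad: float, shape) -> tuple[int, int, int, int]:
    r0 = max(int(np.floor(points[:, 0].min() - pad)), 0)
    c0 = max(int(np.floor(points[:, 1].min() - pad)), 0)
    r1 = min(int(np.ceil(points[:, 0].max() + pad)) + 1, shape[0])
    c1 = min(int(np.ceil(points[:, 1].max() + pad)) + 1, shape[1])
    return (r0, c0, r1, c1)


def _add_scratch(image, config, rng) -> tuple[int, int, int, int]:
    """Hairline scratch: a long, thin, dark chord across the dish."""
    cy, cx = config.dish_center
    radius = config.dish_radius
    a0, a1 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    p0 = np.array([cy + 0.9 * radius * np.sin(a0), cx + 0.9 * radius * np.cos(a0)])
    p1 = np.array([cy + 0.9 * radius * np.sin(a1), cx + 0.9 * radius * np.cos(a1)])
    if np.linalg.norm(p1 - p0) < radius * 0.5:  # avoid degenerate short chords
        p1 = 2.0 * np.array([cy, cx]) - p0
    width = rng.uniform(1.0, 3.0)
    intensity = config.worm_intensity + 20
    _thick_line(image, p0, p1, width, intensity)
    return _box_of(np.vstack([p0, p1]), width, image.shape)


def _add_glyph(image, config, rng) -> tuple[int, int, int, int]:
    """Inscription fragment: a cluster of marker-pen strokes.

    A felt-tip line on the lid is ~0.5 mm wide, i.e. tens of pixels at the
    working resolution — far thicker than a worm body.
    """
    cy, cx = config.dish_center
    radius = rng.uniform(0.2, 0.7) * config.dish_radius
    angle = rng.uniform(0.0, 2.0 * np.pi)
    anchor = np.array([cy + radius * np.sin(angle), cx + radius * np.cos(angle)])
    points = [anchor]
    for _ in range(rng.integers(2, 5)):
        start = anchor + rng.uniform(-60, 60, size=2)
        direction = rng.uniform(0.0, np.pi)
        length = rng.uniform(50.0, 120.0)
        end = start + length * np.array([np.sin(direction), np.cos(direction)])
        _thick_line(image, start, end, rng.uniform(20.0, 50.0), config.worm_intensity)
        points += [start, end]
    return _box_of(np.vstack(points), 25.0, image.shape)


def _add_tape_corner(image, config, rng) -> tuple[int, int, int, int]:
    """Adhesive-tape corner: a solid right-angle wedge at the image edge."""
    h, w = image.shape
    size = rng.uniform(60.0, 140.0)
    corner = rng.integers(0, 4)
    base_r = 0.0 if corner in (0, 1) else float(h)
    base_c = 0.0 if corner in (0, 2) else float(w)
    dr = 1.0 if corner in (0, 1) else -1.0
    dc = 1.0 if corner in (0, 2) else -1.0
    rows = np.array([base_r, base_r + dr * size, base_r])
    cols = np.array([base_c, base_c, base_c + dc * size])
    rr, cc = draw_polygon(rows, cols, shape=image.shape)
    intensity = config.worm_intensity + 30
    image[rr, cc] = np.minimum(image[rr, cc], intensity)
    return _box_of(np.column_stack([rows, cols]), 1.0, image.shape)


def _render(config: SceneConfig, rng: np.random.Generator):
    """Compose one plate; returns (image, worm annotations, distractor boxes)."""
    h, w = config.image_height, config.image_width
    image = np.full((h, w), float(config.background_intensity))

    # mild linear illumination gradient in a random direction
    if config.illumination_gradient_amplitude > 0:
        direction = rng.uniform(0.0, 2.0 * np.pi)
        rows = (np.arange(h) - h / 2.0)[:, None]
        cols = (np.arange(w) - w / 2.0)[None, :]
        proj = rows * np.sin(direction) + cols * np.cos(direction)
        half_diag = 0.5 * np.hypot(h, w)
        image += config.illumination_gradient_amplitude * 0.5 * proj / half_diag

    # dish rim: a dark ring at the dish boundary
    cy, cx = config.dish_center
    rows = (np.arange(h) - cy)[:, None]
    cols = (np.arange(w) - cx)[None, :]
    dist = np.sqrt(rows * rows + cols * cols)
    rim = np.abs(dist - config.dish_radius) < 2.0
    image[rim] = np.minimum(image[rim], config.worm_intensity + 40)

    annotations: list[WormAnnotation] = []
    for _ in range(config.n_worms):
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            ann = generate_worm_shape(config, rng)
            center = np.array(ann.center)
            if all(
                np.linalg.norm(center - np.array(prev.center)) >= config.min_center_spacing
                for prev in annotations
            ):
                annotations.append(ann)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {config.n_worms} worms with center spacing "
                f">= {config.min_center_spacing} px inside the dish"
            )
    for ann in annotations:
        _paint_worm(image, ann, config.worm_intensity)

    distractors: list[tuple[int, int, int, int]] = []
    for _ in range(config.n_scratches):
        distractors.append(_add_scratch(image, config, rng))
    for _ in range(config.n_glyphs):
        distractors.append(_add_glyph(image, config, rng))
    for _ in range(config.n_tape_corners):
        distractors.append(_add_tape_corner(image, config, rng))

    if config.noise_sigma > 0:
        image += rng.normal(0.0, config.noise_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, annotations, distractors


def render_scene(
    config: SceneConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[WormAnnotation]]:
    """Render one plate image with its worm annotations.

    Distractors are rendered but never annotated — they are background as
    far as ground truth is concerned.  With ``rng`` omitted the generator
    is seeded from ``config.seed``, so identical configs give bit-identical
    scenes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    image, annotations, _ = _render(config, rng)
    return image, annotations


def _crop_scene_config(config: SceneConfig, crop_size: int) -> SceneConfig:
    # the mini-scene must hold a whole worm regardless of crop size
    scene = max(2 * crop_size, int(2.5 * config.worm_length_range[1])) + 24
    return replace(
        config,
        image_height=scene,
        image_width=scene,
        dish_margin=min(config.dish_margin, scene // 8),
        n_worms=0,
        n_scratches=0,
        n_glyphs=0,
        n_tape_corners=0,
    )


def _clamp(value: int, low: int, high: int) -> int:
    return max(low, min(value, high))


def make_crop_set(
    n_positive: int,
    n_negative: int,
    config: SceneConfig | None = None,
    rng: np.random.Generator | None = None,
    crop_size: int = DEFAULT_CROP_SIZE,
    distractor_fraction: float = 0.3,
    positive_jitter: int = 20,
) -> LabeledCropSet:
    """Build a labeled set of window-sized crops from mini-scenes.

    Positive crops render a single worm and are centered on its bounding
    box up to a uniform jitter of ``positive_jitter`` px per axis — squares
    picked by hand around a worm are never pixel-centered, and a detector
    sliding at 50% overlap sees worms off-center too (clamped at scene
    edges).  Negative crops come from worm-free
    scenes; a ``distractor_fraction`` share of them is centered on a
    scratch, inscription fragment or tape corner so the classifier must
    face the plate's real false-positive sources, while the rest show only
    background, rim and noise.  Positives precede negatives in the output;
    shuffle downstream if order matters.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("crop counts must be nonnegative")
    cfg = config or SceneConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    base = _crop_scene_config(cfg, crop_size)

    crops = np.empty((n_positive + n_negative, crop_size, crop_size), dtype=np.uint8)
    labels: list[str] = []
    provenance: list[dict] = []
    max_offset = base.image_height - crop_size

    for i in range(n_positive):
        crop_seed = int(rng.integers(0, 2**31))
        crop_rng = np.random.default_rng(crop_seed)
        scene_cfg = replace(base, n_worms=1)
        image, anns, _ = _render(scene_cfg, crop_rng)
        cy, cx = anns[0].center
        jr = int(crop_rng.integers(-positive_jitter, positive_jitter + 1)) if positive_jitter else 0
        jc = int(crop_rng.integers(-positive_jitter, positive_jitter + 1)) if positive_jitter else 0
        r0 = _clamp(int(round(cy)) + jr - crop_size // 2, 0, max_offset)
        c0 = _clamp(int(round(cx)) + jc - crop_size // 2, 0, max_offset)
        crops[i] = image[r0 : r0 + crop_size, c0 : c0 + crop_size]
        labels.append("positive")
        provenance.append({"index": i, "label": "positive", "seed": crop_seed,
                           "scene_offset": [r0, c0]})

    for j in range(n_negative):
        i = n_positive + j
        crop_seed = int(rng.integers(0, 2**31))
        with_distractor = bool(rng.uniform() < distractor_fraction)
        kind = rng.choice(["scratch", "glyph", "tape"]) if with_distractor else "none"
        crop_rng = np.random.default_rng(crop_seed)
        # vary the mini-scene extent so the dish rim crosses negative crops
        # at a range of curvatures, as it does on plates of different scale
        scale = int(crop_rng.choice([2, 3, 4, 6]))
        scene_cfg = replace(
            base,
            image_height=crop_size * scale + 24,
            image_width=crop_size * scale + 24,
            n_scratches=int(kind == "scratch"),
            n_glyphs=int(kind == "glyph"),
            n_tape_corners=int(kind == "tape"),
        )
        neg_max_offset = scene_cfg.image_height - crop_size
        image, _, boxes = _render(scene_cfg, crop_rng)
        if with_distractor and boxes:
            r0b, c0b, r1b, c1b = boxes[0]
            cy, cx = (r0b + r1b) // 2, (c0b + c1b) // 2
            r0 = _clamp(cy - crop_size // 2, 0, neg_max_offset)
            c0 = _clamp(cx - crop_size // 2, 0, neg_max_offset)
        else:
            # sample the crop center inside the dish, where real negative
            # squares would have been selected
            scy, scx = scene_cfg.dish_center
            rad = scene_cfg.dish_radius * np.sqrt(crop_rng.uniform())
            ang = crop_rng.uniform(0.0, 2.0 * np.pi)
            r0 = _clamp(int(scy + rad * np.sin(ang)) - crop_size // 2, 0, neg_max_offset)
            c0 = _clamp(int(scx + rad * np.cos(ang)) - crop_size // 2, 0, neg_max_offset)
        crops[i] = image[r0 : r0 + crop_size, c0 : c0 + crop_size]
        labels.append("negative")
        provenance.append({"index": i, "label": "negative", "seed": crop_seed,
                           "distractor": kind, "scene_offset": [r0, c0]})

    return LabeledCropSet(crops=crops, labels=labels, provenance=provenance)
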