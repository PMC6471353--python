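"""Histogram of Oriented Gradients over a binarized-edge gradient field.

The descriptor follows the edge-based variant used for worm detection:
8 x 8-px cells, 9 unsigned orientation bins of 20 degrees spanning
0-180 degrees, 2 x 2-cell blocks stepping one cell (50% overlap), L2 block
normalization, and row-major concatenation.  Votes are hard-assigned to a
single bin and weighted by gradient magnitude — there is no bilinear
interpolation between bins or cells, which suits the quantized gradients a
binary edge map produces.  A 168-px window at these defaults yields
(21 - 1)^2 blocks x 36 values = 14 400 features.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import GradientField

logger = logging.getLogger(__name__)

L2_EPSILON = 1e-6


@dataclass(frozen=True)
class HogConfig:
    cell_size: int = 8
    n_bins: int = 9
    bin_width: float = 20.0
    block_cells: int = 2
    block_stride: int = 1
    window_size: int = 168
    magnitude_weighted: bool = True  # False counts edge pixels instead
    soft_binning: bool = False  # classic linear vote split between bins

    def __post_init__(self) -> None:
        if self.n_bins * self.bin_width != 180.0:
            raise ValueError("n_bins * bin_width must span 180 degrees")
        if self.block_stride > self.block_cells:
            raise ValueError("block_stride must not exceed block_cells")
        if self.window_size % self.cell_size != 0:
            logger.warning(
                "window_size %d not divisible by cell_size %d; "
                "trailing pixels will be truncated from the cell grid",
                self.window_size,
                self.cell_size,
            )

    @property
    def cells_per_side(self) -> int:
        return self.window_size // self.cell_size

    @property
    def blocks_per_side(self) -> int:
        return (self.cells_per_side - self.block_cells) // self.block_stride + 1

    @property
    def descriptor_length(self) -> int:
        return self.blocks_per_side**2 * self.block_cells**2 * self.n_bins

    def as_dict(self) -> dict:
        return {
            "cell_size": self.cell_size,
            "n_bins": self.n_bins,
            "bin_width": self.bin_width,
            "block_cells": self.block_cells,
            "block_stride": self.block_stride,
            "window_size": self.window_size,
            "magnitude_weighted": self.magnitude_weighted,
            "soft_binning": self.soft_binning,
        }


def feature_fingerprint(hog_config: HogConfig, preprocess_config=None) -> str:
    """Stable hash of the feature-defining configuration.

    Stored inside trained models so that a model is refused at predict time
    when the feature pipeline no longer matches the one it was trained on.
    """
    payload: dict = {"hog": hog_config.as_dict()}
    if preprocess_config is not None:
        payload["preprocess"] = preprocess_config.as_dict()
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def orientation_bin(g_x: float, g_y: float, config: HogConfig | None = None) -> tuple[int, float]:
    """Bin index and magnitude of a single gradient vector.

    The direction is the full-quadrant arctangent folded into [0, 180)
    (unsigned orientation: a gradient and its negation share a bin); the bin
    is ``floor(theta / bin_width)``.  A zero vector returns magnitude 0 and
    bin 0 — it contributes nothing to any histogram.
    """
    cfg = config or HogConfig()
    magnitude = float(np.hypot(g_x, g_y))
    if magnitude == 0.0:
        return 0, 0.0
    theta = np.degrees(np.arctan2(g_y, g_x)) % 180.0
    index = min(int(theta // cfg.bin_width), cfg.n_bins - 1)
    return index, magnitude


def _orientation_arrays(field: GradientField, cfg: HogConfig) -> tuple[np.ndarray, np.ndarray]:
    gx = field.g_x.astype(np.float64)
    gy = field.g_y.astype(np.float64)
    magnitude = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 180.0
    bins = np.minimum((theta // cfg.bin_width).astype(np.intp), cfg.n_bins - 1)
    return bins, magnitude


def cell_histograms(field: GradientField, config: HogConfig | None = None) -> np.ndarray:
    """Accumulate per-cell orientation histograms.

    Returns an array of shape ``(cells_y, cells_x, n_bins)`` where entry b of
    each cell holds the summed magnitude (or pixel count when unweighted) of
    the gradients whose orientation falls in bin b.  Total histogram mass per
    cell therefore equals the total gradient magnitude in that cell.
    """
    cfg = config or HogConfig()
    h, w = field.shape
    if h % cfg.cell_size or w % cfg.cell_size:
        raise ValueError(
            f"field shape {(h, w)} not divisible by cell_size {cfg.cell_size}"
        )
    cells_y, cells_x = h // cfg.cell_size, w // cfg.cell_size
    bins, magnitude = _orientation_arrays(field, cfg)
    weights = magnitude if cfg.magnitude_weighted else (magnitude > 0).astype(np.float64)

    rows = np.arange(h)[:, None] // cfg.cell_size
    cols = np.arange(w)[None, :] // cfg.cell_size
    cell_index = rows * cells_x + cols

    if not cfg.soft_binning:
        flat = cell_index * cfg.n_bins + bins
        hist = np.bincount(
            flat.ravel(), weights=weights.ravel(), minlength=cells_y * cells_x * cfg.n_bins
        )
        return hist.reshape(cells_y, cells_x, cfg.n_bins)

    # soft variant: split each vote linearly between the two nearest bin centers
    gx = field.g_x.astype(np.float64)
    gy = field.g_y.astype(np.float64)
    theta = np.degrees(np.arctan2(gy, gx)) % 180.0
    pos = theta / cfg.bin_width - 0.5
    lo = np.floor(pos).astype(np.intp)
    frac = pos - lo
    lo_bin = lo % cfg.n_bins
    hi_bin = (lo + 1) % cfg.n_bins
    n_total = cells_y * cells_x * cfg.n_bins
    hist = np.bincount(
        (cell_index * cfg.n_bins + lo_bin).ravel(),
        weights=(weights * (1.0 - frac)).ravel(),
        minlength=n_total,
    )
    hist += np.bincount(
        (cell_index * cfg.n_bins + hi_bin).ravel(),
        weights=(weights * frac).ravel(),
        minlength=n_total,
    )
    return hist.reshape(cells_y, cells_x, cfg.n_bins)


def block_normalize(grid: np.ndarray, config: HogConfig | None = None) -> np.ndarray:
    """L2-normalize overlapping blocks of cells and concatenate them.

    Blocks of ``block_cells x block_cells`` cells step ``block_stride`` cells
    in each dimension; each 36-element block vector v is divided by
    ``sqrt(||v||^2 + eps^2)`` so all-zero blocks stay zero.  Concatenation is
    row-major over blocks, row-major over cells within a block, bins in
    ascending angle.
    """
    cfg = config or HogConfig()
    cells_y, cells_x, n_bins = grid.shape
    if cells_y < cfg.block_cells or cells_x < cfg.block_cells:
        raise ValueError(
            f"cell grid {(cells_y, cells_x)} smaller than one "
            f"{cfg.block_cells}x{cfg.block_cells} block"
        )
    s, b = cfg.block_stride, cfg.block_cells
    ny = (cells_y - b) // s + 1
    nx = (cells_x - b) // s + 1
    view = np.lib.stride_tricks.sliding_window_view(grid, (b, b, n_bins))
    blocks = view[::s, ::s, 0].reshape(ny, nx, b * b * n_bins)
    norms = np.sqrt(np.einsum("ijk,ijk->ij", blocks, blocks) + L2_EPSILON**2)
    return (blocks / norms[:, :, None]).reshape(-1)


def window_descriptor(
    field: GradientField,
    roi: tuple[int, int] = (0, 0),
    config: HogConfig | None = None,
) -> np.ndarray:
    """HOG feature vector for one detection window of the gradient field."""
    cfg = config or HogConfig()
    r0, c0 = roi
    h, w = field.shape
    if r0 < 0 or c0 < 0 or r0 + cfg.window_size > h or c0 + cfg.window_size > w:
        raise ValueError(
            f"window at {roi} size {cfg.window_size} exceeds field shape {(h, w)}"
        )
    # truncate to whole cells when the window size is not cell-divisible
    span = (cfg.window_size // cfg.cell_size) * cfg.cell_size
    sub = GradientField(
        g_x=field.g_x[r0 : r0 + span, c0 : c0 + span],
        g_y=field.g_y[r0 : r0 + span, c0 : c0 + span],
    )
    return block_normalize(cell_histograms(sub, cfg), cfg)
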