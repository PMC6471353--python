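"""Tiling of a plate image into square detection windows.

A 3024 x 4032 smartphone capture tiles into exactly 18 x 24 = 432
nonoverlapping 168-px windows; at the default 50% overlap the same image
yields 35 x 47 = 1645 windows.  Trailing pixels that cannot host a full
window are dropped rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class WindowGrid:
    """Row-major offsets of half-open windows [r, r+w) x [c, c+w)."""

    window_size: int
    overlap_fraction: float
    stride: int
    image_shape: tuple[int, int]
    offsets: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def shape(self) -> tuple[int, int]:
        """Window counts (rows, cols)."""
        h, w = self.image_shape
        return (
            (h - self.window_size) // self.stride + 1,
            (w - self.window_size) // self.stride + 1,
        )

    def boxes(self) -> np.ndarray:
        """(n, 4) array of (row0, col0, row1, col1) half-open boxes."""
        arr = np.array(self.offsets, dtype=np.int64).reshape(-1, 2)
        return np.hstack([arr, arr + self.window_size])


def tile(
    image_height: int,
    image_width: int,
    window_size: int = 168,
    overlap_fraction: float = 0.5,
) -> WindowGrid:
    """Enumerate all fully-contained windows at the given size and overlap.

    The stride is ``round(window_size * (1 - overlap_fraction))`` and the
    per-axis count is ``floor((extent - window_size) / stride) + 1``.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    if window_size > min(image_height, image_width):
        raise ValueError(
            f"window_size {window_size} exceeds image extent "
            f"{(image_height, image_width)}"
        )
    stride = int(round(window_size * (1.0 - overlap_fraction)))
    stride = max(stride, 1)
    rows = range(0, image_height - window_size + 1, stride)
    cols = range(0, image_width - window_size + 1, stride)
    offsets = tuple((r, c) for r in rows for c in cols)
    return WindowGrid(
        window_size=window_size,
        overlap_fraction=overlap_fraction,
        stride=stride,
        image_shape=(image_height, image_width),
        offsets=offsets,
    )


def coverage_mask(grid: WindowGrid) -> np.ndarray:
    """Boolean map of pixels covered by at least one window.

    Useful for diagnosing worms missed because no window reached them: the
    dropped trailing margin is exactly the mask's false region.
    """
    mask = np.zeros(grid.image_shape, dtype=bool)
    w = grid.window_size
    for r, c in grid.offsets:
        mask[r : r + w, c : c + w] = True
    return mask
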