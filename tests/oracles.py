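"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plainly as possible — nested loops, explicit
padding, scalar arithmetic — and stays independent of the vectorized code
paths it checks.
"""

import numpy as np

from plateworm.hog import HogConfig, orientation_bin
from plateworm.preprocess import gaussian_kernel_1d


def adaptive_binarize_bruteforce(img, block_size, c=3.0, maxval=255):
    """Per-pixel Gaussian-weighted neighborhood threshold, fully looped."""
    w1 = gaussian_kernel_1d(block_size)
    kernel = np.outer(w1, w1)
    half = block_size // 2
    padded = np.pad(img.astype(np.float64), half, mode="symmetric")
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for col in range(w):
            block = padded[r : r + block_size, col : col + block_size]
            threshold = float((block * kernel).sum()) - c
            if img[r, col] > threshold:
                out[r, col] = maxval
    return out


def hog_bruteforce(g_x, g_y, cfg: HogConfig):
    """Cell histograms and normalized descriptor via scalar loops."""
    h, w = g_x.shape
    cells_y, cells_x = h // cfg.cell_size, w // cfg.cell_size
    grid = np.zeros((cells_y, cells_x, cfg.n_bins))
    for r in range(cells_y * cfg.cell_size):
        for col in range(cells_x * cfg.cell_size):
            b, m = orientation_bin(float(g_x[r, col]), float(g_y[r, col]), cfg)
            if m > 0:
                weight = m if cfg.magnitude_weighted else 1.0
                grid[r // cfg.cell_size, col // cfg.cell_size, b] += weight

    pieces = []
    for by in range(0, cells_y - cfg.block_cells + 1, cfg.block_stride):
        for bx in range(0, cells_x - cfg.block_cells + 1, cfg.block_stride):
            v = grid[by : by + cfg.block_cells, bx : bx + cfg.block_cells, :].ravel()
            pieces.append(v / np.sqrt(np.dot(v, v) + 1e-12))
    return grid, np.concatenate(pieces)


def window_count_bruteforce(extent, window, stride):
    """Count windows by explicit stepping."""
    count = 0
    pos = 0
    while pos + window <= extent:
        count += 1
        pos += stride
    return count


def decision_bruteforce(model, z):
    """f(z) = sum_i a_i K(s_i, z) + b evaluated one support vector at a time."""
    total = 0.0
    for sv, a in zip(model.support_vectors, model.dual_coefficients):
        k = 0.0
        for u, v in zip(sv, z):
            k += u if u < v else v
        total += a * k
    return total + model.bias


def dual_objective(gram, alpha_signed):
    """Dual objective W(alpha) = sum alpha_i - 1/2 sum_ij a_i a_j K_ij,
    with a_i = alpha_i * y_i the signed coefficients."""
    alpha = np.abs(alpha_signed)
    return float(alpha.sum() - 0.5 * alpha_signed @ gram @ alpha_signed)
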