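"""Histogram of Oriented Gradients with a fixed 64x128 geometry.

The descriptor follows the classic pedestrian-detection construction:
Sobel gradients, unsigned orientations folded to [0, 180) degrees,
9-bin magnitude-weighted cell histograms over 8x8-pixel cells with
linear interpolation between the two nearest bin centers, and 2x2-cell
blocks at one-cell stride whose concatenated 36-vectors are L2
normalized.  On a 64-wide by 128-tall input this yields an 8x16 cell
grid, 7x15 = 105 blocks and a 105 * 36 = 3780-dimensional descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import DomainError
from .preprocess import resize_image

HOG_WIDTH = 64
HOG_HEIGHT = 128
CELL = 8
BINS = 9
BLOCK_CELLS = 2  # 2x2 cells per block
BIN_WIDTH = 180.0 / BINS
NORM_EPS = 1e-5  # stabilizer k in v / sqrt(|v|^2 + k^2)


@dataclass
class GradientField:
    """Signed per-pixel gradients with magnitude and unsigned orientation."""

    mx: np.ndarray
    my: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray  # degrees in [0, 180)


@dataclass
class HOGDescriptor:
    vector: np.ndarray  # (3780,)
    geometry: dict = field(
        default_factory=lambda: {
            "image": (HOG_HEIGHT, HOG_WIDTH),
            "cell": CELL,
            "bins": BINS,
            "block": (BLOCK_CELLS, BLOCK_CELLS),
            "block_stride_cells": 1,
            "blocks": (HOG_HEIGHT // CELL - 1, HOG_WIDTH // CELL - 1),
            "block_vector": BLOCK_CELLS * BLOCK_CELLS * BINS,
        }
    )


def sobel_gradients(image: np.ndarray) -> GradientField:
    """3x3 Sobel gradients with reflected borders.

    Magnitude is ``sqrt(Mx^2 + My^2)``; orientation is ``atan2(My, Mx)``
    folded to [0, 180) degrees (unsigned orientation).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise DomainError("need a 2-D image of at least 3x3 pixels")
    mx = ndimage.sobel(image, axis=1, mode="reflect")
    my = ndimage.sobel(image, axis=0, mode="reflect")
    magnitude = np.hypot(mx, my)
    orientation = np.degrees(np.arctan2(my, mx)) % 180.0
    return GradientField(mx=mx, my=my, magnitude=magnitude, orientation=orientation)


def cell_histograms(grad: GradientField, cell: int = CELL, bins: int = BINS) -> np.ndarray:
    """Magnitude-weighted orientation histograms per cell.

    Each pixel votes its gradient magnitude into the two bins whose
    centers (at ``(b + 0.5) * 180 / bins`` degrees) bracket its
    orientation, with linear weights; the orientation axis wraps at 180.
    Returns an array of shape (n_cells_y, n_cells_x, bins).
    """
    h, w = grad.magnitude.shape
    if h % cell or w % cell:
        raise DomainError("image dimensions must be divisible by the cell size")
    bw = 180.0 / bins
    centers_pos = grad.orientation / bw - 0.5  # continuous bin coordinate
    lo = np.floor(centers_pos).astype(np.int64)
    frac = centers_pos - lo
    lo_bin = lo % bins
    hi_bin = (lo + 1) % bins

    cy = np.repeat(np.arange(h // cell), cell)[:, None] * np.ones((1, w), dtype=np.int64)
    cx = np.ones((h, 1), dtype=np.int64) * np.repeat(np.arange(w // cell), cell)[None, :]
    hist = np.zeros((h // cell, w // cell, bins))
    np.add.at(hist, (cy.ravel(), cx.ravel(), lo_bin.ravel()), (grad.magnitude * (1 - frac)).ravel())
    np.add.at(hist, (cy.ravel(), cx.ravel(), hi_bin.ravel()), (grad.magnitude * frac).ravel())
    return hist


def block_normalize(cells: np.ndarray) -> np.ndarray:
    """L2-normalized 36-vectors over 2x2-cell blocks at one-cell stride.

    Each block concatenates its four cell histograms row-major and is
    scaled by ``1 / sqrt(|v|^2 + k^2)`` with ``k = 1e-5``; blocks are
    emitted row-major.  Returns shape (n_blocks, 36).
    """
    ny, nx, bins = cells.shape
    if ny < BLOCK_CELLS or nx < BLOCK_CELLS:
        raise DomainError("cell grid smaller than one block")
    out = []
    for by in range(ny - BLOCK_CELLS + 1):
        for bx in range(nx - BLOCK_CELLS + 1):
            v = cells[by : by + BLOCK_CELLS, bx : bx + BLOCK_CELLS].ravel()
            out.append(v / np.sqrt(v @ v + NORM_EPS**2))
    return np.asarray(out)


def hog_descriptor(image: np.ndarray) -> HOGDescriptor:
    """Full HOG descriptor of a grey image (resized to 64x128 if needed)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise DomainError("HOG expects a single-channel image")
    if image.shape != (HOG_HEIGHT, HOG_WIDTH):
        image = resize_image(image, HOG_HEIGHT, HOG_WIDTH)
    grad = sobel_gradients(image)
    cells = cell_histograms(grad)
    blocks = block_normalize(cells)
    return HOGDescriptor(vector=blocks.ravel())
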