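"""HOG-style block features with selective per-block bin counts.

Gradients are forward differences dx = I(x+1, y) - I(x, y) and
dy = I(x, y+1) - I(x, y) (x = column, y = row; last column/row replicated so
the border gradient is 0), with the unsigned orientation
theta = atan(dy/dx) mapped into [0, 180) degrees. The window — canonically
64 pixels wide by 128 high — is tiled into 8x8 cells, and a 16x16 block
window (four adjacent cells) slides across at stride 8, giving
(64/8 - 1) * (128/8 - 1) = 105 blocks. Each pixel of a block casts one
unweighted vote into an orientation histogram; blocks flagged "high" in the
block mask use a finer bin count than the rest, shrinking the descriptor
while keeping detail where it matters. An optional magnitude-weighted voting
mode is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ArgumentError, DomainError
from .imaging import IntensityImage

__all__ = [
    "GradientField",
    "HOGDescriptor",
    "gradient_fields",
    "tile_blocks",
    "block_count",
    "block_histogram",
    "hog_descriptor",
]

CELL = 8
BLOCK = 16


@dataclass
class GradientField:
    """Signed forward differences and unsigned orientations in [0, 180)."""

    dx: np.ndarray
    dy: np.ndarray
    theta: np.ndarray
    magnitude: np.ndarray


def gradient_fields(img) -> GradientField:
    """Forward-difference gradients and orientations of a 2D image."""
    values = img.values if isinstance(img, IntensityImage) else np.asarray(img, dtype=float)
    if values.ndim != 2:
        raise DomainError("gradient computation requires a 2D image")
    dx = np.zeros_like(values)
    dy = np.zeros_like(values)
    dx[:, :-1] = values[:, 1:] - values[:, :-1]  # x step = column step
    dy[:-1, :] = values[1:, :] - values[:-1, :]  # y step = row step
    theta = np.degrees(np.arctan2(dy, dx)) % 180.0
    theta[(dx == 0) & (dy == 0)] = 0.0
    magnitude = np.hypot(dx, dy)
    return GradientField(dx, dy, theta, magnitude)


def block_count(shape: Tuple[int, int]) -> int:
    """Number of 16x16 windows at stride 8 covering an (H, W) grid."""
    h, w = shape
    if h % CELL or w % CELL:
        raise DomainError(f"dimensions must be multiples of {CELL}, got {shape}")
    if h < BLOCK or w < BLOCK:
        raise DomainError(f"image must be at least {BLOCK}x{BLOCK}, got {shape}")
    return (h // CELL - 1) * (w // CELL - 1)


def tile_blocks(arr: np.ndarray) -> List[np.ndarray]:
    """16x16 views of ``arr`` at stride 8, row-major; 105 for a 128x64 grid."""
    h, w = arr.shape
    block_count((h, w))  # validates
    blocks = []
    for r in range(0, h - BLOCK + 1, CELL):
        for c in range(0, w - BLOCK + 1, CELL):
            blocks.append(arr[r : r + BLOCK, c : c + BLOCK])
    return blocks


def block_histogram(
    block_theta: np.ndarray,
    n_bins: int,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Hard-assignment orientation histogram over [0, 180) with uniform bins.

    Unweighted (one vote per pixel) unless ``weights`` is given.
    """
    if n_bins < 1:
        raise ArgumentError(f"n_bins must be >= 1, got {n_bins}")
    hist, _ = np.histogram(
        block_theta.ravel(),
        bins=n_bins,
        range=(0.0, 180.0),
        weights=None if weights is None else weights.ravel(),
    )
    return hist.astype(np.float64)


@dataclass
class HOGDescriptor:
    """Per-block selective-bin histograms and their concatenation."""

    block_histograms: List[np.ndarray]
    bin_plan: np.ndarray
    feature_vector: np.ndarray


def hog_descriptor(
    img,
    block_mask: Optional[Sequence[int]] = None,
    high_bins: int = 9,
    low_bins: int = 4,
    weighted: bool = False,
) -> HOGDescriptor:
    """Selective-bin HOG descriptor of a (canonically 128x64) image.

    ``block_mask`` flags, per block in row-major order, whether it uses
    ``high_bins`` (1) or ``low_bins`` (0); default is all-high. Feature
    length is the sum of per-block bin counts.
    """
    field = gradient_fields(img)
    theta_blocks = tile_blocks(field.theta)
    nb = len(theta_blocks)
    if block_mask is None:
        block_mask = np.ones(nb, dtype=np.int64)
    else:
        block_mask = np.asarray(block_mask, dtype=np.int64)
        if block_mask.shape != (nb,):
            raise DomainError(f"block_mask must have length {nb}, got {block_mask.shape}")
    mag_blocks = tile_blocks(field.magnitude) if weighted else [None] * nb
    bin_plan = np.where(block_mask == 1, high_bins, low_bins)
    hists = [
        block_histogram(tb, int(bins), weights=mb)
        for tb, bins, mb in zip(theta_blocks, bin_plan, mag_blocks)
    ]
    return HOGDescriptor(hists, bin_plan, np.concatenate(hists))
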