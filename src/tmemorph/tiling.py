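"""Slide tiling and tissue-fraction filtering.

An RGB slide is cut into a non-overlapping grid of square tiles
(175 x 175 pixels by default, the unit of all downstream analysis).
Tissue content per tile is measured with Otsu's threshold computed once
per slide on the grayscale image — tissue is darker than the threshold —
and tiles whose tissue fraction falls below a cutoff (default 20%) are
excluded before classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu

DEFAULT_TILE_SIZE = 175
DEFAULT_MIN_TISSUE = 0.20


@dataclass
class Tile:
    """One grid tile: position, pixels and measured tissue fraction."""

    row: int
    col: int
    pixels: np.ndarray
    tissue_fraction: float | None = None

    @property
    def pixel_offset(self) -> tuple[int, int]:
        size = self.pixels.shape[0]
        return (self.row * size, self.col * size)


def tile_image(image: np.ndarray, tile_size: int = DEFAULT_TILE_SIZE) -> list[Tile]:
    """Cut an RGB image into a non-overlapping tile grid.

    Tiling starts at the top-left origin with 0-based (row, col) indices;
    partial tiles at the right/bottom edges are dropped.  Raises
    ``ValueError`` if the image is smaller than a single tile.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB array of shape (H, W, 3)")
    height, width = image.shape[:2]
    if height < tile_size or width < tile_size:
        raise ValueError(
            f"image {height}x{width} smaller than one {tile_size}px tile"
        )
    n_rows, n_cols = height // tile_size, width // tile_size
    tiles = []
    for row in range(n_rows):
        for col in range(n_cols):
            block = image[
                row * tile_size : (row + 1) * tile_size,
                col * tile_size : (col + 1) * tile_size,
            ]
            tiles.append(Tile(row=row, col=col, pixels=block))
    return tiles


def slide_tissue_threshold(image: np.ndarray) -> float | None:
    """Per-slide Otsu threshold on grayscale intensity.

    Returns ``None`` for a constant image, where no foreground/background
    split exists; callers treat that as "no tissue anywhere".
    """
    gray = rgb2gray(np.asarray(image))
    if np.ptp(gray) == 0:
        return None
    return float(threshold_otsu(gray))


def compute_tissue_fraction(tile: Tile, threshold: float | None) -> float:
    """Fraction of tile pixels darker than the slide-level Otsu threshold.

    Tissue absorbs stain and is darker than the glass background, so a
    pixel counts as tissue when its grayscale intensity is strictly below
    the threshold.  A ``None`` threshold (constant slide) yields 0.
    """
    if threshold is None:
        tile.tissue_fraction = 0.0
        return 0.0
    gray = rgb2gray(tile.pixels)
    frac = float(np.mean(gray < threshold))
    tile.tissue_fraction = frac
    return frac


def filter_tiles(
    tiles: list[Tile], min_fraction: float = DEFAULT_MIN_TISSUE
) -> tuple[list[Tile], list[Tile]]:
    """Split tiles into (retained, excluded) by tissue fraction.

    Tiles with tissue fraction strictly below ``min_fraction`` are
    excluded; the boundary tile (fraction == min_fraction) is retained.
    Excluded tiles later carry the ``excluded`` label in the TS-image.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction {min_fraction} outside [0, 1]")
    for tile in tiles:
        if tile.tissue_fraction is None:
            raise ValueError("tissue fractions must be computed before filtering")
    retained = [t for t in tiles if t.tissue_fraction >= min_fraction]
    excluded = [t for t in tiles if t.tissue_fraction < min_fraction]
    return retained, excluded


def prepare_tiles(
    image: np.ndarray,
    tile_size: int = DEFAULT_TILE_SIZE,
    min_fraction: float = DEFAULT_MIN_TISSUE,
) -> tuple[dict[tuple[int, int], np.ndarray], tuple[int, int]]:
    """Tile a slide, measure tissue, filter, and return cascade input.

    Convenience wrapper producing the ``{(row, col): tile_pixels}``
    mapping and grid shape expected by the classification cascade.
    """
    tiles = tile_image(image, tile_size=tile_size)
    threshold = slide_tissue_threshold(image)
    for tile in tiles:
        compute_tissue_fraction(tile, threshold)
    retained, _ = filter_tiles(tiles, min_fraction=min_fraction)
    height, width = image.shape[:2]
    grid_shape = (height // tile_size, width // tile_size)
    return {(t.row, t.col): t.pixels for t in retained}, grid_shape
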