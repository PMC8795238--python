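"""Tile-grid co-localization of IHC stain channels.

Aligned stain images are divided into a rectangular grid of tiles sized to
approximate a tumor cell (the reference layout is 45 x 34 = 1530 tiles).  A
tile is positive for a channel when at least a configured fraction of its
pixels exceeds an intensity threshold (Otsu per channel by default); marker
co-localization is the intersection of per-channel positive tile sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu


@dataclass
class TileGrid:
    """Axis-aligned rectangular tiling of a width x height image.

    ``x_edges`` / ``y_edges`` are integer pixel boundaries (len n_cols+1 /
    n_rows+1); remainder pixels are absorbed by the last column/row.
    """

    width: int
    height: int
    n_cols: int
    n_rows: int
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows

    def tile_bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) pixel bounds of a tile, end-exclusive."""
        return (
            int(self.x_edges[col]), int(self.y_edges[row]),
            int(self.x_edges[col + 1]), int(self.y_edges[row + 1]),
        )


def grid_tiles(image_width: int, image_height: int, n_cols: int = 45,
               n_rows: int = 34) -> TileGrid:
    """Partition an image into n_cols x n_rows integer-pixel tiles."""
    if image_width <= 0 or image_height <= 0 or n_cols <= 0 or n_rows <= 0:
        raise ValueError("dimensions and grid shape must be positive")
    if image_width < n_cols or image_height < n_rows:
        raise ValueError("image smaller than the grid")
    tw, th = image_width // n_cols, image_height // n_rows
    x_edges = np.array([tw * i for i in range(n_cols)] + [image_width])
    y_edges = np.array([th * i for i in range(n_rows)] + [image_height])
    return TileGrid(image_width, image_height, n_cols, n_rows, x_edges, y_edges)


def annotate_tiles(
    image: np.ndarray,
    grid: TileGrid,
    intensity_threshold: float | None = None,
    positive_fraction: float = 0.1,
) -> np.ndarray:
    """Boolean (n_rows x n_cols) tile positivity for one channel.

    A tile is positive iff the fraction of its pixels strictly above
    ``intensity_threshold`` is at least ``positive_fraction``.  With no
    threshold given, Otsu's method is applied per channel; a constant image
    cannot be thresholded and returns all-negative with a warning.
    """
    img = np.asarray(image)
    if img.shape != (grid.height, grid.width):
        raise ValueError(f"image shape {img.shape} does not match grid "
                         f"({grid.height}, {grid.width})")
    if intensity_threshold is None:
        if img.min() == img.max():
            import warnings

            warnings.warn("constant image; no Otsu threshold, all tiles negative",
                          stacklevel=2)
            return np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
        intensity_threshold = float(threshold_otsu(img))
    if intensity_threshold >= img.max():
        import warnings

        warnings.warn("threshold at or above image maximum; all tiles negative",
                      stacklevel=2)
    hot = img > intensity_threshold
    out = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x0, y0, x1, y1 = grid.tile_bounds(r, c)
            out[r, c] = hot[y0:y1, x0:x1].mean() >= positive_fraction
    return out


def overlap_tiles(
    positivity_a: np.ndarray, positivity_b: np.ndarray
) -> tuple[np.ndarray, int]:
    """Double-positive tiles of two channels on the same grid.

    Returns (boolean co-positivity array, count)."""
    a, b = np.asarray(positivity_a, bool), np.asarray(positivity_b, bool)
    if a.shape != b.shape:
        raise ValueError("tile grids do not match")
    both = a & b
    return both, int(both.sum())


def tile_table(grid: TileGrid, positivity: dict[str, np.ndarray]) -> pd.DataFrame:
    """Long-format per-tile table of channel positivity and pairwise
    co-positivity (one row per tile)."""
    rows = []
    chans = list(positivity)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            rec = {"row": r, "col": c}
            for ch in chans:
                rec[ch] = bool(positivity[ch][r, c])
            for i, a in enumerate(chans):
                for b in chans[i + 1 :]:
                    rec[f"{a}+{b}"] = bool(positivity[a][r, c] and positivity[b][r, c])
            rows.append(rec)
    return pd.DataFrame(rows)


def render_overlay(
    images: dict[str, np.ndarray], grid: TileGrid, double_positive: np.ndarray
) -> np.ndarray:
    """RGB overlay: mean of channels in gray, double-positive tiles in blue."""
    stack = np.stack([np.asarray(im, float) for im in images.values()])
    base = stack.mean(axis=0)
    base = (255 * (base - base.min()) / max(np.ptp(base), 1)).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            if double_positive[r, c]:
                x0, y0, x1, y1 = grid.tile_bounds(r, c)
                rgb[y0:y1, x0:x1, 0] //= 3
                rgb[y0:y1, x0:x1, 1] //= 3
                rgb[y0:y1, x0:x1, 2] = 255
    return rgb
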