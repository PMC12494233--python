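"""Tile iteration and stitching for large rasters.

A :class:`TileGrid` walks an image in fixed-size tiles with a configurable
overlap: consecutive origins step by ``tile_size - overlap``, so interior
neighbors share exactly ``overlap`` rows/cols, and edge tiles are clipped
to the image.  Stitching with first-writer overlap resolution
reconstructs the mosaic exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import read_image

__all__ = ["TileGrid", "iterate_tiles", "stitch_tiles"]


@dataclass(frozen=True)
class TileGrid:
    tile_size: tuple
    overlap: int = 0

    def __post_init__(self):
        th, tw = self.tile_size
        if th < 1 or tw < 1:
            raise ValueError("tile size must be positive")
        if self.overlap < 0 or self.overlap >= min(th, tw):
            raise ValueError("overlap must satisfy 0 <= overlap < min(tile_size)")

    def offsets(self, shape):
        """Tile origin coordinates covering an (H, W) image."""
        h, w = shape[:2]
        th, tw = self.tile_size

        def axis_offsets(n, t):
            step = t - self.overlap
            offs = list(range(0, max(n - self.overlap, 1), step))
            return offs

        return [(r, c) for r in axis_offsets(h, th) for c in axis_offsets(w, tw)]

    def core_slices(self, origin, shape):
        """The ownership region of a tile: half the overlap on interior sides."""
        h, w = shape[:2]
        th, tw = self.tile_size
        r, c = origin
        half = self.overlap // 2
        r0 = 0 if r == 0 else r + half
        c0 = 0 if c == 0 else c + half
        r1 = h if r + th >= h else r + th - (self.overlap - half)
        c1 = w if c + tw >= w else c + tw - (self.overlap - half)
        return slice(r0, r1), slice(c0, c1)


def iterate_tiles(image, grid: TileGrid):
    """Yield ``(tile, (row, col) origin)`` over an image or raster file."""
    if isinstance(image, (str, Path)):
        image = read_image(image)
    image = np.asarray(image)
    th, tw = grid.tile_size
    for r, c in grid.offsets(image.shape):
        yield image[r : r + th, c : c + tw], (r, c)


def stitch_tiles(tiles_with_offsets, shape, dtype=float):
    """Reassemble tiles into a mosaic; overlaps resolved first-writer."""
    canvas = np.zeros(shape, dtype=dtype)
    written = np.zeros(shape[:2], dtype=bool)
    for tile, (r, c) in tiles_with_offsets:
        tile = np.asarray(tile)
        h, w = tile.shape[:2]
        region_written = written[r : r + h, c : c + w]
        fresh = ~region_written
        canvas[r : r + h, c : c + w][fresh] = tile[fresh]
        region_written |= True
    return canvas
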