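"""Partition of the scan field into angular tiles (default 1° x 1°).

Tile width is the floor of A-scans-per-degree (e.g. floor(512/36) = 14
A-scans for the default raster); remainder A-scans are split between
the two edge tiles so that every A-scan belongs to exactly one tile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ScanGeometry


@dataclass(frozen=True)
class Tiling:
    tile_x: np.ndarray   # per fast-axis A-scan index -> tile column
    tile_y: np.ndarray   # per slow-axis B-scan index -> tile row
    tile_deg: float

    @property
    def shape(self) -> tuple[int, int]:
        return (int(self.tile_x.max()) + 1, int(self.tile_y.max()) + 1)

    def ascans_in_tile(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.tile_x == i)[0], np.nonzero(self.tile_y == j)[0]


def _axis_tiles(n: int, field_deg: float, tile_deg: float) -> np.ndarray:
    n_tiles = max(int(round(field_deg / tile_deg)), 1)
    width = n // n_tiles
    if width < 1:
        raise ValueError(f"tile of {tile_deg} deg is narrower than one A-scan")
    rem = n - width * n_tiles
    idx = np.minimum((np.arange(n) - rem // 2) // width, n_tiles - 1)
    return np.maximum(idx, 0)


def tile_volume(geometry: ScanGeometry, tile_deg: float = 1.0) -> Tiling:
    """Assign every A-scan to an angular tile of the given size."""
    if tile_deg <= 0:
        raise ValueError("tile_deg must be > 0")
    return Tiling(
        tile_x=_axis_tiles(geometry.n_fast, geometry.field_deg_x, tile_deg),
        tile_y=_axis_tiles(geometry.n_slow, geometry.field_deg_y, tile_deg),
        tile_deg=tile_deg)
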