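"""ETDRS-grid averaging of thickness maps.

The grid comprises a central disc (here 1.5 mm diameter, the central
submacular field), an inner annulus (1.5-3 mm) and an outer annulus
(3-6 mm), each annulus split into superior / temporal / inferior /
nasal quadrants by the +-45° diagonals.  The total macular field is the
whole 6 mm disc.  Map axes follow the volume convention: the first map
axis is the fast (horizontal) axis, the second the slow (vertical)
axis with superior at low indices.  For a right eye the nasal side is
at high fast-axis indices; flipping laterality swaps nasal/temporal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LATERALITIES, ThicknessMap

SUBFIELDS = ("central",
             "superior_inner", "temporal_inner", "inferior_inner", "nasal_inner",
             "superior_outer", "temporal_outer", "inferior_outer", "nasal_outer")


@dataclass
class ETDRSGrid:
    """Boolean subfield masks over a map grid."""

    masks: dict[str, np.ndarray]
    center: tuple[float, float]
    cell_mm: tuple[float, float]
    diameters_mm: tuple[float, float, float]
    laterality: str

    @property
    def disc(self) -> np.ndarray:
        """The full outer disc (total macular field)."""
        out = np.zeros_like(next(iter(self.masks.values())))
        for m in self.masks.values():
            out |= m
        return out


def build_grid(shape: tuple[int, int], cell_mm: tuple[float, float],
               center: tuple[float, float] | None = None,
               laterality: str = "right",
               diameters_mm: tuple[float, float, float] = (1.5, 3.0, 6.0)
               ) -> ETDRSGrid:
    """Construct the nine ETDRS subfield masks on a map grid.

    ``shape`` and ``cell_mm`` describe the thickness map (fast, slow
    axes); ``center`` defaults to the map center (fovea assumed
    centered).  Raises if the outer disc does not fit in the field.
    """
    if laterality not in LATERALITIES:
        raise ValueError(f"laterality must be one of {LATERALITIES}")
    d_c, d_i, d_o = diameters_mm
    if not 0 < d_c < d_i < d_o:
        raise ValueError("diameters must satisfy 0 < central < inner < outer")
    nx, ny = shape
    if center is None:
        center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    cx, cy = center
    dx_mm = (np.arange(nx) - cx)[:, None] * cell_mm[0]
    dy_mm = (np.arange(ny) - cy)[None, :] * cell_mm[1]
    extent_x = min(cx, nx - 1 - cx) * cell_mm[0]
    extent_y = min(cy, ny - 1 - cy) * cell_mm[1]
    if d_o / 2 > extent_x + cell_mm[0] / 2 or d_o / 2 > extent_y + cell_mm[1] / 2:
        raise ValueError(f"{d_o} mm disc exceeds the mapped field "
                         f"({2 * extent_x:.2f} x {2 * extent_y:.2f} mm)")
    r = np.hypot(dx_mm, np.broadcast_to(dy_mm, (nx, ny)))
    central = r < d_c / 2
    inner = (r >= d_c / 2) & (r < d_i / 2)
    outer = (r >= d_i / 2) & (r < d_o / 2)
    superior = -dy_mm >= np.abs(dx_mm)           # low slow-index = superior
    inferior = dy_mm > np.abs(dx_mm)
    nasal_sign = 1.0 if laterality == "right" else -1.0
    nasal = (nasal_sign * dx_mm > np.abs(dy_mm))
    temporal = (-nasal_sign * dx_mm > np.abs(dy_mm))
    quads = {"superior": np.broadcast_to(superior, (nx, ny)),
             "inferior": np.broadcast_to(inferior, (nx, ny)),
             "nasal": nasal, "temporal": temporal}
    masks = {"central": central}
    for ring, ring_mask in (("inner", inner), ("outer", outer)):
        for quad, quad_mask in quads.items():
            masks[f"{quad}_{ring}"] = ring_mask & quad_mask
    return ETDRSGrid(masks, center, cell_mm, diameters_mm, laterality)


@dataclass
class ETDRSSummary:
    """Per-subfield mean/SD plus the CSM and total-macular aggregates."""

    table: pd.DataFrame          # rows: subfields + csm + total

    def mean(self, field: str) -> float:
        return float(self.table.loc[field, "mean_um"])

    def sd(self, field: str) -> float:
        return float(self.table.loc[field, "sd_um"])


def subfield_means(tmap: ThicknessMap, grid: ETDRSGrid,
                   max_missing_frac: float = 0.5) -> ETDRSSummary:
    """Mean and SD of a thickness map over each ETDRS subfield.

    Subfields with more than ``max_missing_frac`` undefined cells are
    reported missing.  ``csm`` duplicates the central subfield and
    ``total`` averages the whole outer disc.
    """
    vals = tmap.values
    if vals.shape != next(iter(grid.masks.values())).shape:
        raise ValueError("map and grid shapes differ")
    rows = {}

    def summarize(mask: np.ndarray) -> tuple[float, float, int]:
        v = vals[mask]
        ok = np.isfinite(v)
        n = int(ok.sum())
        if v.size == 0 or n <= (1 - max_missing_frac) * v.size - 1e-12 \
                or n == 0:
            return (np.nan, np.nan, n)
        sd = float(np.std(v[ok], ddof=1)) if n > 1 else 0.0
        return (float(np.mean(v[ok])), sd, n)

    for name in SUBFIELDS:
        rows[name] = summarize(grid.masks[name])
    rows["csm"] = rows["central"]
    rows["total"] = summarize(grid.disc)
    table = pd.DataFrame(
        {k: {"mean_um": m, "sd_um": s, "n_cells": n}
         for k, (m, s, n) in rows.items()}).T
    table.index.name = "field"
    return ETDRSSummary(table)
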