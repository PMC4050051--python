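"""Haller's/Sattler's sublayer split from volume/surface voxel-ratio profiles.

For every 1° x 1° tile, the segmented vessel voxels are binned by their
depth from the scleral boundary (the choroidal-scleral interface of the
A-scan they belong to) and the ratio of vessel volume voxels to vessel
surface voxels is computed per depth bin.  Larger vessels have a larger
volume-to-surface ratio, so the profile peaks inside Haller's layer of
large-caliber vessels next to the sclera.  Scanning anteriorly from the
peak, the first valley of the smoothed profile marks the border between
Haller's and Sattler's layer, and the inner border of Sattler's layer
is reached where no vessels (or only noise-level ratios) remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ChoroidRegion, ScanGeometry, ThicknessMap
from .tiling import Tiling, tile_volume  # noqa: F401  (tiling is part of this surface)
from .vessels import VesselMask, surface_voxels


@dataclass
class RatioProfile:
    """Volume/surface voxel ratio vs depth-from-sclera for one tile.

    Bin 0 is the deepest choroid voxel (adjacent to the sclera); bin
    indices increase anteriorly.  ``ratio`` is NaN where the bin holds
    no surface voxels; ``smoothed`` is a moving average over defined
    bins and is NaN only where the whole window is undefined.
    """

    tile: tuple[int, int]
    volume_counts: np.ndarray
    surface_counts: np.ndarray
    ratio: np.ndarray
    smoothed: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.smoothed)


@dataclass
class SublayerBorders:
    """Per-tile border depths (voxels from the scleral boundary)."""

    haller_sattler: np.ndarray   # first valley after the profile maximum
    sattler_inner: np.ndarray    # anterior end of vessel signal
    defined: np.ndarray


def _smooth_profile(ratio: np.ndarray, smooth_w: int) -> np.ndarray:
    """Moving average over defined bins (NaN-aware)."""
    if smooth_w < 1 or smooth_w % 2 == 0:
        raise ValueError("smooth_w must be a positive odd integer")
    if smooth_w == 1:
        return ratio.copy()
    ok = np.isfinite(ratio)
    filled = np.where(ok, ratio, 0.0)
    kernel = np.ones(smooth_w)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(ok.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def _tile_bin_counts(vm: VesselMask, region: ChoroidRegion, tiling: Tiling
                     ) -> tuple[np.ndarray, np.ndarray, int]:
    """Vessel volume and surface voxel counts per (tile, depth bin)."""
    n_bins = int(region.length.max()) if region.defined.any() else 0
    tx, ty = tiling.shape
    vol_counts = np.zeros((tx, ty, max(n_bins, 1)), dtype=np.int64)
    surf_counts = np.zeros_like(vol_counts)
    if n_bins == 0:
        return vol_counts, surf_counts, 0
    surf = surface_voxels(vm.mask)
    for counts, grid in ((vol_counts, vm.mask), (surf_counts, surf)):
        z, x, y = np.nonzero(grid)
        if z.size == 0:
            continue
        d = region.stop[x, y] - 1 - z
        ok = (region.defined[x, y] & (d >= 0) & (z >= region.start[x, y]))
        z, x, y, d = z[ok], x[ok], y[ok], d[ok]
        flat = (tiling.tile_x[x] * ty + tiling.tile_y[y]) * n_bins + d
        binned = np.bincount(flat, minlength=tx * ty * n_bins)
        counts += binned.reshape(tx, ty, n_bins)
    return vol_counts, surf_counts, n_bins


def ratio_profile(vm: VesselMask, region: ChoroidRegion, tiling: Tiling,
                  tile: tuple[int, int], smooth_w: int = 5) -> RatioProfile:
    """Ratio profile of a single tile (see :func:`ratio_profiles`)."""
    return ratio_profiles(vm, region, tiling, smooth_w)[tile]


def ratio_profiles(vm: VesselMask, region: ChoroidRegion, tiling: Tiling,
                   smooth_w: int = 5) -> dict[tuple[int, int], RatioProfile]:
    """Ratio profiles for every tile of the field."""
    if not region.defined.any():
        raise ValueError("empty choroid region")
    vol_counts, surf_counts, n_bins = _tile_bin_counts(vm, region, tiling)
    tx, ty = tiling.shape
    out: dict[tuple[int, int], RatioProfile] = {}
    for i in range(tx):
        for j in range(ty):
            v = vol_counts[i, j].astype(np.float64)
            s = surf_counts[i, j].astype(np.float64)
            # a bin whose vessel voxels are all interior (no surface voxel
            # falls in this tile/bin) is maximally vessel-filled, not empty:
            # count its surface as 1 rather than marking it undefined
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(s > 0, v / s, np.where(v > 0, v, np.nan))
            out[(i, j)] = RatioProfile(
                tile=(i, j), volume_counts=vol_counts[i, j],
                surface_counts=surf_counts[i, j], ratio=ratio,
                smoothed=_smooth_profile(ratio, smooth_w))
    return out


def find_borders(profile: RatioProfile, noise_floor: float = 1.05,
                 prominence: float = 0.25, descent_frac: float = 0.15,
                 descent_max: float = 1.0, max_valley_frac: float = 0.6
                 ) -> tuple[float, float, bool]:
    """Apply the valley rule to one smoothed profile.

    Returns ``(haller_sattler, sattler_inner, defined)``.  Haller's
    layer runs from the scleral boundary (bin 0) through the profile
    maximum until the first small ratio: the valley separating the
    large-vessel mode from the medium-vessel mode is located as the
    running minimum after the maximum once the profile rebounds by at
    least ``prominence`` (and the minimum has dropped below
    ``max_valley_frac`` of the peak, which rejects sampling wiggles on
    top of the mode), and the border is then placed at the first bin
    after the peak that descends to within
    ``min(descent_frac * (peak - valley), descent_max)`` of the valley
    level - the onset of the valley floor, where the large-vessel mass
    ends.  The scan then continues anteriorly to the first undefined or
    noise-level bin, which closes Sattler's layer.  A profile that
    decays without an interior valley yields a zero-thickness Sattler
    layer.  Ties at the minimum resolve to the most posterior bin.
    """
    sm = profile.smoothed
    ok = np.isfinite(sm)
    if not ok.any():
        return (np.nan, np.nan, False)
    usable = ok & (sm >= noise_floor)
    if not usable.any():
        return (np.nan, np.nan, False)
    vals = np.where(ok, sm, -np.inf)
    m0 = int(np.argmax(vals))
    peak = sm[m0]
    n = sm.size

    def bad(i: int) -> bool:
        return not ok[i] or sm[i] < noise_floor

    valley = None
    run_min = peak
    for i in range(m0 + 1, n):
        if bad(i):
            return (float(i), float(i), True)   # no valley: zero Sattler
        if sm[i] < run_min:                     # strict: posterior tie-break
            run_min, run_idx = sm[i], i
        elif (sm[i] >= run_min + prominence
                and run_min <= max_valley_frac * peak):
            valley = run_idx
            break
    if valley is None:                           # no valley before signal end
        return (float(n), float(n), True)
    thr = run_min + min(descent_frac * (peak - run_min), descent_max)
    haller_sattler = valley
    for i in range(m0 + 1, valley + 1):
        if sm[i] <= thr:
            haller_sattler = i
            break
    j = valley + 1
    while j < n and not bad(j):
        j += 1
    return (float(haller_sattler), float(j), True)


def sublayer_borders(vm: VesselMask, region: ChoroidRegion, tiling: Tiling,
                     smooth_w: int = 5, noise_floor: float = 1.05,
                     prominence: float = 0.25) -> SublayerBorders:
    """Valley-rule borders for every tile."""
    profiles = ratio_profiles(vm, region, tiling, smooth_w)
    tx, ty = tiling.shape
    hs = np.full((tx, ty), np.nan)
    si = np.full((tx, ty), np.nan)
    defined = np.zeros((tx, ty), dtype=bool)
    # deepest choroid extent per tile: borders cannot exceed it
    max_len = np.zeros((tx, ty))
    np.maximum.at(max_len,
                  (tiling.tile_x[:, None], tiling.tile_y[None, :]),
                  region.length.astype(float))
    for (i, j), prof in profiles.items():
        hs[i, j], si[i, j], defined[i, j] = find_borders(prof, noise_floor,
                                                         prominence)
        if defined[i, j]:
            si[i, j] = min(si[i, j], max_len[i, j])
            hs[i, j] = min(hs[i, j], si[i, j])
    return SublayerBorders(hs, si, defined)


def borders_to_thickness(borders: SublayerBorders, geometry: ScanGeometry,
                         tile_deg: float = 1.0
                         ) -> tuple[ThicknessMap, ThicknessMap]:
    """Convert border bins to per-tile Sattler/Haller thickness maps (µm).

    One depth bin corresponds to ``axial_sampling_um / refractive_index``
    µm of anatomical distance.
    """
    f = geometry.voxel_um_axial
    haller = np.where(borders.defined, borders.haller_sattler * f, np.nan)
    sattler = np.where(borders.defined,
                       (borders.sattler_inner - borders.haller_sattler) * f,
                       np.nan)
    cell = (geometry.mm_per_degree * tile_deg,) * 2
    return (ThicknessMap(sattler, cell_mm=cell),
            ThicknessMap(haller, cell_mm=cell))


def upsample_to_ascans(tmap: ThicknessMap, tiling: Tiling,
                       geometry: ScanGeometry) -> ThicknessMap:
    """Expand a tile-resolution map to A-scan resolution (block repeat,
    so area weighting is preserved exactly)."""
    vals = tmap.values[tiling.tile_x[:, None], tiling.tile_y[None, :]]
    return ThicknessMap(vals, cell_mm=(geometry.mm_per_voxel_x,
                                       geometry.mm_per_voxel_y))
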