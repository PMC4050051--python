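"""Synthetic 1060-nm OCT choroid phantom with voxel-level ground truth.

The phantom emulates the anatomy the segmentation assumes: two smooth
boundary surfaces (the RPE/Bruch's/choriocapillaris complex above and
the choroidal-scleral interface below), hyporeflective tubular vessels
in two caliber populations stratified by depth (medium/small anterior
tubes standing for Sattler's layer, large posterior tubes for Haller's
layer), depth-dependent signal attenuation below the RBC complex, and
multiplicative gamma speckle of unit mean.

Large-vessel placement follows the anatomical picture in which Haller's
layer is the band of large-caliber vasculature resting on the sclera:
each Haller tube is placed so that its anterior surface lies near a
per-eye border depth, and the ground-truth Haller/Sattler border of a
tile is the anterior envelope of its Haller tubes: the largest
anterior-most surface voxel depth (distance from the scleral boundary)
over the tubes crossing the tile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import OCTVolume, ScanGeometry, SurfaceMap, ThicknessMap
from .config import RunConfig
from .sublayers import tile_volume


@dataclass
class VesselTube:
    """A single tubular vessel: centerline polyline plus caliber."""

    centerline: np.ndarray      # (N, 3) float voxel coords (z, x, y)
    radius_um: float
    layer_class: str            # "sattler" | "haller"

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=np.float64)
        if self.radius_um <= 0:
            raise ValueError("radius must be > 0")
        if self.layer_class not in ("sattler", "haller"):
            raise ValueError("layer_class must be 'sattler' or 'haller'")


@dataclass
class PhantomTruth:
    """Complete ground truth of a rendered phantom volume."""

    rbc_surface: SurfaceMap
    csi_surface: SurfaceMap
    tubes: list
    labels: np.ndarray              # int32 [z, x, y]; 0 = background, i = tubes[i-1]
    true_border: np.ndarray         # per-tile depth-from-sclera (voxels), NaN undefined
    true_sattler_inner: np.ndarray  # per-tile anterior vessel limit (voxels), NaN undefined
    seed: int
    tile_deg: float = 1.0

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.labels > 0


def make_surfaces(geometry: ScanGeometry, rbc_mean: float, csi_mean: float,
                  amplitude: float = 6.0, order: int = 3,
                  seed: int | np.random.Generator = 0) -> tuple[SurfaceMap, SurfaceMap]:
    """Two smooth boundary surfaces from a low-order 2D cosine series.

    Each surface is ``mean + amplitude * S(x, y)`` with ``S`` a random
    cosine series normalized to unit maximum amplitude, so the mean
    depths must be separated by more than twice the amplitude.
    """
    if not rbc_mean < csi_mean:
        raise ValueError(f"rbc mean depth ({rbc_mean}) must be < csi mean "
                         f"depth ({csi_mean})")
    if csi_mean - rbc_mean <= 2 * amplitude:
        raise ValueError("surface separation must exceed the summed amplitudes")
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 1, geometry.n_fast)[:, None]
    y = np.linspace(0, 1, geometry.n_slow)[None, :]

    def series() -> np.ndarray:
        s = np.zeros((geometry.n_fast, geometry.n_slow))
        for i in range(order + 1):
            for j in range(order + 1):
                if i == 0 and j == 0:
                    continue
                c = rng.normal()
                p, q = rng.uniform(0, np.pi, 2)
                s += c * np.cos(np.pi * i * x + p) * np.cos(np.pi * j * y + q)
        peak = np.abs(s).max()
        return s / peak if peak > 0 else s

    rbc = rbc_mean + amplitude * series()
    csi = csi_mean + amplitude * series()
    for name, surf in (("rbc", rbc), ("csi", csi)):
        if surf.min() < 0 or surf.max() >= geometry.n_depth:
            raise ValueError(f"{name} surface escapes the depth range")
    if np.any(rbc >= csi):
        raise ValueError("rbc surface must lie strictly above csi everywhere")
    return SurfaceMap(rbc, "rbc"), SurfaceMap(csi, "csi")


def _undulation(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """Mild low-frequency sinusoidal wobble along a tube."""
    t = np.linspace(0, 2 * np.pi, n)
    out = np.zeros(n)
    for freq in (1, 2):
        out += rng.normal(scale=amplitude / 2) * np.sin(freq * t + rng.uniform(0, 2 * np.pi))
    return out


def sample_vessels(geometry: ScanGeometry, rbc: SurfaceMap, csi: SurfaceMap, *,
                   n_sattler: int = 45, n_haller: int = 12,
                   sattler_radius_um: tuple[float, float] = (12.0, 30.0),
                   haller_radius_um: tuple[float, float] = (40.0, 100.0),
                   haller_top_frac: tuple[float, float] = (0.42, 0.445),
                   sattler_band_frac: tuple[float, float] = (0.42, 0.75),
                   seed: int | np.random.Generator = 0) -> list[VesselTube]:
    """Sample the two vessel populations inside the choroid region.

    Tubes run roughly parallel to the fast or slow axis with mild
    undulation in both the transverse and the depth direction.  Haller
    tubes occupy the posterior depth fraction with their anterior
    surfaces near ``haller_top_frac`` of the mean choroidal thickness;
    Sattler tubes occupy the ``sattler_band_frac`` band anterior of it.
    Depth positions are expressed as distance from the scleral boundary.
    """
    if not sattler_radius_um[1] < haller_radius_um[0]:
        raise ValueError("radius ranges must be disjoint (sattler < haller)")
    if n_sattler < 0 or n_haller < 0:
        raise ValueError("vessel counts must be >= 0")
    rng = np.random.default_rng(seed)
    mean_thickness = float(np.mean(csi.depth - rbc.depth))
    vz = geometry.voxel_um_axial
    if mean_thickness < 2 * (sattler_radius_um[0] / vz) + 4:
        raise ValueError("choroid region too thin to place both populations")

    tubes: list[VesselTube] = []
    specs = ([("haller", haller_radius_um)] * n_haller
             + [("sattler", sattler_radius_um)] * n_sattler)
    for layer, (r_lo, r_hi) in specs:
        r_um = rng.uniform(r_lo, r_hi)
        a = r_um / vz                                 # axial voxel radius
        along_x = rng.uniform() < 0.5
        n_along = geometry.n_fast if along_x else geometry.n_slow
        n_perp = geometry.n_slow if along_x else geometry.n_fast
        p0 = rng.uniform(2, n_perp - 3)
        perp = np.clip(p0 + _undulation(rng, n_along, 3.0), 1, n_perp - 2)
        axis = np.arange(n_along, dtype=float)
        xs, ys = (axis, perp) if along_x else (perp, axis)
        csi_local = csi.depth[xs.astype(int), ys.astype(int)]
        rbc_local = rbc.depth[xs.astype(int), ys.astype(int)]
        t_local = csi_local - rbc_local              # local choroid thickness
        if layer == "haller":
            # anterior tube surface tracks a fixed fraction of the local
            # thickness: the large-vessel band has a coherent upper envelope
            frac = rng.uniform(*haller_top_frac)
            a = min(a, (frac * t_local.min() - 2) / 2)  # tube must fit below
            r_um = a * vz
            depth = frac * t_local - a + _undulation(rng, n_along, 1.0)
        else:
            lo = sattler_band_frac[0] + a / mean_thickness
            hi = max(sattler_band_frac[1] - a / mean_thickness, lo + 0.005)
            frac = rng.uniform(lo, hi)
            depth = frac * t_local + _undulation(rng, n_along, 1.0)
        # convert depth-from-sclera to absolute z along the local CSI
        z = np.clip(np.floor(csi_local) - 1 - depth,
                    rbc_local + 1, csi_local - 2)
        tubes.append(VesselTube(np.column_stack([z, xs, ys]), r_um, layer))
    return tubes


def _rasterize_tube(tube: VesselTube, geometry: ScanGeometry) -> np.ndarray:
    """Voxel coordinates (M, 3) covered by the tube's elliptical cross-section.

    The cross-section perpendicular to the tube axis is an ellipse with
    an axial half-axis ``radius_um / voxel_um_axial`` and a transverse
    half-axis ``radius_um / transverse voxel pitch``.
    """
    cl = tube.centerline
    a = tube.radius_um / geometry.voxel_um_axial
    along_x = np.ptp(cl[:, 1]) >= np.ptp(cl[:, 2])
    perp_axis = 2 if along_x else 1
    um_perp = (geometry.mm_per_voxel_y if along_x else geometry.mm_per_voxel_x) * 1000
    b = tube.radius_um / um_perp
    za = int(np.ceil(a)) + 1
    pa = int(np.ceil(b)) + 1
    dz = np.arange(-za, za + 1)
    dp = np.arange(-pa, pa + 1)
    z0 = cl[:, 0][:, None, None]
    p0 = cl[:, perp_axis][:, None, None]
    zz = np.round(z0) + dz[None, :, None]
    pp = np.round(p0) + dp[None, None, :]
    inside = ((zz - z0) / a) ** 2 + ((pp - p0) / max(b, 1e-9)) ** 2 <= 1.0
    steps = np.broadcast_to(cl[:, 1 if along_x else 2][:, None, None], inside.shape)
    zz = np.broadcast_to(zz, inside.shape)
    pp = np.broadcast_to(pp, inside.shape)
    z_sel = zz[inside].astype(np.int64)
    p_sel = pp[inside].astype(np.int64)
    s_sel = np.round(steps[inside]).astype(np.int64)
    if along_x:
        coords = np.column_stack([z_sel, s_sel, p_sel])
    else:
        coords = np.column_stack([z_sel, p_sel, s_sel])
    shape = geometry.shape
    ok = ((coords[:, 0] >= 0) & (coords[:, 0] < shape[0])
          & (coords[:, 1] >= 0) & (coords[:, 1] < shape[1])
          & (coords[:, 2] >= 0) & (coords[:, 2] < shape[2]))
    return np.unique(coords[ok], axis=0)


def render_volume(geometry: ScanGeometry, rbc: SurfaceMap, csi: SurfaceMap,
                  tubes: list, *,
                  background_level: float = 15.0, stroma_level: float = 100.0,
                  vessel_level: float = 40.0, attenuation_tau: float = 250.0,
                  speckle_shape: float = 8.0,
                  seed: int | np.random.Generator = 0,
                  tile_deg: float = 1.0) -> tuple[OCTVolume, PhantomTruth]:
    """Render surfaces and tubes into an intensity volume plus its truth.

    Voxel intensity is ``tissue level x exp(-(depth below RBC)/tau) x
    speckle`` where the speckle factor is gamma-distributed with unit
    mean and shape ``speckle_shape``.  ``attenuation_tau = 0`` disables
    attenuation and ``speckle_shape = 0`` disables speckle, yielding a
    piecewise-constant volume with exactly three intensity levels.
    """
    if not vessel_level < stroma_level:
        raise ValueError("vessel_level must be < stroma_level")
    if attenuation_tau < 0 or speckle_shape < 0:
        raise ValueError("attenuation_tau and speckle_shape must be >= 0")
    rng = np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    nz, nx, ny = geometry.shape
    z = np.arange(nz, dtype=np.float32)[:, None, None]
    rbc_d = rbc.depth[None].astype(np.float32)
    csi_d = csi.depth[None].astype(np.float32)
    choroid = (z >= rbc_d) & (z < csi_d)

    labels = np.zeros(geometry.shape, dtype=np.int32)
    tube_coords: list[np.ndarray] = []
    for i, tube in enumerate(tubes, start=1):
        coords = _rasterize_tube(tube, geometry)
        keep = (choroid[coords[:, 0], coords[:, 1], coords[:, 2]]
                & (labels[coords[:, 0], coords[:, 1], coords[:, 2]] == 0))
        coords = coords[keep]          # first tube wins where tubes overlap
        labels[coords[:, 0], coords[:, 1], coords[:, 2]] = i
        tube_coords.append(coords)

    intensity = np.full(geometry.shape, background_level, dtype=np.float32)
    intensity[choroid] = stroma_level
    intensity[labels > 0] = vessel_level
    if attenuation_tau > 0:
        below = z >= rbc_d
        depth_below = np.where(below, z - rbc_d, 0.0)
        intensity = intensity * np.exp(-depth_below / attenuation_tau,
                                       dtype=np.float32)
    if speckle_shape > 0:
        speckle = rng.gamma(speckle_shape, 1.0 / speckle_shape,
                            size=geometry.shape).astype(np.float32)
        intensity = intensity * speckle

    true_border, true_inner = _true_borders(labels, tubes, tube_coords,
                                            csi, geometry, tile_deg)
    truth = PhantomTruth(rbc, csi, list(tubes), labels, true_border,
                         true_inner, seed=int(seed_val), tile_deg=tile_deg)
    return OCTVolume(intensity, geometry), truth


def _true_borders(labels, tubes, tube_coords, csi, geometry, tile_deg):
    """Per-tile ground-truth border depths, in voxels from the sclera.

    The Haller/Sattler border of a tile is the anterior envelope of its
    Haller tubes (the maximum over tubes of each tube's anterior-most
    voxel depth in the tile); the inner Sattler limit is the
    anterior-most vessel voxel overall.
    """
    tiling = tile_volume(geometry, tile_deg)
    tx, ty = tiling.shape
    csi_floor = np.floor(csi.depth).astype(np.int64)
    border = np.full((tx, ty), np.nan)
    inner = np.full((tx, ty), np.nan)
    for tube, coords in zip(tubes, tube_coords):
        if coords.size == 0:
            continue
        d = csi_floor[coords[:, 1], coords[:, 2]] - 1 - coords[:, 0]
        ti = tiling.tile_x[coords[:, 1]]
        tj = tiling.tile_y[coords[:, 2]]
        flat = ti * ty + tj
        order = np.argsort(flat, kind="stable")
        flat_s, d_s = flat[order], d[order]
        uniq, start = np.unique(flat_s, return_index=True)
        tops = np.maximum.reduceat(d_s, start)
        ii, jj = uniq // ty, uniq % ty
        if tube.layer_class == "haller":
            cur = border[ii, jj]
            border[ii, jj] = np.where(np.isnan(cur), tops,
                                      np.maximum(cur, tops))
        cur = inner[ii, jj]
        inner[ii, jj] = np.where(np.isnan(cur), tops, np.maximum(cur, tops))
    has = np.isfinite(border)
    inner[has] = np.maximum(inner[has], border[has])
    return border, inner


def true_tile_summary(truth: PhantomTruth, geometry: ScanGeometry
                      ) -> tuple[ThicknessMap, ThicknessMap]:
    """Ground-truth per-tile Sattler and Haller thickness maps (µm)."""
    f = geometry.voxel_um_axial
    haller = truth.true_border * f
    sattler = np.clip(truth.true_sattler_inner - truth.true_border, 0, None) * f
    cell = (geometry.mm_per_degree * truth.tile_deg,) * 2
    return ThicknessMap(sattler, cell_mm=cell), ThicknessMap(haller, cell_mm=cell)


def generate_phantom(cfg: RunConfig, seed: int
                     ) -> tuple[OCTVolume, PhantomTruth]:
    """One-call phantom generation from a run configuration."""
    geometry = cfg.geometry()
    rng = np.random.default_rng(seed)
    rbc, csi = make_surfaces(geometry, cfg.rbc_mean_depth, cfg.csi_mean_depth,
                             cfg.surface_amplitude, cfg.surface_order, rng)
    tubes = sample_vessels(
        geometry, rbc, csi, n_sattler=cfg.n_sattler, n_haller=cfg.n_haller,
        sattler_radius_um=(cfg.sattler_radius_um_min, cfg.sattler_radius_um_max),
        haller_radius_um=(cfg.haller_radius_um_min, cfg.haller_radius_um_max),
        haller_top_frac=(cfg.haller_top_frac_min, cfg.haller_top_frac_max),
        sattler_band_frac=(cfg.sattler_band_frac_min, cfg.sattler_band_frac_max),
        seed=rng)
    vol, truth = render_volume(
        geometry, rbc, csi, tubes,
        background_level=cfg.background_level, stroma_level=cfg.stroma_level,
        vessel_level=cfg.vessel_level,
        attenuation_tau=cfg.attenuation_tau_voxels,
        speckle_shape=cfg.speckle_shape, seed=rng, tile_deg=cfg.tile_deg)
    truth.seed = seed
    return vol, truth
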