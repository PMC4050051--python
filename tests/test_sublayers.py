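import numpy as np
import pytest

from _oracles import digitized_cylinder, surface_count, surface_mask
from choroseg.core import ChoroidRegion, ScanGeometry
from choroseg.sublayers import (RatioProfile, borders_to_thickness,
                                find_borders, ratio_profile, ratio_profiles,
                                sublayer_borders, tile_volume,
                                upsample_to_ascans)
from choroseg.vessels import label_components


def _flat_region(nx, ny, start, stop):
    return ChoroidRegion(np.full((nx, ny), start, dtype=int),
                         np.full((nx, ny), stop, dtype=int),
                         np.ones((nx, ny), bool))


def _profile(smoothed, ratio=None):
    smoothed = np.asarray(smoothed, dtype=float)
    return RatioProfile(tile=(0, 0),
                        volume_counts=np.zeros_like(smoothed, dtype=int),
                        surface_counts=np.zeros_like(smoothed, dtype=int),
                        ratio=smoothed if ratio is None else ratio,
                        smoothed=smoothed)


def test_default_tiling_has_fourteen_ascans_per_degree():
    tiling = tile_volume(ScanGeometry(), 1.0)
    assert tiling.shape == (36, 36)
    widths = np.bincount(tiling.tile_x)
    assert np.all(widths[1:-1] == 14)              # interior tiles
    assert widths.sum() == 512                     # partition of the A-scans


def test_single_tile_when_tile_equals_field():
    geom = ScanGeometry(n_depth=32, n_fast=40, n_slow=40, field_deg_x=2,
                        field_deg_y=2)
    tiling = tile_volume(geom, 2.0)
    assert tiling.shape == (1, 1)
    assert np.all(tiling.tile_x == 0) and np.all(tiling.tile_y == 0)


def test_tiling_rejects_nonpositive_tile():
    with pytest.raises(ValueError):
        tile_volume(ScanGeometry(), 0.0)


def test_cube_ratio_profile_matches_enumeration():
    # 3x3x3 cube against a flat scleral boundary: bins hold 9 volume voxels
    # each; the middle bin has 8 surface voxels (only the center is interior)
    nx = ny = 12
    region = _flat_region(nx, ny, 2, 40)           # csi_floor = 40
    mask = np.zeros((48, nx, ny), bool)
    mask[37:40, 4:7, 4:7] = True                   # depth bins 0..2 from sclera
    vm = label_components(mask)
    geom = ScanGeometry(n_depth=48, n_fast=nx, n_slow=ny, field_deg_x=1,
                        field_deg_y=1)
    prof = ratio_profile(vm, region, tile_volume(geom), (0, 0), smooth_w=1)
    np.testing.assert_array_equal(prof.volume_counts[:3], [9, 9, 9])
    np.testing.assert_array_equal(prof.surface_counts[:3], [9, 8, 9])
    np.testing.assert_allclose(prof.ratio[:3], [1.0, 1.125, 1.0])
    assert np.isnan(prof.ratio[3:]).all()


def test_empty_tile_has_undefined_profile_and_borders():
    nx = ny = 8
    region = _flat_region(nx, ny, 2, 30)
    mask = np.zeros((32, nx, ny), bool)
    geom = ScanGeometry(n_depth=32, n_fast=nx, n_slow=ny, field_deg_x=1,
                        field_deg_y=1)
    prof = ratio_profile(label_components(mask), region,
                         tile_volume(geom), (0, 0))
    assert np.isnan(prof.ratio).all()
    assert find_borders(prof) == (pytest.approx(np.nan, nan_ok=True),) * 2 \
        + (False,)


def test_two_cylinder_profile_peaks_in_posterior_cylinder():
    # r=2 anterior and r=6 posterior cylinders: the smoothed ratio maximum
    # falls in the posterior (large) cylinder's depth range; verified against
    # a brute-force per-bin recount
    nx, ny, nz = 40, 40, 96
    region = _flat_region(nx, ny, 2, 90)           # csi_floor = 90
    mask = np.zeros((nz, nx, ny), bool)
    z0_big, z0_small = 75, 40                      # bins 14 and 49 at centers
    zg = np.arange(nz)[:, None]
    xg = np.arange(nx)[None, :]
    big = (zg - z0_big) ** 2 + (xg - 20) ** 2 <= 36
    small = (zg - z0_small) ** 2 + (xg - 20) ** 2 <= 4
    mask |= np.broadcast_to((big | small)[:, :, None], mask.shape)
    vm = label_components(mask)
    geom = ScanGeometry(n_depth=nz, n_fast=nx, n_slow=ny, field_deg_x=1,
                        field_deg_y=1)
    prof = ratio_profile(vm, region, tile_volume(geom), (0, 0), smooth_w=5)
    peak_bin = np.nanargmax(prof.smoothed)
    assert 89 - (z0_big + 6) <= peak_bin <= 89 - (z0_big - 6)
    # independent recount of volume/surface per depth bin
    surf = surface_mask(mask)
    for b in [8, 14, 20, 47, 49]:
        z = 89 - b
        assert prof.volume_counts[b] == mask[z].sum()
        assert prof.surface_counts[b] == surf[z].sum()


def test_find_borders_hand_traced_example():
    prof = _profile([5, 4, 2, 3, 2, 1, np.nan, np.nan])
    hs, si, defined = find_borders(prof, noise_floor=1.0, prominence=0.25)
    assert defined
    assert hs == 2.0                               # first valley after max
    assert si == 6.0                               # first undefined bin


def test_find_borders_monotone_profile_gives_zero_sattler():
    prof = _profile([5, 4, 3, 2, 1.5, np.nan])
    hs, si, defined = find_borders(prof, noise_floor=1.0)
    assert defined and hs == si


def test_find_borders_ignores_wiggle_on_large_mode():
    # a shallow notch on top of a large mode is not the inter-layer valley
    prof = _profile([5, 80, 180, 176, 183, 120, 40, 8, 2, 1.4, 1.2, 2.0,
                     2.2, 1.1, np.nan])
    hs, si, defined = find_borders(prof, noise_floor=1.0, prominence=0.25)
    assert defined
    assert 8 <= hs <= 10                           # at the true dip onset
    assert si == 14.0


@pytest.mark.parametrize("radius", range(2, 9))
def test_component_ratio_strictly_increases_with_radius(radius):
    cyl = digitized_cylinder(radius)
    vm = label_components(cyl)
    assert vm.table.n_voxels.iloc[0] == cyl.sum()
    assert vm.table.n_surface.iloc[0] == surface_count(cyl)


def test_ratio_monotonicity_across_radii():
    ratios = []
    for r in range(2, 9):
        cyl = digitized_cylinder(r)
        ratios.append(cyl.sum() / surface_count(cyl))
    assert np.all(np.diff(ratios) > 0)


def test_borders_to_thickness_arithmetic_and_missing():
    from choroseg.sublayers import SublayerBorders
    geom = ScanGeometry(axial_sampling_um=3.5, refractive_index=1.4)
    hs = np.array([[40.0, np.nan]])
    si = np.array([[70.0, np.nan]])
    defined = np.array([[True, False]])
    sattler, haller = borders_to_thickness(
        SublayerBorders(hs, si, defined), geom)
    assert haller.values[0, 0] == pytest.approx(100.0)
    assert sattler.values[0, 0] == pytest.approx(75.0)
    assert np.isnan(haller.values[0, 1]) and np.isnan(sattler.values[0, 1])


def test_layer_additivity_on_phantom(speckled_run):
    cfg, vol, _, result = speckled_run
    total = result.choroid_map.values                  # A-scan resolution, µm
    tiling = tile_volume(vol.geometry, cfg.tile_deg)
    both = result.sattler_ascan.values + result.haller_ascan.values
    ok = np.isfinite(both)
    # compare against the thickest A-scan of each tile
    import pandas as pd
    df = pd.DataFrame({
        "tile": (tiling.tile_x[:, None] * 100
                 + tiling.tile_y[None, :]).ravel(),
        "total": total.ravel(), "both": np.where(ok, both, -np.inf).ravel()})
    per_tile = df.groupby("tile").max()
    assert np.all(per_tile.both <= per_tile.total + 1e-9)


def test_borders_invariant_to_intensity_rescaling(small_cfg):
    from choroseg import phantom, pipeline
    vol, _ = phantom.generate_phantom(small_cfg, 3)
    res1 = pipeline.analyze_volume(vol, small_cfg)
    from choroseg.core import OCTVolume
    scaled = OCTVolume(vol.intensity * 2.7, vol.geometry)
    res2 = pipeline.analyze_volume(scaled, small_cfg)
    np.testing.assert_array_equal(res1.borders.haller_sattler,
                                  res2.borders.haller_sattler)
    np.testing.assert_array_equal(res1.borders.sattler_inner,
                                  res2.borders.sattler_inner)


def test_upsample_preserves_tile_means(study_cfg):
    geom = study_cfg.geometry()
    tiling = tile_volume(geom, study_cfg.tile_deg)
    from choroseg.core import ThicknessMap
    rng = np.random.default_rng(0)
    tmap = ThicknessMap(rng.uniform(50, 300, tiling.shape))
    up = upsample_to_ascans(tmap, tiling, geom)
    assert up.values.shape == (geom.n_fast, geom.n_slow)
    assert up.values[0, 0] == tmap.values[0, 0]
    xs, ys = tiling.ascans_in_tile(2, 3)
    assert np.all(up.values[np.ix_(xs, ys)] == tmap.values[2, 3])
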