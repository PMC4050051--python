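"""Run configuration: flat key-value files with typed, validated defaults."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .core import LATERALITIES, ScanGeometry

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, flat, with defaults.

    Geometry defaults describe a 36° x 36° raster of 512 x 512 A-scans with
    512 depth voxels.  Phantom depths/counts are expressed in voxels of
    that geometry and scale with it only through the config file.
    """

    # --- scan geometry -------------------------------------------------
    n_depth: int = 512
    n_fast: int = 512
    n_slow: int = 512
    field_deg_x: float = 36.0
    field_deg_y: float = 36.0
    axial_sampling_um: float = 3.5
    refractive_index: float = 1.4
    mm_per_degree: float = 0.289
    laterality: str = "right"

    # --- phantom anatomy (voxel units unless noted) --------------------
    rbc_mean_depth: float = 200.0
    csi_mean_depth: float = 340.0
    surface_amplitude: float = 6.0
    surface_order: int = 3
    n_sattler: int = 300
    n_haller: int = 80
    sattler_radius_um_min: float = 12.0
    sattler_radius_um_max: float = 30.0
    haller_radius_um_min: float = 40.0
    haller_radius_um_max: float = 100.0
    haller_top_frac_min: float = 0.42
    haller_top_frac_max: float = 0.445
    sattler_band_frac_min: float = 0.42
    sattler_band_frac_max: float = 0.75
    background_level: float = 15.0
    stroma_level: float = 100.0
    vessel_level: float = 40.0
    attenuation_tau_voxels: float = 250.0   # 0 disables attenuation
    speckle_shape: float = 8.0              # 0 disables speckle

    # --- boundary detection --------------------------------------------
    boundary_lambda: float = 2.0
    boundary_smooth_sigma: float = 4.0
    csi_min_gap_voxels: int = 10

    # --- vessel segmentation --------------------------------------------
    denoise_radius: int = 1
    candidate_percentile: float = -1.0   # < 0 = automatic (Otsu)
    cone_theta_deg: float = 30.0
    cone_length: int = 12
    gradient_percentile: float = 60.0
    core_quantile: float = 50.0
    dilate_max_iter: int = 24               # < 0 = iterate to stability
    min_component_size: int = 2

    # --- sublayer analysis ----------------------------------------------
    tile_deg: float = 1.0
    smooth_w: int = 5
    noise_floor: float = 1.0
    valley_prominence: float = 0.2

    # --- ETDRS grid -------------------------------------------------------
    etdrs_central_mm: float = 1.5
    etdrs_inner_mm: float = 3.0
    etdrs_outer_mm: float = 6.0

    # --- repeatability experiment ----------------------------------------
    n_eyes: int = 10
    n_sessions: int = 3
    session_jitter_voxels: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")
        for name in ("axial_sampling_um", "mm_per_degree", "field_deg_x",
                     "field_deg_y", "tile_deg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.candidate_percentile >= 0 and \
                not 0 < self.candidate_percentile < 100:
            raise ValueError("candidate_percentile must be in (0, 100) "
                             "or negative for automatic selection")
        if not 0 < self.core_quantile < 100:
            raise ValueError("core_quantile must be in (0, 100)")
        if not 0 < self.cone_theta_deg < 90:
            raise ValueError("cone_theta_deg must be in (0, 90)")
        if self.cone_length < 1:
            raise ValueError("cone_length must be >= 1")
        if self.smooth_w < 1 or self.smooth_w % 2 == 0:
            raise ValueError("smooth_w must be a positive odd integer")
        if not self.rbc_mean_depth < self.csi_mean_depth:
            raise ValueError("rbc_mean_depth must be < csi_mean_depth")
        if not (self.sattler_radius_um_max < self.haller_radius_um_min):
            raise ValueError("sattler and haller radius ranges must be "
                             "disjoint (sattler max < haller min)")
        if self.vessel_level >= self.stroma_level:
            raise ValueError("vessel_level must be < stroma_level")
        if self.attenuation_tau_voxels < 0 or self.speckle_shape < 0:
            raise ValueError("noise parameters must be >= 0 (0 disables)")
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")
        if self.n_eyes < 2 or self.n_sessions < 2:
            raise ValueError("repeatability experiment needs >= 2 eyes "
                             "and >= 2 sessions")

    def geometry(self) -> ScanGeometry:
        return ScanGeometry(
            n_depth=self.n_depth, n_fast=self.n_fast, n_slow=self.n_slow,
            field_deg_x=self.field_deg_x, field_deg_y=self.field_deg_y,
            axial_sampling_um=self.axial_sampling_um,
            refractive_index=self.refractive_index,
            mm_per_degree=self.mm_per_degree, laterality=self.laterality)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def default_phantom_config() -> RunConfig:
    """The standard synthetic-study configuration.

    A 5.5° x 5.5° patch sampled by 128 x 128 A-scans of 256 depth voxels
    (transverse pitch ~12.4 µm, anatomical axial pitch 5 µm), a ~500 µm
    choroid, and vessel counts scaled to the patch so that roughly two
    large tubes cross each 1° tile.  The central submacular disc
    (1.5 mm) fits inside the mapped field.
    """
    return RunConfig(
        n_depth=256, n_fast=128, n_slow=128,
        field_deg_x=5.5, field_deg_y=5.5, axial_sampling_um=7.0,
        rbc_mean_depth=100.0, csi_mean_depth=200.0,
        n_sattler=45, n_haller=12)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat key-value (YAML) config file, filling all defaults.

    Unknown keys and out-of-range values raise ``ValueError``; the
    effective configuration is logged at INFO level.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must be a flat mapping")
    kwargs = {}
    for key, value in raw.items():
        if key not in _FIELDS:
            raise ValueError(f"unknown config key: {key!r}")
        typ = _FIELDS[key].type
        if typ == "int":
            if isinstance(value, bool) or int(value) != value:
                raise ValueError(f"{key} must be an integer, got {value!r}")
            value = int(value)
        elif typ == "float":
            value = float(value)
        elif typ == "str":
            value = str(value)
        kwargs[key] = value
    cfg = RunConfig(**kwargs)
    log.info("effective configuration: %s", cfg.to_dict())
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return path
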