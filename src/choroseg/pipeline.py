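"""End-to-end workflows: phantom -> boundaries -> vessels -> sublayers ->
ETDRS summaries, plus the repeated-imaging experiment.

Every run is deterministic given (config, seed): per-eye and
per-session random streams are derived from the master seed, and a run
manifest records the config snapshot, seeds, and SHA-256 hashes of all
written artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boundaries import choroid_thickness_map, detect_boundaries
from .config import RunConfig, save_config
from .core import OCTVolume, ScanGeometry, SurfaceMap, ThicknessMap
from .etdrs import build_grid, subfield_means
from .io import write_map, write_surface, write_volume
from .phantom import PhantomTruth, VesselTube, generate_phantom, make_surfaces, \
    render_volume, sample_vessels, true_tile_summary
from .repeatability import build_report
from .sublayers import borders_to_thickness, sublayer_borders, tile_volume, \
    upsample_to_ascans
from .vessels import segment_vessels

log = logging.getLogger(__name__)

STAGES = ("phantom", "boundaries", "vessels", "sublayers", "etdrs")


class PipelineError(RuntimeError):
    pass


@dataclass
class AnalysisResult:
    """In-memory outputs of one volume analysis."""

    region: object
    vessel_mask: object
    borders: object
    choroid_map: ThicknessMap
    sattler_map: ThicknessMap          # tile resolution
    haller_map: ThicknessMap
    sattler_ascan: ThicknessMap        # A-scan resolution
    haller_ascan: ThicknessMap


def analyze_volume(vol: OCTVolume, cfg: RunConfig) -> AnalysisResult:
    """Boundaries + vessel segmentation + sublayer maps for one volume."""
    geometry = vol.geometry
    tiling = tile_volume(geometry, cfg.tile_deg)
    rbc, csi, region = detect_boundaries(
        vol, cfg.boundary_lambda, transverse_sigma=cfg.boundary_smooth_sigma,
        csi_min_gap=cfg.csi_min_gap_voxels)
    choroid_map = choroid_thickness_map(region, geometry)
    vm = segment_vessels(
        vol, region, denoise_radius=cfg.denoise_radius,
        percentile=(None if cfg.candidate_percentile < 0
                    else cfg.candidate_percentile), theta_deg=cfg.cone_theta_deg,
        cone_length=cfg.cone_length, min_grad=None,
        core_quantile=cfg.core_quantile,
        dilate_max_iter=None if cfg.dilate_max_iter < 0 else cfg.dilate_max_iter,
        min_size=cfg.min_component_size, tiling=tiling)
    borders = sublayer_borders(vm, region, tiling, cfg.smooth_w,
                               cfg.noise_floor, cfg.valley_prominence)
    sattler, haller = borders_to_thickness(borders, geometry, cfg.tile_deg)
    return AnalysisResult(
        region=region, vessel_mask=vm, borders=borders,
        choroid_map=choroid_map, sattler_map=sattler, haller_map=haller,
        sattler_ascan=upsample_to_ascans(sattler, tiling, geometry),
        haller_ascan=upsample_to_ascans(haller, tiling, geometry))


def field_means(tmap: ThicknessMap, geometry: ScanGeometry,
                csm_diameter_mm: float = 1.5, total_diameter_mm: float = 6.0
                ) -> dict[str, float]:
    """CSM and total-field means of an A-scan-resolution map.

    The CSM is the mean over the central disc of ``csm_diameter_mm``.
    The total field is the 6 mm macular disc when the map covers it,
    otherwise the whole mapped field (a reduced-extent scan stands in
    for the full macular field).
    """
    nx, ny = tmap.values.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    dx = (np.arange(nx) - cx)[:, None] * tmap.cell_mm[0]
    dy = (np.arange(ny) - cy)[None, :] * tmap.cell_mm[1]
    r = np.hypot(dx, dy)
    if csm_diameter_mm / 2 > r.max():
        raise PipelineError("CSM disc exceeds the mapped field")
    csm_mask = r < csm_diameter_mm / 2
    extent = min(cx * tmap.cell_mm[0], cy * tmap.cell_mm[1])
    total_mask = (r < total_diameter_mm / 2) if total_diameter_mm / 2 <= extent \
        else np.ones_like(csm_mask)

    def nanmean(mask):
        v = tmap.values[mask]
        v = v[np.isfinite(v)]
        return float(np.mean(v)) if v.size else np.nan

    return {"csm": nanmean(csm_mask), "total": nanmean(total_mask)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: RunConfig, seed: int, outdir: str | Path,
            stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the full phantom-to-report workflow into ``outdir``.

    ``stages`` must be a prefix-closed subset of the stage order; a
    stage whose prerequisite is missing raises :class:`PipelineError`
    naming it.  Identical (config, seed) produce identical outputs.
    """
    for i, stage in enumerate(STAGES):
        if stage in stages:
            missing = [s for s in STAGES[:i] if s not in stages]
            if missing:
                raise PipelineError(
                    f"stage '{stage}' requires missing stage '{missing[0]}'")
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"config": cfg.to_dict(), "seed": seed,
                      "version": __version__, "stages": list(stages),
                      "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def emit(path: Path) -> None:
        written.append(path)

    vol = truth = None
    try:
        if "phantom" in stages:
            vol, truth = generate_phantom(cfg, seed)
            emit(write_volume(vol, outdir / "phantom.tiff"))
            true_sattler, true_haller = true_tile_summary(truth, vol.geometry)
            emit(write_map(true_sattler, outdir / "true_sattler_um.csv"))
            emit(write_map(true_haller, outdir / "true_haller_um.csv"))
            emit(write_surface(truth.rbc_surface, outdir / "true_rbc.csv"))
            emit(write_surface(truth.csi_surface, outdir / "true_csi.csv"))
        result = None
        if "boundaries" in stages:
            result = analyze_volume(vol, cfg)
            emit(write_map(result.choroid_map, outdir / "choroid_thickness_um.csv"))
        if "sublayers" in stages:
            for name, tmap in (("sattler", result.sattler_map),
                               ("haller", result.haller_map)):
                emit(write_map(tmap, outdir / f"{name}_um.csv"))
                emit(write_map(tmap, outdir / f"{name}_um.png", format="png"))
        if "etdrs" in stages:
            geometry = vol.geometry
            grids_ok = True
            try:
                grid = build_grid(result.sattler_ascan.values.shape,
                                  result.sattler_ascan.cell_mm,
                                  laterality=geometry.laterality,
                                  diameters_mm=(cfg.etdrs_central_mm,
                                                cfg.etdrs_inner_mm,
                                                cfg.etdrs_outer_mm))
            except ValueError as exc:
                grids_ok = False
                log.warning("ETDRS grid skipped: %s", exc)
            if grids_ok:
                frames = []
                for name, tmap in (("sattler", result.sattler_ascan),
                                   ("haller", result.haller_ascan)):
                    summary = subfield_means(tmap, grid).table
                    summary.insert(0, "layer", name)
                    frames.append(summary)
                table = pd.concat(frames)
                path = outdir / "etdrs_summary.csv"
                table.to_csv(path)
                emit(path)
    except PipelineError:
        raise
    except Exception as exc:
        stage = "phantom" if vol is None else "analysis"
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    emit(save_config(cfg, outdir / "config.yaml"))
    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _shift_anatomy(rbc: SurfaceMap, csi: SurfaceMap, tubes: list[VesselTube],
                   shift: float):
    if shift == 0.0:
        return rbc, csi, tubes
    rbc2 = SurfaceMap(rbc.depth + shift, rbc.name)
    csi2 = SurfaceMap(csi.depth + shift, csi.name)
    tubes2 = [VesselTube(t.centerline + np.array([shift, 0.0, 0.0]),
                         t.radius_um, t.layer_class) for t in tubes]
    return rbc2, csi2, tubes2


def run_repeatability_experiment(cfg: RunConfig, seed: int,
                                 n_eyes: int | None = None,
                                 n_sessions: int | None = None,
                                 session_jitter: float | None = None
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic repeated-imaging experiment.

    Generates ``n_eyes`` phantom eyes (anatomy varies between eyes via
    the choroidal thickness and the random surfaces/vessels) and
    re-renders each ``n_sessions`` times with fresh speckle and an
    optional axial positioning jitter, keeping the anatomy fixed.  The
    full pipeline runs on every rendering and the Sattler/Haller CSM
    and total-field means feed the agreement report.

    Returns ``(report, measurements)``: the agreement table and the
    long-format per-rendering measurements.
    """
    n_eyes = cfg.n_eyes if n_eyes is None else n_eyes
    n_sessions = cfg.n_sessions if n_sessions is None else n_sessions
    if n_eyes < 2 or n_sessions < 2:
        raise ValueError("need n_eyes >= 2 and n_sessions >= 2")
    jitter = cfg.session_jitter_voxels if session_jitter is None \
        else session_jitter
    master = np.random.default_rng(seed)
    rows = []
    for eye in range(n_eyes):
        eye_seed = int(master.integers(2 ** 31))
        eye_rng = np.random.default_rng(eye_seed)
        thickness = (cfg.csi_mean_depth - cfg.rbc_mean_depth) \
            * eye_rng.uniform(0.75, 1.25)
        eye_cfg = cfg.replace(
            csi_mean_depth=min(cfg.rbc_mean_depth + thickness,
                               cfg.n_depth - 3 * cfg.surface_amplitude - 2))
        geometry = eye_cfg.geometry()
        rbc, csi = make_surfaces(geometry, eye_cfg.rbc_mean_depth,
                                 eye_cfg.csi_mean_depth,
                                 eye_cfg.surface_amplitude,
                                 eye_cfg.surface_order, eye_rng)
        tubes = sample_vessels(
            geometry, rbc, csi,
            n_sattler=eye_cfg.n_sattler, n_haller=eye_cfg.n_haller,
            sattler_radius_um=(eye_cfg.sattler_radius_um_min,
                               eye_cfg.sattler_radius_um_max),
            haller_radius_um=(eye_cfg.haller_radius_um_min,
                              eye_cfg.haller_radius_um_max),
            haller_top_frac=(eye_cfg.haller_top_frac_min,
                             eye_cfg.haller_top_frac_max),
            sattler_band_frac=(eye_cfg.sattler_band_frac_min,
                               eye_cfg.sattler_band_frac_max),
            seed=eye_rng)
        for session in range(1, n_sessions + 1):
            session_seed = int(master.integers(2 ** 31))
            session_rng = np.random.default_rng(session_seed)
            shift = float(session_rng.uniform(-jitter, jitter)) if jitter else 0.0
            r2, c2, t2 = _shift_anatomy(rbc, csi, tubes, shift)
            vol, _ = render_volume(
                geometry, r2, c2, t2,
                background_level=eye_cfg.background_level,
                stroma_level=eye_cfg.stroma_level,
                vessel_level=eye_cfg.vessel_level,
                attenuation_tau=eye_cfg.attenuation_tau_voxels,
                speckle_shape=eye_cfg.speckle_shape,
                seed=session_rng, tile_deg=eye_cfg.tile_deg)
            result = analyze_volume(vol, eye_cfg)
            for layer, tmap in (("sattler", result.sattler_ascan),
                                ("haller", result.haller_ascan)):
                means = field_means(tmap, geometry, cfg.etdrs_central_mm,
                                    cfg.etdrs_outer_mm)
                for fieldname, value in means.items():
                    rows.append({"subject": eye, "session": session,
                                 "layer": layer, "field": fieldname,
                                 "value": value})
    measurements = pd.DataFrame(rows)
    comparisons = tuple((1, s) for s in range(2, n_sessions + 1))
    report = build_report(measurements, comparisons)
    return report, measurements
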