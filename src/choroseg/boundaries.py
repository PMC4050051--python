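"""Detection of the RBC complex and the choroidal-scleral interface.

Each surface is found per B-scan as a minimum-cost column path through
a signed axial-gradient evidence image: a dark-to-bright transition for
the hyperintense RBC band, a bright-to-dark transition for the CSI.
Depth jumps between adjacent A-scans are charged ``smoothness`` evidence
units per voxel, and the optimal path is recovered with a
forward/backward dynamic program.  The volume is smoothed transversely
before edge detection so that locally dark vessel lumens do not divert
the path, while the smooth, large-scale boundary surfaces survive.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .core import ChoroidRegion, OCTVolume, ScanGeometry, SurfaceMap, ThicknessMap

log = logging.getLogger(__name__)


def _lower_envelope_inplace(c: np.ndarray, lam: float) -> None:
    """c[:, z] <- min_z' c[:, z'] + lam * |z - z'|, rows independent."""
    nz = c.shape[1]
    for z in range(1, nz):
        np.minimum(c[:, z], c[:, z - 1] + lam, out=c[:, z])
    for z in range(nz - 2, -1, -1):
        np.minimum(c[:, z], c[:, z + 1] + lam, out=c[:, z])


def _dp_path(evidence: np.ndarray, lam: float) -> np.ndarray:
    """Minimum-cost depth path per B-scan.

    ``evidence`` has shape (nz, n_fast, n_slow); the path runs along the
    fast axis within each B-scan.  Returns (n_fast, n_slow) int depths.
    """
    nz, n_fast, n_slow = evidence.shape
    ev = np.moveaxis(evidence, 0, 2)            # (n_fast, n_slow, nz)
    if np.isinf(lam):
        total = ev.sum(axis=0)                   # (n_slow, nz)
        depth = np.empty((n_fast, n_slow), dtype=np.int64)
        for y in range(n_slow):
            best = total[y].max()
            ties = np.nonzero(total[y] >= best - 1e-9)[0]
            depth[:, y] = int(np.median(ties))
        return depth
    ev = ev.astype(np.float32)
    fwd = np.empty((n_fast, n_slow, nz), dtype=np.float32)
    fwd[0] = -ev[0]
    for x in range(1, n_fast):
        prev = fwd[x - 1].copy()
        _lower_envelope_inplace(prev, lam)
        fwd[x] = -ev[x] + prev
    bwd = np.empty_like(fwd)
    bwd[-1] = -ev[-1]
    for x in range(n_fast - 2, -1, -1):
        nxt = bwd[x + 1].copy()
        _lower_envelope_inplace(nxt, lam)
        bwd[x] = -ev[x] + nxt
    total = fwd + bwd + ev                       # node evidence counted once
    return np.argmin(total, axis=2)


def detect_surface(vol: OCTVolume, which: str, smoothness: float = 2.0, *,
                   transverse_sigma: float = 4.0,
                   z_min: int = 1, z_max: int | None = None) -> SurfaceMap:
    """Detect the ``"rbc"`` or ``"csi"`` interface of a volume.

    ``smoothness`` is the evidence penalty per voxel of depth jump
    between adjacent A-scans (``inf`` forces a flat surface per B-scan,
    placed at the median of the best depths).  ``z_min``/``z_max``
    restrict the search range.  A volume without axial contrast yields
    an all-low-confidence result rather than an error.
    """
    if which not in ("rbc", "csi"):
        raise ValueError("which must be 'rbc' or 'csi'")
    nz = vol.shape[0]
    z_max = nz if z_max is None else min(z_max, nz)
    if not 0 <= z_min < z_max:
        raise ValueError("invalid search range")
    smoothed = ndimage.gaussian_filter(
        vol.intensity, sigma=(0.5, transverse_sigma, transverse_sigma))
    grad = np.diff(smoothed, axis=0, prepend=smoothed[:1])
    evidence = grad if which == "rbc" else -grad
    np.clip(evidence, 0, None, out=evidence)
    slab = evidence[z_min:z_max]
    depth = z_min + _dp_path(slab, smoothness)
    path_ev = np.take_along_axis(
        np.moveaxis(evidence, 0, 2), depth[..., None], axis=2)[..., 0]
    scale = np.percentile(evidence[z_min:z_max], 99.5, axis=(0, 1))  # per B-scan
    with np.errstate(divide="ignore", invalid="ignore"):
        conf = np.where(scale > 1e-9, path_ev / scale[None, :], 0.0)
    conf = np.clip(conf, 0.0, 1.0)
    if conf.max() <= 1e-9:
        log.warning("surface %s: no axial contrast, confidence all zero", which)
    return SurfaceMap(depth.astype(np.float64), which, conf)


def detect_boundaries(vol: OCTVolume, smoothness: float = 2.0, *,
                      transverse_sigma: float = 4.0,
                      csi_min_gap: int = 10
                      ) -> tuple[SurfaceMap, SurfaceMap, ChoroidRegion]:
    """Detect both choroid boundaries and form the choroid region.

    The CSI search is restricted to depths below the detected RBC
    surface plus ``csi_min_gap`` voxels.
    """
    rbc = detect_surface(vol, "rbc", smoothness,
                         transverse_sigma=transverse_sigma)
    z_min = int(np.floor(rbc.depth.min())) + csi_min_gap
    z_min = min(max(z_min, 1), vol.shape[0] - 2)
    csi = detect_surface(vol, "csi", smoothness,
                         transverse_sigma=transverse_sigma, z_min=z_min)
    return rbc, csi, choroid_region(rbc, csi)


def choroid_region(rbc: SurfaceMap, csi: SurfaceMap) -> ChoroidRegion:
    """Half-open per-A-scan interval [ceil(rbc), floor(csi)).

    A-scans where the surfaces cross (rbc > csi) are marked undefined
    and counted in the log; rbc == csi yields a defined zero-length
    interval.
    """
    if rbc.depth.shape != csi.depth.shape:
        raise ValueError("surface grids must share a shape")
    defined = (np.isfinite(rbc.depth) & np.isfinite(csi.depth)
               & (csi.depth >= rbc.depth))
    n_bad = int((~defined).sum())
    if n_bad:
        log.info("choroid region: %d A-scans undefined (rbc > csi)", n_bad)
    start = np.where(defined, np.ceil(rbc.depth), 0).astype(np.int64)
    stop = np.where(defined, np.floor(csi.depth), 0).astype(np.int64)
    stop = np.maximum(stop, start)
    return ChoroidRegion(start, stop, defined)


def choroid_thickness_map(region: ChoroidRegion, geometry: ScanGeometry
                          ) -> ThicknessMap:
    """Total choroidal thickness in anatomical µm per A-scan.

    The voxel distance is converted to optical distance with the axial
    sampling pitch and to anatomical distance with the group index.
    """
    um = region.length * geometry.voxel_um_axial
    values = np.where(region.defined, um, np.nan)
    return ThicknessMap(values, cell_mm=(geometry.mm_per_voxel_x,
                                         geometry.mm_per_voxel_y))
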