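"""Reading and writing OCT volumes, thickness maps, and surface grids.

Volumes are stored either as multi-page TIFF stacks (one page per
B-scan, each page a ``(z, x)`` image) or as NIfTI-1 files holding the
``[z, x, y]`` grid directly.  Either carries a flat YAML sidecar
(``<stem>.geometry.yaml``) with the scan geometry.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import OCTVolume, ScanGeometry, SurfaceMap, ThicknessMap

_GEOM_KEYS = ("n_depth", "n_fast", "n_slow", "field_deg_x", "field_deg_y",
              "axial_sampling_um", "refractive_index", "mm_per_degree",
              "laterality")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".geometry.yaml")


def write_geometry(geom: ScanGeometry, path: str | Path) -> Path:
    path = Path(path)
    data = {k: getattr(geom, k) for k in _GEOM_KEYS}
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def read_geometry(path: str | Path) -> ScanGeometry:
    data = yaml.safe_load(Path(path).read_text())
    return ScanGeometry(**{k: data[k] for k in _GEOM_KEYS})


def read_volume(path: str | Path, geometry: ScanGeometry | None = None) -> OCTVolume:
    """Read a TIFF or NIfTI volume into ``[z, x, y]`` axis order.

    If ``geometry`` is omitted the sidecar next to ``path`` is used.
    The stored shape must match the geometry exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if geometry is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"no geometry given and no sidecar {sidecar}")
        geometry = read_geometry(sidecar)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        arr = np.asanyarray(nib.load(str(path)).dataobj)
    else:
        pages = tifffile.imread(str(path))  # (n_slow, n_depth, n_fast)
        if pages.ndim == 2:
            pages = pages[None]
        arr = np.moveaxis(pages, 0, 2)      # -> (z, x, y)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric voxel data ({arr.dtype})")
    if arr.shape != geometry.shape:
        raise ValueError(
            f"{path}: stored shape {arr.shape} does not match geometry "
            f"shape {geometry.shape}")
    return OCTVolume(arr.astype(np.float32), geometry)


def write_volume(vol: OCTVolume, path: str | Path) -> Path:
    """Write a volume (TIFF one page per B-scan, or NIfTI) plus sidecar."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        nib.save(nib.Nifti1Image(vol.intensity, affine=np.eye(4)), str(path))
    else:
        pages = np.moveaxis(vol.intensity, 2, 0)  # (y, z, x)
        tifffile.imwrite(str(path), pages)
    write_geometry(vol.geometry, _sidecar_path(path))
    return path


def write_map(tmap: ThicknessMap, path: str | Path, format: str = "csv") -> Path:
    """Serialize a thickness map as full-precision CSV or a PNG rendering.

    CSV cells hold repr-precision floats with missing cells left empty.
    The PNG uses a perceptually uniform colormap; its value range is
    recorded in the PNG metadata.
    """
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for row in tmap.values:
                writer.writerow(["" if not np.isfinite(v) else repr(float(v))
                                 for v in row])
        return path
    if format == "png":
        import matplotlib
        matplotlib.use("Agg")
        from matplotlib import cm
        from PIL import Image, PngImagePlugin
        vals = tmap.values
        finite = vals[np.isfinite(vals)]
        vmin = float(finite.min()) if finite.size else 0.0
        vmax = float(finite.max()) if finite.size else 1.0
        span = (vmax - vmin) or 1.0
        norm = np.clip((vals - vmin) / span, 0, 1)
        rgba = (cm.viridis(norm) * 255).astype(np.uint8)
        rgba[~np.isfinite(vals)] = 0
        meta = PngImagePlugin.PngInfo()
        meta.add_text("value_range_um", f"{vmin},{vmax}")
        Image.fromarray(rgba.swapaxes(0, 1)).save(path, pnginfo=meta)
        return path
    raise ValueError(f"unknown map format: {format!r}")


def read_map(path: str | Path, cell_mm: tuple[float, float] = (0.0, 0.0)) -> ThicknessMap:
    """Read a CSV thickness map written by :func:`write_map`."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            rows.append([np.nan if cell == "" else float(cell) for cell in row])
    return ThicknessMap(np.asarray(rows, dtype=np.float64), cell_mm=cell_mm)


def write_surface(surf: SurfaceMap, path: str | Path) -> Path:
    np.savetxt(path, surf.depth, delimiter=",")
    return path


def read_surface(path: str | Path, name: str) -> SurfaceMap:
    return SurfaceMap(np.loadtxt(path, delimiter=",", ndmin=2), name=name)
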