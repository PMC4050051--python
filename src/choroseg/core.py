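"""Core data containers shared across the pipeline.

Coordinate conventions
----------------------
Volumes are indexed ``[z, x, y]``: ``z`` is depth along the A-scan
(z = 0 anterior, increasing toward the sclera), ``x`` the fast axis
(A-scans within a B-scan), ``y`` the slow axis (B-scan index).  All
depth coordinates are 0-based and depth intervals are half-open
``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LATERALITIES = ("left", "right")


@dataclass(frozen=True)
class ScanGeometry:
    """Scan geometry and unit calibration of an OCT raster volume.

    Parameters
    ----------
    n_depth, n_fast, n_slow
        Voxels per A-scan, A-scans per B-scan, and number of B-scans.
    field_deg_x, field_deg_y
        Angular field of view along the fast / slow axes (degrees).
    axial_sampling_um
        Optical path length per depth voxel (µm).  Divide by the group
        refractive index to obtain the anatomical depth per voxel.
    refractive_index
        Dimensionless group index used for optical->anatomical conversion.
    mm_per_degree
        Transverse scale of the emmetropic schematic eye (mm per degree
        of visual angle).
    laterality
        ``"left"`` or ``"right"`` eye; flips the nasal/temporal sides.
    """

    n_depth: int = 512
    n_fast: int = 512
    n_slow: int = 512
    field_deg_x: float = 36.0
    field_deg_y: float = 36.0
    axial_sampling_um: float = 3.5
    refractive_index: float = 1.4
    mm_per_degree: float = 0.289
    laterality: str = "right"

    def __post_init__(self) -> None:
        for name in ("n_depth", "n_fast", "n_slow"):
            v = getattr(self, name)
            if int(v) != v or v < 8:
                raise ValueError(f"{name} must be an integer >= 8, got {v!r}")
        for name in ("field_deg_x", "field_deg_y", "axial_sampling_um",
                     "mm_per_degree"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_depth, self.n_fast, self.n_slow)

    @property
    def voxel_um_axial(self) -> float:
        """Anatomical depth per voxel in µm (optical pitch / group index)."""
        return self.axial_sampling_um / self.refractive_index

    @property
    def mm_per_voxel_x(self) -> float:
        return self.field_deg_x * self.mm_per_degree / self.n_fast

    @property
    def mm_per_voxel_y(self) -> float:
        return self.field_deg_y * self.mm_per_degree / self.n_slow

    @property
    def bscans_per_degree(self) -> float:
        return self.n_slow / self.field_deg_y


@dataclass
class OCTVolume:
    """A 3D OCT intensity grid plus its scan geometry."""

    intensity: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.intensity.shape != self.geometry.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"geometry shape {self.geometry.shape}")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.intensity.min() < 0:
            raise ValueError("intensity must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


@dataclass
class SurfaceMap:
    """Per-A-scan depth of a named interface (``rbc`` or ``csi``)."""

    depth: np.ndarray          # (n_fast, n_slow) float depth index
    name: str
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.ndim != 2:
            raise ValueError("surface depth must be a 2D (x, y) grid")
        if self.confidence is None:
            self.confidence = np.ones_like(self.depth)
        else:
            self.confidence = np.asarray(self.confidence, dtype=np.float64)
            if self.confidence.shape != self.depth.shape:
                raise ValueError("confidence shape mismatch")


@dataclass
class ChoroidRegion:
    """Per-A-scan half-open depth interval [start, stop) of the choroid.

    ``defined`` marks A-scans where both surfaces were found in the
    correct order; undefined A-scans carry start == stop == 0.
    """

    start: np.ndarray   # (n_fast, n_slow) int, ceil(rbc)
    stop: np.ndarray    # (n_fast, n_slow) int, floor(csi)
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.stop = np.asarray(self.stop, dtype=np.int64)
        self.defined = np.asarray(self.defined, dtype=bool)
        if not (self.start.shape == self.stop.shape == self.defined.shape):
            raise ValueError("region grids must share a shape")
        if np.any(self.stop[self.defined] < self.start[self.defined]):
            raise ValueError("defined intervals must have stop >= start")

    @property
    def length(self) -> np.ndarray:
        """Interval length in voxels (0 where undefined)."""
        out = self.stop - self.start
        out[~self.defined] = 0
        return out

    def to_mask(self, n_depth: int) -> np.ndarray:
        """Boolean [z, x, y] volume of choroid voxels."""
        z = np.arange(n_depth)[:, None, None]
        return (z >= self.start[None]) & (z < self.stop[None]) & self.defined[None]


@dataclass
class ThicknessMap:
    """2D thickness grid in µm; NaN marks undefined cells."""

    values: np.ndarray
    cell_mm: tuple[float, float] = (0.0, 0.0)
    units: str = "um"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("thickness map must be 2D")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("defined thickness values must be >= 0")
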