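"""Shared geometric containers for the scanner coordinate frame.

Package-wide axis convention (all arrays, all modules):

* axis 0 — vertical / anterior–posterior, positive toward anterior ("up"),
* axis 1 — lateral, positive toward patient-left,
* axis 2 — longitudinal / Z, positive toward superior.

Vertical positions are measured in mm in the scanner frame; the gantry
isocenter sits at a fixed vertical coordinate (``isocenter_y``, 0 by
default), so positive centerline values mean "above the gantry center".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = ["Grid3D", "Volume3D", "Localizer2D", "INTENSITY_QUANTUM"]

#: Intensity quantization step on the normalized [0, 1] scale.  4096 levels
#: mirror a 12-bit CT detector and, being a power of two, make the
#: integer-storage round trip (DICOM/NIfTI writers) bit-exact in float32.
INTENSITY_QUANTUM = 1.0 / 4096.0


@dataclass(frozen=True)
class Grid3D:
    """Axial voxel grid in the scanner frame.

    Parameters
    ----------
    shape : tuple of int
        Voxels along (vertical/AP, lateral, longitudinal/Z).
    spacing : tuple of float
        mm per voxel along the same axes; strictly positive.
    origin : tuple of float
        mm position of the *center* of voxel (0, 0, 0).
    isocenter_y : float
        Scanner-frame vertical coordinate of the gantry isocenter, a fixed
        property of the scanner, shared by every case of a cohort.
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]
    isocenter_y: float = 0.0

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def centered(cls, shape, spacing, isocenter_y: float = 0.0) -> "Grid3D":
        """Grid whose physical center coincides with (isocenter_y, 0, 0)."""
        shape = tuple(int(n) for n in shape)
        spacing = tuple(float(s) for s in spacing)
        center = np.array([isocenter_y, 0.0, 0.0])
        origin = center - (np.asarray(shape) - 1) / 2.0 * np.asarray(spacing)
        return cls(shape=shape, spacing=spacing, origin=tuple(origin),
                   isocenter_y=isocenter_y)

    def coords(self, axis: int) -> np.ndarray:
        """mm coordinates of voxel centers along ``axis``."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def extent(self, axis: int) -> Tuple[float, float]:
        """Physical extent (outer voxel edges) along ``axis`` in mm."""
        lo = self.origin[axis] - self.spacing[axis] / 2.0
        hi = self.origin[axis] + (self.shape[axis] - 0.5) * self.spacing[axis]
        return (lo, hi)

    def with_isocenter(self, isocenter_y: float) -> "Grid3D":
        return replace(self, isocenter_y=float(isocenter_y))


@dataclass
class Volume3D:
    """Axial voxel volume with physical geometry.

    ``voxels`` is float32, shaped like ``grid.shape``; intensities live on a
    normalized [0, 1] scale for synthetic data (scanner units for real data
    until preprocessing).
    """

    voxels: np.ndarray
    grid: Grid3D
    table_height: Optional[float] = None
    orientation_tag: str = "axial"
    source_id: Optional[str] = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.shape != tuple(self.grid.shape):
            raise ValueError(
                f"voxel array shape {self.voxels.shape} does not match grid "
                f"shape {self.grid.shape}"
            )
        if self.orientation_tag not in ("axial", "coronal"):
            raise ValueError(f"unknown orientation_tag {self.orientation_tag!r}")


@dataclass
class Localizer2D:
    """AP projection radiograph (scout view).

    ``pixels`` rows run along longitudinal Z (superior last row if the grid
    does), columns along the lateral axis; ``pixel_spacing`` and ``position``
    are (row/Z, column/lateral) in mm of pixel centers.
    """

    pixels: np.ndarray
    pixel_spacing: Tuple[float, float]
    position: Tuple[float, float]
    source_id: Optional[str] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("localizer pixels must be 2D")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        self.position = tuple(float(p) for p in self.position)

    def coords(self, axis: int) -> np.ndarray:
        return self.position[axis] + self.pixel_spacing[axis] * np.arange(
            self.pixels.shape[axis]
        )

    def extent(self, axis: int) -> Tuple[float, float]:
        lo = self.position[axis] - self.pixel_spacing[axis] / 2.0
        hi = self.position[axis] + (self.pixels.shape[axis] - 0.5) * self.pixel_spacing[axis]
        return (lo, hi)


def quantize_intensity(values: np.ndarray) -> np.ndarray:
    """Snap normalized intensities to the 12-bit ladder (float32, exact)."""
    v = np.clip(np.asarray(values, dtype=np.float32), 0.0, 1.0)
    return (np.round(v * np.float32(4096.0)) / np.float32(4096.0)).astype(np.float32)
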