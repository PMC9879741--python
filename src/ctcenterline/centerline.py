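"""Bounding-box centerline measurement on axial volumes.

The body contour is found by intensity thresholding followed by region shape
evaluation that removes the couch, blankets and other foreign objects; the
lungs by low-intensity thresholding inside the body.  An axis-aligned
bounding box around each structure yields the anterior/posterior limits and
their midpoint, the AP centerline, in scanner-frame millimetres.  The same
code measures ground-truth volumes (BCGTH/LCGTH) and network reconstructions
(BCDL/LCDL); a longitudinal scan-range restriction reproduces the dependence
of the centerline on the selected axial range.

Thresholds operate on a min--max normalized copy of the volume, so the
measurement is invariant to affine intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .core import Grid3D, Volume3D
from .preprocess import normalize01

__all__ = [
    "CenterlineConfig",
    "BoundingBox3D",
    "CenterlineReport",
    "segment_body",
    "segment_lungs",
    "bbox_and_centerline",
    "detect_truncation",
    "measure_centerlines",
]


@dataclass(frozen=True)
class CenterlineConfig:
    """Segmentation thresholds (normalized scale) and shape rules.

    ``body_threshold`` separates soft tissue from everything less attenuating
    (air, lungs, blanket) and sits above the couch's intensity band so that
    reconstruction blur between couch and body cannot bridge the two; on
    crisp volumes the measured centerline is insensitive to its exact value
    because bounding-box erosion is vertically symmetric.  Components that do
    survive it are additionally screened by shape: wider than ``max_aspect``
    times their height, or mid-slice solidity below ``min_solidity``, means
    a foreign object (couch, blanket).  ``lung_threshold`` selects
    low-intensity voxels inside the body.
    """

    body_threshold: float = 0.65
    lung_threshold: float = 0.3
    max_aspect: float = 4.0
    min_solidity: float = 0.5
    min_volume_fraction: float = 0.005
    truncation_slice_fraction: float = 0.1


@dataclass(frozen=True)
class BoundingBox3D:
    """Axis-aligned box in mm; vertical axis is anterior-positive."""

    anterior_limit: float
    posterior_limit: float
    lateral_limits: Tuple[float, float]
    z_limits: Tuple[float, float]

    def __post_init__(self):
        if self.anterior_limit < self.posterior_limit:
            raise ValueError("empty bounding box: anterior below posterior")

    @property
    def centerline(self) -> float:
        return 0.5 * (self.anterior_limit + self.posterior_limit)


@dataclass
class CenterlineReport:
    """Measured centerlines for one volume (ground truth or predicted)."""

    body_centerline: float
    body_bbox: BoundingBox3D
    lung_centerline: Optional[float]
    lung_bbox: Optional[BoundingBox3D]
    truncated: bool = False
    lung_fallback: bool = False
    source: str = "ground_truth"
    per_slice_centerlines: Optional[np.ndarray] = None
    isocenter_y: float = 0.0


def _normalized(volume: Volume3D) -> np.ndarray:
    return normalize01(volume.voxels)


def _component_passes_shape(mask_comp: np.ndarray, grid: Grid3D,
                            config: CenterlineConfig) -> bool:
    idx = np.nonzero(mask_comp)
    h_mm = (idx[0].max() - idx[0].min() + 1) * grid.spacing[0]
    w_mm = (idx[1].max() - idx[1].min() + 1) * grid.spacing[1]
    if w_mm / h_mm > config.max_aspect:
        return False
    # solidity evaluated on the largest axial cross-section
    areas = mask_comp.sum(axis=(0, 1))
    k = int(np.argmax(areas))
    sl = mask_comp[:, :, k].astype(np.uint8)
    props = regionprops(sl)
    if not props:
        return False
    solidity = max(p.solidity for p in props)
    return solidity >= config.min_solidity


def segment_body(volume: Volume3D,
                 config: CenterlineConfig = CenterlineConfig()) -> np.ndarray:
    """Binary body mask: largest thresholded component passing the shape
    rules, with per-slice hole filling so the lungs lie inside it."""
    norm = _normalized(volume)
    raw = norm > config.body_threshold
    labels, n = ndimage.label(raw, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("no body found: nothing above the body threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    min_vox = config.min_volume_fraction * labels.size
    candidates = []
    for lab in range(1, n + 1):
        if sizes[lab - 1] < min_vox:
            continue
        comp = labels == lab
        if _component_passes_shape(comp, volume.grid, config):
            candidates.append((sizes[lab - 1], lab))
    if not candidates:
        raise ValueError("no body found: all components rejected by shape rules")
    _, lab = max(candidates)
    body = labels == lab
    # fill lungs/airways slice by slice (they are enclosed in every axial slice)
    for k in range(body.shape[2]):
        body[:, :, k] = ndimage.binary_fill_holes(body[:, :, k])
    return body


def segment_lungs(volume: Volume3D, body_mask: np.ndarray,
                  config: CenterlineConfig = CenterlineConfig()
                  ) -> Tuple[np.ndarray, bool]:
    """Lung mask (union of the two largest low-intensity components inside
    the body) plus a fallback flag set when fewer than two are found."""
    norm = _normalized(volume)
    low = (norm < config.lung_threshold) & body_mask
    labels, n = ndimage.label(low, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(body_mask), True
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    order = np.argsort(sizes)[::-1]
    min_vox = max(8, int(0.0005 * labels.size))
    keep = [int(order[i]) + 1 for i in range(min(2, n))
            if sizes[int(order[i])] >= min_vox]
    fallback = len(keep) < 2
    mask = np.isin(labels, keep) if keep else np.zeros_like(body_mask)
    return mask, fallback


def bbox_and_centerline(mask: np.ndarray, grid: Grid3D,
                        scan_range: Optional[Tuple[float, float]] = None
                        ) -> Tuple[BoundingBox3D, float]:
    """Axis-aligned bounding box (mm, voxel centers) of a mask and the AP
    centerline, optionally restricted to a longitudinal mm interval."""
    if scan_range is not None:
        z = grid.coords(2)
        z0, z1 = min(scan_range), max(scan_range)
        sel = (z >= z0) & (z <= z1)
        if not sel.any():
            raise ValueError("scan_range contains no slices")
        mask = mask[:, :, sel]
        z_coords = z[sel]
    else:
        z_coords = grid.coords(2)
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        raise ValueError("empty mask (within scan_range)")
    y = grid.coords(0)
    x = grid.coords(1)
    box = BoundingBox3D(
        anterior_limit=float(y[idx[0].max()]),
        posterior_limit=float(y[idx[0].min()]),
        lateral_limits=(float(x[idx[1].min()]), float(x[idx[1].max()])),
        z_limits=(float(z_coords[idx[2].min()]), float(z_coords[idx[2].max()])),
    )
    return box, box.centerline


def detect_truncation(body_mask: np.ndarray, grid: Grid3D,
                      slice_fraction: float = 0.1) -> bool:
    """True if the body touches a lateral or vertical FOV boundary in more
    than ``slice_fraction`` of the slices it occupies (Z boundaries do not
    count: a chest scan legitimately cuts the torso in Z)."""
    occupied = np.nonzero(body_mask.any(axis=(0, 1)))[0]
    if occupied.size == 0:
        return False
    touching = 0
    for k in occupied:
        sl = body_mask[:, :, k]
        if (sl[0, :].any() or sl[-1, :].any()
                or sl[:, 0].any() or sl[:, -1].any()):
            touching += 1
    return touching > slice_fraction * occupied.size


def measure_centerlines(volume: Volume3D,
                        config: CenterlineConfig = CenterlineConfig(),
                        scan_range: Optional[Tuple[float, float]] = None,
                        source: str = "ground_truth",
                        per_slice: bool = False) -> CenterlineReport:
    """Full measurement for one axial volume: segment, box, centerlines."""
    body = segment_body(volume, config)
    body_bbox, body_cl = bbox_and_centerline(body, volume.grid, scan_range)
    truncated = detect_truncation(body, volume.grid,
                                  config.truncation_slice_fraction)
    lungs, fallback = segment_lungs(volume, body, config)
    lung_bbox = None
    lung_cl = None
    if lungs.any():
        try:
            lung_bbox, lung_cl = bbox_and_centerline(lungs, volume.grid,
                                                     scan_range)
        except ValueError:
            fallback = True
    per_slice_cl = None
    if per_slice:
        y = volume.grid.coords(0)
        vals = []
        for k in range(body.shape[2]):
            sl = body[:, :, k]
            if sl.any():
                rows = np.nonzero(sl.any(axis=1))[0]
                vals.append(0.5 * (y[rows.max()] + y[rows.min()]))
            else:
                vals.append(np.nan)
        per_slice_cl = np.array(vals)
    return CenterlineReport(
        body_centerline=float(body_cl),
        body_bbox=body_bbox,
        lung_centerline=None if lung_cl is None else float(lung_cl),
        lung_bbox=lung_bbox,
        truncated=truncated,
        lung_fallback=fallback,
        source=source,
        per_slice_centerlines=per_slice_cl,
        isocenter_y=volume.grid.isocenter_y,
    )
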