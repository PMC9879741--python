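"""Pre-processing: crop to a common physical extent, [0, 1] normalization,
resizing to the fixed training matrices, and the train/test cohort split.

The training input is the AP localizer resized to 144 (lateral) x 64 (Z)
pixels; the training target is the coronal-reoriented volume resized to
184 (AP) x 144 (lateral) x 64 (Z) voxels.  Smaller matrices (e.g. 48 x 32 and
64 x 48 x 32) are supported through :class:`PreprocessConfig` for desk-scale
experiments.  All geometric bookkeeping needed to map a prediction back into
scanner-frame millimetres travels in a :class:`CropRecord`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .core import Grid3D, Localizer2D, Volume3D

__all__ = [
    "PreprocessConfig",
    "CropRecord",
    "TrainingPair",
    "crop_to_common_extent",
    "normalize01",
    "resize_nd",
    "resize_localizer",
    "resize_volume_coronal",
    "make_training_pair",
    "volume_from_prediction",
    "split_cohort",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Target matrices and interpolation settings.

    ``localizer_shape`` is (lateral, Z); ``volume_shape`` is (AP, lateral, Z).
    """

    localizer_shape: Tuple[int, int] = (144, 64)
    volume_shape: Tuple[int, int, int] = (184, 144, 64)
    interpolation_order: int = 1

    def to_dict(self) -> dict:
        return {
            "localizer_shape": list(self.localizer_shape),
            "volume_shape": list(self.volume_shape),
            "interpolation_order": self.interpolation_order,
        }


@dataclass(frozen=True)
class CropRecord:
    """mm spans (first to last voxel center) retained per axis of the cropped
    volume, plus the scanner's isocenter coordinate.

    Resizing is endpoint-preserving (the first/last sample of an axis keeps
    its mm coordinate), so these spans are exactly what is needed to place a
    network prediction back into the scanner frame.
    """

    ap_span: Tuple[float, float]
    lat_span: Tuple[float, float]
    z_span: Tuple[float, float]
    isocenter_y: float = 0.0

    def to_dict(self) -> dict:
        return {
            "ap_span": list(self.ap_span),
            "lat_span": list(self.lat_span),
            "z_span": list(self.z_span),
            "isocenter_y": self.isocenter_y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CropRecord":
        return cls(
            ap_span=tuple(d["ap_span"]),
            lat_span=tuple(d["lat_span"]),
            z_span=tuple(d["z_span"]),
            isocenter_y=float(d.get("isocenter_y", 0.0)),
        )


@dataclass
class TrainingPair:
    """One (localizer, volume) sample in normalized training space.

    ``localizer_in`` is (lateral, Z); ``volume_out`` is coronal
    (AP, lateral, Z); both float32 in [0, 1].
    """

    localizer_in: np.ndarray
    volume_out: Optional[np.ndarray]
    crop_record: CropRecord
    case_id: str = "case"
    source_id: Optional[str] = None


def _overlap(a: Tuple[float, float], b: Tuple[float, float]) -> Tuple[float, float]:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    if hi <= lo:
        raise ValueError("images do not overlap in physical extent")
    return lo, hi


def _crop_axis(coords: np.ndarray, interval: Tuple[float, float]) -> slice:
    inside = np.nonzero((coords >= interval[0] - 1e-9) & (coords <= interval[1] + 1e-9))[0]
    if inside.size == 0:
        raise ValueError("crop interval contains no voxel centers")
    return slice(int(inside[0]), int(inside[-1]) + 1)


def crop_to_common_extent(
    localizer: Localizer2D, volume: Volume3D
) -> Tuple[Localizer2D, Volume3D, CropRecord]:
    """Restrict localizer and volume to the intersection of their lateral x Z
    physical extents (the localizer knows nothing about the AP axis).

    For a localizer and volume generated from the same phantom the extents
    coincide and this is a no-op.
    """
    lat = _overlap(localizer.extent(1), volume.grid.extent(1))
    zz = _overlap(localizer.extent(0), volume.grid.extent(2))

    lsl_z = _crop_axis(localizer.coords(0), zz)
    lsl_x = _crop_axis(localizer.coords(1), lat)
    loc = Localizer2D(
        pixels=localizer.pixels[lsl_z, lsl_x],
        pixel_spacing=localizer.pixel_spacing,
        position=(
            localizer.coords(0)[lsl_z.start],
            localizer.coords(1)[lsl_x.start],
        ),
        source_id=localizer.source_id,
    )

    g = volume.grid
    vsl_x = _crop_axis(g.coords(1), lat)
    vsl_z = _crop_axis(g.coords(2), zz)
    new_origin = (g.origin[0], g.coords(1)[vsl_x.start], g.coords(2)[vsl_z.start])
    new_shape = (
        g.shape[0],
        vsl_x.stop - vsl_x.start,
        vsl_z.stop - vsl_z.start,
    )
    vol = Volume3D(
        voxels=volume.voxels[:, vsl_x, vsl_z],
        grid=Grid3D(shape=new_shape, spacing=g.spacing, origin=new_origin,
                    isocenter_y=g.isocenter_y),
        table_height=volume.table_height,
        orientation_tag=volume.orientation_tag,
        source_id=volume.source_id,
    )

    vg = vol.grid
    record = CropRecord(
        ap_span=(vg.coords(0)[0], vg.coords(0)[-1]),
        lat_span=(vg.coords(1)[0], vg.coords(1)[-1]),
        z_span=(vg.coords(2)[0], vg.coords(2)[-1]),
        isocenter_y=vg.isocenter_y,
    )
    return loc, vol, record


def normalize01(image: np.ndarray) -> np.ndarray:
    """Affine min–max normalization to [0, 1]; a constant image maps to zeros
    (with a warning) rather than NaN."""
    img = np.asarray(image, dtype=np.float32)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        warnings.warn("normalize01: constant image, returning zeros")
        return np.zeros_like(img)
    return (img - lo) / np.float32(hi - lo)


def resize_nd(image: np.ndarray, shape: Sequence[int], order: int = 1) -> np.ndarray:
    """Endpoint-preserving linear resize: sample i of an output axis of length
    m sits at input index i*(n-1)/(m-1), so first/last samples are exact."""
    image = np.asarray(image, dtype=np.float32)
    shape = tuple(int(m) for m in shape)
    if image.ndim != len(shape):
        raise ValueError("target shape rank does not match image rank")
    axes = [
        np.linspace(0.0, n - 1.0, m) if m > 1 else np.array([(n - 1) / 2.0])
        for n, m in zip(image.shape, shape)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = map_coordinates(image, coords, order=order, mode="nearest")
    return out.astype(np.float32)


def resize_localizer(pixels: np.ndarray, shape: Tuple[int, int] = (144, 64),
                     order: int = 1) -> np.ndarray:
    """Resize a (lateral, Z) localizer to the training matrix, clamped [0,1]."""
    return np.clip(resize_nd(pixels, shape, order=order), 0.0, 1.0)


def resize_volume_coronal(volume_voxels: np.ndarray,
                          shape: Tuple[int, int, int] = (184, 144, 64),
                          order: int = 1) -> np.ndarray:
    """Reorient an axial (AP, lateral, Z) volume to a coronal stack and resize.

    In the package axis convention the axial array *is* a coronal stack read
    along axis 0, so reorientation is the identity permutation; it is still
    funnelled through here so the orientation contract lives in one place.
    """
    return np.clip(resize_nd(volume_voxels, shape, order=order), 0.0, 1.0)


def make_training_pair(
    localizer: Localizer2D,
    volume: Optional[Volume3D],
    config: PreprocessConfig = PreprocessConfig(),
    case_id: str = "case",
) -> TrainingPair:
    """Full preprocessing for one case: crop -> normalize -> resize.

    ``volume`` may be omitted (prediction-time preprocessing); the crop is
    then skipped and the localizer's own extent fills the lateral/Z spans of
    the crop record (the AP span must be supplied downstream).
    """
    if volume is not None:
        loc, vol, record = crop_to_common_extent(localizer, volume)
        vol_norm = normalize01(vol.voxels)
        volume_out = resize_volume_coronal(vol_norm, config.volume_shape,
                                           config.interpolation_order)
    else:
        loc = localizer
        zc, xc = loc.coords(0), loc.coords(1)
        record = CropRecord(ap_span=(np.nan, np.nan),
                            lat_span=(xc[0], xc[-1]),
                            z_span=(zc[0], zc[-1]))
        volume_out = None
    loc_norm = normalize01(loc.pixels).T  # (Z, lat) -> (lat, Z)
    localizer_in = resize_localizer(loc_norm, config.localizer_shape,
                                    config.interpolation_order)
    return TrainingPair(
        localizer_in=localizer_in,
        volume_out=volume_out,
        crop_record=record,
        case_id=case_id,
        source_id=localizer.source_id,
    )


def volume_from_prediction(prediction: np.ndarray, record: CropRecord) -> Volume3D:
    """Place a coronal (AP, lateral, Z) prediction back into the scanner frame
    as an axial :class:`Volume3D`, using the crop record's mm spans."""
    pred = np.clip(np.asarray(prediction, dtype=np.float32), 0.0, 1.0)
    if pred.ndim != 3:
        raise ValueError("prediction must be a 3D (AP, lateral, Z) array")
    spans = (record.ap_span, record.lat_span, record.z_span)
    spacing, origin = [], []
    for (lo, hi), m in zip(spans, pred.shape):
        if not np.isfinite(lo) or not np.isfinite(hi):
            raise ValueError("crop record lacks an AP span; preprocess with a volume")
        spacing.append((hi - lo) / (m - 1) if m > 1 else 1.0)
        origin.append(lo)
    grid = Grid3D(shape=pred.shape, spacing=tuple(spacing), origin=tuple(origin),
                  isocenter_y=record.isocenter_y)
    return Volume3D(voxels=pred, grid=grid, orientation_tag="axial")


def split_cohort(cases: Sequence, fraction: float = 0.8, seed: int = 0,
                 source_of=None) -> Tuple[list, list]:
    """Random train/test split, stratified per source (scanner) id.

    ``source_of`` extracts the stratum label from a case (defaults to the
    case's ``source_id`` attribute, or a single stratum when absent).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to split")
    if source_of is None:
        source_of = lambda c: getattr(c, "source_id", None)
    rng = np.random.default_rng(seed)
    strata: dict = {}
    for i, c in enumerate(cases):
        strata.setdefault(source_of(c), []).append(i)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for key in sorted(strata, key=str):
        idx = np.array(strata[key])
        rng.shuffle(idx)
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 0), len(idx))
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    train_idx.sort()
    test_idx.sort()
    return [cases[i] for i in train_idx], [cases[i] for i in test_idx]
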