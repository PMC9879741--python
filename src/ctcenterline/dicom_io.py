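"""Reading and writing localizer and axial-series images with geometry.

All format dialects are isolated here.  Internally everything lives in the
package axis convention (axis 0 vertical/anterior+, axis 1 lateral/left+,
axis 2 longitudinal/superior+, mm, isocenter at a fixed vertical
coordinate); readers convert into it and writers out of it.

DICOM specifics
---------------
Axial slices are written as CT Image Storage objects in the patient LPS
frame (HFS): columns run along +x (patient left), rows along +y (posterior),
slices along +z (superior).  Intensities are stored as 16-bit integers with
``RescaleSlope = 1/4096`` — the synthetic intensity ladder — which makes the
write/read round trip bit-exact in float32.  The gantry isocenter's vertical
position is carried in Table Height (0018,1130) as the isocenter's y
coordinate in the LPS frame (a documented assumption: the tag a given vendor
uses for this is not standardized).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import Grid3D, Localizer2D, Volume3D

__all__ = [
    "write_axial_series",
    "read_axial_series",
    "write_localizer",
    "read_localizer",
    "write_volume_nifti",
    "read_volume_nifti",
]

_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
_SCALE = np.float32(4096.0)
_SLOPE_DS = "0.000244140625"  # exactly 1/4096


def _stored(values: np.ndarray) -> np.ndarray:
    ints = np.round(np.asarray(values, dtype=np.float64) * 4096.0)
    if ints.min() < 0 or ints.max() > 65535:
        raise ValueError("intensities outside the storable [0, 16] range")
    return ints.astype(np.uint16)


def _base_dataset(sop_instance_uid: str) -> pydicom.FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _CT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = sop_instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _CT_SOP_CLASS
    ds.SOPInstanceUID = sop_instance_uid
    ds.Modality = "CT"
    ds.PatientName = "synthetic^phantom"
    ds.PatientID = "SYN"
    ds.PatientPosition = "HFS"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = _SLOPE_DS
    ds.RescaleIntercept = "0"
    return ds


# ---------------------------------------------------------------------------
# Axial series


def write_axial_series(volume: Volume3D, directory, source_id: str = "C1") -> List[Path]:
    """Write one file per axial slice; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = volume.grid
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    n0, n1, n2 = g.shape
    y_top = g.coords(0)[-1]  # most anterior voxel center
    iso_lps_y = -g.isocenter_y
    paths = []
    for k in range(n2):
        sl = volume.voxels[::-1, :, k].T.T  # flip axis0: rows run posteriorward
        ds = _base_dataset(generate_uid())
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.SeriesNumber = 2
        ds.InstanceNumber = k + 1
        ds.StationName = source_id
        ds.SeriesDescription = "synthetic axial"
        ds.Rows, ds.Columns = n0, n1
        ds.PixelSpacing = [f"{g.spacing[0]:.6f}", f"{g.spacing[1]:.6f}"]
        ds.SliceThickness = f"{g.spacing[2]:.6f}"
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        z = g.coords(2)[k]
        ds.ImagePositionPatient = [f"{g.origin[1]:.6f}", f"{-y_top:.6f}",
                                   f"{z:.6f}"]
        ds.SliceLocation = f"{z:.6f}"
        ds.TableHeight = f"{iso_lps_y:.6f}"
        if volume.table_height is not None:
            ds.add_new(0x00181152, "DS", "0")  # exposure placeholder
        ds.PixelData = _stored(sl).tobytes()
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_axial_series(directory) -> Volume3D:
    """Read a directory of single-frame axial slices into a Volume3D.

    Slices are sorted by longitudinal position regardless of on-disk order;
    mixed series, missing spacing, and non-uniform slice gaps are rejected
    with the offending attribute named.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM slices found in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    uids = {s.SeriesInstanceUID for s in slices}
    if len(uids) != 1:
        raise ValueError("mixed SeriesInstanceUID in directory")
    for s in slices:
        if "PixelSpacing" not in s:
            raise ValueError("missing PixelSpacing")
        if "ImagePositionPatient" not in s:
            raise ValueError("missing ImagePositionPatient")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        gaps = np.diff(zs)
        if gaps.min() <= 0:
            raise ValueError("duplicate or non-increasing ImagePositionPatient")
        if np.ptp(gaps) > 1e-3 * gaps.mean() + 1e-6:
            raise ValueError("non-uniform slice spacing (ImagePositionPatient)")
        dz = float(gaps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    s0 = slices[0]
    rows, cols = int(s0.Rows), int(s0.Columns)
    sp_row, sp_col = (float(v) for v in s0.PixelSpacing)
    slope = float(getattr(s0, "RescaleSlope", 1.0))
    intercept = float(getattr(s0, "RescaleIntercept", 0.0))

    vox = np.empty((rows, cols, len(slices)), dtype=np.float32)
    for k, s in enumerate(slices):
        arr = s.pixel_array.astype(np.float32)
        arr = arr * np.float32(slope) + np.float32(intercept)
        vox[:, :, k] = arr[::-1, :]  # back to anterior-positive axis 0

    ipp = [float(v) for v in s0.ImagePositionPatient]
    origin0 = -ipp[1] - (rows - 1) * sp_row
    origin = (origin0, ipp[0], ipp[2])
    iso_y = -float(getattr(s0, "TableHeight", 0.0))
    grid = Grid3D(shape=(rows, cols, len(slices)),
                  spacing=(sp_row, sp_col, dz),
                  origin=origin, isocenter_y=iso_y)
    return Volume3D(voxels=vox, grid=grid,
                    table_height=None,
                    source_id=str(getattr(s0, "StationName", "")) or None)


# ---------------------------------------------------------------------------
# Localizer (scout)


def write_localizer(localizer: Localizer2D, path, source_id: str = "C1") -> Path:
    """Write the AP scout as a single DICOM image (rows = Z, columns =
    lateral; geometry in PixelSpacing/ImagePositionPatient)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds = _base_dataset(generate_uid())
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesNumber = 1
    ds.InstanceNumber = 1
    ds.ImageType = ["DERIVED", "SECONDARY", "LOCALIZER"]
    ds.StationName = source_id or (localizer.source_id or "C1")
    nz, nx = localizer.pixels.shape
    ds.Rows, ds.Columns = nz, nx
    ds.PixelSpacing = [f"{localizer.pixel_spacing[0]:.6f}",
                       f"{localizer.pixel_spacing[1]:.6f}"]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "0", "1"]
    ds.ImagePositionPatient = [f"{localizer.position[1]:.6f}", "0",
                               f"{localizer.position[0]:.6f}"]
    ds.PixelData = _stored(localizer.pixels).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_localizer(path) -> Localizer2D:
    """Read a single 2D scout written by :func:`write_localizer`."""
    ds = pydicom.dcmread(path)
    if "PixelSpacing" not in ds:
        raise ValueError("missing PixelSpacing")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pix = ds.pixel_array.astype(np.float32) * np.float32(slope) + np.float32(intercept)
    ipp = [float(v) for v in getattr(ds, "ImagePositionPatient", [0, 0, 0])]
    return Localizer2D(
        pixels=pix,
        pixel_spacing=tuple(float(v) for v in ds.PixelSpacing),
        position=(ipp[2], ipp[0]),
        source_id=str(getattr(ds, "StationName", "")) or None,
    )


# ---------------------------------------------------------------------------
# NIfTI (with a JSON sidecar carrying the scanner-frame geometry)


def _nifti_affine(grid: Grid3D) -> np.ndarray:
    """RAS+ affine for our (AP+, left+, superior+) axis order."""
    s0, s1, s2 = grid.spacing
    o0, o1, o2 = grid.origin
    aff = np.zeros((4, 4))
    aff[0, 1] = -s1  # lateral left+ -> RAS x is right+
    aff[1, 0] = s0   # vertical anterior+ -> RAS y
    aff[2, 2] = s2   # superior+ -> RAS z
    aff[:3, 3] = (-o1, o0, o2)
    aff[3, 3] = 1.0
    return aff


def write_volume_nifti(volume: Volume3D, path) -> Path:
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.voxels.astype(np.float32),
                          _nifti_affine(volume.grid))
    nib.save(img, path)
    sidecar = {
        "shape": list(volume.grid.shape),
        "spacing": list(volume.grid.spacing),
        "origin": list(volume.grid.origin),
        "isocenter_y": volume.grid.isocenter_y,
        "table_height": volume.table_height,
        "orientation_tag": volume.orientation_tag,
        "source_id": volume.source_id,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def read_volume_nifti(path) -> Volume3D:
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    grid = Grid3D(shape=tuple(meta["shape"]), spacing=tuple(meta["spacing"]),
                  origin=tuple(meta["origin"]),
                  isocenter_y=float(meta["isocenter_y"]))
    return Volume3D(voxels=np.asarray(img.dataobj, dtype=np.float32),
                    grid=grid, table_height=meta.get("table_height"),
                    orientation_tag=meta.get("orientation_tag", "axial"),
                    source_id=meta.get("source_id"))
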