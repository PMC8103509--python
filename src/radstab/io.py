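"""Readers and writers for the formats the pipeline touches.

Volumes travel as NIfTI (read/write) or DICOM series (read-only, HU via
rescale slope/intercept); feature tables and reports are CSV. NIfTI I/O
goes through nibabel, DICOM through pydicom.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import FeatureTable, ImageVolume, RoiMask, ScanMeta

__all__ = [
    "FormatError",
    "MetadataError",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "write_feature_table",
    "read_feature_table",
    "write_provenance",
]


class FormatError(ValueError):
    """Unreadable or ambiguous image input."""


class MetadataError(ValueError):
    """Inconsistent geometry metadata (e.g. irregular slice spacing)."""


# --------------------------------------------------------------------------
# volumes


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI; spacing/origin go into the affine."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float64), affine)
    nib.save(img, str(path))


def write_mask(mask: RoiMask, vol: ImageVolume, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(mask.labels.astype(np.int16), affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> RoiMask:
    import nibabel as nib

    img = nib.load(str(path))
    return RoiMask(labels=np.asanyarray(img.dataobj).astype(np.int16))


def read_volume(path: str | Path, scan_id: str | None = None) -> tuple[ImageVolume, ScanMeta]:
    """Read a NIfTI file or a directory holding one DICOM series.

    DICOM pixel values are converted to HU with RescaleSlope/Intercept and
    slices are ordered by position along the slice normal. A directory with
    more than one series, or inter-slice spacing irregular beyond 1e-3 mm,
    is rejected.
    """
    p = Path(path)
    if p.is_dir():
        return _read_dicom_series(p, scan_id)
    if "".join(p.suffixes) in (".nii", ".nii.gz") or p.suffix == ".nii":
        return _read_nifti(p, scan_id)
    raise FormatError(f"not a NIfTI file or DICOM directory: {path}")


def _read_nifti(path: Path, scan_id: str | None) -> tuple[ImageVolume, ScanMeta]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    vol = ImageVolume(voxels=data, spacing=tuple(float(z) for z in zooms), origin=origin)
    meta = ScanMeta(
        scan_id=scan_id or path.name.split(".")[0],
        scanner_model="unknown",
        in_plane_spacing_mm=float(zooms[0]),
        slice_thickness_mm=float(zooms[2]),
    )
    return vol, meta


def _read_dicom_series(directory: Path, scan_id: str | None) -> tuple[ImageVolume, ScanMeta]:
    import pydicom

    files = sorted(f for f in directory.iterdir() if f.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM images found in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", "?") for ds in slices}
    if len(uids) > 1:
        raise MetadataError(f"directory contains {len(uids)} series; expected one")

    def z_of(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=z_of)
    zs = np.array([z_of(ds) for ds in slices], dtype=float)
    if len(zs) > 1:
        steps = np.diff(zs)
        if np.ptp(steps) > 1e-3:
            raise MetadataError("inconsistent inter-slice spacing (> 1e-3 mm)")
        dz = float(np.mean(steps))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    ds0 = slices[0]
    dy, dx = (float(v) for v in ds0.PixelSpacing)  # (row, col) spacing
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # DICOM planes are (row=y, col=x); our convention is (x, y, z)
    vox = np.stack(planes, axis=-1).transpose(1, 0, 2)
    pos = getattr(ds0, "ImagePositionPatient", (0.0, 0.0, zs[0]))
    vol = ImageVolume(
        voxels=vox, spacing=(dx, dy, abs(dz)), origin=tuple(float(v) for v in pos)
    )
    meta = ScanMeta(
        scan_id=scan_id or str(getattr(ds0, "SeriesDescription", directory.name)),
        scanner_model=str(getattr(ds0, "ManufacturerModelName", "unknown")),
        in_plane_spacing_mm=dx,
        slice_thickness_mm=float(getattr(ds0, "SliceThickness", abs(dz))),
    )
    return vol, meta


# --------------------------------------------------------------------------
# feature tables


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """CSV with header scan_id, roi_label, batch, then the 91 catalog columns.

    Floats are written with repr precision, so a write/read round-trip is
    lossless to >= 15 significant digits.
    """
    df = table.to_dataframe()
    df.to_csv(str(path), index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    import pandas as pd

    df = pd.read_csv(str(path), float_precision="round_trip")
    return FeatureTable.from_dataframe(df)


def write_provenance(path: str | Path, **info) -> None:
    """JSON sidecar recording seeds and parameters of a run."""
    Path(path).write_text(json.dumps(info, indent=2, sort_keys=True, default=str))
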