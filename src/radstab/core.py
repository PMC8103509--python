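"""Core domain types shared by every pipeline stage.

The package works in Hounsfield units (HU) throughout, stored as float64.
Geometry follows one convention everywhere: arrays are indexed (x, y, z),
``spacing`` is (dx, dy, dz) in mm, and the world position of voxel
(i, j, k) is ``origin + (i*dx, j*dy, k*dz)`` (voxel-center convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ImageVolume",
    "RoiMask",
    "ScanMeta",
    "FeatureVector",
    "FeatureTable",
]


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D grid of HU intensities with physical spacing and origin.

    Parameters
    ----------
    voxels
        3-D float array of HU values, axis order (x, y, z).
    spacing
        (dx, dy, dz) voxel spacing in mm; all components > 0.
    origin
        World coordinates (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        object.__setattr__(self, "voxels", vox)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError("voxels must be a 3-D array with each axis length >= 1")
        if not np.all(np.isfinite(vox)):
            raise ValueError("voxels must be finite (no NaN/Inf)")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing must be three positive components")
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent covered by the voxel footprints, per axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass(frozen=True)
class RoiMask:
    """Integer label volume aligned to an :class:`ImageVolume` grid.

    Label 0 is background; labels 1..10 index the phantom layers.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int16)
        if lab.min() < 0:
            raise ValueError("labels must be >= 0")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def present_labels(self) -> list[int]:
        """Sorted nonzero labels present in the mask."""
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]

    def roi_indices(self, label: int) -> tuple[np.ndarray, ...]:
        return np.nonzero(self.labels == label)


@dataclass(frozen=True)
class ScanMeta:
    """Acquisition metadata for one scan of the phantom."""

    scan_id: str
    scanner_model: str
    in_plane_spacing_mm: float
    slice_thickness_mm: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.in_plane_spacing_mm <= 2):
            raise ValueError("in_plane_spacing_mm must be in (0, 2]")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be > 0")


@dataclass(frozen=True)
class FeatureVector:
    """The 91 handcrafted radiomic features of one (scan, ROI) pair."""

    scan_id: str
    roi_label: int
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        from .features.catalog import FEATURE_NAMES

        if list(self.values.keys()) != FEATURE_NAMES:
            raise ValueError(
                "feature vector keys must equal the 91-entry catalog in canonical order"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad[:5]}")


@dataclass
class FeatureTable:
    """Rectangular table of feature vectors with per-row batch labels.

    One row per (scan, ROI); the batch of a row defaults to its scan_id —
    ComBat treats each scan as a batch.
    """

    rows: list[FeatureVector] = field(default_factory=list)
    batch_of_row: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.batch_of_row:
            self.batch_of_row = [r.scan_id for r in self.rows]
        if len(self.batch_of_row) != len(self.rows):
            raise ValueError("every row needs a batch label")

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self):
        """Long layout: scan_id, roi_label, batch, then the 91 feature columns."""
        import pandas as pd

        from .features.catalog import FEATURE_NAMES

        rec = []
        for row, batch in zip(self.rows, self.batch_of_row):
            d = {"scan_id": row.scan_id, "roi_label": row.roi_label, "batch": batch}
            d.update({k: row.values[k] for k in FEATURE_NAMES})
            rec.append(d)
        cols = ["scan_id", "roi_label", "batch"] + FEATURE_NAMES
        return pd.DataFrame(rec, columns=cols)

    @classmethod
    def from_dataframe(cls, df) -> "FeatureTable":
        from .features.catalog import FEATURE_NAMES

        missing = [c for c in ("scan_id", "roi_label", "batch") if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        missing_f = [c for c in FEATURE_NAMES if c not in df.columns]
        if missing_f:
            raise ValueError(f"missing feature columns: {missing_f[:5]}")
        rows, batches = [], []
        for _, r in df.iterrows():
            rows.append(
                FeatureVector(
                    scan_id=str(r["scan_id"]),
                    roi_label=int(r["roi_label"]),
                    values={k: float(r[k]) for k in FEATURE_NAMES},
                )
            )
            batches.append(str(r["batch"]))
        return cls(rows=rows, batch_of_row=batches)
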