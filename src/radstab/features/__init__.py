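"""Handcrafted radiomic feature extraction (91 non-shape features).

Intensities are discretized with a fixed 25 HU bin width anchored at the
ROI minimum; no resegmentation, outlier clipping or image filtering is
applied. ``extract_all`` is the single entry point used by the pipeline.
"""

from __future__ import annotations

import numpy as np

from ..core import FeatureVector, ImageVolume, RoiMask
from .catalog import FAMILIES, FEATURE_NAMES, catalog_rows
from .firstorder import first_order_features
from .matrices import (
    DiscretizedRoi,
    build_glcm,
    build_gldm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    discretize,
    roi_level_array,
)
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "FEATURE_NAMES",
    "FAMILIES",
    "catalog_rows",
    "DiscretizedRoi",
    "discretize",
    "extract_all",
    "extract_table",
]

DEFAULT_BIN_WIDTH = 25.0


def extract_all(
    vol: ImageVolume,
    mask: RoiMask,
    roi_label: int,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> FeatureVector:
    """Extract the full 91-feature catalog for one ROI of a volume."""
    roi = mask.labels == roi_label
    if not roi.any():
        raise ValueError(f"ROI label {roi_label} is empty")
    if mask.shape != vol.shape:
        raise ValueError("mask and volume grids differ")

    lev, valid, disc = roi_level_array(vol.voxels, roi, bin_width)
    ng = disc.n_levels
    n_vox = int(valid.sum())
    voxel_volume = float(np.prod(vol.spacing))

    values: dict[str, float] = {}
    fo = first_order_features(disc.values, disc, voxel_volume)
    values.update({f"firstorder_{k}": fo[k] for k in FAMILIES["firstorder"]})

    g = glcm_features(build_glcm(lev, valid, ng))
    values.update({f"glcm_{k}": g[k] for k in FAMILIES["glcm"]})

    r = glrlm_features(build_glrlm(lev, valid, ng), n_vox)
    values.update({f"glrlm_{k}": r[k] for k in FAMILIES["glrlm"]})

    z = glszm_features(build_glszm(lev, valid, ng), n_vox)
    values.update({f"glszm_{k}": z[k] for k in FAMILIES["glszm"]})

    d = gldm_features(build_gldm(lev, valid, ng))
    values.update({f"gldm_{k}": d[k] for k in FAMILIES["gldm"]})

    n_i, s_i = build_ngtdm(lev, valid, ng)
    t = ngtdm_features(n_i, s_i)
    values.update({f"ngtdm_{k}": t[k] for k in FAMILIES["ngtdm"]})

    ordered = {name: float(values[name]) for name in FEATURE_NAMES}
    return FeatureVector(scan_id="", roi_label=int(roi_label), values=ordered)


def extract_table(scans, bin_width: float = DEFAULT_BIN_WIDTH):
    """Extract every ROI of every (volume, mask, meta) triple into a table."""
    from ..core import FeatureTable

    rows, batches = [], []
    for vol, mask, meta in scans:
        for label in mask.present_labels():
            fv = extract_all(vol, mask, label, bin_width)
            rows.append(
                FeatureVector(scan_id=meta.scan_id, roi_label=label, values=fv.values)
            )
            batches.append(meta.scan_id)
    return FeatureTable(rows=rows, batch_of_row=batches)
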