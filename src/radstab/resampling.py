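"""Resampling volumes and masks to a new unified in-plane resolution (NUIR).

Only the in-plane axes (x, y) are resampled; the through-plane axis is
left untouched since slice thickness is held fixed in this design. Ten
interpolation methods are supported: NN, Linear, BSpline, Gaussian,
LabelGaussian (mask-only) and five windowed sincs (Hamming, Cosine,
Welch, Lanczos, Blackman), named exactly {NN, Linear, BSpline, Gaussian,
LabelGaussian, HWS, CWS, WWS, LWS, BWS}.

Kernels are evaluated separably in source-pixel units with window radius
m = 3 for the sinc family; per-output-sample weights are normalized to
sum to one (guaranteeing DC preservation, also near edges where the
window is truncated) and out-of-support taps are clamped to the edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, RoiMask

__all__ = [
    "SINC_METHODS",
    "VOLUME_METHODS",
    "MASK_METHODS",
    "ALL_METHODS",
    "ResampleGrid",
    "kernel_weight",
    "target_grid",
    "resample_volume",
    "resample_mask",
]

SINC_METHODS = ("HWS", "CWS", "WWS", "LWS", "BWS")
VOLUME_METHODS = ("NN", "Linear", "BSpline", "Gaussian") + SINC_METHODS
MASK_METHODS = ("NN", "LabelGaussian")
ALL_METHODS = VOLUME_METHODS + ("LabelGaussian",)

#: window radius of the sinc family, in source pixels (the cited
#: toolkit's windowed-sinc interpolators use this radius)
SINC_RADIUS = 5
#: interpolating B-spline order
BSPLINE_ORDER = 3
#: Gaussian interpolator: sigma = this factor x output spacing, support 3 sigma
GAUSSIAN_SIGMA_FACTOR = 0.8


@dataclass(frozen=True)
class ResampleGrid:
    """Output grid of an in-plane resample: spacing, shape, origin."""

    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    origin: tuple[float, float, float]


def _sinc(x: np.ndarray) -> np.ndarray:
    return np.sinc(x)  # sin(pi x)/(pi x), sinc(0)=1


_WINDOWS = {
    "HWS": lambda x, m: 0.54 + 0.46 * np.cos(np.pi * x / m),
    "CWS": lambda x, m: np.cos(np.pi * x / (2 * m)),
    "WWS": lambda x, m: 1.0 - (x / m) ** 2,
    "LWS": lambda x, m: _sinc(x / m),
    "BWS": lambda x, m: 0.42
    + 0.5 * np.cos(np.pi * x / m)
    + 0.08 * np.cos(2 * np.pi * x / m),
}


def kernel_weight(method: str, x, m: int = SINC_RADIUS):
    """Windowed-sinc kernel value w(x)·sinc(x) at source-pixel offset x.

    Zero outside |x| <= m. Only defined for the sinc family.
    """
    if method not in SINC_METHODS:
        raise ValueError(f"{method!r} is not a windowed-sinc method")
    x = np.asarray(x, dtype=np.float64)
    inside = np.abs(x) <= m
    k = np.where(inside, _WINDOWS[method](np.where(inside, x, 0.0), m) * _sinc(x), 0.0)
    return k if k.ndim else float(k)


def target_grid(vol: ImageVolume, nuir_mm: float) -> ResampleGrid:
    """In-plane output grid: n_out = round(n_in * d_in / nuir), minimum 1."""
    if nuir_mm <= 0:
        raise ValueError("nuir_mm must be > 0")
    nx, ny, nz = vol.shape
    dx, dy, dz = vol.spacing
    nx_out = max(1, round(nx * dx / nuir_mm))
    ny_out = max(1, round(ny * dy / nuir_mm))
    return ResampleGrid(
        spacing=(nuir_mm, nuir_mm, dz),
        shape=(nx_out, ny_out, nz),
        origin=vol.origin,
    )


def _axis_weights(
    n_in: int, d_in: float, n_out: int, d_out: float, method: str, normalize: bool
) -> np.ndarray:
    """Dense (n_out, n_in) weight matrix for one axis, edge-clamped."""
    W = np.zeros((n_out, n_in), dtype=np.float64)
    s = np.arange(n_out) * (d_out / d_in)  # output centers in source-index units
    if method == "NN":
        idx = np.clip(np.floor(s + 0.5).astype(np.int64), 0, n_in - 1)
        W[np.arange(n_out), idx] = 1.0
        return W
    if method == "Linear":
        radius = 1.0
        kernel = lambda u: np.maximum(0.0, 1.0 - np.abs(u))
    elif method == "Gaussian":
        sigma = GAUSSIAN_SIGMA_FACTOR * d_out / d_in  # in source pixels
        radius = max(1.0, 3.0 * sigma)
        kernel = lambda u: np.exp(-0.5 * (u / sigma) ** 2)
    elif method in SINC_METHODS:
        radius = float(SINC_RADIUS)
        kernel = lambda u: kernel_weight(method, u)
    else:
        raise ValueError(f"unsupported kernel method {method!r}")
    for i in range(n_out):
        lo = int(np.ceil(s[i] - radius))
        hi = int(np.floor(s[i] + radius))
        taps = np.arange(lo, hi + 1)
        w = kernel(s[i] - taps)
        taps = np.clip(taps, 0, n_in - 1)  # clamp-to-edge boundary
        np.add.at(W[i], taps, w)
        if normalize:
            tot = W[i].sum()
            if tot != 0:
                W[i] /= tot
    return W


def _resample_bspline(vox: np.ndarray, vol: ImageVolume, grid: ResampleGrid) -> np.ndarray:
    from scipy import ndimage

    nx_out, ny_out, nz = grid.shape
    sx = np.arange(nx_out) * grid.spacing[0] / vol.spacing[0]
    sy = np.arange(ny_out) * grid.spacing[1] / vol.spacing[1]
    sz = np.arange(nz, dtype=np.float64)
    cx, cy, cz = np.meshgrid(sx, sy, sz, indexing="ij")
    return ndimage.map_coordinates(
        vox, [cx, cy, cz], order=BSPLINE_ORDER, mode="nearest"
    )


def resample_volume(
    vol: ImageVolume, nuir_mm: float, method: str, *, normalize: bool = True
) -> ImageVolume:
    """Resample the in-plane axes of a volume to ``nuir_mm``.

    ``normalize=False`` skips per-sample kernel normalization (the raw
    toolkit convention); the default preserves constants to ~1e-15.
    """
    if method == "LabelGaussian":
        raise ValueError("LabelGaussian is a mask-only interpolator")
    if method not in VOLUME_METHODS:
        raise ValueError(f"unknown interpolation method {method!r}")
    grid = target_grid(vol, nuir_mm)
    if method == "BSpline":
        out = _resample_bspline(vol.voxels, vol, grid)
    else:
        Wx = _axis_weights(
            vol.shape[0], vol.spacing[0], grid.shape[0], nuir_mm, method, normalize
        )
        Wy = _axis_weights(
            vol.shape[1], vol.spacing[1], grid.shape[1], nuir_mm, method, normalize
        )
        out = np.einsum("ia,ab...->ib...", Wx, vol.voxels)
        out = np.einsum("jb,ib...->ij...", Wy, out)
    return ImageVolume(voxels=out, spacing=grid.spacing, origin=grid.origin)


def resample_mask(mask: RoiMask, vol: ImageVolume, nuir_mm: float, method: str = "NN") -> RoiMask:
    """Resample a label mask; only label-preserving interpolators allowed.

    NN picks the nearest source label. LabelGaussian resamples each
    label's indicator with the Gaussian kernel and takes the argmax, so
    no label absent from the input can appear in the output.
    """
    if method not in MASK_METHODS:
        raise ValueError(f"{method!r} cannot be used for label masks")
    if mask.shape != vol.shape:
        raise ValueError("mask and volume grids differ")
    grid = target_grid(vol, nuir_mm)
    kernel = "NN" if method == "NN" else "Gaussian"
    Wx = _axis_weights(
        vol.shape[0], vol.spacing[0], grid.shape[0], nuir_mm, kernel, True
    )
    Wy = _axis_weights(
        vol.shape[1], vol.spacing[1], grid.shape[1], nuir_mm, kernel, True
    )
    if method == "NN":
        ix = Wx.argmax(axis=1)
        iy = Wy.argmax(axis=1)
        out = mask.labels[np.ix_(ix, iy, range(mask.shape[2]))]
        return RoiMask(labels=out)
    labels = [0] + mask.present_labels()
    scores = np.empty((len(labels),) + grid.shape, dtype=np.float64)
    for n, lab in enumerate(labels):
        ind = (mask.labels == lab).astype(np.float64)
        t = np.einsum("ia,ab...->ib...", Wx, ind)
        scores[n] = np.einsum("jb,ib...->ij...", Wy, t)
    out = np.asarray(labels, dtype=np.int16)[scores.argmax(axis=0)]
    return RoiMask(labels=out)
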