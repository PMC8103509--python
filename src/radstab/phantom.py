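"""Digital stand-in for a 10-layer CT texture phantom.

One continuous "scene" — ten stacked texture slabs on a fine master grid,
surrounded by air (-1000 HU) — is rendered once and then virtually
acquired any number of times: in-plane Gaussian PSF blur, box-averaging
over each output voxel's physical footprint, and additive Gaussian noise
whose standard deviation grows as pixels shrink (small pixels integrate
fewer photons). Two virtual scanner models differ in PSF width and noise
level. The default acquisition protocol is seven in-plane spacings
(0.39-0.98 mm) at a fixed 1.25 mm slice thickness on each of the two
models: 14 scans of the same object.

The master grid is 0.1 mm in-plane. Through-plane it is 0.3125 mm: the
z axis is never resampled and layer thickness is an exact multiple of
the slice thickness, so slices tile layers exactly and a finer z grid
would add nothing but memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import ImageVolume, RoiMask, ScanMeta

__all__ = [
    "TABLE_SPACINGS_MM",
    "SLICE_THICKNESS_MM",
    "TextureLayerSpec",
    "ScannerProfile",
    "PhantomSpec",
    "default_layers",
    "default_profiles",
    "default_spec",
    "small_spec",
    "render_scene",
    "acquire_scan",
    "make_dataset",
]

#: the seven in-plane pixel spacings of the acquisition protocol (mm)
TABLE_SPACINGS_MM = (0.39, 0.49, 0.59, 0.68, 0.78, 0.88, 0.98)
SLICE_THICKNESS_MM = 1.25

HU_AIR = -1000.0
HU_MIN, HU_MAX = -1000.0, 800.0

TEXTURE_KINDS = (
    "uniform-noise",
    "checkerboard",
    "blob-cluster",
    "gradient",
    "ridged",
    "speckle",
    "coarse-cork",
    "fine-cork",
    "honeycomb",
    "lattice",
)


@dataclass(frozen=True)
class TextureLayerSpec:
    layer_index: int
    base_hu: float
    amplitude_hu: float
    texture_kind: str
    correlation_length_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.texture_kind not in TEXTURE_KINDS:
            raise ValueError(f"unknown texture kind {self.texture_kind!r}")
        if not 1 <= self.layer_index <= 10:
            raise ValueError("layer_index must be 1..10")


@dataclass(frozen=True)
class ScannerProfile:
    """Virtual scanner: in-plane PSF blur plus a noise model.

    Noise sd (HU) at in-plane spacing d is ``noise_sd_hu + noise_sd_slope/d``,
    so finer pixels are noisier.
    """

    model_name: str
    psf_fwhm_mm: float
    noise_sd_hu: float
    noise_sd_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0 or self.noise_sd_hu < 0:
            raise ValueError("psf_fwhm_mm and noise_sd_hu must be >= 0")

    def noise_sd(self, in_plane_spacing_mm: float) -> float:
        return self.noise_sd_hu + self.noise_sd_slope / in_plane_spacing_mm


@dataclass(frozen=True)
class PhantomSpec:
    layers: tuple[TextureLayerSpec, ...]
    scene_spacing_mm: float = 0.1
    scene_z_spacing_mm: float = 0.3125
    layer_extent_mm: tuple[float, float, float] = (32.0, 32.0, 3.75)
    air_margin_mm: float = 2.0
    roi_margin_mm: float = 2.0
    master_seed: int = 20210413

    def __post_init__(self) -> None:
        if len(self.layers) != 10:
            raise ValueError("a phantom has exactly 10 layers")


def default_layers() -> tuple[TextureLayerSpec, ...]:
    """Ten layers spanning roughly -900 to +700 HU with fine-to-coarse
    spatial-frequency content (cork-like correlated noise, periodic cell
    patterns, gradients, speckle)."""
    cfg = [
        (-900, 80, "fine-cork", 0.3),
        (-700, 100, "coarse-cork", 1.5),
        (-450, 120, "uniform-noise", 0.1),
        (-250, 100, "blob-cluster", 1.2),
        (-100, 90, "speckle", 0.2),
        (0, 60, "gradient", 1.0),
        (150, 100, "checkerboard", 1.0),
        (300, 110, "ridged", 0.8),
        (500, 120, "honeycomb", 1.2),
        (700, 80, "lattice", 1.0),
    ]
    return tuple(
        TextureLayerSpec(i + 1, b, a, k, c) for i, (b, a, k, c) in enumerate(cfg)
    )


def default_profiles() -> tuple[ScannerProfile, ScannerProfile]:
    """Stand-ins for the two GE models: they differ in PSF width and noise."""
    return (
        ScannerProfile("Discovery-STE", psf_fwhm_mm=0.6, noise_sd_hu=5.0, noise_sd_slope=10.0),
        ScannerProfile("LightSpeed-Pro-32", psf_fwhm_mm=0.8, noise_sd_hu=8.0, noise_sd_slope=12.0),
    )


def default_spec(master_seed: int = 20210413) -> PhantomSpec:
    return PhantomSpec(layers=default_layers(), master_seed=master_seed)


def small_spec(master_seed: int = 20210413) -> PhantomSpec:
    """Reduced-extent phantom for desk-scale studies and tests."""
    return PhantomSpec(
        layers=default_layers(),
        layer_extent_mm=(20.0, 20.0, 2.5),
        roi_margin_mm=1.5,
        master_seed=master_seed,
    )


# ------------------------------------------------------------------ textures


def _smooth_noise(rng, shape, sigma_px) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_px)
    sd = f.std()
    return f / sd if sd > 0 else f


def _render_layer(
    spec: TextureLayerSpec, shape, dx: float, dz: float, rng
) -> np.ndarray:
    nx, ny, nzl = shape
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dx
    z = (np.arange(nzl) + 0.5) * dz
    X, Y = np.meshgrid(x, y, indexing="ij")
    lam = spec.correlation_length_mm
    b, a = spec.base_hu, spec.amplitude_hu
    kind = spec.texture_kind

    if kind == "uniform-noise":
        v = b + a * rng.uniform(-1, 1, size=shape)
    elif kind == "checkerboard":
        par = (
            np.floor(X / lam)[:, :, None]
            + np.floor(Y / lam)[:, :, None]
            + np.floor(z / lam)[None, None, :]
        )
        v = b + a * np.where(par % 2 == 0, 1.0, -1.0)
    elif kind == "blob-cluster":
        f = _smooth_noise(rng, shape, (lam / dx, lam / dx, lam / dz))
        v = b + a * np.tanh(1.5 * f)
    elif kind == "gradient":
        ramp = 2.0 * X / x[-1] - 1.0
        v = b + a * ramp[:, :, None] + 0.05 * a * rng.standard_normal(shape)
    elif kind == "ridged":
        t = X / lam
        tri = 2.0 * np.abs(2.0 * (t - np.floor(t + 0.5))) - 1.0
        v = b + a * tri[:, :, None] * np.ones((1, 1, nzl))
    elif kind == "speckle":
        f = _smooth_noise(rng, shape, (lam / dx, lam / dx, lam / dz))
        v = b + a * np.clip(f, -2.5, 2.5) / 2.5
    elif kind in ("coarse-cork", "fine-cork"):
        f = _smooth_noise(rng, shape, (lam / dx, lam / dx, lam / dz))
        v = b + a * np.clip(f, -2.5, 2.5) / 2.5
    elif kind == "honeycomb":
        k = 2 * np.pi / lam
        f = (
            np.cos(k * X)
            + np.cos(k * (X / 2 + Y * np.sqrt(3) / 2))
            + np.cos(k * (X / 2 - Y * np.sqrt(3) / 2))
        )
        v = b + np.where(f < 0.0, a, -0.4 * a)[:, :, None] * np.ones((1, 1, nzl))
    elif kind == "lattice":
        fx = X / lam - np.floor(X / lam)
        fy = Y / lam - np.floor(Y / lam)
        wall = (fx < 0.3) | (fy < 0.3)
        v = b + np.where(wall, a, -0.5 * a)[:, :, None] * np.ones((1, 1, nzl))
    else:  # pragma: no cover
        raise ValueError(kind)
    return np.clip(v, HU_MIN, HU_MAX)


def render_scene(spec: PhantomSpec) -> tuple[ImageVolume, RoiMask]:
    """Render the fixed master-grid scene and its layer ROI mask.

    Deterministic given ``spec.master_seed``; each layer draws from its
    own child stream so layers are independent of one another.
    """
    dx, dz = spec.scene_spacing_mm, spec.scene_z_spacing_mm
    wx, wy, wz = spec.layer_extent_mm
    m = spec.air_margin_mm
    nx = round((wx + 2 * m) / dx)
    ny = round((wy + 2 * m) / dx)
    nzl = round(wz / dz)
    nz = 10 * nzl

    vox = np.full((nx, ny, nz), HU_AIR, dtype=np.float64)
    labels = np.zeros((nx, ny, nz), dtype=np.int16)

    ix0, ix1 = round(m / dx), round((m + wx) / dx)
    iy0, iy1 = round(m / dx), round((m + wy) / dx)
    rx0, rx1 = round((m + spec.roi_margin_mm) / dx), round((m + wx - spec.roi_margin_mm) / dx)
    ry0, ry1 = round((m + spec.roi_margin_mm) / dx), round((m + wy - spec.roi_margin_mm) / dx)

    ss = np.random.SeedSequence(spec.master_seed)
    children = ss.spawn(10)
    for layer, child in zip(spec.layers, children):
        rng = np.random.default_rng(child)
        iz0 = (layer.layer_index - 1) * nzl
        block = _render_layer(layer, (ix1 - ix0, iy1 - iy0, nzl), dx, dz, rng)
        vox[ix0:ix1, iy0:iy1, iz0 : iz0 + nzl] = block
        labels[rx0:rx1, ry0:ry1, iz0 : iz0 + nzl] = layer.layer_index

    vol = ImageVolume(voxels=vox, spacing=(dx, dx, dz), origin=(dx / 2, dx / 2, dz / 2))
    return vol, RoiMask(labels=labels)


# --------------------------------------------------------------- acquisition


def _box_average_axis(arr: np.ndarray, h: float, d_out: float, n_out: int, axis: int) -> np.ndarray:
    """Exact mean of a piecewise-constant field over output cells of width
    ``d_out`` along one axis (edge-aligned grids), via a prefix integral."""
    arr = np.moveaxis(arr, axis, 0)
    n_in = arr.shape[0]
    cum = np.concatenate(
        [np.zeros((1,) + arr.shape[1:]), np.cumsum(arr, axis=0)], axis=0
    )

    def integral(t: np.ndarray) -> np.ndarray:
        t = np.clip(t, 0.0, float(n_in))
        k = np.minimum(np.floor(t).astype(np.int64), n_in - 1)
        frac = t - k
        return cum[k] + frac[(...,) + (None,) * (arr.ndim - 1)] * arr[k]

    edges = np.arange(n_out + 1) * (d_out / h)
    a, b = edges[:-1], np.minimum(edges[1:], n_in)
    width = (b - a)[(...,) + (None,) * (arr.ndim - 1)]
    out = (integral(b) - integral(a)) / width
    return np.moveaxis(out, 0, axis)


def _box_average(vox: np.ndarray, spacing, out_spacing, out_shape) -> np.ndarray:
    out = vox
    for ax in range(3):
        out = _box_average_axis(out, spacing[ax], out_spacing[ax], out_shape[ax], ax)
    return out


def _majority_mask(labels: np.ndarray, spacing, out_spacing, out_shape) -> np.ndarray:
    present = [0] + [int(v) for v in np.unique(labels) if v != 0]
    best_frac = np.full(out_shape, -1.0)
    best_lab = np.zeros(out_shape, dtype=np.int16)
    for lab in present:
        frac = _box_average(
            (labels == lab).astype(np.float64), spacing, out_spacing, out_shape
        )
        take = frac > best_frac
        best_frac[take] = frac[take]
        best_lab[take] = lab
    return best_lab


def _blur_in_plane(vox: np.ndarray, psf_fwhm_mm: float, dx: float) -> np.ndarray:
    if psf_fwhm_mm == 0:
        return vox
    sigma_px = psf_fwhm_mm / 2.3548200450309493 / dx
    return ndimage.gaussian_filter(vox, sigma=(sigma_px, sigma_px, 0.0))


def acquire_scan(
    scene: ImageVolume,
    scene_mask: RoiMask,
    profile: ScannerProfile,
    in_plane_spacing_mm: float,
    slice_thickness_mm: float = SLICE_THICKNESS_MM,
    seed: int = 0,
    scan_id: str | None = None,
    _pre_blurred: np.ndarray | None = None,
) -> tuple[ImageVolume, RoiMask, ScanMeta]:
    """Virtually acquire the scene: PSF blur, box-average, additive noise.

    The mask is produced by majority vote of master-grid labels within
    each output voxel's footprint.
    """
    dx, _, dz = scene.spacing
    if in_plane_spacing_mm < 3 * dx:
        raise ValueError("acquisition spacing must be >= 3x the scene grid spacing")
    ext = scene.extent_mm()
    n_out = (
        round(ext[0] / in_plane_spacing_mm),
        round(ext[1] / in_plane_spacing_mm),
        round(ext[2] / slice_thickness_mm),
    )
    out_spacing = (in_plane_spacing_mm, in_plane_spacing_mm, slice_thickness_mm)

    blurred = (
        _pre_blurred
        if _pre_blurred is not None
        else _blur_in_plane(scene.voxels, profile.psf_fwhm_mm, dx)
    )
    img = _box_average(blurred, scene.spacing, out_spacing, n_out)
    rng = np.random.default_rng(seed)
    sd = profile.noise_sd(in_plane_spacing_mm)
    if sd > 0:
        img = img + rng.normal(0.0, sd, size=img.shape)

    mask = _majority_mask(scene_mask.labels, scene.spacing, out_spacing, n_out)
    vol = ImageVolume(
        voxels=img,
        spacing=out_spacing,
        origin=tuple(s / 2 for s in out_spacing),
    )
    meta = ScanMeta(
        scan_id=scan_id or f"{profile.model_name}_{in_plane_spacing_mm:.2f}mm",
        scanner_model=profile.model_name,
        in_plane_spacing_mm=in_plane_spacing_mm,
        slice_thickness_mm=slice_thickness_mm,
        seed=seed,
    )
    return vol, RoiMask(labels=mask), meta


def make_dataset(
    spec: PhantomSpec | None = None,
    profiles: tuple[ScannerProfile, ...] | None = None,
    spacings: tuple[float, ...] = TABLE_SPACINGS_MM,
    base_seed: int = 0,
) -> list[tuple[ImageVolume, RoiMask, ScanMeta]]:
    """The full study dataset: every profile at every spacing, all
    acquired from the SAME rendered scene (one physical object), with
    independently seeded per-scan noise."""
    spec = spec or default_spec()
    profiles = profiles or default_profiles()
    scene, scene_mask = render_scene(spec)
    seeds = np.random.SeedSequence(base_seed).generate_state(
        len(profiles) * len(spacings)
    ) % (2**31)
    out = []
    k = 0
    for profile in profiles:
        blurred = _blur_in_plane(scene.voxels, profile.psf_fwhm_mm, scene.spacing[0])
        for spacing in spacings:
            out.append(
                acquire_scan(
                    scene,
                    scene_mask,
                    profile,
                    spacing,
                    seed=int(seeds[k]),
                    _pre_blurred=blurred,
                )
            )
            k += 1
    return out
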