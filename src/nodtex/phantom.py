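"""Synthetic CT phantom of lung nodules under a factorial scan-parameter design.

This module is a digital stand-in for an anthropomorphic thorax phantom with
spherical nodule inserts of known attenuation (+100 HU solid, -630 HU
ground-glass), scanned repeatedly under every combination of slice thickness
(1.25 / 2.5 / 5.0 mm), tube current-time product (30 / 120 mAs) and
reconstruction kernel ("lung" = sharp, "standard" = smooth).

The image-formation chain is deliberately simple and fully deterministic given
a seed:

1. nodules are rasterized on a supersampled grid (<= 0.25 mm along each axis)
   and block-averaged onto the protocol grid, so partial-volume dilution grows
   with slice thickness;
2. an in-plane point-spread blur is applied (wide Gaussian for the standard
   kernel; narrow Gaussian plus an edge-enhancing high-pass term for the lung
   kernel);
3. zero-mean Gaussian noise with sigma = :func:`noise_sigma` is added;
4. HU values are clamped to the representable window [-1024, 3071].

Ground-truth masks (voxel inside iff >= 50% subsample occupancy) are returned
alongside each rendered volume, so segmentation and feature extraction are
testable without any acquired data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "SLICE_THICKNESSES_MM",
    "TUBE_CURRENTS_MAS",
    "KERNELS",
    "ScanProtocol",
    "NoduleSpec",
    "CTVolume",
    "PhantomScene",
    "ScanEntry",
    "StudyDesign",
    "RenderConfig",
    "all_protocols",
    "make_design",
    "noise_sigma",
    "render_phantom",
    "default_scene",
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
]

# Representable HU window: 4096 integer levels when stored.
HU_MIN = -1024.0
HU_MAX = 3071.0

# The factorial design axes.
SLICE_THICKNESSES_MM = (1.25, 2.5, 5.0)
TUBE_CURRENTS_MAS = (30, 120)
KERNELS = ("lung", "standard")


class ConfigurationError(ValueError):
    """A scene/protocol combination that cannot be rendered."""


@dataclass(frozen=True)
class ScanProtocol:
    """One cell of the 3 x 2 x 2 factorial design.

    ``slice_thickness_mm`` doubles as the z voxel spacing of any volume
    rendered under this protocol.
    """

    slice_thickness_mm: float
    tube_current_mas: int
    kernel: str

    def __post_init__(self) -> None:
        if self.slice_thickness_mm not in SLICE_THICKNESSES_MM:
            raise ValueError(
                f"slice_thickness_mm must be one of {SLICE_THICKNESSES_MM}, "
                f"got {self.slice_thickness_mm}"
            )
        if self.tube_current_mas not in TUBE_CURRENTS_MAS:
            raise ValueError(
                f"tube_current_mas must be one of {TUBE_CURRENTS_MAS}, "
                f"got {self.tube_current_mas}"
            )
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")

    def label(self) -> str:
        return f"t{self.slice_thickness_mm}_mas{self.tube_current_mas}_{self.kernel}"


@dataclass(frozen=True)
class NoduleSpec:
    """A spherical nodule insert: diameter, target attenuation, centre (mm)."""

    diameter_mm: float
    target_hu: float
    center_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter_mm must be positive, got {self.diameter_mm}")


@dataclass
class CTVolume:
    """A 3D HU-valued voxel grid with anisotropic spacing.

    Axis order is (z, y, x); ``spacing_mm`` and ``origin_mm`` are (x, y, z),
    following the medical-imaging convention used by SimpleITK.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def index_to_mm(self, index_zyx: tuple[int, int, int]) -> np.ndarray:
        """Physical (x, y, z) centre of the voxel at (z, y, x) index."""
        iz, iy, ix = index_zyx
        sx, sy, sz = self.spacing_mm
        ox, oy, oz = self.origin_mm
        return np.array([ox + (ix + 0.5) * sx, oy + (iy + 0.5) * sy, oz + (iz + 0.5) * sz])

    def mm_to_index(self, point_mm) -> tuple[int, int, int]:
        """(z, y, x) index of the voxel containing a physical (x, y, z) point."""
        px, py, pz = point_mm
        sx, sy, sz = self.spacing_mm
        ox, oy, oz = self.origin_mm
        return (int((pz - oz) // sz), int((py - oy) // sy), int((px - ox) // sx))


@dataclass
class PhantomScene:
    """Scene geometry: lung-field background, body shell, nodule inserts."""

    lung_hu: float = -850.0
    body_hu: float = 40.0
    nodules: list[NoduleSpec] = field(default_factory=list)
    field_of_view_mm: tuple[float, float, float] = (60.0, 60.0, 40.0)
    body_margin_mm: float = 4.0  # x/y rim rendered at body_hu

    def __post_init__(self) -> None:
        if self.lung_hu >= -500.0:
            raise ValueError(f"lung_hu must be < -500 (air-like), got {self.lung_hu}")
        for nod in self.nodules:
            if nod.target_hu <= self.lung_hu:
                raise ValueError(
                    f"nodule target_hu {nod.target_hu} must exceed lung background {self.lung_hu}"
                )
            self._check_inside(nod)

    def _check_inside(self, nod: NoduleSpec) -> None:
        r = nod.diameter_mm / 2.0
        fov = self.field_of_view_mm
        lo = (self.body_margin_mm, self.body_margin_mm, 0.0)
        for axis in range(3):
            if nod.center_mm[axis] - r < lo[axis] or nod.center_mm[axis] + r > fov[axis] - lo[axis]:
                raise ConfigurationError(
                    f"nodule at {nod.center_mm} (d={nod.diameter_mm} mm) "
                    f"extends outside the lung field of FOV {fov}"
                )


@dataclass(frozen=True)
class ScanEntry:
    """One scheduled scan: a protocol, a repetition index and its child seed."""

    protocol: ScanProtocol
    repetition: int
    seed: int


@dataclass
class StudyDesign:
    """The full factorial protocol list crossed with repetition indices."""

    protocols: list[ScanProtocol]
    repetitions: int
    relocation_jitter_mm: float
    master_seed: int
    scans: list[ScanEntry]


def all_protocols() -> list[ScanProtocol]:
    """The 12 distinct protocols of the 3 x 2 x 2 factorial design."""
    return [
        ScanProtocol(t, mas, k)
        for t, mas, k in itertools.product(SLICE_THICKNESSES_MM, TUBE_CURRENTS_MAS, KERNELS)
    ]


def _child_seed(master_seed: int, scan_index: int) -> int:
    # Splittable counter scheme: any single scan is reproducible in isolation.
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(scan_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def make_design(
    repetitions: int,
    master_seed: int,
    relocation_jitter_mm: float = 2.0,
) -> StudyDesign:
    """Schedule the study: 12 protocols x `repetitions` repeat scans.

    Each (protocol, repetition) pair carries a child seed derived from
    ``master_seed`` by a splittable counter scheme, so the schedule is
    deterministic and any single scan can be re-rendered in isolation.
    """
    if repetitions < 0:
        raise ValueError(f"repetitions must be >= 0, got {repetitions}")
    if relocation_jitter_mm < 0:
        raise ValueError("relocation_jitter_mm must be >= 0")
    protocols = all_protocols()
    scans = []
    index = 0
    for rep in range(repetitions):
        for proto in protocols:
            scans.append(ScanEntry(proto, rep, _child_seed(master_seed, index)))
            index += 1
    return StudyDesign(protocols, repetitions, relocation_jitter_mm, master_seed, scans)


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderConfig:
    """Tunable constants of the image-formation model.

    Noise follows sigma = sigma_ref * sqrt(mas_ref/mas) * sqrt(t_ref/t) * k,
    the usual quantum-noise scaling (fewer photons per voxel at low mAs and
    thin slices), with a kernel multiplier for the sharp lung kernel.
    """

    pixel_spacing_mm: float = 0.7          # in-plane; typical thorax FOV on a 512 grid
    supersample_max_mm: float = 0.25       # rasterization grid upper bound
    sigma_ref_hu: float = 12.0             # noise at the reference protocol
    mas_ref: float = 120.0
    thickness_ref_mm: float = 5.0
    kernel_noise_factor: dict = field(
        default_factory=lambda: {"lung": 2.0, "standard": 1.0}
    )
    psf_sigma_mm: dict = field(
        default_factory=lambda: {"lung": 0.3, "standard": 0.6}
    )
    edge_enhancement: float = 0.6          # lung-kernel high-pass gain
    edge_sigma_mm: float = 1.0             # high-pass reference blur scale
    texture_sd_hu: float = 5.0             # nodule-interior heterogeneity
    texture_corr_mm: float = 2.0           # its correlation length
    noise_scale: float = 1.0               # 0 disables noise (noise-free renders)


DEFAULT_RENDER_CONFIG = RenderConfig()


def noise_sigma(protocol: ScanProtocol, config: RenderConfig = DEFAULT_RENDER_CONFIG) -> float:
    """Background noise SD (HU) for a protocol under the quantum-noise model."""
    t = protocol.slice_thickness_mm
    mas = protocol.tube_current_mas
    if t <= 0 or mas <= 0:
        raise ValueError("slice thickness and mAs must be positive")
    k = config.kernel_noise_factor[protocol.kernel]
    return config.sigma_ref_hu * np.sqrt(config.mas_ref / mas) * np.sqrt(
        config.thickness_ref_mm / t
    ) * k


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _supersample_factors(spacing: tuple[float, float, float], max_mm: float) -> tuple[int, int, int]:
    return tuple(int(np.ceil(s / max_mm)) for s in spacing)


def _sphere_occupancy(
    nod: NoduleSpec,
    vol_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    factors: tuple[int, int, int],
) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Fractional occupancy of a sphere per protocol voxel, over its bbox.

    Computed by averaging subsample-point membership on the supersampled grid
    (block averaging), restricted to the sphere's bounding box for speed.
    """
    sx, sy, sz = spacing
    fx, fy, fz = factors
    cx, cy, cz = nod.center_mm
    r = nod.diameter_mm / 2.0
    pad = 1.0  # mm, so boundary voxels are fully covered
    lo = [
        max(0, int((cz - r - pad) // sz)),
        max(0, int((cy - r - pad) // sy)),
        max(0, int((cx - r - pad) // sx)),
    ]
    hi = [
        min(vol_shape[0], int(np.ceil((cz + r + pad) / sz))),
        min(vol_shape[1], int(np.ceil((cy + r + pad) / sy))),
        min(vol_shape[2], int(np.ceil((cx + r + pad) / sx))),
    ]
    bbox = tuple(slice(l, h) for l, h in zip(lo, hi))
    nz, ny, nx = (h - l for l, h in zip(lo, hi))
    if min(nz, ny, nx) <= 0:
        return np.zeros((0, 0, 0)), bbox

    # Subsample-point coordinates along each axis, shape (n_voxels, factor).
    def axis_coords(l, n, s, f):
        edges = (l + np.arange(n))[:, None] * s
        offs = (np.arange(f)[None, :] + 0.5) * (s / f)
        return edges + offs

    zc = axis_coords(lo[0], nz, sz, fz) - cz
    yc = axis_coords(lo[1], ny, sy, fy) - cy
    xc = axis_coords(lo[2], nx, sx, fx) - cx
    r2 = r * r
    inside = (
        (zc**2)[:, None, None, :, None, None]
        + (yc**2)[None, :, None, None, :, None]
        + (xc**2)[None, None, :, None, None, :]
    ) <= r2
    occ = inside.reshape(nz, ny, nx, -1).mean(axis=3)
    return occ, bbox


def _smooth_texture_field(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    sd_hu: float,
    corr_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Low-amplitude correlated Gaussian random field (nodule heterogeneity)."""
    from scipy.ndimage import gaussian_filter

    white = rng.standard_normal(shape)
    sig_vox = [corr_mm / s for s in (spacing[2], spacing[1], spacing[0])]  # (z,y,x)
    smooth = gaussian_filter(white, sigma=sig_vox, mode="nearest")
    sd = smooth.std()
    if sd > 0:
        smooth *= sd_hu / sd
    return smooth


def render_phantom(
    scene: PhantomScene,
    protocol: ScanProtocol,
    seed: int,
    config: RenderConfig = DEFAULT_RENDER_CONFIG,
):
    """Render one scan: returns ``(CTVolume, list of ground-truth masks)``.

    Deterministic given ``seed``. Masks are boolean arrays on the protocol
    grid (voxel inside iff >= 50% subsample occupancy), one per nodule, in
    scene order.
    """
    from scipy.ndimage import gaussian_filter

    sx = sy = config.pixel_spacing_mm
    sz = protocol.slice_thickness_mm
    spacing = (sx, sy, sz)
    fov = scene.field_of_view_mm
    shape = (
        int(round(fov[2] / sz)),
        int(round(fov[1] / sy)),
        int(round(fov[0] / sx)),
    )  # (z, y, x)
    if min(shape) < 1:
        raise ConfigurationError(f"field of view {fov} too small for spacing {spacing}")
    for nod in scene.nodules:
        scene._check_inside(nod)

    rng = np.random.default_rng(seed)
    vox = np.full(shape, scene.lung_hu, dtype=np.float64)

    # Body shell: an x/y rim at soft-tissue attenuation bounding the lung field.
    m = scene.body_margin_mm
    mx, my = int(round(m / sx)), int(round(m / sy))
    if mx > 0 and my > 0:
        vox[:, :my, :] = scene.body_hu
        vox[:, -my:, :] = scene.body_hu
        vox[:, :, :mx] = scene.body_hu
        vox[:, :, -mx:] = scene.body_hu

    factors = _supersample_factors(spacing, config.supersample_max_mm)
    masks = []
    for nod in scene.nodules:
        occ, bbox = _sphere_occupancy(nod, shape, spacing, factors)
        if occ.size:
            region = vox[bbox]
            base = region + occ * (nod.target_hu - region)
            if config.texture_sd_hu > 0:
                tex = _smooth_texture_field(
                    occ.shape, spacing, config.texture_sd_hu, config.texture_corr_mm, rng
                )
                base = base + occ * tex
            vox[bbox] = base
        mask = np.zeros(shape, dtype=bool)
        if occ.size:
            mask[bbox] = occ >= 0.5
        masks.append(mask)

    # In-plane PSF; the sharp lung kernel adds an edge-enhancing high-pass term.
    psf_mm = config.psf_sigma_mm[protocol.kernel]
    sig_xy = (psf_mm / sy, psf_mm / sx)
    blurred = gaussian_filter(vox, sigma=(0.0, *sig_xy), mode="nearest")
    if protocol.kernel == "lung" and config.edge_enhancement > 0:
        wide = gaussian_filter(
            vox, sigma=(0.0, config.edge_sigma_mm / sy, config.edge_sigma_mm / sx), mode="nearest"
        )
        blurred = blurred + config.edge_enhancement * (blurred - wide)

    sigma = noise_sigma(protocol, config) * config.noise_scale
    if sigma > 0:
        blurred = blurred + rng.normal(0.0, sigma, size=shape)

    np.clip(blurred, HU_MIN, HU_MAX, out=blurred)
    volume = CTVolume(blurred, spacing_mm=spacing)
    return volume, masks


def default_scene(
    jitter_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    lung_hu: float = -850.0,
    texture_ok: bool = True,
) -> PhantomScene:
    """The study scene: four nodules (10/12 mm at +100 and -630 HU) in a 2x2
    layout, optionally relocated by a Gaussian jitter per repetition."""
    centers = [(18.0, 18.0, 20.0), (42.0, 18.0, 20.0), (18.0, 42.0, 20.0), (42.0, 42.0, 20.0)]
    specs = [(10.0, 100.0), (12.0, 100.0), (10.0, -630.0), (12.0, -630.0)]
    if jitter_mm > 0:
        if rng is None:
            raise ValueError("rng required when jitter_mm > 0")
        centers = [tuple(np.asarray(c) + rng.normal(0.0, jitter_mm, 3)) for c in centers]
    nodules = [NoduleSpec(d, hu, c) for (d, hu), c in zip(specs, centers)]
    return PhantomScene(lung_hu=lung_hu, nodules=nodules)


# ---------------------------------------------------------------------------
# Volume I/O (MetaImage / NIfTI via SimpleITK)
# ---------------------------------------------------------------------------

def _to_sitk(volume: CTVolume, dtype) -> sitk.Image:
    img = sitk.GetImageFromArray(np.asarray(volume.voxels, dtype=dtype))
    img.SetSpacing(tuple(float(s) for s in volume.spacing_mm))
    img.SetOrigin(tuple(float(o) for o in volume.origin_mm))
    return img


def write_volume(volume: CTVolume, path: str) -> None:
    """Write an HU volume as MetaImage (.mha) or NIfTI (.nii/.nii.gz)."""
    sitk.WriteImage(_to_sitk(volume, np.float32), str(path))


def read_volume(path: str) -> CTVolume:
    img = sitk.ReadImage(str(path))
    return CTVolume(
        sitk.GetArrayFromImage(img).astype(np.float64),
        spacing_mm=tuple(img.GetSpacing()),
        origin_mm=tuple(img.GetOrigin()),
    )


def write_mask(mask: np.ndarray, like: CTVolume, path: str) -> None:
    """Write a binary mask as a uint8 volume on the same grid as ``like``."""
    vol = CTVolume(mask.astype(np.uint8), like.spacing_mm, like.origin_mm)
    sitk.WriteImage(_to_sitk(vol, np.uint8), str(path))


def read_mask(path: str) -> tuple[np.ndarray, CTVolume]:
    vol = read_volume(path)
    return vol.voxels.astype(bool), vol
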