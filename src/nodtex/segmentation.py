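"""Seeded region growing of lung nodules on CT volumes.

The growth rule is a frozen HU-interval criterion over 26-connected
neighbours: a voxel joins the region iff its HU lies in [low, high] and it is
connected to the seed through voxels that also satisfy the criterion.
Because the interval never drifts during growth, the result is exactly the
26-connected component of the thresholded volume that contains the seed —
order-independent, idempotent, and monotone in the interval.

In ``seed_adaptive`` mode the interval is derived from the 3x3x3
neighbourhood of the seed (mean +/- k*SD) and then frozen before growth.

Manual editing by a radiologist is replaced by automated quality control:
masks failing sphericity or volume bounds are flagged, never silently edited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import CTVolume

__all__ = [
    "GrowCriterion",
    "ROIMask",
    "EmptyRegionError",
    "region_grow",
    "auto_seed",
    "dice",
    "mask_qc",
    "DEFAULT_SOLID_INTERVAL",
    "DEFAULT_GGO_INTERVAL",
]

# Default frozen HU intervals for the two nodule density classes, for a
# -850 HU lung background. The active bound follows the half-contrast
# (full-width-at-half-maximum) sizing rule: the midpoint between nodule
# density and background, i.e. the contour that in-plane blur does not move,
# so the grown region matches the >= 50%-occupancy ground truth.
DEFAULT_SOLID_INTERVAL = (-375.0, 400.0)   # +100 HU nodules: (100 + -850)/2
DEFAULT_GGO_INTERVAL = (-740.0, -400.0)    # -630 HU nodules: (-630 + -850)/2

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class EmptyRegionError(ValueError):
    """The seed voxel itself fails the growth criterion."""


@dataclass(frozen=True)
class GrowCriterion:
    """Inclusion rule for region growing.

    ``fixed_interval``: voxels with HU in [low_hu, high_hu].
    ``seed_adaptive``: interval m +/- adapt_k * s from the seed's 3x3x3
    neighbourhood, frozen before growth.
    """

    mode: str = "fixed_interval"
    low_hu: float = DEFAULT_SOLID_INTERVAL[0]
    high_hu: float = DEFAULT_SOLID_INTERVAL[1]
    adapt_k: float = 2.5

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_interval", "seed_adaptive"):
            raise ValueError(f"unknown criterion mode {self.mode!r}")
        if self.mode == "fixed_interval" and not self.low_hu < self.high_hu:
            raise ValueError("fixed_interval requires low_hu < high_hu")
        if self.mode == "seed_adaptive" and self.adapt_k <= 0:
            raise ValueError("seed_adaptive requires adapt_k > 0")


@dataclass
class ROIMask:
    """A segmented (or ground-truth) nodule mask on a CTVolume grid."""

    mask: np.ndarray
    source: str = "region_grow"                 # or "ground_truth"
    boundary_leak: bool = False                 # region reached the volume border
    interval_hu: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _frozen_interval(volume: CTVolume, seed_point, criterion: GrowCriterion):
    if criterion.mode == "fixed_interval":
        return criterion.low_hu, criterion.high_hu
    z, y, x = seed_point
    nb = volume.voxels[
        max(z - 1, 0) : z + 2, max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2
    ]
    m, s = float(nb.mean()), float(nb.std())
    return m - criterion.adapt_k * s, m + criterion.adapt_k * s


def region_grow(
    volume: CTVolume, seed_point: tuple[int, int, int], criterion: GrowCriterion
) -> ROIMask:
    """Grow a 26-connected region from ``seed_point`` under a frozen criterion.

    Raises :class:`EmptyRegionError` if the seed voxel fails the criterion.
    If the grown region touches the volume border, the returned mask carries
    a ``boundary_leak`` warning flag.
    """
    vox = volume.voxels
    z, y, x = seed_point
    if not (0 <= z < vox.shape[0] and 0 <= y < vox.shape[1] and 0 <= x < vox.shape[2]):
        raise ValueError(f"seed_point {seed_point} outside volume of shape {vox.shape}")
    if not np.all(np.isfinite(vox)):
        raise ValueError("volume contains non-finite HU values")

    low, high = _frozen_interval(volume, seed_point, criterion)
    if not (low <= vox[z, y, x] <= high):
        raise EmptyRegionError(
            f"seed voxel HU {vox[z, y, x]:.1f} outside criterion interval "
            f"[{low:.1f}, {high:.1f}]"
        )

    admissible = (vox >= low) & (vox <= high)
    labels, _ = ndimage.label(admissible, structure=_STRUCT_26)
    region = labels == labels[z, y, x]

    leak = bool(
        region[0].any() or region[-1].any()
        or region[:, 0].any() or region[:, -1].any()
        or region[:, :, 0].any() or region[:, :, -1].any()
    )
    return ROIMask(region, source="region_grow", boundary_leak=leak, interval_hu=(low, high))


def auto_seed(
    volume: CTVolume, approx_center_mm, search_radius_mm: float = 5.0
) -> tuple[int, int, int]:
    """Seed selection: the voxel of maximal HU within ``search_radius_mm`` of
    an approximate nodule centre (physical x, y, z in mm).

    Ties are broken by the lowest lexicographic (z, y, x) index. Raises if
    the approximate centre or the search window falls outside the volume.
    """
    center = np.asarray(approx_center_mm, dtype=float)
    sx, sy, sz = volume.spacing_mm
    ox, oy, oz = volume.origin_mm
    shape = volume.shape
    if not (
        ox <= center[0] < ox + shape[2] * sx
        and oy <= center[1] < oy + shape[1] * sy
        and oz <= center[2] < oz + shape[0] * sz
    ):
        raise ValueError(f"approx_center_mm {tuple(center)} outside volume extent")

    zc, yc, xc = volume.mm_to_index(center)
    rz = int(np.ceil(search_radius_mm / sz))
    ry = int(np.ceil(search_radius_mm / sy))
    rx = int(np.ceil(search_radius_mm / sx))
    zs = slice(max(zc - rz, 0), min(zc + rz + 1, shape[0]))
    ys = slice(max(yc - ry, 0), min(yc + ry + 1, shape[1]))
    xs = slice(max(xc - rx, 0), min(xc + rx + 1, shape[2]))

    zz, yy, xx = np.meshgrid(
        np.arange(zs.start, zs.stop),
        np.arange(ys.start, ys.stop),
        np.arange(xs.start, xs.stop),
        indexing="ij",
    )
    pts = np.stack(
        [
            ox + (xx + 0.5) * sx - center[0],
            oy + (yy + 0.5) * sy - center[1],
            oz + (zz + 0.5) * sz - center[2],
        ]
    )
    within = (pts**2).sum(axis=0) <= search_radius_mm**2
    if not within.any():
        raise ValueError("auto_seed search window is empty")

    window = volume.voxels[zs, ys, xs]
    best = np.max(window[within])
    cand = np.argwhere(within & (window == best))  # argwhere is lexicographic
    z, y, x = cand[0]
    return (int(z + zs.start), int(y + ys.start), int(x + xs.start))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) between two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def mask_qc(
    mask: ROIMask,
    volume: CTVolume,
    min_volume_mm3: float = 50.0,
    max_volume_mm3: float = 5000.0,
    min_sphericity: float = 0.6,
) -> dict:
    """Automated quality control for a segmented nodule.

    Returns one summary record: voxel count, physical volume, sphericity
    (pi^(1/3) (6V)^(2/3) / A, with the surface area A from a marching-cubes
    mesh), and pass/fail flags. Flagged masks are reported, never edited.
    """
    from skimage import measure

    n = mask.voxel_count
    vol_mm3 = n * volume.voxel_volume_mm3()
    sphericity = 0.0
    if n > 0:
        m = mask.mask.astype(np.uint8)
        padded = np.pad(m, 1)
        try:
            sx, sy, sz = volume.spacing_mm
            verts, faces, _, _ = measure.marching_cubes(
                padded, level=0.5, spacing=(sz, sy, sx)
            )
            area = measure.mesh_surface_area(verts, faces)
            if area > 0:
                sphericity = float(np.pi ** (1 / 3) * (6.0 * vol_mm3) ** (2 / 3) / area)
        except (ValueError, RuntimeError):
            sphericity = 0.0
    flags = []
    if not (min_volume_mm3 <= vol_mm3 <= max_volume_mm3):
        flags.append("volume_out_of_bounds")
    if sphericity < min_sphericity:
        flags.append("low_sphericity")
    if mask.boundary_leak:
        flags.append("boundary_leak")
    return {
        "voxel_count": n,
        "volume_mm3": vol_mm3,
        "sphericity": sphericity,
        "flags": ";".join(flags),
        "passed": not flags,
    }
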