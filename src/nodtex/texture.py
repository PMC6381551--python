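"""3D histogram, GLCM and GLRLM radiomic features of a segmented nodule.

The 20-feature panel:

* 7 histogram features — mean, stddev, variance, skewness, kurtosis (excess),
  energy, entropy — computed from the per-voxel quantized gray values and
  the 256-bin normalized histogram;
* 8 gray-level co-occurrence matrix (GLCM) features — contrast,
  dissimilarity, homogeneity, angular second moment (ASM), energy
  (= sqrt(ASM)), probability max, entropy, correlation;
* 5 gray-level run length matrix (GLRLM) features — long runs emphasis
  (LRE), gray-level nonuniformity (GLN), run length nonuniformity (RLN),
  low- and high-gray-level run emphasis (LGRE, HGRE).

HU values (4,096 integer levels in [-1024, 3071]) are quantized to 256 gray
levels with a fixed global window, g = floor((HU + 1024)/16), so features are
comparable across scan protocols. GLCM and GLRLM are accumulated per
direction over the 13 unique axes of the 26-neighbourhood at voxel distance
1, and each matrix feature is the arithmetic mean over the non-degenerate
directions.

GLCM accumulation is single-direction (asymmetric) by default — each ordered
voxel pair (p, p+offset) with both endpoints in the mask contributes one
count — with symmetric accumulation available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import CTVolume, HU_MIN

__all__ = [
    "GRAY_LEVELS",
    "DIRECTIONS_13",
    "FEATURE_NAMES",
    "HISTOGRAM_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "QuantizedROI",
    "GLCMatrix",
    "RunLengthMatrix",
    "EmptyROIError",
    "DegenerateMatrixError",
    "quantize",
    "histogram_features",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "extract_features",
]

GRAY_LEVELS = 256
_BIN_WIDTH = 16  # 4096 HU levels / 256 gray levels

# The 13 unique 3D offset axes of the 26-neighbourhood: the lexicographically
# positive representative of each {d, -d} pair, in (z, y, x) order.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13

HISTOGRAM_FEATURES = (
    "hist_mean",
    "hist_stddev",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_energy",
    "hist_entropy",
)
GLCM_FEATURES = (
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_homogeneity",
    "glcm_asm",
    "glcm_energy",
    "glcm_probability_max",
    "glcm_entropy",
    "glcm_correlation",
)
GLRLM_FEATURES = (
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_rln",
    "glrlm_lgre",
    "glrlm_hgre",
)
FEATURE_NAMES = HISTOGRAM_FEATURES + GLCM_FEATURES + GLRLM_FEATURES
assert len(FEATURE_NAMES) == 20


class EmptyROIError(ValueError):
    """Feature extraction requested on an empty region of interest."""


class DegenerateMatrixError(ValueError):
    """A texture matrix with no voxel pairs / runs along its direction."""


@dataclass
class QuantizedROI:
    """Gray-level view of a masked region.

    ``gray_volume`` carries the quantized value for masked voxels and -1
    outside; ``gray`` is the flat vector of masked values.
    """

    gray_volume: np.ndarray   # int16, -1 marks voxels outside the mask
    mask: np.ndarray          # bool, same shape
    levels: int = GRAY_LEVELS

    @property
    def gray(self) -> np.ndarray:
        return self.gray_volume[self.mask]

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class GLCMatrix:
    """A single-direction gray-level co-occurrence matrix."""

    counts: np.ndarray                 # (256, 256) int64
    direction: tuple[int, int, int]
    symmetric: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probs(self) -> np.ndarray:
        t = self.total
        if t == 0:
            raise DegenerateMatrixError(f"no voxel pairs along direction {self.direction}")
        return self.counts / t


@dataclass
class RunLengthMatrix:
    """A single-direction gray-level run length matrix N(gray, run length)."""

    counts: np.ndarray                 # (256, Rmax) int64; column j-1 = runs of length j
    direction: tuple[int, int, int]

    @property
    def total_runs(self) -> int:
        return int(self.counts.sum())

    @property
    def probs(self) -> np.ndarray:
        t = self.total_runs
        if t == 0:
            raise DegenerateMatrixError(f"no runs along direction {self.direction}")
        return self.counts / t


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def quantize(volume: CTVolume, mask: np.ndarray) -> QuantizedROI:
    """Quantize masked HU values from 4,096 levels to 256 gray levels.

    Fixed global window: g = floor((HU + 1024) / 16), clamped to [0, 255];
    exactly 16 raw integer HU levels map to each gray level.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume shape")
    if not mask.any():
        raise EmptyROIError("empty mask")
    g = np.floor((volume.voxels - HU_MIN) / _BIN_WIDTH)
    np.clip(g, 0, GRAY_LEVELS - 1, out=g)
    gray_volume = np.where(mask, g, -1).astype(np.int16)
    return QuantizedROI(gray_volume=gray_volume, mask=mask)


# ---------------------------------------------------------------------------
# Histogram features
# ---------------------------------------------------------------------------

def histogram_features(values: np.ndarray) -> dict[str, float]:
    """The 7 first-order features of a gray-value sample.

    Moments are population moments of the per-voxel values; kurtosis is
    excess kurtosis (normal = 0); energy and entropy are computed on the
    256-bin normalized histogram. Skewness and kurtosis are defined as 0
    for a zero-variance sample.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    n = v.size
    if n == 0:
        raise EmptyROIError("no voxels in ROI")
    mean = v.mean()
    dev = v - mean
    var = float(np.mean(dev**2))
    std = float(np.sqrt(var))
    if var > 0:
        skew = float(np.mean(dev**3) / var**1.5)
        kurt = float(np.mean(dev**4) / var**2 - 3.0)
    else:
        skew = kurt = 0.0
    counts = np.bincount(v.astype(np.int64), minlength=GRAY_LEVELS)
    p = counts / n
    nz = p[p > 0]
    energy = float(np.sum(p**2))
    entropy = float(-np.sum(nz * np.log2(nz)))
    return {
        "hist_mean": float(mean),
        "hist_stddev": std,
        "hist_variance": var,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_energy": energy,
        "hist_entropy": entropy,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _shifted_views(arr: np.ndarray, offset: tuple[int, int, int]):
    """Views (a, b) such that b is arr displaced by +offset relative to a."""
    src = []
    dst = []
    for d, size in zip(offset, arr.shape):
        step = d  # distance folded into the offset by the caller
        if step > 0:
            src.append(slice(0, size - step))
            dst.append(slice(step, size))
        elif step < 0:
            src.append(slice(-step, size))
            dst.append(slice(0, size + step))
        else:
            src.append(slice(0, size))
            dst.append(slice(0, size))
    return arr[tuple(src)], arr[tuple(dst)]


def compute_glcm(
    roi: QuantizedROI,
    offset: tuple[int, int, int],
    distance: int = 1,
    symmetric: bool = False,
) -> GLCMatrix:
    """Accumulate the co-occurrence matrix for one direction.

    Every ordered voxel pair (p, p + offset*distance) with both endpoints in
    the mask increments counts[g(p), g(p + offset*distance)]. With
    ``symmetric=True`` the transposed pair is accumulated as well.
    """
    if all(d == 0 for d in offset):
        raise ValueError("offset must be non-zero")
    step = tuple(int(d) * int(distance) for d in offset)
    g = roi.gray_volume.astype(np.int64)
    a, b = _shifted_views(g, step)
    valid = (a >= 0) & (b >= 0)
    ga = a[valid]
    gb = b[valid]
    flat = np.bincount(ga * GRAY_LEVELS + gb, minlength=GRAY_LEVELS * GRAY_LEVELS)
    counts = flat.reshape(GRAY_LEVELS, GRAY_LEVELS)
    if symmetric:
        counts = counts + counts.T
    return GLCMatrix(counts=counts.astype(np.int64), direction=tuple(offset), symmetric=symmetric)


def glcm_features(m: GLCMatrix) -> dict[str, float]:
    """The 8 co-occurrence features of one direction's matrix.

    correlation is defined as 1 (perfect linear dependence) when a marginal
    SD vanishes, i.e. when all pairs share a single gray level.
    """
    p = m.probs  # raises DegenerateMatrixError on an empty matrix
    nz_i, nz_j = np.nonzero(p)
    pv = p[nz_i, nz_j]
    diff = nz_i - nz_j
    contrast = float(np.sum(pv * diff.astype(np.float64) ** 2))
    dissimilarity = float(np.sum(pv * np.abs(diff)))
    homogeneity = float(np.sum(pv / (1.0 + diff.astype(np.float64) ** 2)))
    asm = float(np.sum(pv**2))
    energy = float(np.sqrt(asm))
    pmax = float(pv.max())
    entropy = float(-np.sum(pv * np.log2(pv)))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    lev = np.arange(GRAY_LEVELS, dtype=np.float64)
    mu_i = float(np.sum(lev * pi))
    mu_j = float(np.sum(lev * pj))
    sd_i = float(np.sqrt(np.sum(pi * (lev - mu_i) ** 2)))
    sd_j = float(np.sqrt(np.sum(pj * (lev - mu_j) ** 2)))
    if sd_i * sd_j > 0:
        corr = float(np.sum(pv * (nz_i - mu_i) * (nz_j - mu_j)) / (sd_i * sd_j))
    else:
        corr = 1.0
    return {
        "glcm_contrast": contrast,
        "glcm_dissimilarity": dissimilarity,
        "glcm_homogeneity": homogeneity,
        "glcm_asm": asm,
        "glcm_energy": energy,
        "glcm_probability_max": pmax,
        "glcm_entropy": entropy,
        "glcm_correlation": corr,
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _shift(arr: np.ndarray, step: tuple[int, int, int], fill) -> np.ndarray:
    """arr displaced so that out[v] = arr[v + step], padded with ``fill``."""
    out = np.full_like(arr, fill)
    src_idx = []
    dst_idx = []
    for d, size in zip(step, arr.shape):
        if d > 0:
            src_idx.append(slice(0, size - d))
            dst_idx.append(slice(d, size))
        elif d < 0:
            src_idx.append(slice(-d, size))
            dst_idx.append(slice(0, size + d))
        else:
            src_idx.append(slice(0, size))
            dst_idx.append(slice(0, size))
    out[tuple(src_idx)] = arr[tuple(dst_idx)]
    return out


def compute_glrlm(roi: QuantizedROI, offset: tuple[int, int, int]) -> RunLengthMatrix:
    """Accumulate the run length matrix for one direction.

    The ROI is swept by maximal lines parallel to ``offset``; within each
    line, maximal runs of equal gray value (broken wherever the mask is) are
    counted once each into N(gray, length). Every masked voxel belongs to
    exactly one maximal run, so sum_ij j * N(i, j) equals the voxel count.
    """
    if all(d == 0 for d in offset):
        raise ValueError("offset must be non-zero")
    if roi.voxel_count == 0:
        raise EmptyROIError("empty ROI")
    step = tuple(int(d) for d in offset)
    g = roi.gray_volume.astype(np.int64)

    # cont[v]: v and v+step both masked with equal gray (the run continues).
    nxt = _shift(g, step, fill=-1)
    cont = (g >= 0) & (nxt >= 0) & (g == nxt)

    # run_len[v] = length of the maximal run segment starting at v.
    max_extent = max(
        (size if d != 0 else 1) for d, size in zip(step, g.shape)
    )
    run_len = np.ones_like(g)
    for _ in range(max_extent - 1):
        nxt_len = _shift(run_len, step, fill=0)
        new = np.where(cont, 1 + nxt_len, 1)
        if np.array_equal(new, run_len):
            break
        run_len = new

    # A maximal run starts at v iff v is masked and v-step does not continue into v.
    back = tuple(-d for d in step)
    prev_cont = _shift(cont, back, fill=False)
    starts = (g >= 0) & ~prev_cont

    grays = g[starts]
    lengths = run_len[starts]
    rmax = int(lengths.max())
    counts = np.zeros((GRAY_LEVELS, rmax), dtype=np.int64)
    np.add.at(counts, (grays, lengths - 1), 1)
    return RunLengthMatrix(counts=counts, direction=tuple(offset))


def glrlm_features(m: RunLengthMatrix) -> dict[str, float]:
    """The 5 run-length features of one direction's matrix.

    Probabilities are run-count normalized. Gray levels are weighted
    1-based (i' = i + 1) in LGRE/HGRE so gray level 0 stays finite.
    """
    p = m.probs  # raises DegenerateMatrixError when no runs exist
    rmax = p.shape[1]
    j = np.arange(1, rmax + 1, dtype=np.float64)        # run lengths
    i1 = np.arange(1, GRAY_LEVELS + 1, dtype=np.float64)  # 1-based gray levels
    p_g = p.sum(axis=1)   # per-gray-level marginal
    p_r = p.sum(axis=0)   # per-run-length marginal
    return {
        "glrlm_lre": float(np.sum(p_r * j**2)),
        "glrlm_gln": float(np.sum(p_g**2)),
        "glrlm_rln": float(np.sum(p_r**2)),
        "glrlm_lgre": float(np.sum(p_g / i1**2)),
        "glrlm_hgre": float(np.sum(p_g * i1**2)),
    }


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

def extract_features(
    volume: CTVolume,
    mask: np.ndarray,
    covariates: dict | None = None,
    symmetric_glcm: bool = False,
) -> dict[str, float]:
    """The 20-feature vector of one nodule observation.

    Histogram features are computed once over the quantized ROI values; each
    GLCM and GLRLM feature is computed in all 13 directions at distance 1
    and averaged over the non-degenerate directions. Optional ``covariates``
    (density class, diameter, protocol, repetition, ...) are attached to the
    output record unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume shape")
    if not mask.any():
        raise EmptyROIError("empty mask")
    # Crop to the mask bounding box: features are translation invariant and
    # the matrices only see masked voxels, so this is a pure speedup.
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    bbox = tuple(slice(l, h) for l, h in zip(lo, hi))
    cropped = CTVolume(volume.voxels[bbox], volume.spacing_mm, volume.origin_mm)
    roi = quantize(cropped, mask[bbox])
    out: dict[str, float] = dict(histogram_features(roi.gray))

    glcm_acc: list[dict[str, float]] = []
    glrlm_acc: list[dict[str, float]] = []
    for offset in DIRECTIONS_13:
        glcm = compute_glcm(roi, offset, symmetric=symmetric_glcm)
        if glcm.total > 0:
            glcm_acc.append(glcm_features(glcm))
        glrlm = compute_glrlm(roi, offset)
        if glrlm.total_runs > 0:
            glrlm_acc.append(glrlm_features(glrlm))
    if not glcm_acc or not glrlm_acc:
        raise DegenerateMatrixError("all 13 directions degenerate for this ROI")

    for name in GLCM_FEATURES:
        out[name] = float(np.mean([d[name] for d in glcm_acc]))
    for name in GLRLM_FEATURES:
        out[name] = float(np.mean([d[name] for d in glrlm_acc]))

    if covariates:
        out.update(covariates)
    return out
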