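"""End-to-end study pipeline: simulate -> segment -> extract -> analyze.

Mirrors the phantom study's workflow: for every repetition the four nodule
inserts (10 and 12 mm at +100 and -630 HU) are relocated inside the lung
field, the arrangement is rendered under each of the 12 scan-parameter
combinations, each nodule is segmented by seeded region growing, the
20-feature panel is extracted, and each density stratum is analysed by
dummy-coded regression and Cohen's d.

Relocation is tied to the repetition (the same arrangement is "reconstructed"
under all 12 protocols, as a real repeat scan would be); noise is tied to the
per-scan child seed. Identical config + master seed reproduce every output
byte-exactly; a JSON run manifest records the config hash, seeds, file
inventory and convention flags.

For robustness at the highest noise levels the segmentation stage grows on a
lightly smoothed copy of the volume, restricted to a local VOI box around the
expected nodule position — the automated stand-in for the radiologist's
visual inspection and manual editing; failing masks are flagged by QC, never
edited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from . import __version__
from .phantom import (
    CTVolume,
    RenderConfig,
    StudyDesign,
    default_scene,
    make_design,
    render_phantom,
    write_mask,
    write_volume,
)
from .reference_tables import reference_table
from .segmentation import (
    DEFAULT_GGO_INTERVAL,
    DEFAULT_SOLID_INTERVAL,
    EmptyRegionError,
    GrowCriterion,
    ROIMask,
    auto_seed,
    mask_qc,
    region_grow,
)
from .stats import analyze_stratum
from .texture import FEATURE_NAMES, extract_features

__all__ = [
    "DEFAULT_CONFIG",
    "TOY_GRID",
    "load_config",
    "segment_nodule",
    "run_study",
    "make_fixtures",
]

DEFAULT_CONFIG: dict = {
    "repetitions": 10,
    "master_seed": 20190206,
    "relocation_jitter_mm": 2.0,
    "scene": {"lung_hu": -850.0, "body_hu": 40.0},
    "render": {},                      # RenderConfig overrides
    "segmentation": {
        "smoothing_sigma_mm": 1.0,     # pre-growth in-plane denoising
        "voi_margin_mm": 6.0,          # VOI half-width beyond the nodule radius
        "solid_interval_hu": list(DEFAULT_SOLID_INTERVAL),
        "ggo_interval_hu": list(DEFAULT_GGO_INTERVAL),
    },
    "keep_volumes": False,
}

# Toy 4x4 test grid (gray levels 0..3). Along the 0-degree in-plane direction
# at distance 1 its co-occurrence matrix has entry (1,1) = 2 (the run of three
# 1s) and its run length matrix has entry (2,2) = 1 (one maximal run of two
# 2s) -- the canonical worked example for both matrices.
TOY_GRID = np.array(
    [
        [1, 1, 1, 0],
        [2, 2, 0, 3],
        [0, 3, 1, 2],
        [3, 0, 2, 0],
    ],
    dtype=np.int16,
)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Default config, optionally merged with a YAML file and explicit overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _render_config(cfg: dict) -> RenderConfig:
    return dataclasses.replace(RenderConfig(), **(cfg.get("render") or {}))


def segment_nodule(
    volume: CTVolume,
    approx_center_mm,
    diameter_mm: float,
    target_hu: float,
    seg_cfg: dict,
) -> ROIMask:
    """Segment one nodule: VOI crop, light smoothing, seeded region growing.

    The growth interval is chosen by density class (solid vs ground-glass).
    Smoothing (``smoothing_sigma_mm``, in-plane) only shapes the mask; the
    features downstream are always extracted from the unsmoothed volume.
    """
    sigma_mm = float(seg_cfg.get("smoothing_sigma_mm", 1.0))
    margin = float(seg_cfg.get("voi_margin_mm", 6.0))
    interval = (
        tuple(seg_cfg.get("solid_interval_hu", DEFAULT_SOLID_INTERVAL))
        if target_hu > -300
        else tuple(seg_cfg.get("ggo_interval_hu", DEFAULT_GGO_INTERVAL))
    )
    half = diameter_mm / 2.0 + margin
    sx, sy, sz = volume.spacing_mm
    cz, cy, cx = volume.mm_to_index(approx_center_mm)
    rz, ry, rx = (int(np.ceil(half / s)) for s in (sz, sy, sx))
    zs = slice(max(cz - rz, 0), min(cz + rz + 1, volume.shape[0]))
    ys = slice(max(cy - ry, 0), min(cy + ry + 1, volume.shape[1]))
    xs = slice(max(cx - rx, 0), min(cx + rx + 1, volume.shape[2]))

    sub = volume.voxels[zs, ys, xs]
    if sigma_mm > 0:
        sub = gaussian_filter(sub, sigma=(0.0, sigma_mm / sy, sigma_mm / sx), mode="nearest")
    sub_vol = CTVolume(
        sub,
        spacing_mm=volume.spacing_mm,
        origin_mm=(
            volume.origin_mm[0] + xs.start * sx,
            volume.origin_mm[1] + ys.start * sy,
            volume.origin_mm[2] + zs.start * sz,
        ),
    )
    seed = auto_seed(sub_vol, approx_center_mm, search_radius_mm=min(5.0, diameter_mm / 2.0))
    grown = region_grow(sub_vol, seed, GrowCriterion("fixed_interval", *interval))
    full = np.zeros(volume.shape, dtype=bool)
    full[zs, ys, xs] = grown.mask
    return ROIMask(
        full, source="region_grow", boundary_leak=grown.boundary_leak,
        interval_hu=grown.interval_hu,
    )


def _scan_rows(cfg: dict, design: StudyDesign, outdir: Path | None):
    """Render, segment and extract every scheduled scan; yields feature rows
    and QC rows."""
    render_cfg = _render_config(cfg)
    seg_cfg = cfg.get("segmentation") or {}
    scene_cfg = cfg.get("scene") or {}
    keep = bool(cfg.get("keep_volumes")) and outdir is not None
    feature_rows = []
    qc_rows = []
    for entry in design.scans:
        rep_rng = np.random.default_rng([design.master_seed, entry.repetition])
        scene = default_scene(
            jitter_mm=design.relocation_jitter_mm,
            rng=rep_rng,
            lung_hu=float(scene_cfg.get("lung_hu", -850.0)),
        )
        volume, gt_masks = render_phantom(scene, entry.protocol, entry.seed, render_cfg)
        if keep:
            vdir = outdir / "volumes"
            vdir.mkdir(exist_ok=True)
            write_volume(volume, vdir / f"scan_{entry.protocol.label()}_rep{entry.repetition}.mha")
        for nod_idx, nod in enumerate(scene.nodules):
            try:
                mask = segment_nodule(
                    volume, nod.center_mm, nod.diameter_mm, nod.target_hu, seg_cfg
                )
                if mask.voxel_count == 0:
                    raise EmptyRegionError("empty grown region")
            except (EmptyRegionError, ValueError):
                # QC fallback: the ground-truth mask, flagged.
                mask = ROIMask(gt_masks[nod_idx], source="ground_truth")
            qc = mask_qc(mask, volume)
            qc.update(
                {
                    "nodule": nod_idx,
                    "density_hu": nod.target_hu,
                    "diameter_mm": nod.diameter_mm,
                    "thickness_mm": entry.protocol.slice_thickness_mm,
                    "mas": entry.protocol.tube_current_mas,
                    "kernel": entry.protocol.kernel,
                    "repetition": entry.repetition,
                    "source": mask.source,
                }
            )
            qc_rows.append(qc)
            covariates = {
                "density_hu": nod.target_hu,
                "diameter_mm": nod.diameter_mm,
                "thickness_mm": entry.protocol.slice_thickness_mm,
                "mas": entry.protocol.tube_current_mas,
                "kernel": entry.protocol.kernel,
                "repetition": entry.repetition,
                "seed": entry.seed,
            }
            feature_rows.append(extract_features(volume, mask.mask, covariates))
    return feature_rows, qc_rows


def run_study(
    config_path: str | None = None,
    out: str = "nodtex_out",
    overrides: dict | None = None,
) -> Path:
    """Execute the full study and write all outputs under ``out``.

    Outputs: ``features.csv`` (one row per nodule observation: 20 features +
    covariates), ``segmentation_qc.csv``, per-stratum coefficient /
    effect-size / |RC|-summary / tally tables, and ``manifest.json``.
    Returns the output directory.
    """
    cfg = load_config(config_path, overrides)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    design = make_design(
        int(cfg["repetitions"]), int(cfg["master_seed"]), float(cfg["relocation_jitter_mm"])
    )
    feature_rows, qc_rows = _scan_rows(cfg, design, outdir)
    col_order = list(FEATURE_NAMES) + [
        "density_hu", "diameter_mm", "thickness_mm", "mas", "kernel", "repetition", "seed",
    ]
    features = pd.DataFrame(feature_rows, columns=col_order)
    features.to_csv(outdir / "features.csv", index=False, float_format="%.10g")
    pd.DataFrame(qc_rows).to_csv(outdir / "segmentation_qc.csv", index=False)

    inventory = ["features.csv", "segmentation_qc.csv"]
    results = {}
    if cfg["repetitions"] > 0:
        for stratum, density in (("solid", 100.0), ("ggo", -630.0)):
            sub = features[features["density_hu"] == density].reset_index(drop=True)
            res = analyze_stratum(sub)
            results[stratum] = res
            res["coefficients"].to_csv(outdir / f"coefficients_{stratum}.csv")
            res["effect_sizes"].to_csv(outdir / f"effect_sizes_{stratum}.csv", index=False)
            res["rc_summaries"].to_csv(outdir / f"rc_summaries_{stratum}.csv")
            res["p_values"].to_csv(outdir / f"p_values_{stratum}.csv")
            with open(outdir / f"tally_{stratum}.json", "w") as fh:
                json.dump(res["tally"], fh, indent=2)
            inventory += [
                f"coefficients_{stratum}.csv",
                f"effect_sizes_{stratum}.csv",
                f"rc_summaries_{stratum}.csv",
                f"p_values_{stratum}.csv",
                f"tally_{stratum}.json",
            ]

    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "master_seed": design.master_seed,
        "n_protocols": len(design.protocols),
        "n_scans": len(design.scans),
        "child_seeds": [s.seed for s in design.scans],
        "outputs": sorted(inventory),
        "conventions": {
            "median_rule": "lower",
            "glcm_accumulation": "asymmetric",
            "scaling": "minmax_per_stratum",
            "gray_levels": 256,
            "directions": 13,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def _brute_glcm_2d(grid: np.ndarray, doffset: tuple[int, int], levels: int = 4) -> np.ndarray:
    # Independent exhaustive pair enumeration (kept separate from texture.py).
    out = np.zeros((levels, levels), dtype=int)
    h, w = grid.shape
    dy, dx = doffset
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w:
                out[grid[y, x], grid[y2, x2]] += 1
    return out


def make_fixtures(out: str) -> Path:
    """Write the small deterministic test inputs.

    Contents: the toy 4x4 grid with its expected 0-degree GLCM (computed at
    creation by exhaustive enumeration), the bundled reference coefficient
    tables as CSV, and two tiny rendered nodule volumes with ground-truth
    masks. Regenerates identically on every call.
    """
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "toy_grid.csv", TOY_GRID, fmt="%d", delimiter=",")
    np.savetxt(
        outdir / "toy_grid_glcm_0deg.csv",
        _brute_glcm_2d(TOY_GRID, (0, 1)),
        fmt="%d",
        delimiter=",",
    )
    reference_table("solid").to_csv(outdir / "reference_coefficients_solid.csv")
    reference_table("ggo").to_csv(outdir / "reference_coefficients_ggo.csv")

    from .phantom import NoduleSpec, PhantomScene, ScanProtocol

    for name, hu in (("solid", 100.0), ("ggo", -630.0)):
        scene = PhantomScene(
            nodules=[NoduleSpec(10.0, hu, (15.0, 15.0, 15.0))],
            field_of_view_mm=(30.0, 30.0, 30.0),
        )
        vol, masks = render_phantom(
            scene, ScanProtocol(2.5, 120, "standard"), seed=7,
        )
        write_volume(vol, outdir / f"nodule_{name}_10mm.mha")
        write_mask(masks[0], vol, outdir / f"nodule_{name}_10mm_mask.mha")
    return outdir
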