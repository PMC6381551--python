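# nodtex

Synthetic lung-nodule CT phantom radiomics: how much do scan parameters
move texture features?

CT radiomics studies routinely pool images acquired with different slice
thicknesses, doses and reconstruction kernels, yet first-order and texture
features are sensitive to all three. `nodtex` re-creates the canonical
phantom experiment for quantifying that sensitivity as a fully synthetic,
fully tested pipeline: spherical nodule phantoms of known density (+100 HU
solid, −630 HU ground-glass; 10 and 12 mm) are embedded in a lung-like
background and "scanned" under every cell of a 3 × 2 × 2 factorial —
slice thickness {1.25, 2.5, 5.0} mm × tube current {30, 120} mAs ×
reconstruction kernel {lung, standard} — with 10 repeat scans per cell and
nodule relocation between repeats. Each nodule is segmented by seeded
region growing, a 20-feature panel is extracted, and each scan parameter's
effect on each feature is quantified. It is intended for imaging scientists
who want a reference implementation of the 3D feature definitions and the
effect-size analysis, with a simulator in place of the physical phantom.

The feature panel (all in 3D, 256 gray levels from a fixed HU window,
g = ⌊(HU + 1024)/16⌋):

- **Histogram (7):** mean, SD, variance, skewness, excess kurtosis,
  energy Σpᵢ², entropy −Σpᵢlog₂pᵢ.
- **Gray-level co-occurrence matrix, GLCM (8):** contrast ΣP(i−j)²,
  dissimilarity ΣP|i−j|, homogeneity ΣP/(1+(i−j)²), angular second moment
  (ASM) ΣP², energy √ASM, max probability, entropy, correlation
  ΣP(i−μᵢ)(j−μⱼ)/σᵢσⱼ.
- **Gray-level run length matrix, GLRLM (5):** long-runs emphasis Σj²P,
  gray-level nonuniformity Σᵢ(ΣⱼP)², run-length nonuniformity Σⱼ(ΣᵢP)²,
  low- and high-gray-level run emphasis ΣP/i′², Σi′²P (i′ = i+1).

GLCM and GLRLM are accumulated at voxel distance 1 along the 13 unique
axes of the 26-neighbourhood and averaged over directions. Statistics per
density stratum: each feature is min–max scaled, regressed by OLS on
dummy-coded scan parameters (reference levels 5.0 mm / 30 mAs / lung),
contrasts reported as regression coefficients (RC) with t-test p-values,
|RC| summarized by max / lower-median / min over the 20 features, and
Cohen's d = |m_A − m_B|/s_pooled classified small/medium/large at
0.20/0.50/0.80. See `docs/methods.md` for the full model.

## Worked example

```python
import numpy as np
from nodtex import (ScanProtocol, default_scene, render_phantom, auto_seed,
                    region_grow, GrowCriterion, extract_features, dice,
                    reference_table, rc_summary)

scene = default_scene()                    # four nodules in a lung-like box
protocol = ScanProtocol(slice_thickness_mm=1.25, tube_current_mas=120,
                        kernel="standard")
volume, truth = render_phantom(scene, protocol, seed=42)

nod = scene.nodules[0]                     # 10 mm, +100 HU
seed_voxel = auto_seed(volume, nod.center_mm)
mask = region_grow(volume, seed_voxel, GrowCriterion("fixed_interval", -375, 400))
print(f"Dice vs ground truth: {dice(mask.mask, truth[0]):.3f}")

feats = extract_features(volume, mask.mask)
for name in ("hist_mean", "hist_entropy", "glcm_contrast",
             "glcm_homogeneity", "glrlm_hgre"):
    print(f"{name:18s} {feats[name]:8.3f}")

s = rc_summary(reference_table("solid")["thickness_1.25"].to_numpy())
print(f"|RC| 5.0 vs 1.25 mm: max={s.max_abs:.3f} med={s.median_abs:.3f} "
      f"min={s.min_abs:.3f}")
```

prints

```
Dice vs ground truth: 0.982
hist_mean            62.331
hist_entropy          4.544
glcm_contrast        78.029
glcm_homogeneity      0.245
glrlm_hgre         4030.641
|RC| 5.0 vs 1.25 mm: max=0.672 med=0.574 min=0.135
```

The segmentation recovers the ground-truth sphere almost exactly
(Dice 0.982). The quantized ROI mean of 62.3 corresponds to ≈ −27 HU —
below the +100 HU target because boundary voxels are diluted by partial
volume even at 1.25 mm slices. Entropy, contrast and the run-length
features characterize the noise texture inside the nodule at this
protocol. The last line recomputes, from the bundled published coefficient
table, the |RC| summary for the 5.0-vs-1.25 mm slice-thickness contrast in
solid nodules: thickness changes move scaled features by up to 0.672 of
their observed range, with a median effect of 0.574 — the headline result
that slice thickness dominates the solid-nodule stratum.

## The full study from the command line

```sh
nodtex run-all --out study --seed 20190206 --reps 10   # 480 observations
nodtex make-fixtures --out fixtures
```

`study/` then contains `features.csv` (480 rows × 20 features +
covariates), segmentation QC, per-stratum coefficient, effect-size, |RC|
summary and significance-tally tables, and a JSON manifest (config hash,
child seeds, conventions) that makes the run byte-reproducible. The stages
are also available separately (`simulate`, `segment`, `extract`,
`analyze`), communicating through MetaImage/NIfTI volumes and CSV tables.

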