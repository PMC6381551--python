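"""Published reference regression coefficients for worked examples.

These are the dummy-coded regression coefficient tables reported by the
physical lung-nodule phantom study this package emulates: for each of the 20
features, the constant plus the coefficients of [thickness=2.5],
[thickness=1.25], [mAs=120] and [kernel=standard] against reference levels
5.0 mm / 30 mAs / lung kernel, per density stratum (+100 HU solid, -630 HU
ground-glass). The physical scans behind them are not reproducible here; the
tables serve as fixed inputs for arithmetic summaries (|RC| max / median /
min per contrast) and as the shape template for this package's own output.

Column order per feature: (constant, thickness_2.5, thickness_1.25, mas_120,
kernel_standard).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .texture import FEATURE_NAMES

__all__ = [
    "REFERENCE_COEFFICIENTS_SOLID",
    "REFERENCE_COEFFICIENTS_GGO",
    "reference_table",
]

_COLS = ("constant", "thickness_2.5", "thickness_1.25", "mas_120", "kernel_standard")

# +100 HU (solid) stratum.
REFERENCE_COEFFICIENTS_SOLID = {
    "hist_mean":            (0.323, 0.418, 0.613, 0.020, -0.271),
    "hist_stddev":          (0.442, -0.085, -0.237, -0.055, -0.075),
    "hist_variance":        (0.260, -0.058, -0.152, -0.036, -0.047),
    "hist_skewness":        (0.008, 0.179, 0.463, 0.051, 0.108),
    "hist_kurtosis":        (0.772, -0.135, -0.177, -0.032, -0.234),
    "hist_energy":          (0.112, 0.388, 0.642, 0.103, -0.209),
    "hist_entropy":         (0.814, -0.430, -0.664, -0.079, 0.188),
    "glcm_contrast":        (0.078, 0.171, 0.383, -0.022, -0.026),
    "glcm_dissimilarity":   (0.231, 0.011, 0.135, -0.058, 0.036),
    "glcm_homogeneity":     (0.147, 0.472, 0.600, 0.131, -0.127),
    "glcm_asm":             (0.025, 0.387, 0.552, 0.186, -0.159),
    "glcm_energy":          (0.130, 0.476, 0.614, 0.142, -0.145),
    "glcm_probability_max": (0.150, 0.466, 0.583, 0.141, -0.137),
    "glcm_entropy":         (0.856, -0.454, -0.646, -0.116, 0.153),
    "glcm_correlation":     (0.927, -0.129, -0.299, 0.026, 0.015),
    "glrlm_lre":            (0.036, 0.452, 0.574, 0.178, -0.097),
    "glrlm_gln":            (0.105, 0.418, 0.621, 0.117, -0.181),
    "glrlm_rln":            (0.745, -0.541, -0.636, -0.105, 0.116),
    "glrlm_lgre":           (0.212, -0.130, -0.180, -0.011, 0.037),
    "glrlm_hgre":           (0.288, 0.509, 0.672, 0.039, -0.161),
}

# -630 HU (ground-glass) stratum.
REFERENCE_COEFFICIENTS_GGO = {
    "hist_mean":            (0.617, 0.247, 0.277, -0.011, -0.154),
    "hist_stddev":          (0.369, 0.036, 0.158, -0.149, -0.279),
    "hist_variance":        (0.230, 0.034, 0.154, -0.125, -0.200),
    "hist_skewness":        (-0.023, 0.209, 0.256, 0.143, 0.224),
    "hist_kurtosis":        (0.985, -0.146, -0.098, -0.149, -0.436),
    "hist_energy":          (0.061, 0.063, -0.021, 0.189, 0.361),
    "hist_entropy":         (0.664, 0.014, 0.122, -0.196, -0.394),
    "glcm_contrast":        (0.237, 0.111, 0.238, -0.108, -0.206),
    "glcm_dissimilarity":   (0.349, 0.121, 0.251, -0.141, -0.292),
    "glcm_homogeneity":     (0.193, -0.039, -0.154, 0.191, 0.422),
    "glcm_asm":             (0.027, -0.004, -0.060, 0.109, 0.166),
    "glcm_energy":          (0.080, -0.015, -0.086, 0.139, 0.233),
    "glcm_probability_max": (0.052, -0.008, -0.036, 0.084, 0.122),
    "glcm_entropy":         (0.788, 0.042, 0.130, -0.153, -0.284),
    "glcm_correlation":     (0.752, -0.100, -0.228, 0.109, 0.204),
    "glrlm_lre":            (0.068, 0.014, -0.054, 0.130, 0.258),
    "glrlm_gln":            (0.033, 0.033, -0.018, 0.125, 0.223),
    "glrlm_rln":            (0.891, -0.004, 0.078, -0.163, -0.318),
    "glrlm_lgre":           (0.167, -0.106, -0.086, -0.018, 0.011),
    "glrlm_hgre":           (0.639, 0.227, 0.269, -0.030, -0.144),
}


def reference_table(stratum: str) -> pd.DataFrame:
    """The reference coefficient table as a DataFrame indexed by feature.

    ``stratum``: ``"solid"`` (+100 HU) or ``"ggo"`` (-630 HU).
    """
    src = {"solid": REFERENCE_COEFFICIENTS_SOLID, "ggo": REFERENCE_COEFFICIENTS_GGO}
    try:
        data = src[stratum]
    except KeyError:
        raise ValueError(f"stratum must be 'solid' or 'ggo', got {stratum!r}") from None
    assert set(data) == set(FEATURE_NAMES)
    return pd.DataFrame(
        np.array([data[f] for f in FEATURE_NAMES]), index=list(FEATURE_NAMES), columns=_COLS
    )
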