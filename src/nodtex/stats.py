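"""Scan-parameter effect statistics for the 20-feature radiomics panel.

Per density stratum (+100 HU solid vs -630 HU ground-glass), each min-max
scaled feature is regressed on dummy-coded scan parameters by ordinary least
squares:

    feature ~ 1 + [thickness=2.5] + [thickness=1.25] + [mAs=120] + [kernel=standard]

with reference levels 5.0 mm, 30 mAs and the lung kernel. Five pairwise
contrasts are reported per feature — the three slice-thickness comparisons
(5.0 vs 2.5, 5.0 vs 1.25, 2.5 vs 1.25), mAs, and kernel — as regression
coefficients (RC) with two-sided t-test p-values; |RC| summarises the scale
of an effect and is reduced per contrast to its max / median / min over the
20 features (the median is the LOWER median, the 10th of 20 ordered values).
Cohen's d = |mean difference| / pooled SD, classified small / medium / large
at 0.20 / 0.50 / 0.80, quantifies each contrast independently of the model;
its direction symbol comes from a Welch two-sample t-test at p <= 0.05.

p-values are not multiplicity-adjusted in the headline tallies; a
Holm-adjusted column is emitted alongside for reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .texture import FEATURE_NAMES

__all__ = [
    "COEF_NAMES",
    "CONTRASTS",
    "ALPHA",
    "RegressionFit",
    "EffectSizeResult",
    "RCSummary",
    "minmax_scale",
    "fit_regression",
    "pairwise_contrast",
    "rc_summary",
    "lower_median",
    "cohens_d",
    "classify_effect",
    "significance_tally",
    "analyze_stratum",
]

ALPHA = 0.05

# Dummy-variable names; reference levels are thickness 5.0, 30 mAs, lung kernel.
COEF_NAMES = ("thickness_2.5", "thickness_1.25", "mas_120", "kernel_standard")

# The five reported pairwise contrasts: (factor, level A, level B).
CONTRASTS = (
    ("thickness", 5.0, 2.5),
    ("thickness", 5.0, 1.25),
    ("thickness", 2.5, 1.25),
    ("mas", 30, 120),
    ("kernel", "lung", "standard"),
)


def contrast_label(contrast) -> str:
    _, a, b = contrast
    return f"{a}_vs_{b}"


@dataclass
class RegressionFit:
    """OLS fit of one feature on the dummy-coded design."""

    feature_name: str
    constant: float
    coefficients: dict[str, float]
    p_values: dict[str, float]
    cov_params: pd.DataFrame = field(repr=False)
    df_resid: float = 0.0
    reference_levels: dict = field(
        default_factory=lambda: {"thickness": 5.0, "mas": 30, "kernel": "lung"}
    )


@dataclass
class EffectSizeResult:
    """Cohen's d for one (feature, contrast) pair."""

    feature_name: str
    contrast: tuple
    d: float
    category: str          # none / small / medium / large
    direction: str         # '<', '>', '0'
    p_value: float


@dataclass
class RCSummary:
    """Max / median / min of |RC| over the 20 features for one contrast."""

    contrast: str
    max_abs: float
    median_abs: float
    min_abs: float


def _check_features(table: pd.DataFrame) -> None:
    missing = [f for f in FEATURE_NAMES if f not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    vals = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("feature table contains non-finite values")


def minmax_scale(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Scale each feature to [0, 1] by (x - min) / (max - min) over the table.

    Applied per density stratum so regression coefficients are comparable
    across features. Returns the scaled table and the per-feature (min, max)
    scaling constants. A constant feature column is an error (its scale is
    undefined).
    """
    _check_features(table)
    scaled = table.copy()
    constants: dict[str, tuple[float, float]] = {}
    for name in FEATURE_NAMES:
        col = table[name].to_numpy(dtype=float)
        lo, hi = float(col.min()), float(col.max())
        if hi == lo:
            raise ValueError(f"feature {name!r} is constant; cannot min-max scale")
        scaled[name] = (col - lo) / (hi - lo)
        constants[name] = (lo, hi)
    return scaled, constants


def design_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded design: intercept + 4 indicator columns."""
    for col in ("thickness_mm", "mas", "kernel"):
        if col not in table.columns:
            raise ValueError(f"feature table is missing covariate column {col!r}")
    X = pd.DataFrame(
        {
            "const": 1.0,
            "thickness_2.5": (table["thickness_mm"] == 2.5).astype(float),
            "thickness_1.25": (table["thickness_mm"] == 1.25).astype(float),
            "mas_120": (table["mas"] == 120).astype(float),
            "kernel_standard": (table["kernel"] == "standard").astype(float),
        },
        index=table.index,
    )
    return X


def fit_regression(table: pd.DataFrame, feature_name: str) -> RegressionFit:
    """OLS of one (scaled) feature on the dummy-coded scan parameters."""
    if feature_name not in table.columns:
        raise ValueError(f"unknown feature {feature_name!r}")
    X = design_matrix(table)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient (a protocol cell is missing)")
    y = table[feature_name].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    coefs = {k: float(res.params[k]) for k in COEF_NAMES}
    pvals = {k: float(res.pvalues[k]) for k in COEF_NAMES}
    return RegressionFit(
        feature_name=feature_name,
        constant=float(res.params["const"]),
        coefficients=coefs,
        p_values=pvals,
        cov_params=res.cov_params(),
        df_resid=float(res.df_resid),
    )


_LEVEL_COEF = {
    ("thickness", 5.0): None,
    ("thickness", 2.5): "thickness_2.5",
    ("thickness", 1.25): "thickness_1.25",
    ("mas", 30): None,
    ("mas", 120): "mas_120",
    ("kernel", "lung"): None,
    ("kernel", "standard"): "kernel_standard",
}


def pairwise_contrast(fit: RegressionFit, factor: str, level_a, level_b) -> tuple[float, float]:
    """RC and p-value for the A-vs-B comparison within one factor.

    Computed as the linear contrast coef(B) - coef(A) of the fitted dummy
    coefficients (a reference level has coefficient 0), with the t-test based
    on the contrast's standard error from the coefficient covariance. For a
    reference-level contrast this reduces exactly to the fitted coefficient
    and its OLS p-value.
    """
    if level_a == level_b:
        raise ValueError("contrast levels must differ")
    try:
        ca = _LEVEL_COEF[(factor, level_a)]
        cb = _LEVEL_COEF[(factor, level_b)]
    except KeyError as exc:
        raise ValueError(f"unknown factor/level: {exc}") from exc
    names = list(fit.cov_params.columns)
    vec = np.zeros(len(names))
    if cb is not None:
        vec[names.index(cb)] += 1.0
    if ca is not None:
        vec[names.index(ca)] -= 1.0
    full = {"const": fit.constant, **fit.coefficients}
    rc = float(sum(vec[i] * full[n] for i, n in enumerate(names)))
    var = float(vec @ fit.cov_params.to_numpy() @ vec)
    if var <= 0:
        return rc, 1.0 if rc == 0 else 0.0
    t = rc / np.sqrt(var)
    p = float(2.0 * sps.t.sf(abs(t), fit.df_resid))
    return rc, p


def lower_median(values) -> float:
    """The lower median: the n//2-th order statistic (1-based) for even n."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty input")
    return float(v[(n - 1) // 2])


def rc_summary(coefficients, contrast: str = "") -> RCSummary:
    """Max, lower median and min of |RC| over the 20 features of a contrast."""
    c = np.asarray(list(coefficients), dtype=float)
    if c.size != 20:
        raise ValueError(f"expected 20 coefficients, got {c.size}")
    a = np.abs(c)
    return RCSummary(
        contrast=contrast,
        max_abs=float(a.max()),
        median_abs=lower_median(a),
        min_abs=float(a.min()),
    )


def classify_effect(d: float) -> str:
    if d >= 0.80:
        return "large"
    if d >= 0.50:
        return "medium"
    if d >= 0.20:
        return "small"
    return "none"


def cohens_d(
    group_a, group_b, feature_name: str = "", contrast: tuple = ()
) -> EffectSizeResult:
    """Cohen's d with pooled SD, classified at 0.20 / 0.50 / 0.80.

    d = |m_A - m_B| / s_pooled, s_pooled the usual two-sample pooled SD.
    The direction symbol is '<' when A is significantly smaller than B by a
    Welch t-test at p <= 0.05, '>' when larger, '0' otherwise. A zero pooled
    SD yields d = 0 for identical means and d = inf otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    diff = a.mean() - b.mean()
    if pooled == 0:
        d = 0.0 if diff == 0 else float("inf")
        p = 1.0 if diff == 0 else 0.0
    else:
        d = float(abs(diff) / pooled)
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    if p <= ALPHA and diff < 0:
        direction = "<"
    elif p <= ALPHA and diff > 0:
        direction = ">"
    else:
        direction = "0"
    return EffectSizeResult(
        feature_name=feature_name,
        contrast=tuple(contrast),
        d=d,
        category=classify_effect(d),
        direction=direction,
        p_value=p,
    )


def significance_tally(p_table: pd.DataFrame) -> dict:
    """Count significant (feature, contrast) pairs at p <= 0.05.

    ``p_table``: 20 features (rows) x 5 contrasts (columns) of p-values.
    Returns per-contrast counts plus the total over the 100 comparison sets.
    """
    if list(p_table.index.sort_values()) != sorted(FEATURE_NAMES):
        raise ValueError("p_table must have exactly the 20 feature rows")
    if p_table.shape[1] != len(CONTRASTS):
        raise ValueError(f"p_table must have {len(CONTRASTS)} contrast columns")
    sig = p_table.le(ALPHA)
    per = {col: int(sig[col].sum()) for col in p_table.columns}
    per["total"] = int(sig.to_numpy().sum())
    per["n_comparison_sets"] = int(p_table.size)
    return per


def _factor_column(factor: str) -> str:
    return {"thickness": "thickness_mm", "mas": "mas", "kernel": "kernel"}[factor]


def analyze_stratum(table: pd.DataFrame) -> dict:
    """Full per-stratum analysis of a feature table.

    Runs the min-max scaling, the 20 regressions, the 5 pairwise contrasts
    per feature, the |RC| summaries, Cohen's d per (feature, contrast) with
    level groups pooled over the other factors, and the significance tallies.
    Returns a dict of DataFrames plus metadata (scaling constants,
    conventions).
    """
    scaled, constants = minmax_scale(table)

    coef_rows = []
    rc = {}
    pv = {}
    for name in FEATURE_NAMES:
        fit = fit_regression(scaled, name)
        row = {"feature": name, "constant": fit.constant}
        row.update(fit.coefficients)
        row.update({f"p_{k}": v for k, v in fit.p_values.items()})
        coef_rows.append(row)
        for contrast in CONTRASTS:
            lab = contrast_label(contrast)
            r, p = pairwise_contrast(fit, *contrast)
            rc.setdefault(lab, {})[name] = r
            pv.setdefault(lab, {})[name] = p
    coef_table = pd.DataFrame(coef_rows).set_index("feature")
    rc_table = pd.DataFrame(rc).loc[list(FEATURE_NAMES)]
    p_table = pd.DataFrame(pv).loc[list(FEATURE_NAMES)]

    holm = p_table.copy()
    from statsmodels.stats.multitest import multipletests

    flat = p_table.to_numpy().ravel()
    holm.loc[:, :] = multipletests(flat, method="holm")[1].reshape(p_table.shape)

    summaries = [
        rc_summary(rc_table[contrast_label(c)].to_numpy(), contrast=contrast_label(c))
        for c in CONTRASTS
    ]
    rc_summary_table = pd.DataFrame(
        [
            {"contrast": s.contrast, "max_abs": s.max_abs, "median_abs": s.median_abs,
             "min_abs": s.min_abs}
            for s in summaries
        ]
    ).set_index("contrast")

    effect_rows = []
    for contrast in CONTRASTS:
        factor, a, b = contrast
        col = _factor_column(factor)
        sel_a = scaled[col] == a
        sel_b = scaled[col] == b
        for name in FEATURE_NAMES:
            res = cohens_d(
                scaled.loc[sel_a, name], scaled.loc[sel_b, name],
                feature_name=name, contrast=contrast,
            )
            effect_rows.append(
                {
                    "feature": name,
                    "contrast": contrast_label(contrast),
                    "direction": res.direction,
                    "d": res.d,
                    "category": res.category,
                    "p_welch": res.p_value,
                }
            )
    effect_table = pd.DataFrame(effect_rows)

    tally = significance_tally(p_table)
    return {
        "coefficients": coef_table,
        "rc": rc_table,
        "p_values": p_table,
        "p_holm": holm,
        "rc_summaries": rc_summary_table,
        "effect_sizes": effect_table,
        "tally": tally,
        "scaling_constants": constants,
        "conventions": {
            "median_rule": "lower",
            "scaling": "minmax_per_stratum",
            "alpha": ALPHA,
            "direction_test": "welch",
            "multiplicity": "unadjusted (Holm column informational)",
        },
    }
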