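"""Technical-validation statistics: ROI sampling, CV summaries, ANOVA,
Welch t-tests and Benjamini-Hochberg adjustment.

Reproducibility is assessed on 3x3-pixel regions of interest (150 um
squares at 50 um pixels) rather than single pixels, and "unpaired t-test"
is realized as Welch's unequal-variance test — adipose versus merged
multi-tissue pixel groups have grossly unequal sizes and variances, making
the pooled-variance flavour inappropriate (it remains available via
``equal_var=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .io import TissueMask
from .preprocess import FeatureTable

__all__ = [
    "ROI",
    "CVSummary",
    "select_rois",
    "cv_percent",
    "cv_summary",
    "one_way_anova",
    "two_way_anova",
    "welch_t_test",
    "bh_adjust",
]

ROI_SIDE = 3  # pixels; 150 um at the 50 um acquisition pitch


@dataclass(frozen=True)
class ROI:
    """A 3x3 block of same-tissue pixels."""

    tissue: str
    pixels: tuple[int, ...]  # flat row-major indices
    replicate_id: str = ""

    def __post_init__(self):
        if len(self.pixels) != ROI_SIDE * ROI_SIDE:
            raise ValueError("an ROI is exactly 9 pixels")


@dataclass
class CVSummary:
    tissue: str
    per_feature_cv: np.ndarray  # percent
    frac_below_20: float
    frac_below_25: float


def select_rois(
    mask: TissueMask, label: str, n_rois: int, seed: int = 0,
) -> list[ROI]:
    """Sample disjoint 3x3 blocks fully inside a labeled region.

    Blocks are drawn uniformly (without replacement, greedily enforcing
    disjointness) from all fully-interior placements; deterministic per
    seed.  Raises if the region cannot host ``n_rois`` disjoint blocks,
    reporting how many were feasible.
    """
    h, w = mask.height, mask.width
    good = mask.labels == label
    corners = [
        (y, x)
        for y in range(h - ROI_SIDE + 1)
        for x in range(w - ROI_SIDE + 1)
        if good[y:y + ROI_SIDE, x:x + ROI_SIDE].all()
    ]
    rng = np.random.default_rng([seed, 0x401])
    rng.shuffle(corners)
    taken: list[tuple[int, int]] = []
    rois: list[ROI] = []
    for (y, x) in corners:
        if any(abs(y - ty) < ROI_SIDE and abs(x - tx) < ROI_SIDE
               for ty, tx in taken):
            continue
        taken.append((y, x))
        pixels = tuple(
            (y + dy) * w + (x + dx)
            for dy in range(ROI_SIDE) for dx in range(ROI_SIDE)
        )
        rois.append(ROI(tissue=label, pixels=pixels))
        if len(rois) == n_rois:
            return rois
    raise ValueError(
        f"region {label!r} supports only {len(rois)} disjoint "
        f"{ROI_SIDE}x{ROI_SIDE} ROIs (requested {n_rois})")


def cv_percent(values) -> float:
    """Coefficient of variation: 100 x sample SD (n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / m)


def cv_summary(table: FeatureTable, rois: list[ROI]) -> CVSummary:
    """Per-feature CV across ROI-mean intensities, with threshold fractions."""
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")
    tissues = {r.tissue for r in rois}
    if len(tissues) != 1:
        raise ValueError("ROIs must share one tissue label")
    roi_means = np.stack([
        table.matrix[:, list(r.pixels)].mean(axis=1) for r in rois
    ], axis=1)  # features x rois
    means = roi_means.mean(axis=1)
    sds = roi_means.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, 100.0 * sds / means, np.nan)
    valid = np.isfinite(cv)
    return CVSummary(
        tissue=tissues.pop(),
        per_feature_cv=cv,
        frac_below_20=float(np.mean(cv[valid] < 20.0)) if valid.any() else 0.0,
        frac_below_25=float(np.mean(cv[valid] < 25.0)) if valid.any() else 0.0,
    )


def one_way_anova(groups: list) -> tuple[float, float]:
    """Fixed-effects one-way ANOVA F and p over >= 2 groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:
        raise ValueError("all values identical: F undefined (0/0)")
    means = np.array([a.mean() for a in arrays])
    if np.ptp(means) == 0 and all(a.std() == 0 for a in arrays):
        raise ValueError("zero within- and between-group variance")
    f, p = sps.f_oneway(*arrays)
    if np.isnan(f):  # zero within-group variance, nonzero between
        return float("inf"), 0.0
    return float(f), float(p)


def two_way_anova(cells: dict) -> pd.DataFrame:
    """Balanced fixed-effects two-way ANOVA with interaction.

    ``cells`` maps ``(level_a, level_b)`` — e.g. (tissue, lipid) — to a list
    of replicate values; the design must be complete and balanced.  Returns
    a table with F and p for both factors and their interaction.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    sizes = {len(v) for v in cells.values()}
    if len(sizes) != 1 or sizes == {0}:
        raise ValueError("unbalanced design: equal replicates per cell required")
    a_levels = sorted({k[0] for k in cells})
    b_levels = sorted({k[1] for k in cells})
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("need >= 2 levels per factor")
    if set(cells) != {(a, b) for a in a_levels for b in b_levels}:
        raise ValueError("incomplete design: every (a, b) cell required")
    rows = [
        {"a": a, "b": b, "value": float(v)}
        for (a, b), vals in cells.items() for v in vals
    ]
    df = pd.DataFrame(rows)
    if df["value"].nunique() == 1:
        idx = ["C(a)", "C(b)", "C(a):C(b)"]
        return pd.DataFrame({"F": [0.0] * 3, "p": [1.0] * 3}, index=idx)
    model = ols("value ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = table.loc[["C(a)", "C(b)", "C(a):C(b)"], ["F", "PR(>F)"]]
    return out.rename(columns={"PR(>F)": "p"})


def welch_t_test(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided unpaired t-test, Welch/Satterthwaite by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
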