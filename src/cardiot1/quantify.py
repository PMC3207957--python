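"""Regional statistics and contrast-agent quantification.

Per-segment R1 means and ΔR1 (difference of segment means), wall-thickening
based tissue classification, ex vivo Gd mass → concentration conversion,
aggregation of mid-level AHA segments into the four ex vivo cutting sectors,
Pearson correlation with per-slice averaging, Deming (orthogonal,
errors-in-variables) regression yielding the effective in vivo relaxivity,
and one-way ANOVA with post-hoc Tukey comparison of tissue classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .relaxometry import RelaxationMap

__all__ = [
    "GdMeasurement",
    "DemingFit",
    "GroupComparison",
    "SWT_INFARCT_MAX",
    "SWT_REMOTE_MIN",
    "regional_means",
    "classify_tissue",
    "gd_concentration",
    "build_regional_table",
    "sectors_from_segments",
    "orthogonal_regression",
    "correlate",
    "compare_groups",
]

# Wall-thickening classification thresholds (%), strict inequalities:
# SWT < 15 -> infarct, SWT > 45 -> remote, otherwise intermediate.
SWT_INFARCT_MAX = 15.0
SWT_REMOTE_MIN = 45.0

GD_MOLAR_MASS_G_MOL = 157.25
TISSUE_DENSITY_G_ML = 1.05

# Angular spans of the four ex vivo cutting sectors, in degrees relative to
# the anterior RV-insertion anchor (counterclockwise viewed from apex).
# "posterior" of the cutting protocol corresponds to AHA "inferior".
EXVIVO_SECTORS = {
    "anterior": (315.0, 45.0),
    "septal": (45.0, 135.0),
    "posterior": (135.0, 225.0),
    "lateral": (225.0, 315.0),
}


@dataclass
class GdMeasurement:
    """One ex vivo sector: Gd mass (ng) and tissue mass (mg) from ICP-MS."""

    sector_id: str
    gd_mass_ng: float
    tissue_mass_mg: float

    def __post_init__(self) -> None:
        if self.gd_mass_ng < 0:
            raise ValueError("gd_mass_ng must be nonnegative")
        if self.tissue_mass_mg < 0:
            raise ValueError("tissue_mass_mg must be nonnegative")

    @property
    def gd_concentration_mM(self) -> float:
        return gd_concentration(self.gd_mass_ng, self.tissue_mass_mg)


@dataclass
class DemingFit:
    """Deming regression result: slope is the effective relaxivity when y is
    ΔR1 (s⁻¹) and x is concentration (mM)."""

    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    slope_ci: tuple
    intercept_ci: tuple
    variance_ratio: float
    n: int
    degenerate: bool = False


@dataclass
class GroupComparison:
    """One-way ANOVA F/p plus pairwise Tukey HSD p-values."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha: float = 0.05


def regional_means(relax: RelaxationMap, segmentation) -> pd.DataFrame:
    """Arithmetic mean of valid voxels of a map per AHA segment.

    Returns a table with columns segment_id, mean, n_voxels; segments whose
    valid-voxel count is zero get NaN means and are flagged via n_voxels=0.
    """
    labels = segmentation.segment_id
    if labels.shape != relax.value.shape:
        raise ValueError("map and segmentation are on different grids")
    rows = []
    for seg in segmentation.segment_table["segment_id"]:
        sel = (labels == seg) & relax.valid_mask & np.isfinite(relax.value)
        n = int(sel.sum())
        rows.append((int(seg), float(relax.value[sel].mean()) if n else np.nan, n))
    return pd.DataFrame(rows, columns=["segment_id", "mean", "n_voxels"])


def classify_tissue(swt):
    """Classify by systolic wall thickening: <15% infarct, >45% remote,
    otherwise intermediate (boundary values are intermediate); NaN -> None."""

    def one(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        if v < SWT_INFARCT_MAX:
            return "infarct"
        if v > SWT_REMOTE_MIN:
            return "remote"
        return "intermediate"

    if np.isscalar(swt) or swt is None:
        return one(swt)
    return [one(float(v)) if v is not None and np.isfinite(v) else None for v in np.asarray(swt, dtype=float)]


def gd_concentration(gd_mass_ng: float, tissue_mass_mg: float) -> float:
    """Convert a Gd mass in a weighed tissue piece to concentration in mM.

    volume_µl = tissue_mg / 1.05 (myocardial specific gravity, g/ml);
    amount_nmol = gd_ng / 157.25 (Gd molar mass, g/mol);
    concentration = nmol/µl = mM.
    """
    if tissue_mass_mg <= 0:
        raise ValueError("tissue_mass_mg must be positive")
    if gd_mass_ng < 0:
        raise ValueError("gd_mass_ng must be nonnegative")
    return (gd_mass_ng / GD_MOLAR_MASS_G_MOL) / (tissue_mass_mg / TISSUE_DENSITY_G_ML)


def build_regional_table(
    r1_pre_means: pd.DataFrame,
    r1_post_means: pd.DataFrame,
    swt: pd.DataFrame,
    animal_id: str = "phantom",
) -> pd.DataFrame:
    """Join per-segment pre/post R1 means with wall thickening into the
    regional table: ΔR1 is the difference of segment means, and the tissue
    class follows the wall-thickening thresholds."""
    pre = r1_pre_means.rename(columns={"mean": "mean_r1_pre"})
    post = r1_post_means.rename(columns={"mean": "mean_r1_post", "n_voxels": "n_voxels_post"})
    tab = pre.merge(post, on="segment_id").merge(
        swt[["segment_id", "wt_ed_mm", "wt_es_mm", "swt_percent"]], on="segment_id", how="left"
    )
    tab["delta_r1"] = tab["mean_r1_post"] - tab["mean_r1_pre"]
    tab["tissue_class"] = classify_tissue(tab["swt_percent"].to_numpy())
    tab.insert(0, "animal_id", animal_id)
    return tab


def _span_overlap_deg(a, b):
    """Overlap in degrees of two circular spans given as (start, end) with
    end possibly < start (wrap through 0)."""

    def unroll(s, e):
        return [(s, e)] if s <= e else [(s, 360.0), (0.0, e)]

    total = 0.0
    for s1, e1 in unroll(*a):
        for s2, e2 in unroll(*b):
            total += max(0.0, min(e1, e2) - max(s1, s2))
    return total


def sectors_from_segments(table: pd.DataFrame, segmentation, level: str = "mid", value: str = "delta_r1") -> pd.DataFrame:
    """Aggregate the mid-level AHA segments into the 4 ex vivo sectors.

    Each 60° segment contributes to each 90° sector in proportion to its
    angular overlap, weighted by its voxel count; the sector value is the
    resulting weighted mean.  Sectors with no contributing segment are NaN.
    """
    seg_tab = segmentation.segment_table
    level_ids = seg_tab.loc[seg_tab["level"] == level, "segment_id"].tolist()
    rows = []
    for name, span in EXVIVO_SECTORS.items():
        w_sum = 0.0
        v_sum = 0.0
        for seg in level_ids:
            row = table.loc[table["segment_id"] == seg]
            if row.empty or not np.isfinite(row[value].iloc[0]):
                continue
            srow = seg_tab.loc[seg_tab["segment_id"] == seg].iloc[0]
            overlap = _span_overlap_deg((srow["span_start_deg"], srow["span_end_deg"]), span)
            if overlap <= 0:
                continue
            seg_width = (srow["span_end_deg"] - srow["span_start_deg"]) % 360.0 or 360.0
            w = row["n_voxels"].iloc[0] * overlap / seg_width
            w_sum += w
            v_sum += w * row[value].iloc[0]
        rows.append((name, v_sum / w_sum if w_sum > 0 else np.nan, w_sum))
    return pd.DataFrame(rows, columns=["sector_id", value, "weight"])


def orthogonal_regression(x, y, variance_ratio: float = 1.0, ci_level: float = 0.95) -> DemingFit:
    """Deming (orthogonal) regression of y on x with error-variance ratio λ.

    λ = Var(y-errors)/Var(x-errors); λ = 1 is classical orthogonal / total
    least squares, λ → ∞ recovers ordinary least squares of y on x.  The
    slope is the closed form

        β = [s_yy − λ·s_xx + √((s_yy − λ·s_xx)² + 4λ·s_xy²)] / (2·s_xy),

    the intercept ȳ − β·x̄.  Confidence intervals come from a leave-one-out
    jackknife.  Pearson r / R² of the raw (x, y) pairs are attached.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x values must not all be equal")
    lam = float(variance_ratio)
    if lam <= 0:
        raise ValueError("variance_ratio must be positive")

    def deming_slope_intercept(xv, yv):
        xm, ym = xv.mean(), yv.mean()
        sxx = np.sum((xv - xm) ** 2)
        syy = np.sum((yv - ym) ** 2)
        sxy = np.sum((xv - xm) * (yv - ym))
        if sxy == 0:
            if np.isclose(syy, lam * sxx):
                return np.nan, np.nan  # direction undetermined
            # axis-aligned solutions: pick the principal direction
            slope = 0.0 if syy < lam * sxx else np.inf
            return slope, ym - slope * xm if np.isfinite(slope) else np.nan
        slope = (syy - lam * sxx + np.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (2 * sxy)
        return slope, ym - slope * xm

    slope, intercept = deming_slope_intercept(x, y)
    degenerate = not np.isfinite(slope)

    r, _ = stats.pearsonr(x, y)

    if degenerate or n < 4:
        ci_s = (np.nan, np.nan)
        ci_i = (np.nan, np.nan)
    else:
        js = np.empty(n)
        ji = np.empty(n)
        keep = np.ones(n, dtype=bool)
        for i in range(n):
            keep[i] = False
            js[i], ji[i] = deming_slope_intercept(x[keep], y[keep])
            keep[i] = True
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, n - 1)
        se_s = np.sqrt((n - 1) / n * np.sum((js - js.mean()) ** 2))
        se_i = np.sqrt((n - 1) / n * np.sum((ji - ji.mean()) ** 2))
        ci_s = (slope - tcrit * se_s, slope + tcrit * se_s)
        ci_i = (intercept - tcrit * se_i, intercept + tcrit * se_i)

    return DemingFit(
        slope=float(slope),
        intercept=float(intercept),
        pearson_r=float(r),
        r_squared=float(r**2),
        slope_ci=ci_s,
        intercept_ci=ci_i,
        variance_ratio=lam,
        n=int(n),
        degenerate=degenerate,
    )


def correlate(x, y, groups=None):
    """Pearson correlation of (x, y), optionally after within-group averaging.

    ``groups`` (e.g. an (animal, slice) key per point) triggers the
    per-slice mode: x and y are averaged within each group (unweighted over
    the sectors of the slice) before correlating.  Returns (r, r²).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if groups is not None:
        df = pd.DataFrame({"g": list(groups), "x": x, "y": y})
        agg = df.groupby("g", sort=False).mean()
        x, y = agg["x"].to_numpy(), agg["y"].to_numpy()
    if x.size < 3:
        raise ValueError("need at least 3 points after grouping")
    r, _ = stats.pearsonr(x, y)
    return float(r), float(r**2)


def compare_groups(groups: dict, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA and post-hoc Tukey HSD across tissue groups.

    Intended for R1-scale values (rates, not times).  ``groups`` maps group
    name (e.g. infarct / remote / control) to a 1-D array of values.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                (
                    names[i],
                    names[j],
                    float(arrays[i].mean() - arrays[j].mean()),
                    float(hsd.pvalue[i, j]),
                    bool(hsd.pvalue[i, j] < alpha),
                )
            )
    tukey = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p_value", "significant"])
    return GroupComparison(f_statistic=float(f), p_value=float(p), tukey=tukey, alpha=alpha)
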