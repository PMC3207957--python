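"""LV geometry: AHA 17-segment labelling and wall-thickness measurement.

Angle convention (documented once, used everywhere): short-axis slices are
viewed from the apex; angles increase counterclockwise; 0° is the anterior
RV-insertion anchor.  Proceeding from the anchor the 60° sectors of the
basal and mid levels are anterior, anteroseptal, inferoseptal, inferior,
inferolateral, anterolateral; the apical level has four 90° sectors
(anterior, septal, inferior, lateral) with boundaries at 45°, 135°, 225°,
315°.  "Posterior" in the ex vivo cutting protocol corresponds to AHA
"inferior".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LVMask",
    "AHASegmentation",
    "WallMeasure",
    "lv_centerline",
    "aha17_labels",
    "wall_thickness",
    "systolic_wall_thickening",
]

BACKGROUND, BLOOD_POOL, MYOCARDIUM = 0, 1, 2

BASAL_MID_NAMES = ["anterior", "anteroseptal", "inferoseptal", "inferior", "inferolateral", "anterolateral"]
APICAL_NAMES = ["apical anterior", "apical septal", "apical inferior", "apical lateral"]
APICAL_OFFSET_DEG = -45.0  # apical 90° sectors are centred on the cardinal walls


@dataclass
class LVMask:
    """Label volume {0 background, 1 blood pool, 2 myocardium} for one
    cardiac phase, with voxel spacing and the anterior RV-insertion anchor
    angle that fixes the segment frame."""

    labels: np.ndarray
    phase: str  # "ED" or "ES"
    spacing_mm: tuple = (0.1, 0.1, 0.5)
    long_axis: int = 2
    rv_insertion_angle_deg: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.long_axis != 2:
            raise NotImplementedError("short-axis stacks with long_axis=2 only")
        if not np.any(self.labels == MYOCARDIUM):
            raise ValueError("mask contains no myocardium")


@dataclass
class AHASegmentation:
    """Per-voxel AHA segment ids (1–17; 0 outside myocardium) plus the
    per-slice level assignment and a segment lookup table with angular
    spans (degrees relative to the anchor)."""

    segment_id: np.ndarray
    slice_levels: dict  # z index -> "basal"|"mid"|"apical"|"apex"
    segment_table: pd.DataFrame
    rv_insertion_angle_deg: float
    centroids: dict = field(default_factory=dict)  # z -> (x_mm, y_mm)


@dataclass
class WallMeasure:
    """Per-segment wall thickness for one phase (table columns:
    segment_id, wt_mm, n_rays); segments with < 3 contributing rays are NaN."""

    table: pd.DataFrame
    phase: str
    n_rays: int


def _slice_grid_mm(shape, spacing):
    nx, ny = shape
    dx, dy = spacing[0], spacing[1]
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    return x, y


def _is_annular(myo2d, cx_idx, cy_idx, n_bins: int = 36) -> bool:
    """A slice is acceptable if its myocardium covers the full angular range
    around the centroid (annulus or solid apex disk); a crescent leaves an
    angular gap and is rejected."""
    ii, jj = np.nonzero(myo2d)
    theta = np.degrees(np.arctan2(jj - cy_idx, ii - cx_idx)) % 360.0
    hist, _ = np.histogram(theta, bins=n_bins, range=(0, 360))
    return bool(np.all(hist > 0))


def lv_centerline(mask: LVMask):
    """Per-slice LV center in mm coordinates (grid-centered frame).

    The centroid of the blood pool is used where present, otherwise the
    centroid of the cavity enclosed by the myocardium; for solid (apex)
    slices the myocardium centroid itself.  Slices whose myocardium is not
    a closed annulus/disk (e.g. a crescent) are flagged and excluded.
    Returns (centroids, flagged): dicts/lists keyed by slice index.
    """
    labels = mask.labels
    x, y = _slice_grid_mm(labels.shape[:2], mask.spacing_mm)
    centroids: dict[int, tuple] = {}
    flagged: list[int] = []
    for z in range(labels.shape[2]):
        myo = labels[:, :, z] == MYOCARDIUM
        if not myo.any():
            continue
        blood = labels[:, :, z] == BLOOD_POOL
        if blood.any():
            ii, jj = np.nonzero(blood)
        else:
            cavity = ndimage.binary_fill_holes(myo) & ~myo
            ii, jj = np.nonzero(cavity if cavity.any() else myo)
        ci, cj = ii.mean(), jj.mean()
        if not _is_annular(myo, ci, cj):
            flagged.append(z)
            continue
        centroids[z] = (float(np.interp(ci, np.arange(x.size), x)), float(np.interp(cj, np.arange(y.size), y)))
    return centroids, flagged


def _relative_angle(theta_deg, anchor_deg):
    return (theta_deg - anchor_deg) % 360.0


def aha17_labels(mask: LVMask) -> AHASegmentation:
    """AHA 17-segment labels from an LV mask.

    Slices containing a blood pool are split base→apex into thirds by slice
    count (remainder assigned basally): basal and mid levels get six 60°
    segments each, the apical level four 90° segments; the most apical
    slice(s) without blood pool form segment 17 (apex).  Apex is taken as
    the end of the stack adjacent to the solid (no blood pool) slices; for
    a stack without such slices the lower slice index is treated as apical.
    """
    if mask.rv_insertion_angle_deg is None or not np.isfinite(mask.rv_insertion_angle_deg):
        raise ValueError("rv_insertion_angle_deg is not set; supply the anterior RV-insertion anchor")
    labels = mask.labels
    centroids, flagged = lv_centerline(mask)

    has_myo = [z for z in range(labels.shape[2]) if (labels[:, :, z] == MYOCARDIUM).any()]
    annular = [z for z in has_myo if z in centroids and (labels[:, :, z] == BLOOD_POOL).any()]
    solid = [z for z in has_myo if z in centroids and not (labels[:, :, z] == BLOOD_POOL).any()]
    if len(annular) < 3:
        raise ValueError(f"need >= 3 annular LV slices, found {len(annular)}")

    # apex side: the end where the solid slices sit
    apex_low = True
    if solid:
        apex_low = bool(np.mean(solid) < np.mean(annular))
    order = sorted(annular, reverse=apex_low)  # base -> apex

    q, r = divmod(len(order), 3)
    n_basal = q + (1 if r > 0 else 0)
    n_mid = q + (1 if r > 1 else 0)
    slice_levels: dict[int, str] = {}
    for i, z in enumerate(order):
        slice_levels[z] = "basal" if i < n_basal else ("mid" if i < n_basal + n_mid else "apical")
    for z in solid:
        slice_levels[z] = "apex"

    x, y = _slice_grid_mm(labels.shape[:2], mask.spacing_mm)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    anchor = float(mask.rv_insertion_angle_deg)

    seg = np.zeros(labels.shape, dtype=np.int16)
    for z, level in slice_levels.items():
        myo = labels[:, :, z] == MYOCARDIUM
        if level == "apex":
            seg[:, :, z][myo] = 17
            continue
        cx, cy = centroids[z]
        theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
        rel = _relative_angle(theta, anchor)
        if level == "basal":
            ids = 1 + np.minimum((rel // 60.0).astype(int), 5)
        elif level == "mid":
            ids = 7 + np.minimum((rel // 60.0).astype(int), 5)
        else:  # apical
            rel_a = (rel - APICAL_OFFSET_DEG) % 360.0
            ids = 13 + np.minimum((rel_a // 90.0).astype(int), 3)
        seg[:, :, z][myo] = ids[myo]

    rows = []
    for i, name in enumerate(BASAL_MID_NAMES):
        rows.append((1 + i, f"basal {name}", "basal", i * 60.0, (i + 1) * 60.0))
    for i, name in enumerate(BASAL_MID_NAMES):
        rows.append((7 + i, f"mid {name}", "mid", i * 60.0, (i + 1) * 60.0))
    for i, name in enumerate(APICAL_NAMES):
        start = (APICAL_OFFSET_DEG + i * 90.0) % 360.0
        rows.append((13 + i, name, "apical", start, (start + 90.0) % 360.0))
    rows.append((17, "apex", "apex", 0.0, 360.0))
    table = pd.DataFrame(rows, columns=["segment_id", "name", "level", "span_start_deg", "span_end_deg"])

    return AHASegmentation(
        segment_id=seg,
        slice_levels=slice_levels,
        segment_table=table,
        rv_insertion_angle_deg=anchor,
        centroids=centroids,
    )


def _segment_for_ray(level: str, rel_deg: float) -> int | None:
    if level == "basal":
        return 1 + min(int(rel_deg // 60.0), 5)
    if level == "mid":
        return 7 + min(int(rel_deg // 60.0), 5)
    if level == "apical":
        return 13 + min(int(((rel_deg - APICAL_OFFSET_DEG) % 360.0) // 90.0), 3)
    return None  # apex: no annulus, thickness undefined


def wall_thickness(mask: LVMask, segmentation: AHASegmentation, n_rays: int = 360) -> WallMeasure:
    """Radial ray-cast wall thickness per AHA segment for one phase.

    From each annular slice's center, ``n_rays`` equally spaced rays are
    cast; along a ray the wall thickness is the chord from the endocardial
    entry to the epicardial exit of the myocardium (nearest-voxel sampling
    at a quarter-voxel step).  Rays are assigned to segments by their angle
    and the slice's level — the same convention that produced the labels —
    and each segment reports the mean over its rays across its slices.
    Rays that never meet myocardium are excluded; segments with fewer than
    3 contributing rays are flagged (NaN).  The apex (17) has no annulus
    and is not measured.
    """
    labels = mask.labels
    dx, dy = mask.spacing_mm[0], mask.spacing_mm[1]
    step = min(dx, dy) / 4.0
    x, y = _slice_grid_mm(labels.shape[:2], mask.spacing_mm)
    r_max = float(np.hypot(x[-1] - x[0], y[-1] - y[0])) / 2.0
    radii = np.arange(step / 2.0, r_max, step)
    anchor = segmentation.rv_insertion_angle_deg

    per_segment: dict[int, list] = {int(s): [] for s in segmentation.segment_table["segment_id"]}
    centroids, _ = lv_centerline(mask)

    for z, level in segmentation.slice_levels.items():
        if level == "apex" or z not in centroids:
            continue
        if z >= labels.shape[2] or not (labels[:, :, z] == MYOCARDIUM).any():
            continue
        cx, cy = centroids[z]
        sl = labels[:, :, z]
        for k in range(n_rays):
            theta = 360.0 * k / n_rays
            seg_id = _segment_for_ray(level, _relative_angle(theta, anchor))
            if seg_id is None:
                continue
            t = np.deg2rad(theta)
            px = cx + radii * np.cos(t)
            py = cy + radii * np.sin(t)
            ix = np.round((px - x[0]) / dx).astype(int)
            iy = np.round((py - y[0]) / dy).astype(int)
            inside = (ix >= 0) & (ix < sl.shape[0]) & (iy >= 0) & (iy < sl.shape[1])
            hit = np.zeros(radii.shape, dtype=bool)
            hit[inside] = sl[ix[inside], iy[inside]] == MYOCARDIUM
            if not hit.any():
                continue
            first, last = np.flatnonzero(hit)[[0, -1]]
            wt = radii[last] - radii[first] + step
            per_segment[seg_id].append(wt)

    rows = []
    for seg_id, vals in per_segment.items():
        if len(vals) >= 3:
            rows.append((seg_id, float(np.mean(vals)), len(vals)))
        else:
            rows.append((seg_id, np.nan, len(vals)))
    table = pd.DataFrame(rows, columns=["segment_id", "wt_mm", "n_rays"])
    return WallMeasure(table=table, phase=mask.phase, n_rays=n_rays)


def systolic_wall_thickening(ed: WallMeasure, es: WallMeasure) -> pd.DataFrame:
    """SWT per segment: (WT_ES / WT_ED − 1) · 100%.

    Missing segments (NaN wall thickness in either phase, or WT_ED = 0)
    propagate as NaN rather than raising.
    """
    tab = ed.table.rename(columns={"wt_mm": "wt_ed_mm", "n_rays": "n_rays_ed"}).merge(
        es.table.rename(columns={"wt_mm": "wt_es_mm", "n_rays": "n_rays_es"}), on="segment_id"
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        swt = (tab["wt_es_mm"] / tab["wt_ed_mm"] - 1.0) * 100.0
    swt[tab["wt_ed_mm"] <= 0] = np.nan
    tab["swt_percent"] = swt
    return tab
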